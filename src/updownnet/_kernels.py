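"""Numba-compiled integration kernels.

The network kernel advances all neurons with the stochastic Heun scheme
(the same Wiener increment enters predictor and corrector; for additive
noise the Ito and Stratonovich readings coincide).  Spikes are detected at
the end of a step (``v >= v_peak``), the trace sample at that instant is
clamped to ``v_peak``, the fire-and-reset rule is applied, and conductance
jumps on the postsynaptic targets are delivered at the next step.

These kernels are an implementation detail; their dynamics are pinned to
the pure-Python operations in :mod:`updownnet.neurons` and
:mod:`updownnet.synapses` by equivalence tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_BLOWUP = 1

_V_SANITY = 500.0  # |v| beyond this aborts the run with a diagnostic


@njit(cache=False)
def _rhs_v(kind, v, u, alpha, beta, gamma, gL, DeltaT, vT, EL, offset):
    if kind == 0:  # izhikevich
        return alpha * v * v + beta * v + gamma - u
    # adex
    return (
        -gL * (v - EL)
        + gL * DeltaT * np.exp((v - vT) / DeltaT)
        + offset
        - u
    )


@njit(cache=False)
def integrate_network(
    kind,  # 0 izhikevich, 1 adex
    a, b, c, d, EL,  # per-neuron (EL only used by adex; == c)
    alpha, beta, gamma, v_peak,
    gL, DeltaT, vT, offset,
    E_ex, E_in, tau_ex, tau_in,
    g_ex_inc, g_in_inc,
    sig_ex, sig_in,  # per-neuron noise amplitudes sqrt(2 D n) * sqrt(dt)
    indptr, targets, is_exc,
    stim_amp, t_stim,
    v, u, gex, gin,  # initial state, modified in place
    dt, n_steps, rec_every,
    rec_ids,
    seed,
    reflect,
    stop_silent_steps,  # 0 disables; only meaningful for D = 0
):
    np.random.seed(seed)
    N = v.shape[0]
    n_rec_ids = rec_ids.shape[0]
    n_rec = n_steps // rec_every + 1

    t_rec = np.empty(n_rec)
    mean_v = np.empty(n_rec)
    mean_u = np.empty(n_rec)
    mean_gex = np.empty(n_rec)
    mean_gin = np.empty(n_rec)
    sub_v = np.empty((n_rec, n_rec_ids))
    sub_u = np.empty((n_rec, n_rec_ids))
    sub_gex = np.empty((n_rec, n_rec_ids))
    sub_gin = np.empty((n_rec, n_rec_ids))

    cap = 1 << 16
    spike_t = np.empty(cap)
    spike_id = np.empty(cap, dtype=np.int64)
    n_spk = 0
    n_resets = 0

    pend_ex = np.zeros(N)
    pend_in = np.zeros(N)

    # record initial sample
    t_rec[0] = 0.0
    mean_v[0] = np.mean(v)
    mean_u[0] = np.mean(u)
    mean_gex[0] = np.mean(gex)
    mean_gin[0] = np.mean(gin)
    for m in range(n_rec_ids):
        j = rec_ids[m]
        sub_v[0, m] = v[j]
        sub_u[0, m] = u[j]
        sub_gex[0, m] = gex[j]
        sub_gin[0, m] = gin[j]

    status = STATUS_OK
    noisy = False
    for j in range(N):
        if sig_ex[j] > 0.0 or sig_in[j] > 0.0:
            noisy = True
            break
    last_spike_step = -1

    for step in range(n_steps):
        t = step * dt
        t_next = t + dt

        # deliver conductance jumps queued by spikes of the previous step
        for j in range(N):
            if pend_ex[j] != 0.0:
                gex[j] += pend_ex[j]
                pend_ex[j] = 0.0
            if pend_in[j] != 0.0:
                gin[j] += pend_in[j]
                pend_in[j] = 0.0

        if noisy:
            zx = np.random.standard_normal(N)
            zi = np.random.standard_normal(N)
        else:
            zx = np.zeros(N)
            zi = np.zeros(N)

        stim_on = t < t_stim
        stim_on_next = t_next < t_stim

        for j in range(N):
            wex = sig_ex[j] * zx[j]
            win = sig_in[j] * zi[j]
            vj = v[j]
            uj = u[j]
            gxe = gex[j]
            gxi = gin[j]

            Iext1 = stim_amp[j] if stim_on else 0.0
            Isyn1 = gxe * (E_ex - vj) + gxi * (E_in - vj)
            dv1 = _rhs_v(kind, vj, uj, alpha, beta, gamma, gL, DeltaT, vT, EL[j], offset) + Isyn1 + Iext1
            du1 = a[j] * (b[j] * vj - uj)
            dgx1 = -gxe / tau_ex
            dgi1 = -gxi / tau_in

            vp = vj + dt * dv1
            up = uj + dt * du1
            gxp = gxe + dt * dgx1 + wex
            gip = gxi + dt * dgi1 + win

            Iext2 = stim_amp[j] if stim_on_next else 0.0
            Isyn2 = gxp * (E_ex - vp) + gip * (E_in - vp)
            dv2 = _rhs_v(kind, vp, up, alpha, beta, gamma, gL, DeltaT, vT, EL[j], offset) + Isyn2 + Iext2
            du2 = a[j] * (b[j] * vp - up)
            dgx2 = -gxp / tau_ex
            dgi2 = -gip / tau_in

            v[j] = vj + 0.5 * dt * (dv1 + dv2)
            u[j] = uj + 0.5 * dt * (du1 + du2)
            gex[j] = gxe + 0.5 * dt * (dgx1 + dgx2) + wex
            gin[j] = gxi + 0.5 * dt * (dgi1 + dgi2) + win
            if reflect:
                gex[j] = abs(gex[j])
                gin[j] = abs(gin[j])

        # spike detection: clamp to v_peak for the recorded sample
        for j in range(N):
            if v[j] >= v_peak or not np.isfinite(v[j]):
                if not np.isfinite(v[j]) or v[j] > _V_SANITY:
                    # quadratic/exponential blow-up within one step is
                    # handled by the reset; non-finite values abort
                    if not np.isfinite(v[j]):
                        status = STATUS_BLOWUP
                v[j] = v_peak
            elif v[j] < -_V_SANITY:
                status = STATUS_BLOWUP

        if status != STATUS_OK:
            return (
                status, spike_t[:n_spk], spike_id[:n_spk], n_resets,
                t_rec, mean_v, mean_u, mean_gex, mean_gin,
                sub_v, sub_u, sub_gex, sub_gin,
            )

        if (step + 1) % rec_every == 0:
            r = (step + 1) // rec_every
            t_rec[r] = t_next
            mean_v[r] = np.mean(v)
            mean_u[r] = np.mean(u)
            mean_gex[r] = np.mean(gex)
            mean_gin[r] = np.mean(gin)
            for m in range(n_rec_ids):
                j = rec_ids[m]
                sub_v[r, m] = v[j]
                sub_u[r, m] = u[j]
                sub_gex[r, m] = gex[j]
                sub_gin[r, m] = gin[j]

        # reset + enqueue jumps for the next step
        for j in range(N):
            if v[j] >= v_peak:
                if n_spk >= cap:
                    new_cap = cap * 2
                    new_t = np.empty(new_cap)
                    new_i = np.empty(new_cap, dtype=np.int64)
                    new_t[:cap] = spike_t
                    new_i[:cap] = spike_id
                    spike_t = new_t
                    spike_id = new_i
                    cap = new_cap
                spike_t[n_spk] = t_next
                spike_id[n_spk] = j
                n_spk += 1
                v[j] = c[j]
                u[j] += d[j]
                n_resets += 1
                last_spike_step = step
                if is_exc[j]:
                    for k in range(indptr[j], indptr[j + 1]):
                        pend_ex[targets[k]] += g_ex_inc
                else:
                    for k in range(indptr[j], indptr[j + 1]):
                        pend_in[targets[k]] += g_in_inc

        # a noiseless, unstimulated network with no recent spikes and fully
        # decayed conductances can never fire again: freeze and return early
        if (
            stop_silent_steps > 0
            and not noisy
            and not stim_on_next
            and step - last_spike_step >= stop_silent_steps
            and (step + 1) % rec_every == 0
        ):
            g_max = 0.0
            for j in range(N):
                if gex[j] > g_max:
                    g_max = gex[j]
                if gin[j] > g_max:
                    g_max = gin[j]
            if g_max < 1e-10:
                r0 = (step + 1) // rec_every
                for r in range(r0 + 1, n_rec):
                    t_rec[r] = r * rec_every * dt
                    mean_v[r] = mean_v[r0]
                    mean_u[r] = mean_u[r0]
                    mean_gex[r] = mean_gex[r0]
                    mean_gin[r] = mean_gin[r0]
                    for m in range(n_rec_ids):
                        sub_v[r, m] = sub_v[r0, m]
                        sub_u[r, m] = sub_u[r0, m]
                        sub_gex[r, m] = sub_gex[r0, m]
                        sub_gin[r, m] = sub_gin[r0, m]
                break

    return (
        status, spike_t[:n_spk], spike_id[:n_spk], n_resets,
        t_rec, mean_v, mean_u, mean_gex, mean_gin,
        sub_v, sub_u, sub_gex, sub_gin,
    )


@njit(cache=False)
def first_spike_trials(
    kind,
    a, b, v_peak,
    alpha, beta, gamma,
    gL, DeltaT, vT, EL, offset,
    E_ex, E_in, tau_ex, tau_in,
    sig,  # sqrt(2 D n) * sqrt(dt), same for both conductances
    v0, u0,
    dt, max_steps, n_trials,
    seed,
):
    """First passage of v to v_peak for an isolated neuron, per trial.

    The neuron starts at rest with zero conductances; both conductances
    fluctuate as reflected OU processes with no presynaptic input.
    Censored trials (no spike within ``max_steps``) return NaN.
    """
    np.random.seed(seed)
    out = np.empty(n_trials)
    for trial in range(n_trials):
        v = v0
        u = u0
        gx = 0.0
        gi = 0.0
        out[trial] = np.nan
        for step in range(max_steps):
            wex = sig * np.random.normal(0.0, 1.0)
            win = sig * np.random.normal(0.0, 1.0)

            Isyn1 = gx * (E_ex - v) + gi * (E_in - v)
            dv1 = _rhs_v(kind, v, u, alpha, beta, gamma, gL, DeltaT, vT, EL, offset) + Isyn1
            du1 = a * (b * v - u)
            dgx1 = -gx / tau_ex
            dgi1 = -gi / tau_in

            vp = v + dt * dv1
            up = u + dt * du1
            gxp = gx + dt * dgx1 + wex
            gip = gi + dt * dgi1 + win

            Isyn2 = gxp * (E_ex - vp) + gip * (E_in - vp)
            dv2 = _rhs_v(kind, vp, up, alpha, beta, gamma, gL, DeltaT, vT, EL, offset) + Isyn2 + 0.0
            du2 = a * (b * vp - up)
            dgx2 = -gxp / tau_ex
            dgi2 = -gip / tau_in

            v = v + 0.5 * dt * (dv1 + dv2)
            u = u + 0.5 * dt * (du1 + du2)
            gx = abs(gx + 0.5 * dt * (dgx1 + dgx2) + wex)
            gi = abs(gi + 0.5 * dt * (dgi1 + dgi2) + win)

            if v >= v_peak:
                out[trial] = (step + 1) * dt
                break
    return out
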