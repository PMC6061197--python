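"""Isolated-neuron first-spike times and phase-plane trajectory extraction.

An isolated neuron at rest with purely stochastic synaptic conductances
(reflected OU processes, no presynaptic input) fires once a conductance
fluctuation pushes the instantaneous current past the rest-destroying
threshold; the mean time to the first spike as a function of the noise
intensity D is a Monte-Carlo first-passage problem.  Because the noise
amplitude is sqrt(2 D n), doubling the in-degree n is statistically
equivalent to doubling D.

Phase-plane utilities reconstruct a network-embedded neuron's trajectory
together with the instantaneous position of its (current-shifted) voltage
nullcline, the view that explains up/down switching mechanistically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kernels
from .network import SimResult
from .neurons import IZHIKEVICH, NeuronParams, nullclines, resting_state
from .synapses import SynapseParams


@dataclass
class FirstSpikeResult:
    """Mean first-spike time (ms) with trial bookkeeping."""

    mean: float
    se: float
    n_trials: int
    censored_fraction: float
    times: np.ndarray  # uncensored samples, ms
    class_label: str
    D: float
    n: int


def first_spike_time(
    params: NeuronParams,
    D: float,
    n: int = 1,
    n_trials: int = 400,
    t_max: float = 1e4,
    dt: float = 0.05,
    seed: int = 0,
    synapses: SynapseParams = SynapseParams(),
) -> FirstSpikeResult:
    """Monte-Carlo mean first passage of the voltage to ``v_peak``.

    Each trial starts at the resting state with zero conductances; both
    conductances evolve as reflected OU processes of amplitude
    ``sqrt(2 D n)``.  Trials without a spike by ``t_max`` are censored and
    reported, not silently dropped.  ``D = 0`` is rejected: the rest state
    is then stable forever and no first-spike time exists.
    """
    if D <= 0:
        raise ValueError("D = 0 never produces a spike (rest is stable)")
    rest = resting_state(params, 0.0)
    if rest is None:  # pragma: no cover
        raise RuntimeError("no resting state at I=0")
    sig = np.sqrt(2.0 * D * n) * np.sqrt(dt)
    kind = 0 if params.model_kind == IZHIKEVICH else 1
    times = _kernels.first_spike_trials(
        kind,
        params.a, params.b, params.v_peak,
        params.alpha, params.beta, params.gamma,
        params.adex_gL, params.adex_DeltaT, params.adex_vT, params.adex_EL,
        params.adex_offset,
        synapses.E_ex, synapses.E_in, synapses.tau_ex, synapses.tau_in,
        sig,
        rest.v, rest.u,
        dt, int(round(t_max / dt)), n_trials,
        seed,
    )
    ok = times[np.isfinite(times)]
    censored = 1.0 - ok.size / n_trials
    if ok.size == 0:
        mean = float("nan")
        se = float("nan")
    else:
        mean = float(ok.mean())
        se = float(ok.std(ddof=1) / np.sqrt(ok.size)) if ok.size > 1 else float("nan")
    return FirstSpikeResult(
        mean=mean,
        se=se,
        n_trials=n_trials,
        censored_fraction=float(censored),
        times=ok,
        class_label=params.class_label,
        D=D,
        n=n,
    )


@dataclass
class FirstSpikeCurve:
    """Mean first-spike time versus noise intensity for one neuron class."""

    D_grid: np.ndarray
    mean_time: np.ndarray
    se: np.ndarray
    censored_fraction: np.ndarray
    n_trials: int
    class_label: str


def first_spike_curve(
    params: NeuronParams,
    D_grid: Sequence[float],
    n_trials: int = 400,
    t_max: float = 1e4,
    dt: float = 0.05,
    seed: int = 0,
) -> FirstSpikeCurve:
    means, ses, cens = [], [], []
    for i, D in enumerate(D_grid):
        res = first_spike_time(
            params, D, n=1, n_trials=n_trials, t_max=t_max, dt=dt, seed=seed + i
        )
        means.append(res.mean)
        ses.append(res.se)
        cens.append(res.censored_fraction)
    return FirstSpikeCurve(
        D_grid=np.asarray(D_grid, dtype=float),
        mean_time=np.array(means),
        se=np.array(ses),
        censored_fraction=np.array(cens),
        n_trials=n_trials,
        class_label=params.class_label,
    )


@dataclass
class PhasePlaneTrace:
    """Trajectory of one neuron with nullcline snapshots per time window."""

    neuron_id: int
    windows: list  # (start, end) ms
    t: list  # per-window sample times
    v: list
    u: list
    nullclines_start: list  # Nullclines at window start (instantaneous I_syn)
    nullclines_end: list
    inside_parabola: list  # per-window bool arrays: u > u_bar(v)
    reset_voltage: float
    v_peak: float


def phase_plane_trace(
    sim: SimResult,
    neuron_id: int,
    windows: Sequence[tuple],
    params: NeuronParams,
    synapses: SynapseParams,
    v_grid: np.ndarray = None,
) -> PhasePlaneTrace:
    """Extract (v, u) trajectory and nullcline snapshots for one neuron.

    The voltage nullcline is drawn with the neuron's reconstructed
    instantaneous synaptic current ``I_syn = Gex (E_ex - v) + Gin (E_in - v)``
    at the window boundary instants.  ``inside_parabola`` flags samples
    with ``u > u_bar(v)`` (the region where dv/dt < 0; a down-state
    signature together with v below the reset value).
    """
    col = sim.trace_column(neuron_id)
    if v_grid is None:
        v_grid = np.linspace(-90.0, params.v_peak, 200)

    t_all = sim.t
    v_all = sim.v[:, col]
    u_all = sim.u[:, col]
    gex_all = sim.Gex[:, col]
    gin_all = sim.Gin[:, col]
    I_syn = gex_all * (synapses.E_ex - v_all) + gin_all * (synapses.E_in - v_all)

    ts, vs, us, nc0, nc1, inside = [], [], [], [], [], []
    for start, end in windows:
        m = (t_all >= start) & (t_all <= end)
        if not np.any(m):
            raise ValueError(f"window ({start}, {end}) outside the recorded range")
        idx = np.nonzero(m)[0]
        ts.append(t_all[m])
        vs.append(v_all[m])
        us.append(u_all[m])
        nc0.append(nullclines(params, float(I_syn[idx[0]]), v_grid))
        nc1.append(nullclines(params, float(I_syn[idx[-1]]), v_grid))
        from .neurons import voltage_rhs_curve

        u_bar_at_v = np.array(
            [voltage_rhs_curve(params, v, float(I)) for v, I in zip(v_all[m], I_syn[m])]
        )
        inside.append(u_all[m] > u_bar_at_v)

    return PhasePlaneTrace(
        neuron_id=neuron_id,
        windows=list(windows),
        t=ts,
        v=vs,
        u=us,
        nullclines_start=nc0,
        nullclines_end=nc1,
        inside_parabola=inside,
        reset_voltage=params.c,
        v_peak=params.v_peak,
    )


@dataclass
class PopulationSnapshot:
    """Per-neuron (v, u) scatter and synaptic-current histogram at one instant."""

    t: float
    neuron_ids: np.ndarray
    v: np.ndarray
    u: np.ndarray
    I_syn: np.ndarray


def population_snapshot(
    sim: SimResult,
    t: float,
    synapses: SynapseParams,
    sample: int = 200,
    seed: int = 0,
) -> PopulationSnapshot:
    """Sample ``sample`` recorded neurons at the recording instant nearest t."""
    if sim.v is None:
        raise ValueError("simulation was run without per-neuron trace recording")
    if t < sim.t[0] or t > sim.t[-1]:
        raise ValueError(f"t={t} outside the recorded range [{sim.t[0]}, {sim.t[-1]}]")
    k = int(np.argmin(np.abs(sim.t - t)))
    n_avail = sim.rec_ids.size
    rng = np.random.default_rng(seed)
    take = rng.choice(n_avail, size=min(sample, n_avail), replace=False)
    v = sim.v[k, take]
    u = sim.u[k, take]
    gex = sim.Gex[k, take]
    gin = sim.Gin[k, take]
    I_syn = gex * (synapses.E_ex - v) + gin * (synapses.E_in - v)
    return PopulationSnapshot(
        t=float(sim.t[k]),
        neuron_ids=sim.rec_ids[take],
        v=v,
        u=u,
        I_syn=I_syn,
    )
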