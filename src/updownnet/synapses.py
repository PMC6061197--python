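"""Conductance-based synapses with Ornstein-Uhlenbeck synaptic noise.

The synaptic current into a neuron is

    I_syn = G_ex (E_ex - v) + G_in (E_in - v),

and each conductance follows a jump-diffusion: exponential decay with time
constant ``tau``, an upward jump of size ``g`` at every presynaptic spike
arrival, and additive Gaussian white noise of intensity ``sqrt(2 D n)``
(an Ornstein-Uhlenbeck process between spikes).  ``n`` is the number of
presynaptic inputs of the matching sign, so neurons with more afferents see
proportionally larger noise variance.  The physical origin of the noise is
spontaneous neurotransmitter release (miniature postsynaptic potentials).

Conductances are kept non-negative by a reflecting boundary at zero, which
slightly shifts the stationary mean upward relative to the free process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SynapseParams:
    """Synaptic increments, time constants, reversal potentials and noise.

    Defaults: ``E_ex = 0`` mV, ``E_in = -80`` mV, ``tau_ex = 5`` ms,
    ``tau_in = 6`` ms, increments ``g_ex = 0.15`` and ``g_in = 1``.
    ``D`` is the synaptic noise intensity (zero for deterministic runs).
    """

    g_ex: float = 0.15
    g_in: float = 1.0
    tau_ex: float = 5.0
    tau_in: float = 6.0
    E_ex: float = 0.0
    E_in: float = -80.0
    D: float = 0.0

    def __post_init__(self):
        if self.tau_ex <= 0 or self.tau_in <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.D < 0:
            raise ValueError("noise intensity D must be non-negative")


@dataclass
class ConductancePair:
    """Excitatory and inhibitory conductance of one neuron."""

    G_ex: float
    G_in: float


def synaptic_current(v: float, G: ConductancePair, params: SynapseParams) -> float:
    """``G_ex (E_ex - v) + G_in (E_in - v)``."""
    return G.G_ex * (params.E_ex - v) + G.G_in * (params.E_in - v)


def _heun_component(G: float, tau: float, sigma_dt: float, dt: float, z: float) -> float:
    # stochastic Heun for dG = -G/tau dt + sigma dW; the same Wiener
    # increment enters predictor and corrector (additive noise).
    w = sigma_dt * z
    d1 = -G / tau
    G_pred = G + dt * d1 + w
    d2 = -G_pred / tau
    return G + 0.5 * dt * (d1 + d2) + w


def conductance_step(
    G: ConductancePair,
    dt: float,
    n_ex: int,
    n_in: int,
    incoming_ex_spikes: int,
    incoming_in_spikes: int,
    params: SynapseParams,
    rng: np.random.Generator,
) -> ConductancePair:
    """Advance both conductances by one Heun step of the jump-diffusion.

    Order within the step: stochastic OU integration, then the jump
    ``g * (number of arriving spikes)``, then reflection at zero.  Neurons
    with zero in-degree of a kind receive no stochastic term on that
    conductance (the noise amplitude is ``sqrt(2 D n)``).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_ex < 0 or n_in < 0 or incoming_ex_spikes < 0 or incoming_in_spikes < 0:
        raise ValueError("counts must be non-negative")

    sqdt = math.sqrt(dt)
    sig_ex = math.sqrt(2.0 * params.D * n_ex) * sqdt if (params.D > 0 and n_ex > 0) else 0.0
    sig_in = math.sqrt(2.0 * params.D * n_in) * sqdt if (params.D > 0 and n_in > 0) else 0.0

    z_ex = rng.standard_normal() if sig_ex > 0 else 0.0
    z_in = rng.standard_normal() if sig_in > 0 else 0.0

    g_ex = _heun_component(G.G_ex, params.tau_ex, sig_ex, dt, z_ex)
    g_in = _heun_component(G.G_in, params.tau_in, sig_in, dt, z_in)

    g_ex += params.g_ex * incoming_ex_spikes
    g_in += params.g_in * incoming_in_spikes

    return ConductancePair(G_ex=abs(g_ex), G_in=abs(g_in))


def ou_stationary_stats(D: float, tau: float, n: int) -> tuple[float, float]:
    """Stationary (mean, variance) of the unreflected OU conductance.

    For ``dG = -G/tau dt + sqrt(2 D n) dW`` the stationary distribution is
    Gaussian with zero mean and variance ``D n tau``.  This closed form is
    the reference for Monte-Carlo checks of the simulated conductances
    (reflection at zero biases the mean slightly upward).
    """
    return 0.0, D * n * tau
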