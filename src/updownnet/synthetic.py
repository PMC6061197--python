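"""Synthetic rasters and traces with known statistical structure.

These generators emulate the statistics the measures and the segmentation
logic assume — Poisson rasters for asynchronous-irregular activity,
jittered periodic rasters for oscillatory activity, and two/three-level
voltage traces with exponential dwell times for up/down/rest
classification — so every analysis routine is testable against ground
truth without running the full network simulator.  Generation is fully
determined by (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .measures import RateSeries
from .raster import Raster


def make_poisson_raster(N: int, rate: float, T: float, seed: int = 0) -> Raster:
    """Independent homogeneous Poisson trains.

    ``rate`` in Hz, ``T`` in ms.
    """
    if rate < 0 or T < 0:
        raise ValueError("rate and T must be non-negative")
    rng = np.random.default_rng(seed)
    lam = rate * T * 1e-3
    counts = rng.poisson(lam, size=N)
    times = rng.uniform(0.0, T, size=counts.sum())
    ids = np.repeat(np.arange(N), counts)
    return Raster(times=times, ids=ids, N=N, t_start=0.0, t_end=T)


def make_periodic_raster(
    N: int,
    f: float,
    jitter_sd: float,
    participation: float,
    T: float,
    seed: int = 0,
) -> Raster:
    """Population bursts every 1/f with Gaussian per-spike jitter.

    Each neuron joins each burst with probability ``participation``; with
    zero jitter and full participation the population rate is a pure
    periodic impulse train (spectral entropy near 0).
    """
    if f <= 0:
        raise ValueError("burst frequency must be positive")
    rng = np.random.default_rng(seed)
    period = 1000.0 / f
    burst_times = np.arange(period / 2, T, period)
    times, ids = [], []
    for t_burst in burst_times:
        joins = np.nonzero(rng.random(N) < participation)[0]
        jitter = rng.normal(0.0, jitter_sd, size=joins.size) if jitter_sd > 0 else 0.0
        t = np.clip(t_burst + jitter, 0.0, np.nextafter(T, 0.0))
        times.append(np.broadcast_to(t, joins.shape).astype(float).ravel()
                     if np.ndim(t) else np.full(joins.size, t))
        ids.append(joins)
    times = np.concatenate(times) if times else np.empty(0)
    ids = np.concatenate(ids) if ids else np.empty(0, dtype=int)
    return Raster(times=times, ids=ids, N=N, t_start=0.0, t_end=T)


def make_phase_locked_pair(f: float, jitter_sd: float, T: float, seed: int = 0) -> Raster:
    """Two spike trains locked to a common periodic drive."""
    return make_periodic_raster(2, f, jitter_sd, 1.0, T, seed)


@dataclass
class TwoStateFixture:
    """Alternating-level voltage trace with matched rate series.

    ``state_index`` holds the generating level index per bin (ground truth
    for classifier parameter-recovery tests), ``dwell_samples`` the drawn
    dwell durations (ms) per visit in order.
    """

    t: np.ndarray
    v: np.ndarray
    rate: RateSeries
    levels: tuple
    state_index: np.ndarray
    dwell_samples: list


def make_two_state_voltage(
    levels: Sequence[float],
    dwell_means: Sequence[float],
    noise_sd: float,
    T: float,
    seed: int = 0,
    rates: Optional[Sequence[float]] = None,
    delta_t: float = 1.0,
) -> TwoStateFixture:
    """Voltage trace cycling through 2-3 levels with exponential dwells.

    ``levels`` are mean voltages (mV), visited cyclically in the given
    order; each visit lasts Exp(dwell_mean) ms (at least one bin).  The
    paired rate series is high while the most depolarized level is active
    and near zero otherwise, mirroring up states versus down/rest, unless
    per-level ``rates`` (Hz) are given explicitly.
    """
    levels = tuple(float(x) for x in levels)
    if not 2 <= len(levels) <= 3:
        raise ValueError("need two or three voltage levels")
    if len(dwell_means) != len(levels):
        raise ValueError("dwell_means must match levels")
    rng = np.random.default_rng(seed)
    n_bins = int(np.floor(T / delta_t))

    if rates is None:
        depol = int(np.argmax(levels))
        rates = [40.0 if i == depol else 0.5 for i in range(len(levels))]

    state_index = np.empty(n_bins, dtype=np.int8)
    dwells = []
    pos = 0
    state = 0
    while pos < n_bins:
        dwell = max(delta_t, rng.exponential(dwell_means[state]))
        n = min(n_bins - pos, max(1, int(round(dwell / delta_t))))
        state_index[pos : pos + n] = state
        dwells.append((state, n * delta_t))
        pos += n
        state = (state + 1) % len(levels)

    v = np.array([levels[s] for s in state_index])
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=n_bins)
    r = np.array([rates[s] for s in state_index])
    if noise_sd > 0:
        r = np.maximum(0.0, r + rng.normal(0.0, 0.05 * (1 + r), size=n_bins))

    t = delta_t * np.arange(n_bins)
    return TwoStateFixture(
        t=t,
        v=v,
        rate=RateSeries(t=t, r=r, delta_t=delta_t),
        levels=levels,
        state_index=state_index,
        dwell_samples=dwells,
    )
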