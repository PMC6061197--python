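"""Experiment recipes: noise/inhibition sweeps, state diagrams, duration scans.

The canonical study conditions bundled here:

* weak-noise asynchronous-irregular state: mixed 16% CH / 64% RS / 20% LTS
  network, (g_ex, g_in) = (0.15, 1), D = 2.5e-6, no stimulation;
* intermittent active/quiescent switching: same composition, D = 1e-5;
* deterministic up/down oscillation: same composition, D = 0, brief
  stimulation, long-lived trials kept (free activity >= 400 ms);
* strong-noise spectra: RS + LTS network at D = 4.5e-5;
* duration-versus-noise scans over D with composition variants.

All recipes are pure functions of (configuration, seed) and reproduce
bit-exactly under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .measures import (
    RateSeries,
    averaged_spike_spectrum,
    firing_rate,
    per_neuron_rates,
    plv,
    spectral_entropy,
    spectral_peak,
)
from .network import (
    NetworkConfig,
    SimResult,
    StimulationProtocol,
    build_network,
    run_deterministic_trials,
    simulate,
)
from .segmentation import (
    SegmentationParams,
    composition_rest_voltage,
    label_bins,
    segment_periods,
    segment_spectral_entropy,
    voltage_histogram,
)
from .synapses import SynapseParams

# Canonical compositions (fractions within each subpopulation)
MIXED_CH_RS_LTS = dict(exc_composition={"RS": 0.8, "CH": 0.2}, inh_composition={"LTS": 1.0})
RS_LTS = dict(exc_composition={"RS": 1.0}, inh_composition={"LTS": 1.0})
RS_FS = dict(exc_composition={"RS": 1.0}, inh_composition={"FS": 1.0})

DEFAULT_TRANSIENT_MS = 500.0


def _noisy_sim(
    composition: dict,
    D: float,
    t_end: float,
    seed: int,
    g_ex: float = 0.15,
    g_in: float = 1.0,
    N: int = 2**10,
    p: float = 0.01,
    model_kind: str = "izhikevich",
    dt: float = 0.05,
    record_neurons=None,
) -> SimResult:
    config = NetworkConfig(N=N, p=p, model_kind=model_kind, seed=seed, **composition)
    conn = build_network(config)
    syn = SynapseParams(g_ex=g_ex, g_in=g_in, D=D)
    return simulate(
        conn,
        syn,
        t_end,
        model_kind=model_kind,
        dt=dt,
        seed=seed + 1,
        record_neurons=record_neurons,
    )


@dataclass
class WeakNoiseSummary:
    H_s: float
    plv: float
    exc_rate_hz: float
    inh_rate_hz: float
    sim: SimResult


def weak_noise_experiment(
    seed: int = 0,
    D: float = 2.5e-6,
    t_end: float = 3000.0,
    transient: float = DEFAULT_TRANSIENT_MS,
    composition: Optional[dict] = None,
    model_kind: str = "izhikevich",
) -> WeakNoiseSummary:
    """Asynchronous-irregular state under weak synaptic noise.

    Returns the post-transient spectral entropy, PLV over a 2000-ms window,
    and excitatory/inhibitory population mean rates.
    """
    composition = MIXED_CH_RS_LTS if composition is None else composition
    sim = _noisy_sim(composition, D, t_end, seed, model_kind=model_kind)
    rate = firing_rate(sim.raster, t_start=transient, t_end=t_end)
    H = spectral_entropy(rate).H_s
    window = min(2000.0, t_end - transient)
    p = plv(sim.raster, K=60, t_start=transient, T_window=window, seed=seed).plv
    rates = per_neuron_rates(sim.raster, transient, t_end)
    is_exc = np.array([lab in ("RS", "CH") for lab in sim.raster.labels])
    return WeakNoiseSummary(
        H_s=H,
        plv=p,
        exc_rate_hz=float(rates[is_exc].mean()),
        inh_rate_hz=float(rates[~is_exc].mean()),
        sim=sim,
    )


@dataclass
class IntermittentSummary:
    H_s_quiescent: float
    H_s_active: float
    n_active: int
    n_quiescent: int
    n_voltage_modes: int
    segments: object
    rate: RateSeries
    sim: SimResult


def intermittent_experiment(
    seed: int = 0,
    D: float = 1e-5,
    t_end: float = 10000.0,
    transient: float = DEFAULT_TRANSIENT_MS,
    composition: Optional[dict] = None,
    model_kind: str = "izhikevich",
    seg_params: SegmentationParams = SegmentationParams(),
) -> IntermittentSummary:
    """Intermittent switching between active (up/down) and quiescent regimes.

    Segments the run, computes the spectral entropy separately over
    quiescent and active periods, and counts the modes of the mean-voltage
    histogram (three in the intermittent regime: depolarized, rest,
    hyperpolarized).
    """
    composition = MIXED_CH_RS_LTS if composition is None else composition
    sim = _noisy_sim(composition, D, t_end, seed, model_kind=model_kind)
    rate = firing_rate(sim.raster, t_start=transient, t_end=t_end)
    keep = sim.t >= transient
    mean_v = sim.mean_v[keep][: len(rate)]

    v_rest = composition_rest_voltage(
        sorted(set(sim.raster.labels)), model_kind=model_kind
    )
    labels = label_bins(mean_v, rate, v_rest, seg_params)
    segments = segment_periods(labels)

    def seg_entropy(kind):
        try:
            return segment_spectral_entropy(rate, segments, kind)
        except ValueError:
            return float("nan")

    hist = voltage_histogram(mean_v)
    return IntermittentSummary(
        H_s_quiescent=seg_entropy("quiescent"),
        H_s_active=seg_entropy("active"),
        n_active=len(segments.of_kind("active")),
        n_quiescent=len(segments.of_kind("quiescent")),
        n_voltage_modes=hist.n_modes,
        segments=segments,
        rate=rate,
        sim=sim,
    )


def default_stimulation_grid(target_seed: int = 0) -> list:
    """A small sample of the stimulation grid (amplitude x duration x fraction)."""
    protocols = []
    for i, (I_stim, t_stim, fraction) in enumerate(
        [
            (10.0, 100.0, 1.0),
            (15.0, 100.0, 0.5),
            (20.0, 50.0, 1.0),
            (15.0, 200.0, 0.25),
            (10.0, 300.0, 0.5),
            (20.0, 150.0, 0.125),
            (20.0, 100.0, 0.0625),
            (12.0, 150.0, 0.0625),
        ]
    ):
        protocols.append(
            StimulationProtocol(
                I_stim=I_stim, t_stim=t_stim, fraction=fraction, target_seed=target_seed + i
            )
        )
    return protocols


@dataclass
class DeterministicOscillationSummary:
    period_ms: float
    peak_hz: float
    n_kept: int
    periods: np.ndarray


def deterministic_oscillation_experiment(
    seed: int = 0,
    t_end: float = 5000.0,
    composition: Optional[dict] = None,
    protocols: Optional[list] = None,
    min_duration: float = 400.0,
    max_network_draws: int = 3,
) -> DeterministicOscillationSummary:
    """Dominant up-down cycle period of long-lived deterministic trials.

    Runs the stimulation grid with D = 0, keeps trials whose free activity
    exceeds ``min_duration``, and measures the dominant period of
    r(t; 1 ms) from the spectral peak over the free-activity window.
    Long-lived transients are realization-dependent, so up to
    ``max_network_draws`` network realizations are tried until at least
    one trial survives.
    """
    composition = MIXED_CH_RS_LTS if composition is None else composition
    syn = SynapseParams(D=0.0)
    kept = []
    for attempt in range(max_network_draws):
        config = NetworkConfig(seed=seed + attempt, **composition)
        grid = (
            protocols
            if protocols is not None
            else default_stimulation_grid(target_seed=seed + attempt)
        )
        kept = run_deterministic_trials(
            config, syn, grid, t_end=t_end, min_duration=min_duration,
            seed=seed + attempt,
        )
        if kept:
            break
    periods = []
    for trial in kept:
        t0 = trial.protocol.t_stim
        t1 = min(trial.sim.t_end, float(trial.sim.raster.times.max()))
        if t1 - t0 < 300:
            continue
        rate = firing_rate(trial.sim.raster, t_start=t0, t_end=t1)
        x = rate.r - rate.r.mean()
        from .measures import power_spectrum

        spec = power_spectrum(x, rate.delta_t, kind="spikes")
        band = (spec.f >= 2.0) & (spec.f <= 50.0)
        f_peak = spec.f[band][np.argmax(spec.S[band])]
        periods.append(1000.0 / f_peak)
    periods = np.array(periods)
    if periods.size == 0:
        return DeterministicOscillationSummary(
            period_ms=float("nan"), peak_hz=float("nan"), n_kept=0, periods=periods
        )
    return DeterministicOscillationSummary(
        period_ms=float(np.median(periods)),
        peak_hz=float(1000.0 / np.median(periods)),
        n_kept=int(periods.size),
        periods=periods,
    )


def strong_noise_spectrum_experiment(
    seed: int = 0,
    D: float = 4.5e-5,
    t_end: float = 10000.0,
    transient: float = DEFAULT_TRANSIENT_MS,
    composition: Optional[dict] = None,
    n_neurons: int = 200,
    smooth_window: int = 20,
):
    """Peak of the ensemble-averaged spike-train spectrum at strong noise.

    Averages periodograms of ``n_neurons`` random neurons, smooths with a
    20-point moving average and reports the argmax frequency with the
    zeroth bin excluded.  Returns (peak_hz, smoothed averaged Spectrum).
    """
    composition = RS_LTS if composition is None else composition
    sim = _noisy_sim(composition, D, t_end, seed)
    rng = np.random.default_rng(seed)
    ids = rng.choice(sim.raster.N, size=n_neurons, replace=False)
    window = sim.raster.window(transient, t_end)
    spec = averaged_spike_spectrum(window, ids)
    peak = spectral_peak(spec, smooth_window=smooth_window, skip_zero_bin=True)
    return peak, spec


@dataclass
class SweepGrid:
    """(g_in/g_ex, D) grid: linear ratios in [0.5, 7], log-spaced D."""

    ratio_values: np.ndarray = field(
        default_factory=lambda: np.linspace(0.5, 7.0, 12)
    )
    D_values: np.ndarray = field(
        default_factory=lambda: np.logspace(-6, -2, 12)
    )
    g_ex: float = 0.15


@dataclass
class StateDiagram:
    """Per-cell H_s and PLV with derived qualitative labels."""

    ratios: np.ndarray
    Ds: np.ndarray
    H_s: np.ndarray  # shape (len(Ds), len(ratios))
    plv: np.ndarray
    labels: np.ndarray  # object array of state names
    hs_threshold: float
    plv_threshold: float
    failures: list


def classify_state(
    H_s: float,
    plv_value: float,
    hs_threshold: float = 0.5,
    plv_threshold: float = 0.5,
    transition_band: float = 0.1,
) -> str:
    """Qualitative state label from (H_s, PLV) and explicit thresholds.

    Low H_s means oscillatory, high PLV means synchronous.  Cells with both
    measures inside ``transition_band`` of their thresholds are labelled
    ``transition``.  Pure function: relabelling with new thresholds needs
    no re-simulation.
    """
    if np.isnan(H_s) or np.isnan(plv_value):
        return "missing"
    if (
        abs(H_s - hs_threshold) < transition_band
        and abs(plv_value - plv_threshold) < transition_band
    ):
        return "transition"
    oscillatory = H_s < hs_threshold
    synchronous = plv_value > plv_threshold
    if oscillatory and synchronous:
        return "sync_oscillatory"
    if oscillatory:
        return "oscillatory_async"
    if synchronous:
        return "sync_nonoscillatory"
    return "async_nonoscillatory"


def run_sweep(
    grid: SweepGrid,
    composition: Optional[dict] = None,
    t_sim: float = 4000.0,
    transient: float = DEFAULT_TRANSIENT_MS,
    seed: int = 0,
    hs_threshold: float = 0.5,
    plv_threshold: float = 0.5,
    N: int = 2**10,
) -> StateDiagram:
    """One simulation per (D, ratio) cell; H_s and PLV post-transient.

    Per-cell failures are logged and the cell marked missing (NaN); the
    sweep continues.
    """
    composition = RS_LTS if composition is None else composition
    nD, nR = len(grid.D_values), len(grid.ratio_values)
    H = np.full((nD, nR), np.nan)
    P = np.full((nD, nR), np.nan)
    labels = np.empty((nD, nR), dtype=object)
    failures = []
    for i, D in enumerate(grid.D_values):
        for j, ratio in enumerate(grid.ratio_values):
            cell_seed = seed + 1000 * i + j
            try:
                sim = _noisy_sim(
                    composition,
                    D,
                    t_sim,
                    cell_seed,
                    g_ex=grid.g_ex,
                    g_in=ratio * grid.g_ex,
                    N=N,
                )
                rate = firing_rate(sim.raster, t_start=transient, t_end=t_sim)
                H[i, j] = spectral_entropy(rate).H_s
                window = min(2000.0, t_sim - transient)
                P[i, j] = plv(
                    sim.raster, K=60, t_start=transient, T_window=window, seed=cell_seed
                ).plv
            except (ValueError, RuntimeError) as exc:
                failures.append((float(D), float(ratio), str(exc)))
            labels[i, j] = classify_state(H[i, j], P[i, j], hs_threshold, plv_threshold)
    return StateDiagram(
        ratios=np.asarray(grid.ratio_values, dtype=float),
        Ds=np.asarray(grid.D_values, dtype=float),
        H_s=H,
        plv=P,
        labels=labels,
        hs_threshold=hs_threshold,
        plv_threshold=plv_threshold,
        failures=failures,
    )


def segment_run(
    sim: SimResult,
    transient: float = DEFAULT_TRANSIENT_MS,
    seg_params: SegmentationParams = SegmentationParams(),
    model_kind: str = "izhikevich",
):
    """Label and segment a simulation; returns (rate, labels, segments)."""
    rate = firing_rate(sim.raster, t_start=transient, t_end=sim.t_end)
    keep = sim.t >= transient
    mean_v = sim.mean_v[keep][: len(rate)]
    v_rest = composition_rest_voltage(sorted(set(sim.raster.labels)), model_kind)
    labels = label_bins(mean_v, rate, v_rest, seg_params)
    return rate, labels, segment_periods(labels)


def duration_vs_noise(
    D_values: Sequence[float],
    compositions: Optional[dict] = None,
    t_sim: float = 60000.0,
    transient: float = DEFAULT_TRANSIENT_MS,
    seed: int = 0,
    kinds: Sequence[str] = ("active", "quiescent", "up", "down"),
    g_ex: float = 0.15,
    g_in: float = 1.0,
) -> pd.DataFrame:
    """Mean +/- SE of period durations per noise level and composition.

    Returns a tidy table with columns composition, D, kind, n, mean_ms,
    se_ms.  Compositions with no detected periods of a kind get NaN means
    with n = 0 (reported, not dropped).
    """
    from .segmentation import duration_stats

    compositions = {"RS+LTS": RS_LTS} if compositions is None else compositions
    rows = []
    for name, comp in compositions.items():
        for i, D in enumerate(D_values):
            sim = _noisy_sim(comp, D, t_sim, seed + 97 * i, g_ex=g_ex, g_in=g_in)
            _, _, segments = segment_run(sim, transient)
            for kind in kinds:
                try:
                    st = duration_stats(segments, kind)
                    rows.append(
                        dict(
                            composition=name, D=D, kind=kind, n=st.n,
                            mean_ms=st.mean, se_ms=st.se,
                        )
                    )
                except ValueError:
                    rows.append(
                        dict(
                            composition=name, D=D, kind=kind, n=0,
                            mean_ms=float("nan"), se_ms=float("nan"),
                        )
                    )
    return pd.DataFrame(rows)
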