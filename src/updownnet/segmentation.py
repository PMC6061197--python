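"""Up/down/rest state labelling and active/quiescent period segmentation.

A network in the intermittent regime alternates between *active* periods
(rhythmic up/down oscillation of the mean voltage accompanied by bursts of
collective firing) and *quiescent* periods (mean voltage near rest,
sporadic noise-induced spikes only).  Within an active period the mean
voltage swings between a depolarized *up* band and a hyperpolarized *down*
band close to -80 mV.

Labels are assigned per 1-ms bin from the network-averaged voltage and the
population rate, with all thresholds recorded alongside the labels:

* down  - mean voltage within ``down_halfwidth`` of ``down_center``;
* up    - population rate at or above ``rate_fraction`` of its window
          reference (maximum by default) and voltage above the rest band;
* rest  - everything else (voltage near the composition-weighted resting
          value with near-zero rate).

Bins with high rate but non-depolarized voltage (onset bins of a wave) are
counted as up; the rate criterion dominates there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .measures import RateSeries, spectral_entropy

REST, UP, DOWN = 0, 1, 2
_KIND_OF_LABEL = {UP: "up", DOWN: "down", REST: "rest"}

ACTIVE = "active"
QUIESCENT = "quiescent"


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds of the state classifier (all configurable, all recorded)."""

    rate_fraction: float = 0.2  # fraction of the window rate reference
    rate_ref: str = "max"  # "max" or "mean" of the rate over the window
    down_center: float = -80.0  # mV
    down_halfwidth: float = 5.0  # mV
    rest_halfwidth: float = 3.0  # mV
    min_gap: float = 20.0  # ms; shorter active/quiescent runs are merged
    sub_min_gap: float = 5.0  # ms; same for up/down sub-runs


@dataclass
class StateLabelSeries:
    """Per-bin state labels plus the thresholds used to produce them."""

    t: np.ndarray  # bin left edges, ms
    labels: np.ndarray  # int8: REST/UP/DOWN
    delta_t: float
    v_rest: float
    rate_threshold: float
    params: SegmentationParams


@dataclass
class Interval:
    start: float
    end: float
    kind: str

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class PeriodSegments:
    """Disjoint ordered intervals covering the analysed window."""

    intervals: list  # active/quiescent
    sub_intervals: list  # up/down inside active periods
    t_start: float
    t_end: float

    def of_kind(self, kind: str) -> list:
        pool = self.sub_intervals if kind in ("up", "down") else self.intervals
        return [iv for iv in pool if iv.kind == kind]

    def total_duration(self, kind: str) -> float:
        return float(sum(iv.duration for iv in self.of_kind(kind)))


@dataclass
class DurationStats:
    kind: str
    n: int
    mean: float
    sd: float
    se: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    outliers: np.ndarray  # durations flagged as > mean + 3 sd
    log_linearity_r2: float  # exponential-shape diagnostic
    se_defined: bool


def composition_rest_voltage(labels, model_kind: str = "izhikevich") -> float:
    """Composition-weighted resting voltage of a population."""
    from .neurons import NeuronParams, resting_state

    labels = np.asarray(labels)
    vals = []
    for lab in labels:
        state = resting_state(NeuronParams.from_class(str(lab), model_kind), 0.0)
        vals.append(state.v)
    return float(np.mean(vals))


def label_bins(
    mean_v: np.ndarray,
    rate: RateSeries,
    v_rest: float,
    params: SegmentationParams = SegmentationParams(),
) -> StateLabelSeries:
    """Classify each 1-ms bin as up, down or rest."""
    v = np.asarray(mean_v, dtype=float)
    r = np.asarray(rate.r, dtype=float)
    n = min(v.size, r.size)
    if n == 0:
        raise ValueError("empty traces")
    v, r = v[:n], r[:n]
    if np.all(r == 0) and np.all(v == v[0]):
        raise ValueError("all-zero inputs: nothing to label")

    ref = r.max() if params.rate_ref == "max" else r.mean()
    thr = params.rate_fraction * ref

    labels = np.full(n, REST, dtype=np.int8)
    down = np.abs(v - params.down_center) <= params.down_halfwidth
    labels[down] = DOWN
    up = ~down & (r >= thr) & (thr > 0)
    labels[up] = UP

    return StateLabelSeries(
        t=rate.t[:n].copy(),
        labels=labels,
        delta_t=rate.delta_t,
        v_rest=v_rest,
        rate_threshold=float(thr),
        params=params,
    )


def _runs(binary: np.ndarray):
    """(start_idx, end_idx, value) for maximal constant runs."""
    edges = np.nonzero(np.diff(binary))[0] + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [binary.size]])
    return [(int(s), int(e), binary[s]) for s, e in zip(starts, ends)]


def _merge_short_runs(values: np.ndarray, min_len: int) -> np.ndarray:
    """Absorb runs shorter than ``min_len`` into their longer neighbour."""
    vals = values.copy()
    while True:
        runs = _runs(vals)
        if len(runs) <= 1:
            return vals
        lengths = [e - s for s, e, _ in runs]
        shortest = int(np.argmin(lengths))
        if lengths[shortest] >= min_len:
            return vals
        s, e, _ = runs[shortest]
        left_len = lengths[shortest - 1] if shortest > 0 else -1
        right_len = lengths[shortest + 1] if shortest < len(runs) - 1 else -1
        donor = runs[shortest - 1] if left_len >= right_len else runs[shortest + 1]
        vals[s:e] = donor[2]


def segment_periods(
    label_series: StateLabelSeries,
    min_gap: Optional[float] = None,
) -> PeriodSegments:
    """Merge up/down alternation into active periods, rest runs into quiescent.

    Runs shorter than ``min_gap`` ms (hysteresis against single-bin
    flicker) are merged into their neighbours.
    """
    p = label_series.params
    min_gap = p.min_gap if min_gap is None else min_gap
    dt = label_series.delta_t
    t0 = float(label_series.t[0])
    n = label_series.labels.size

    active = (label_series.labels != REST).astype(np.int8)
    active = _merge_short_runs(active, max(1, int(round(min_gap / dt))))

    intervals = []
    for s, e, val in _runs(active):
        kind = ACTIVE if val else QUIESCENT
        intervals.append(Interval(t0 + s * dt, t0 + e * dt, kind))

    sub = []
    sub_min = max(1, int(round(p.sub_min_gap / dt)))
    for iv in intervals:
        if iv.kind != ACTIVE:
            continue
        s = int(round((iv.start - t0) / dt))
        e = int(round((iv.end - t0) / dt))
        seg_labels = label_series.labels[s:e].copy()
        # inside an active period every bin is up or down; fold stray rest
        # bins into "down" (low-rate, relaxing) before run extraction
        seg_labels[seg_labels == REST] = DOWN
        is_up = (seg_labels == UP).astype(np.int8)
        is_up = _merge_short_runs(is_up, sub_min)
        for ss, ee, val in _runs(is_up):
            sub.append(
                Interval(iv.start + ss * dt, iv.start + ee * dt, "up" if val else "down")
            )

    return PeriodSegments(
        intervals=intervals,
        sub_intervals=sub,
        t_start=t0,
        t_end=t0 + n * dt,
    )


def duration_stats(segments: PeriodSegments, kind: str, n_hist_bins: int = 20) -> DurationStats:
    """Mean, SD, SE and histogram of interval durations of one kind."""
    durations = np.array([iv.duration for iv in segments.of_kind(kind)])
    if durations.size == 0:
        raise ValueError(f"no intervals of kind {kind!r}")
    mean = float(durations.mean())
    if durations.size > 1:
        sd = float(durations.std(ddof=1))
        se = sd / np.sqrt(durations.size)
        se_defined = True
    else:
        sd = float("nan")
        se = float("nan")
        se_defined = False
    counts, edges = np.histogram(durations, bins=n_hist_bins)
    outliers = durations[durations > mean + 3 * (sd if se_defined else 0)] if se_defined else np.array([])

    # exponential-shape diagnostic: linearity of the log empirical survival
    if durations.size > 2:
        x = np.sort(durations)
        log_surv = np.log(1.0 - (np.arange(durations.size) / durations.size))
        A = np.vstack([x, np.ones_like(x)]).T
        coef, res, *_ = np.linalg.lstsq(A, log_surv, rcond=None)
        ss_tot = float(((log_surv - log_surv.mean()) ** 2).sum())
        r2 = 1.0 - float(res[0]) / ss_tot if (res.size and ss_tot > 0) else float("nan")
    else:
        r2 = float("nan")

    return DurationStats(
        kind=kind,
        n=int(durations.size),
        mean=mean,
        sd=sd,
        se=float(se),
        hist_edges=edges,
        hist_counts=counts,
        outliers=outliers,
        log_linearity_r2=r2,
        se_defined=se_defined,
    )


@dataclass
class VoltageHistogram:
    edges: np.ndarray
    counts: np.ndarray
    median: float
    mean: float
    n_modes: int
    mode_voltages: np.ndarray


def voltage_histogram(
    v: np.ndarray,
    bins: int = 60,
    value_range: Optional[tuple] = None,
    smooth_sigma: float = 1.5,
    prominence_frac: float = 0.05,
) -> VoltageHistogram:
    """Histogram of (network-averaged) voltage with a modality count.

    Modes are local maxima of the lightly smoothed histogram with
    prominence at least ``prominence_frac`` of the histogram peak.
    """
    v = np.asarray(v, dtype=float).ravel()
    counts, edges = np.histogram(v, bins=bins, range=value_range)
    if np.ptp(v) == 0:
        return VoltageHistogram(
            edges=edges, counts=counts, median=float(np.median(v)),
            mean=float(v.mean()), n_modes=1, mode_voltages=np.array([v[0]]),
        )
    smooth = gaussian_filter1d(counts.astype(float), smooth_sigma)
    peaks, _ = find_peaks(smooth, prominence=prominence_frac * smooth.max())
    centers = 0.5 * (edges[:-1] + edges[1:])
    # a maximum at either edge of the support is a mode too
    interior = list(peaks)
    if smooth.size > 1 and smooth[0] > smooth[1] and smooth[0] >= prominence_frac * smooth.max():
        interior = [0] + interior
    if smooth.size > 1 and smooth[-1] > smooth[-2] and smooth[-1] >= prominence_frac * smooth.max():
        interior = interior + [smooth.size - 1]
    modes = np.array(sorted(set(interior)), dtype=int)
    return VoltageHistogram(
        edges=edges,
        counts=counts,
        median=float(np.median(v)),
        mean=float(v.mean()),
        n_modes=int(modes.size),
        mode_voltages=centers[modes],
    )


def segment_spectral_entropy(
    rate: RateSeries,
    segments: PeriodSegments,
    kind: str,
    N_b: int = 1000,
    min_len_ms: float = 100.0,
) -> float:
    """Duration-weighted mean spectral entropy over segments of one kind.

    Segments shorter than ``min_len_ms`` are skipped (their spectra carry
    too few independent frequencies).
    """
    vals, weights = [], []
    for iv in segments.of_kind(kind):
        if iv.duration < min_len_ms:
            continue
        seg = rate.window(iv.start, iv.end)
        try:
            res = spectral_entropy(seg, N_b=N_b)
        except ValueError:
            continue
        vals.append(res.H_s)
        weights.append(iv.duration)
    if not vals:
        raise ValueError(f"no usable segments of kind {kind!r}")
    return float(np.average(vals, weights=weights))
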