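"""Spike raster container shared by the simulator, fixtures and measures."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass
class Raster:
    """Spike times (ms) with neuron ids, sorted by time.

    ``N`` is the population size (ids run 0..N-1 even if some neurons never
    spiked).  ``labels`` optionally holds the per-neuron class label.
    """

    times: np.ndarray
    ids: np.ndarray
    N: int
    t_start: float = 0.0
    t_end: float = 0.0
    labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.times.shape != self.ids.shape:
            raise ValueError("times and ids must have the same length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            order = np.argsort(self.times, kind="stable")
            self.times = self.times[order]
            self.ids = self.ids[order]
        if self.t_end == 0.0 and self.times.size:
            self.t_end = float(self.times.max())

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def spike_times(self, neuron_id: int) -> np.ndarray:
        """Spike times of one neuron (strictly increasing)."""
        return self.times[self.ids == neuron_id]

    def window(self, t0: float, t1: float) -> "Raster":
        """Restrict to spikes with ``t0 <= t < t1`` (time base unchanged)."""
        m = (self.times >= t0) & (self.times < t1)
        return Raster(
            times=self.times[m],
            ids=self.ids[m],
            N=self.N,
            t_start=t0,
            t_end=t1,
            labels=self.labels,
        )

    def counts_per_neuron(self) -> np.ndarray:
        return np.bincount(self.ids, minlength=self.N)

    def binned(self, neuron_id: int, delta_t: float = 1.0) -> np.ndarray:
        """Spike counts of one neuron in contiguous ``delta_t``-ms bins."""
        n_bins = int(np.floor((self.t_end - self.t_start) / delta_t))
        t = self.spike_times(neuron_id)
        edges = self.t_start + delta_t * np.arange(n_bins + 1)
        counts, _ = np.histogram(t, bins=edges)
        return counts.astype(np.float64)
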