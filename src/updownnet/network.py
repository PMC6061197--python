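"""Random directed network construction, stimulation, and simulation.

The network is a sparse directed Erdos-Renyi graph: every ordered pair of
distinct nodes is connected with probability ``p`` (default 0.01 at
``N = 2**10``, giving a mean in-degree ``p (N-1) ~ 10``).  Excitatory and
inhibitory subpopulations are sized 4:1; each subpopulation is a mixture of
electrophysiological classes (RS/CH excitatory, FS/LTS inhibitory).

Simulation integrates the coupled neuron + conductance equations with the
stochastic Heun scheme at ``dt = 0.05`` ms by default; spikes detected at
the end of a step reset the neuron and deliver conductance jumps to all
postsynaptic targets at the next step (no conduction delays).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _kernels
from .neurons import EXCITATORY_CLASSES, IZHIKEVICH, NeuronParams, resting_state
from .raster import Raster
from .synapses import SynapseParams

ALLOWED_STIM_FRACTIONS = (1.0, 0.5, 0.25, 0.125, 0.0625)


@dataclass
class NetworkConfig:
    """Network size, sparseness and neuron-class composition.

    ``exc_composition`` / ``inh_composition`` give the fraction of each
    class *within its subpopulation* (they must each sum to 1).  The
    default is the all-RS / all-LTS mixture; the mixed cortical composition
    used in many experiments is ``{"RS": 0.8, "CH": 0.2}`` excitatory with
    LTS inhibition (i.e. 64% RS, 16% CH, 20% LTS overall).
    """

    N: int = 2**10
    p: float = 0.01
    exc_fraction: float = 0.8
    exc_composition: dict = field(default_factory=lambda: {"RS": 1.0})
    inh_composition: dict = field(default_factory=lambda: {"LTS": 1.0})
    model_kind: str = IZHIKEVICH
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.p < 1:
            raise ValueError("connection probability must satisfy 0 < p < 1")
        if self.N < 2:
            raise ValueError("need at least two neurons")
        for comp, allowed in (
            (self.exc_composition, EXCITATORY_CLASSES),
            (self.inh_composition, ("FS", "LTS")),
        ):
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError(f"composition fractions must sum to 1: {comp}")
            for label in comp:
                if label not in allowed:
                    raise ValueError(f"class {label!r} not allowed in {allowed}")


@dataclass
class Connectivity:
    """Directed adjacency (CSR by presynaptic neuron) plus class labels."""

    indptr: np.ndarray  # len N+1; targets of neuron i are targets[indptr[i]:indptr[i+1]]
    targets: np.ndarray
    labels: np.ndarray  # per-neuron class label (str)
    is_exc: np.ndarray  # bool per neuron
    n_ex: np.ndarray  # excitatory in-degree per neuron
    n_in: np.ndarray  # inhibitory in-degree per neuron

    @property
    def N(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.targets.size)

    def in_degree(self) -> np.ndarray:
        return self.n_ex + self.n_in


def _class_counts(n: int, composition: dict) -> dict:
    """Deterministic integer counts per class (largest-remainder rounding)."""
    items = sorted(composition.items())
    raw = [(label, frac * n) for label, frac in items]
    counts = {label: int(np.floor(x)) for label, x in raw}
    short = n - sum(counts.values())
    remainders = sorted(raw, key=lambda kv: kv[1] - np.floor(kv[1]), reverse=True)
    for label, _ in remainders[:short]:
        counts[label] += 1
    return counts


def build_network(config: NetworkConfig) -> Connectivity:
    """Draw the random graph and assign neuron classes.

    Every ordered pair (i, j), i != j, is an edge independently with
    probability ``p`` (no self-loops).  Class counts are deterministic
    (rounded from the composition fractions); their placement among the
    node indices is a seeded shuffle.
    """
    rng = np.random.default_rng(config.seed)
    N = config.N

    adj = rng.random((N, N)) < config.p
    np.fill_diagonal(adj, False)
    src, tgt = np.nonzero(adj)
    indptr = np.zeros(N + 1, dtype=np.int64)
    np.cumsum(np.bincount(src, minlength=N), out=indptr[1:])
    targets = tgt.astype(np.int64)

    n_exc = int(round(N * config.exc_fraction))
    exc_counts = _class_counts(n_exc, config.exc_composition)
    inh_counts = _class_counts(N - n_exc, config.inh_composition)
    label_list = []
    for label, cnt in sorted(exc_counts.items()):
        label_list += [label] * cnt
    for label, cnt in sorted(inh_counts.items()):
        label_list += [label] * cnt
    labels = np.array(label_list, dtype=object)
    perm = rng.permutation(N)
    placed = np.empty(N, dtype=object)
    placed[perm] = labels
    labels = placed

    is_exc = np.array([lab in EXCITATORY_CLASSES for lab in labels], dtype=bool)
    n_ex = adj[is_exc, :].sum(axis=0).astype(np.int64)
    n_in = adj[~is_exc, :].sum(axis=0).astype(np.int64)

    return Connectivity(
        indptr=indptr,
        targets=targets,
        labels=labels,
        is_exc=is_exc,
        n_ex=n_ex,
        n_in=n_in,
    )


@dataclass
class StimulationProtocol:
    """Brief constant-current kick delivered to a subset of neurons.

    The amplitude range 10-20 and durations 50-300 ms span the stimulation
    grid of the deterministic experiments; after ``t_stim`` the network
    evolves freely.
    """

    I_stim: float = 15.0
    t_stim: float = 100.0
    fraction: float = 1.0
    target_seed: int = 0

    def __post_init__(self):
        if not any(abs(self.fraction - f) < 1e-12 for f in ALLOWED_STIM_FRACTIONS):
            raise ValueError(
                f"fraction must be one of {ALLOWED_STIM_FRACTIONS}, got {self.fraction}"
            )


@dataclass
class Stimulus:
    """Per-neuron constant amplitude on [0, t_stim); zero afterwards."""

    amplitude: np.ndarray
    t_stim: float

    def current(self, t: float) -> np.ndarray:
        return self.amplitude if t < self.t_stim else np.zeros_like(self.amplitude)


def make_stimulus(protocol: StimulationProtocol, connectivity: Connectivity) -> Stimulus:
    N = connectivity.N
    k = int(np.floor(N * protocol.fraction))
    rng = np.random.default_rng(protocol.target_seed)
    chosen = rng.choice(N, size=k, replace=False)
    amp = np.zeros(N)
    amp[chosen] = protocol.I_stim
    return Stimulus(amplitude=amp, t_stim=protocol.t_stim)


@dataclass
class SimResult:
    """Raster plus sampled traces sharing one time base.

    ``mean_*`` traces are network averages at every recording sample;
    ``rec_ids`` lists the neurons with full per-neuron traces in ``v, u,
    Gex, Gin`` (columns in recording order).
    """

    raster: Raster
    t: np.ndarray
    mean_v: np.ndarray
    mean_u: np.ndarray
    mean_Gex: np.ndarray
    mean_Gin: np.ndarray
    rec_ids: np.ndarray
    v: Optional[np.ndarray]
    u: Optional[np.ndarray]
    Gex: Optional[np.ndarray]
    Gin: Optional[np.ndarray]
    dt: float
    t_end: float
    n_resets: int
    config: dict

    def spike_times(self, neuron_id: int) -> np.ndarray:
        return self.raster.spike_times(neuron_id)

    def trace_column(self, neuron_id: int) -> int:
        idx = np.nonzero(self.rec_ids == neuron_id)[0]
        if idx.size == 0:
            raise KeyError(f"neuron {neuron_id} was not recorded")
        return int(idx[0])


def _per_neuron_params(conn: Connectivity, model_kind: str):
    by_class = {lab: NeuronParams.from_class(lab, model_kind) for lab in set(conn.labels)}
    N = conn.N
    a = np.empty(N)
    b = np.empty(N)
    c = np.empty(N)
    d = np.empty(N)
    for j, lab in enumerate(conn.labels):
        p = by_class[lab]
        a[j], b[j], c[j], d[j] = p.a, p.b, p.c, p.d
    ref = next(iter(by_class.values()))
    return a, b, c, d, ref, by_class


def rest_initial_state(conn: Connectivity, model_kind: str = IZHIKEVICH):
    """All neurons at their class resting state with zero conductances."""
    v0 = np.empty(conn.N)
    u0 = np.empty(conn.N)
    rests = {}
    for lab in set(conn.labels):
        params = NeuronParams.from_class(lab, model_kind)
        state = resting_state(params, 0.0)
        if state is None:  # pragma: no cover - rest exists for all classes
            raise RuntimeError(f"class {lab} has no resting state at I=0")
        rests[lab] = state
    for j, lab in enumerate(conn.labels):
        v0[j] = rests[lab].v
        u0[j] = rests[lab].u
    return v0, u0, np.zeros(conn.N), np.zeros(conn.N)


def simulate(
    connectivity: Connectivity,
    synapses: SynapseParams,
    t_end: float,
    *,
    model_kind: str = IZHIKEVICH,
    stimulus: Optional[Stimulus] = None,
    dt: float = 0.05,
    record_interval: float = 1.0,
    record_neurons: Optional[Sequence[int]] = None,
    initial_state: Optional[tuple] = None,
    reflect: bool = True,
    seed: int = 0,
    stop_when_silent_ms: Optional[float] = None,
) -> SimResult:
    """Integrate the network and return raster + traces.

    With ``D = 0``, no stimulus and all neurons at rest the network stays
    exactly at rest (zero spikes).  Numeric blow-up (non-finite or
    ``|v| > 500`` mV) aborts with a RuntimeError.

    ``stop_when_silent_ms`` (noiseless runs only): once no spike has
    occurred for that long after the stimulus, and all conductances have
    decayed below 1e-10, the network can never fire again; integration
    stops and the remaining trace samples hold the state at that instant.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if dt > record_interval:
        raise ValueError("dt must not exceed record_interval")

    a, b, c, d, ref, _ = _per_neuron_params(connectivity, model_kind)
    N = connectivity.N

    if initial_state is None:
        v0, u0, gex0, gin0 = rest_initial_state(connectivity, model_kind)
    else:
        v0, u0, gex0, gin0 = (np.array(x, dtype=float) for x in initial_state)

    if stimulus is None:
        stim_amp = np.zeros(N)
        t_stim = 0.0
    else:
        stim_amp = np.asarray(stimulus.amplitude, dtype=float)
        t_stim = float(stimulus.t_stim)

    rec_ids = np.asarray(
        [] if record_neurons is None else list(record_neurons), dtype=np.int64
    )

    n_steps = int(round(t_end / dt))
    rec_every = max(1, int(round(record_interval / dt)))
    sqdt = np.sqrt(dt)
    sig_ex = np.sqrt(2.0 * synapses.D * connectivity.n_ex.astype(float)) * sqdt
    sig_in = np.sqrt(2.0 * synapses.D * connectivity.n_in.astype(float)) * sqdt

    kind = 0 if model_kind == IZHIKEVICH else 1

    out = _kernels.integrate_network(
        kind,
        a, b, c, d, c.copy(),
        ref.alpha, ref.beta, ref.gamma, ref.v_peak,
        ref.adex_gL, ref.adex_DeltaT, ref.adex_vT, ref.adex_offset,
        synapses.E_ex, synapses.E_in, synapses.tau_ex, synapses.tau_in,
        synapses.g_ex, synapses.g_in,
        sig_ex, sig_in,
        connectivity.indptr, connectivity.targets, connectivity.is_exc,
        stim_amp, t_stim,
        v0.copy(), u0.copy(), gex0.copy(), gin0.copy(),
        dt, n_steps, rec_every,
        rec_ids,
        seed,
        reflect,
        0 if stop_when_silent_ms is None else int(round(stop_when_silent_ms / dt)),
    )
    (
        status, spike_t, spike_id, n_resets,
        t_rec, mean_v, mean_u, mean_gex, mean_gin,
        sub_v, sub_u, sub_gex, sub_gin,
    ) = out
    if status != _kernels.STATUS_OK:
        raise RuntimeError(
            "numeric blow-up during integration (|v| exceeded the sanity "
            "bound); reduce dt or check parameters"
        )

    raster = Raster(
        times=spike_t,
        ids=spike_id,
        N=N,
        t_start=0.0,
        t_end=t_end,
        labels=connectivity.labels,
    )
    have_sub = rec_ids.size > 0
    config = {
        "N": N,
        "model_kind": model_kind,
        "dt": dt,
        "t_end": t_end,
        "record_interval": record_interval,
        "seed": seed,
        "D": synapses.D,
        "g_ex": synapses.g_ex,
        "g_in": synapses.g_in,
        "reflect": bool(reflect),
        "t_stim": t_stim,
    }
    return SimResult(
        raster=raster,
        t=t_rec,
        mean_v=mean_v,
        mean_u=mean_u,
        mean_Gex=mean_gex,
        mean_Gin=mean_gin,
        rec_ids=rec_ids,
        v=sub_v if have_sub else None,
        u=sub_u if have_sub else None,
        Gex=sub_gex if have_sub else None,
        Gin=sub_gin if have_sub else None,
        dt=dt,
        t_end=t_end,
        n_resets=int(n_resets),
        config=config,
    )


@dataclass
class Trial:
    """One stimulation trial of the deterministic setup."""

    sim: SimResult
    protocol: StimulationProtocol
    free_activity_ms: float  # time from stimulus end to last network spike
    kept: bool


def run_deterministic_trials(
    config: NetworkConfig,
    synapses: SynapseParams,
    protocols: Iterable[StimulationProtocol],
    *,
    t_end: float = 5000.0,
    min_duration: float = 400.0,
    dt: float = 0.05,
    record_interval: float = 1.0,
    seed: int = 0,
) -> list[Trial]:
    """Run the stimulation grid without noise and keep long-lived trials.

    The free-activity duration of a trial is the time from stimulus end to
    the last network spike; trials shorter than ``min_duration`` are
    discarded.  Requires ``D = 0``.
    """
    if synapses.D != 0:
        raise ValueError("deterministic trials require D = 0")
    conn = build_network(config)
    trials = []
    for i, protocol in enumerate(protocols):
        stim = make_stimulus(protocol, conn)
        sim = simulate(
            conn,
            synapses,
            t_end,
            model_kind=config.model_kind,
            stimulus=stim,
            dt=dt,
            record_interval=record_interval,
            seed=seed + i,
            stop_when_silent_ms=500.0,
        )
        if sim.raster.n_spikes:
            free = max(0.0, float(sim.raster.times.max()) - protocol.t_stim)
        else:
            free = 0.0
        trials.append(
            Trial(sim=sim, protocol=protocol, free_activity_ms=free, kept=free >= min_duration)
        )
    return [tr for tr in trials if tr.kept]
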