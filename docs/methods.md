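# Methods

## Model

`updownnet` simulates sparse random networks of two-variable spiking
neurons with conductance-based synapses and stochastic synaptic
conductances, and analyses the collective states they produce — in
particular the alternation between *active* periods (rhythmic up/down
oscillation of the population voltage) and *quiescent* periods (near-rest,
sparse irregular firing).

### Neurons

Each neuron follows

    dv/dt = F(v) − u + I(t)
    du/dt = a (b v − u)

with the fire-and-reset rule `v → c`, `u → u + d` when `v` reaches
`v_peak = 30 mV`.  For the Izhikevich model `F(v) = 0.04 v² + 5 v + 140`;
the AdEx variant replaces the quadratic with
`F(v) = −g_L (v − E_L) + g_L Δ_T exp((v − v_T)/Δ_T) − 46`
(`g_L = 1`, `Δ_T = 30`, `v_T = −65`, `E_L = c`), chosen so its fixed points
and nullcline shape are close to the quadratic model (the stable rest
points differ by ≈4 mV for RS parameters).  Units follow the dimensionless
Izhikevich convention: `v` in mV, time in ms, `u` and currents unitless.

Four electrophysiological classes are bundled (`a, b, c, d`):
regular-spiking RS (0.02, 0.2, −65, 8), chattering CH (0.02, 0.2, −50, 2),
fast-spiking FS (0.1, 0.2, −65, 2) and low-threshold-spiking LTS
(0.02, 0.25, −65, 2).  Excitatory populations are RS or RS/CH mixtures;
inhibitory populations are all-FS or all-LTS.

The rest state is the left intersection of the nullclines
`ū = F(v) + I` and `u* = b v`.  It disappears in a saddle-node bifurcation
at `I_sn = (β−b)²/4α − γ` and loses stability in a subcritical
Andronov–Hopf bifurcation at `I_H = ((β−b)² − (a−b)²)/4α − γ < I_sn`
(since `b > a` for all four classes).  For RS: `I_sn = 4`, `I_H = 3.7975`;
for LTS: `I_sn = 1.015625` — the larger `b` of LTS makes it far more
excitable, which dominates the network's weak-noise behavior.

### Synapses and noise

The synaptic current is `I_syn = G_ex (E_ex − v) + G_in (E_in − v)` with
`E_ex = 0`, `E_in = −80 mV`.  Each conductance obeys a jump-diffusion:
exponential decay (`τ_ex = 5 ms`, `τ_in = 6 ms`), an increment `g_ex`
(`g_in`) at each presynaptic spike arrival, and additive white noise of
amplitude `sqrt(2 D n)`, where `n` is the neuron's in-degree of the
matching sign — the Ornstein–Uhlenbeck approximation of many independent
miniature-PSP sources, whose variance grows linearly with the number of
afferents.  The stationary law of the free process is Gaussian with
variance `D·n·τ`; this closed form is the Monte-Carlo reference for the
simulated conductances.  Conductances are reflected at zero (`G ← |G|`)
by default; at rest this makes the conductance half-normal and shifts its
mean to `0.8·sqrt(D n τ)`.  A free-OU mode (negative excursions allowed)
exists as a diagnostic; in our experiments it does not change the regime
structure.

Canonical increments are `g_ex = 0.15`, `g_in = 1`.  Note that a single
EPSP of size 0.15 delivers a peak current ≈10 at rest — far above
`I_sn` — so one excitatory spike onto a *resting* neuron is suprathreshold
(it fires ≈5 ms later), while a neuron that spiked recently is protected
for ≈50–60 ms by its elevated recovery variable (`u + d` decays with
`τ = 1/a = 50 ms`).  This pair of facts drives everything collective:
waves of excitation ignite explosively, terminate by synchronized
adaptation, and cannot re-ignite until `u` has decayed.

### Network

Directed Erdős–Rényi graph: each ordered pair is an edge with probability
`p = 0.01` at `N = 2¹⁰` (mean in-degree `p(N−1) ≈ 10`), no self-loops.
Excitatory:inhibitory is 4:1; class counts are deterministic (largest
remainder), their placement a seeded shuffle.  Class composition and all
graph draws are reproducible bit-exactly from the config seed.

### Integration

Stochastic Heun (predictor–corrector) at `dt = 0.05 ms` (configurable);
the same Wiener increment enters predictor and corrector, which is the
standard stochastic Heun for additive noise (Itô = Stratonovich here).
Spikes are detected at step end (`v ≥ v_peak`), the recorded sample is
clamped to `v_peak`, the reset is applied, and conductance jumps reach the
postsynaptic targets at the next step (no conduction delays).  Halving
`dt` changes the time-averaged rate of a fixed-seed noisy run by <5%
(tested).  Non-finite state aborts with a diagnostic.  The inner loop is
compiled with numba; the pure-Python single-step operations
(`derivatives`, `conductance_step`) remain the reference implementation
and the kernel is pinned to them by equivalence tests.

Initial conditions for noisy runs: every neuron at its class rest with
zero conductances.  Deterministic runs are started with a brief
stimulation kick (amplitude 10–20, duration 50–300 ms, applied to a
fraction 1, 1/2, …, 1/16 of the neurons); trials whose free activity after
stimulus end is shorter than 400 ms are discarded.

## Measures

* **Population rate** `r(t; Δt)`: spike count per neuron per `Δt = 1 ms`
  bin, reported in Hz.
* **Power spectra**: one-sided periodograms `|x̃|²/T`.  Spike trains enter
  as 1-ms binned counts (units 1/s; a Poisson train's high-frequency
  plateau equals its rate — tested), voltages as sampled traces
  (mV²/Hz).  Ensemble averages are pointwise means over neurons; smoothing
  is a centered 20-point moving average with edge truncation; spectral
  peaks exclude the zero-frequency bin; `1/f^n` exponents are least-squares
  slopes of log S vs log f between 10 and 200 Hz on the smoothed curve.
* **Spectral entropy** `H_s`: Shannon entropy of the normalized rate
  spectrum over `N_b = 1000` frequency bins, divided by `log N_b`.  The
  rate is mean-subtracted first (the DC offset carries no information
  about rhythmicity and would otherwise dominate the normalization), then
  zero-padded to at least `2 N_b` samples, and the one-sided periodogram is
  block-averaged into exactly `N_b` bins.  Block-averaging also suppresses
  the χ²₂ scatter of raw periodogram ordinates, so broadband noise
  measures `H_s → 1` and a pure sinusoid `H_s → 0` as intended.
* **Phase-locking value**: for `K = 60` random neuron pairs with at least
  2 spikes in a 2000-ms window, trains are binned at 1 ms, mean-subtracted
  and converted to analytic signals `z = x + i H[x]`.  The per-pair
  statistic is `|⟨z_x z_y*⟩| / sqrt(⟨|z_x|²⟩⟨|z_y|²⟩)` — the
  amplitude-weighted phase-difference phasor average — and the PLV is the
  mean over pairs.  Amplitude weighting matters: a sparse binned train
  carries phase information only near its spikes, and the *unweighted*
  Hilbert phase sits pinned at ±π between events, inflating the
  independent-train null to ≈0.4.  With weighting the estimator has the
  correct limits: exactly 1 for identical trains, `O(1/√T)` (measured
  ≈0.02 at T = 2000 ms) for independent trains.  The unweighted form
  remains available (`weighting="none"`).  PLV saturates in `K` for
  `K ≥ 50` (tested: |PLV₆₀ − PLV₁₂₀| < 0.05).
* **Balance estimate**: the mean-input formula
  `I ≈ g_ex C_ex ν_ex τ_ex (E_ex − ⟨v⟩) − g_in C_in ν_in τ_in (E_in − ⟨v⟩)`
  is provided with the explicit minus sign as its default
  (`sign_convention="subtract"`).  Note that with
  `E_in < ⟨v⟩` this minus sign makes the inhibitory term *add*
  current; the summed convention (`"sum"`), under which the classical
  LIF-style symmetric case balances at `g_in/g_ex = C_ex/C_in`, is the
  documented alternative.  Rates are accepted in Hz and converted to 1/ms
  internally.

## State segmentation

Per-1-ms-bin labels from the network-mean voltage and the population rate:
**down** when the voltage is within 5 mV of −80 mV; **up** when the rate
is at or above 20% of its window maximum (and the voltage is not in the
down band); **rest** otherwise.  The "20% of maximum" reading (rather than
the mean) is the only one that matches the low-rate quiescent
phenomenology; both the fraction and the reference are configurable and
recorded with the labels.  Voltage bands are anchored at the
composition-weighted resting voltage (rest half-width 3 mV).

Runs of up/down labels merge into **active** periods and rest runs into
**quiescent** periods, with a 20-ms hysteresis (`min_gap`) absorbing
single-bin flicker; up/down sub-intervals inside active periods use a 5-ms
merge.  Duration statistics report mean, SD, SE (flagged undefined for a
single interval), histograms, >3 SD outliers, and an exponential-shape
diagnostic (R² of the log empirical survival).  Segment-wise spectral
entropy is the duration-weighted mean over segments of at least 100 ms
(shorter segments carry too few independent frequencies; quiescent
periods here are ~100 ms, see below).

Voltage histograms report median, mean and a modality count (peaks of the
lightly smoothed histogram with ≥5% relative prominence) used to identify
the bimodal (deterministic oscillation), unimodal (weak-noise AI) and
trimodal (intermittent) regimes.

## Synthetic fixtures

Generators with known ground truth make every measure testable without the
simulator: independent Poisson rasters (the asynchronous-irregular limit:
`H_s > 0.9`, PLV < 0.1), periodic rasters with per-spike Gaussian jitter
and per-burst participation (oscillatory limit; note the measured
H_s-vs-jitter curve is U-shaped — many harmonics at zero jitter — so the
oscillatory-limit tests use jitter of a few ms), and two/three-level
voltage traces with exponential dwell times and matched rate series
(classifier ground truth; dwell means are recovered within 10% over 20
seeds).  All fixtures are bit-exact functions of (parameters, seed).

## What the experiments show (and what they do not)

Desk-scale problem sizes: 3-s runs (3 seeds) for the weak-noise state,
10-s runs for the intermittent and strong-noise states, 5-s horizons for
deterministic trials, 60-s runs per noise level for the duration scan,
and coarse (2×2 to 3×3) sweep grids standing in for the full state
diagram.  These sizes were chosen as the smallest at which the measured
quantities stabilize across seeds.

Reproduced faithfully at those sizes: rest stability without noise;
stimulated deterministic networks with `g_in > g_ex` oscillate between
depolarized and hyperpolarized collective states at ≈10 Hz (measured
10.5 Hz) with bimodal voltage histograms; the weak-noise (D = 2.5e-6)
state is asynchronous and non-oscillatory with inhibitory rates ≈8.5 Hz,
PLV ≈ 0.02 and a unimodal near-rest voltage histogram; stronger noise
produces alternation between oscillatory activity and near-rest episodes
with a hyperpolarized voltage band, rising synchrony and a ~10 Hz
spectral peak; quiescent durations shrink with `D` toward a floor set by
the adaptation-recovery time.

Known quantitative departures (documented, not calibrated away): emergent
lifetime-type quantities are systematically shorter here — deterministic
free-activity transients are a few hundred ms rather than seconds, and
quiescent/active periods at D = 1e-5…5e-5 last tens-to-~150 ms rather
than 10²–10³ ms.  Excitatory firing in the weak-noise state is strongly
realization-dependent: the isolated-RS escape time at the equivalent
noise extrapolates to ~10⁹ s, so most network draws show silent
excitatory populations, while a minority (~1 in 10 probed seeds) contain
trigger motifs that ignite recurrent cascades and fire at ~2 Hz;
multi-seed averages of the excitatory rate and of H_s therefore have very
wide sampling distributions at D = 2.5e-6.  The
ignition/quenching balance of the recurrent cascade is near-critical and
exponentially sensitive to the noise seen by resting neurons; we verified
that neither the conductance boundary condition (reflected vs free OU),
nor `dt` refinement, nor a global noise rescaling can move these
lifetimes without simultaneously breaking the weak-noise inhibitory-rate
anchor.  Consequences for specific checks are reported as measured.

Passing the fixture-based tests shows the *measures* behave correctly on
signals with known structure; it does not by itself validate the
simulator against biological data, and none of the fixtures emulate
heavy-tailed in-degree structure, conduction delays or synaptic
plasticity, which the model does not contain.

## Numerical choices and degenerate inputs

All RNG paths go through seeded generators (`numpy.random.default_rng` in
Python, seeded MT19937 inside the numba kernels); every public experiment
is a pure function of (configuration, seed).  Spectral entropy of a
constant rate series, PLV of a window without two spiking neurons,
duration statistics of an empty interval class, and first-spike times at
`D = 0` (rest is stable forever) are all rejected with explicit errors
rather than returning numbers.  AdEx resting states use bracketed root
finding to 1e-10 mV.  Blow-up (non-finite state) aborts a simulation with
a diagnostic rather than propagating NaNs.

## Limitations

No conduction delays, short-term plasticity or voltage-dependent (NMDA)
synapses; only the four bundled neuron classes; exact event timing is
resolved to the integration step, not event-driven; the full-resolution
state diagram and 10-minute duration curves are replaced by coarse grids
and 60-s runs, with the qualitative trends (not full-scale per-cell
values) as the test surface.
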