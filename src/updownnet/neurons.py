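"""Single-neuron dynamics: Izhikevich and AdEx models.

Both models share the two-variable structure

    dv/dt = F(v) - u + I(t),        du/dt = a (b v - u),

with a fire-and-reset rule: when ``v`` reaches ``v_peak`` the neuron spikes,
``v`` is reset to ``c`` and the recovery variable ``u`` is incremented by
``d``.  For the Izhikevich model ``F(v) = alpha v^2 + beta v + gamma`` is
quadratic; for the AdEx variant used here,

    F(v) = -g_L (v - E_L) + g_L Delta_T exp((v - v_T)/Delta_T) + offset,

with constants chosen so that the fixed points and nullcline shape are close
to the quadratic model (``E_L`` is tied to the reset voltage ``c``).

Units follow the dimensionless Izhikevich convention: ``v`` in mV, time in
ms, currents and ``u`` are unitless model quantities.

Four electrophysiological classes are bundled: regular spiking (RS) and
chattering (CH) excitatory neurons, fast spiking (FS) and low-threshold
spiking (LTS) inhibitory neurons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import yaml
from scipy.optimize import brentq

IZHIKEVICH = "izhikevich"
ADEX = "adex"

EXCITATORY_CLASSES = ("RS", "CH")
INHIBITORY_CLASSES = ("FS", "LTS")
ALL_CLASSES = EXCITATORY_CLASSES + INHIBITORY_CLASSES


def _load_class_table() -> dict:
    with resources.files("updownnet.data").joinpath("neuron_classes.yml").open() as fh:
        return yaml.safe_load(fh)


_TABLE = _load_class_table()


@dataclass(frozen=True)
class NeuronParams:
    """Dynamical constants of one neuron class.

    ``a`` is the recovery rate constant (1/ms), ``b`` couples ``v`` into
    ``u``, ``c`` is the reset voltage (mV) and ``d`` the recovery increment
    per spike.  ``alpha, beta, gamma, v_peak`` are shared across classes.
    The ``adex_*`` constants are only used when ``model_kind == "adex"``;
    the AdEx leak reversal equals the reset voltage ``c``.
    """

    model_kind: str = IZHIKEVICH
    class_label: str = "RS"
    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    alpha: float = 0.04
    beta: float = 5.0
    gamma: float = 140.0
    v_peak: float = 30.0
    adex_gL: float = 1.0
    adex_DeltaT: float = 30.0
    adex_vT: float = -65.0
    adex_offset: float = -46.0

    def __post_init__(self):
        if self.model_kind not in (IZHIKEVICH, ADEX):
            raise ValueError(f"unknown model kind {self.model_kind!r}")

    @property
    def adex_EL(self) -> float:
        return self.c

    @property
    def is_excitatory(self) -> bool:
        return self.class_label in EXCITATORY_CLASSES

    @classmethod
    def from_class(cls, label: str, model_kind: str = IZHIKEVICH) -> "NeuronParams":
        """Load the bundled parameter set for an electrophysiological class."""
        try:
            row = _TABLE["classes"][label]
        except KeyError:
            raise KeyError(
                f"unknown neuron class {label!r}; available: {sorted(_TABLE['classes'])}"
            ) from None
        common = _TABLE["common"]
        adex = _TABLE["adex"]
        return cls(
            model_kind=model_kind,
            class_label=label,
            a=float(row["a"]),
            b=float(row["b"]),
            c=float(row["c"]),
            d=float(row["d"]),
            alpha=float(common["alpha"]),
            beta=float(common["beta"]),
            gamma=float(common["gamma"]),
            v_peak=float(common["v_peak"]),
            adex_gL=float(adex["gL"]),
            adex_DeltaT=float(adex["DeltaT"]),
            adex_vT=float(adex["vT"]),
            adex_offset=float(adex["offset"]),
        )


@dataclass
class NeuronState:
    """Instantaneous (voltage, recovery) pair."""

    v: float
    u: float


@dataclass(frozen=True)
class CriticalCurrents:
    """Bifurcation current thresholds of the rest state.

    ``I_sn``: the rest equilibrium disappears in a saddle-node bifurcation.
    ``I_H``: the equilibrium loses stability in a subcritical Andronov-Hopf
    bifurcation; for ``b > a`` this happens below ``I_sn``, so spiking starts
    already at ``I_H``.
    """

    I_sn: float
    I_H: float


@dataclass
class Nullclines:
    """Sampled nullclines on a voltage grid at a given input current."""

    v: np.ndarray
    u_bar: np.ndarray  # v-nullcline: u = F(v) + I
    u_star: np.ndarray  # u-nullcline: u = b v
    I_used: float


def voltage_rhs_curve(params: NeuronParams, v, I: float = 0.0):
    """``F(v) + I``, the v-nullcline ``u_bar`` evaluated at voltage(s) ``v``."""
    v = np.asarray(v, dtype=float)
    if params.model_kind == IZHIKEVICH:
        out = params.alpha * v**2 + params.beta * v + params.gamma + I
    else:
        gL, DT = params.adex_gL, params.adex_DeltaT
        out = (
            -gL * (v - params.adex_EL)
            + gL * DT * np.exp((v - params.adex_vT) / DT)
            + params.adex_offset
            + I
        )
    return out if out.ndim else float(out)


def derivatives(state: NeuronState, I: float, params: NeuronParams) -> tuple[float, float]:
    """Instantaneous (dv/dt, du/dt) for either model kind."""
    if not (math.isfinite(state.v) and math.isfinite(state.u) and math.isfinite(I)):
        raise ValueError(
            f"non-finite neuron state or current: v={state.v}, u={state.u}, I={I}"
        )
    dv = voltage_rhs_curve(params, state.v, I) - state.u
    du = params.a * (params.b * state.v - state.u)
    return float(dv), float(du)


def apply_reset(state: NeuronState, params: NeuronParams) -> NeuronState:
    """Fire-and-reset rule: ``v -> c``, ``u -> u + d``.

    Must only be called after a spike was detected (``v >= v_peak``).
    """
    if state.v < params.v_peak:
        raise ValueError(
            f"apply_reset called with v={state.v} < v_peak={params.v_peak}"
        )
    return NeuronState(v=params.c, u=state.u + params.d)


def critical_currents(params: NeuronParams) -> CriticalCurrents:
    """Closed-form saddle-node and Andronov-Hopf currents (Izhikevich only)."""
    if params.model_kind != IZHIKEVICH:
        raise ValueError("closed-form critical currents require the izhikevich model")
    bb = (params.beta - params.b) ** 2
    I_sn = bb / (4 * params.alpha) - params.gamma
    I_H = (bb - (params.a - params.b) ** 2) / (4 * params.alpha) - params.gamma
    return CriticalCurrents(I_sn=I_sn, I_H=I_H)


def resting_state(params: NeuronParams, I: float = 0.0) -> Optional[NeuronState]:
    """Stable (left) intersection of the nullclines, or None above ``I_sn``.

    For the quadratic model the intersection condition
    ``alpha v^2 + (beta - b) v + gamma + I = 0`` is solved in closed form;
    for AdEx the leftmost root is bracketed on a voltage grid and refined
    numerically to 1e-10 mV.
    """
    if params.model_kind == IZHIKEVICH:
        disc = (params.beta - params.b) ** 2 - 4 * params.alpha * (params.gamma + I)
        if disc < 0:
            return None
        v = (-(params.beta - params.b) - math.sqrt(disc)) / (2 * params.alpha)
        return NeuronState(v=v, u=params.b * v)

    def g(v: float) -> float:
        return voltage_rhs_curve(params, v, I) - params.b * v

    grid = np.linspace(-120.0, params.v_peak, 600)
    vals = np.array([g(v) for v in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        return None
    i = sign_change[0]  # leftmost crossing = stable equilibrium
    v = brentq(g, grid[i], grid[i + 1], xtol=1e-10)
    return NeuronState(v=v, u=params.b * v)


def nullclines(params: NeuronParams, I: float, v_grid: np.ndarray) -> Nullclines:
    """Sample ``u_bar = F(v) + I`` and ``u_star = b v`` on a voltage grid."""
    v_grid = np.asarray(v_grid, dtype=float)
    if v_grid.size == 0:
        raise ValueError("empty voltage grid")
    dv = np.diff(v_grid)
    if v_grid.size > 1 and not (np.all(dv > 0) or np.all(dv < 0)):
        raise ValueError("voltage grid must be monotone")
    return Nullclines(
        v=v_grid,
        u_bar=np.asarray(voltage_rhs_curve(params, v_grid, I)),
        u_star=params.b * v_grid,
        I_used=I,
    )


def jacobian(params: NeuronParams, v: float) -> np.ndarray:
    """Jacobian of the subthreshold flow at an equilibrium voltage ``v``."""
    if params.model_kind == IZHIKEVICH:
        dF = 2 * params.alpha * v + params.beta
    else:
        dF = -params.adex_gL + params.adex_gL * math.exp(
            (v - params.adex_vT) / params.adex_DeltaT
        )
    return np.array([[dF, -1.0], [params.a * params.b, -params.a]])
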