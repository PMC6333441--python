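"""Membrane biophysics: passive properties, Hodgkin–Huxley channels, NMDA gating.

The cell is passive everywhere except the soma, which carries fast Na and
delayed-rectifier K channels for action-potential generation plus a slow
non-inactivating K conductance for spike-frequency adaptation.  The NMDA
receptor conductance carries the voltage-dependent magnesium-block factor

    g_NMDA(V) = 1 / (1 + 0.25 * exp(-0.08 * V))

which is the source of the regenerative dendritic nonlinearity (the NMDA
spike) that the whole model is about.

Units: potentials mV, time ms, specific conductances mS/cm², specific
capacitance µF/cm², membrane resistance Ω·cm², axial resistivity Ω·cm.
Current densities returned by :func:`ionic_current_density` are in µA/cm²
(mS/cm² × mV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "PassiveParams",
    "ChannelSet",
    "GatingState",
    "nmda_gating",
    "passive_time_constant",
    "gating_steady_state",
    "channel_currents",
    "ionic_current_density",
]


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane parameters (defaults are the model cell's values)."""

    Rm: float = 25_000.0  # Ω·cm² membrane resistance
    Ra: float = 100.0  # Ω·cm axial resistivity
    Cm: float = 1.0  # µF/cm² specific capacitance
    E_rest: float = -70.0  # mV resting (and leak reversal) potential

    def __post_init__(self) -> None:
        if self.Rm <= 0 or self.Ra <= 0 or self.Cm < 0:
            raise ValueError("Rm, Ra must be > 0 and Cm >= 0")


def passive_time_constant(p: PassiveParams) -> float:
    """Membrane time constant Rm·Cm in ms (Ω·cm² × µF/cm² = µs × 10³)."""
    return p.Rm * p.Cm * 1e-3


@dataclass(frozen=True)
class ChannelSet:
    """Voltage-gated conductance densities and their placement.

    The Hodgkin–Huxley rate functions are the canonical squid-axon forms
    with per-channel voltage shifts (``na_shift``, ``kdr_shift``, relative to
    the canonical −65 mV resting mapping) chosen so that the −70 mV resting
    state is stable with the high somatic densities used here.  The slow
    potassium conductance activates with a first-order Boltzmann gate
    (midpoint ``ks_vhalf``, slope ``ks_slope``, time constant ``ks_tau``),
    producing spike-frequency adaptation.
    """

    gNa: float = 1000.0  # mS/cm²
    ENa: float = 50.0  # mV
    gKdr: float = 500.0  # mS/cm²
    gKs: float = 20.0  # mS/cm²
    EK: float = -87.0  # mV
    na_shift: float = 10.0  # mV; positive shifts activation to more depolarized V
    kdr_shift: float = 20.0
    ks_vhalf: float = -25.0  # mV
    ks_slope: float = 6.0  # mV
    ks_tau: float = 100.0  # ms
    placement: str = "soma"  # "soma" | "all"

    def __post_init__(self) -> None:
        if min(self.gNa, self.gKdr, self.gKs) < 0:
            raise ValueError("conductance densities must be >= 0")
        if self.placement not in ("soma", "all"):
            raise ValueError("placement must be 'soma' or 'all'")

    @staticmethod
    def passive() -> "ChannelSet":
        return ChannelSet(gNa=0.0, gKdr=0.0, gKs=0.0)


# ---------------------------------------------------------------------------
# NMDA voltage dependence
# ---------------------------------------------------------------------------


def nmda_gating(Vm):
    """Fraction of NMDA conductance unblocked at membrane potential ``Vm``.

    ``1 / (1 + 0.25·exp(−0.08·Vm))``; strictly increasing, → 1 as Vm → +∞.
    Accepts scalars or arrays.
    """
    return 1.0 / (1.0 + 0.25 * np.exp(-0.08 * np.asarray(Vm, dtype=float)))


# ---------------------------------------------------------------------------
# Hodgkin–Huxley rate functions (scalar, numba-compiled; shared with engine)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _vtrap(x: float, y: float) -> float:
    # x / (1 - exp(-x/y)) with the removable singularity handled
    if abs(x / y) < 1e-6:
        return y + x / 2.0
    return x / (1.0 - math.exp(-x / y))


@njit(cache=True)
def na_rates(v: float, shift: float) -> tuple[float, float, float, float]:
    """(alpha_m, beta_m, alpha_h, beta_h) at absolute potential v (mV)."""
    # canonical squid frame rests at −65 mV; +5 maps the model's −70 mV rest
    # onto it, and `shift` then moves activation to more depolarized potentials
    u = v - shift + 5.0
    am = 0.1 * _vtrap(u + 40.0, 10.0)
    bm = 4.0 * math.exp(-(u + 65.0) / 18.0)
    ah = 0.07 * math.exp(-(u + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(u + 35.0) / 10.0))
    return am, bm, ah, bh


@njit(cache=True)
def kdr_rates(v: float, shift: float) -> tuple[float, float]:
    """(alpha_n, beta_n) for the delayed rectifier."""
    u = v - shift + 5.0
    an = 0.01 * _vtrap(u + 55.0, 10.0)
    bn = 0.125 * math.exp(-(u + 65.0) / 80.0)
    return an, bn


@njit(cache=True)
def ks_steady_tau(v: float, vhalf: float, slope: float, tau: float) -> tuple[float, float]:
    s_inf = 1.0 / (1.0 + math.exp(-(v - vhalf) / slope))
    return s_inf, tau


# ---------------------------------------------------------------------------
# gating state containers and updates (python-level API; the integration
# engine uses the same compiled rate functions inside its inner loop)
# ---------------------------------------------------------------------------


@dataclass
class GatingState:
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    s: np.ndarray

    def copy(self) -> "GatingState":
        return GatingState(self.m.copy(), self.h.copy(), self.n.copy(), self.s.copy())


def gating_steady_state(V, channels: ChannelSet) -> GatingState:
    """Steady-state gating variables at (per-compartment) potential V."""
    V = np.atleast_1d(np.asarray(V, dtype=float))
    m = np.empty_like(V)
    h = np.empty_like(V)
    n = np.empty_like(V)
    s = np.empty_like(V)
    for i, v in enumerate(V):
        am, bm, ah, bh = na_rates(v, channels.na_shift)
        an, bn = kdr_rates(v, channels.kdr_shift)
        s_inf, _ = ks_steady_tau(v, channels.ks_vhalf, channels.ks_slope, channels.ks_tau)
        m[i] = am / (am + bm)
        h[i] = ah / (ah + bh)
        n[i] = an / (an + bn)
        s[i] = s_inf
    return GatingState(m, h, n, s)


def _advance(state: GatingState, V: np.ndarray, channels: ChannelSet, dt: float) -> None:
    """Exact exponential relaxation of each gate toward its V-dependent target."""
    for i, v in enumerate(V):
        am, bm, ah, bh = na_rates(v, channels.na_shift)
        an, bn = kdr_rates(v, channels.kdr_shift)
        s_inf, s_tau = ks_steady_tau(
            v, channels.ks_vhalf, channels.ks_slope, channels.ks_tau
        )
        for arr, a, b in ((state.m, am, bm), (state.h, ah, bh), (state.n, an, bn)):
            inf = a / (a + b)
            tau = 1.0 / (a + b)
            arr[i] = inf + (arr[i] - inf) * math.exp(-dt / tau)
        state.s[i] = s_inf + (state.s[i] - s_inf) * math.exp(-dt / s_tau)


def ionic_current_density(state: GatingState, V, channels: ChannelSet) -> np.ndarray:
    """Total voltage-gated current density (µA/cm², outward positive)."""
    V = np.atleast_1d(np.asarray(V, dtype=float))
    g_na = channels.gNa * state.m**3 * state.h
    g_k = channels.gKdr * state.n**4 + channels.gKs * state.s
    return g_na * (V - channels.ENa) + g_k * (V - channels.EK)


def channel_currents(
    state: GatingState, V, channels: ChannelSet, dt: float
) -> tuple[np.ndarray, GatingState]:
    """Advance gating by ``dt`` at potential ``V``; return (current, new state).

    Current density is in µA/cm², outward positive.  Gating variables remain
    in [0, 1] by construction (exponential relaxation between fixed points).
    """
    V = np.atleast_1d(np.asarray(V, dtype=float))
    new = state.copy()
    _advance(new, V, channels, dt)
    return ionic_current_density(new, V, channels), new
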