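"""Synaptic conductances, stochastic vesicular release, presynaptic trains.

Excitatory synapses combine a fast AMPA conductance (instantaneous rise,
1.5 ms decay, 1 nS unitary) with a slow NMDA conductance (2 ms rise, 80 ms
decay, 2 nS unitary) whose voltage dependence lives in
:func:`piriform.biophysics.nmda_gating`.  Inhibition is GABA-A (instant
rise, 7 ms decay, 2 nS, reversal −70 mV).  All excitatory conductances
reverse at 0 mV.

"Unitary" conductance means the conductance reached when the synapse's full
presynaptic vesicle pool (5 vesicles) is released at once; each vesicle
contributes ``g_unit / n_slots``.  Release at each presynaptic spike is
binomial over the currently available vesicles with per-vesicle probability
0.1, and emptied slots refill independently at 100 s⁻¹.

Presynaptic "odor response" trains follow the in-vivo firing statistics of
mitral / piriform cells: excitatory onset 100 ± 6 ms, inhibitory onset
110 ± 6 ms, inter-spike intervals 8 ± 5 ms, spike counts 5 ± 3 (excitatory)
or 10 ± 3 (inhibitory).  Background activity is homogeneous Poisson at
10 Hz on 100 AMPA-only excitatory plus 20 inhibitory inputs spread uniformly
over the apical membrane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from piriform.biophysics import nmda_gating
from piriform.morphology import CompartmentGrid, DendriticLocation

__all__ = [
    "SynapseSpec",
    "ReleaseState",
    "PresynTrain",
    "TrainParams",
    "EXC_TRAIN",
    "INH_TRAIN",
    "ampa_spec",
    "nmda_spec",
    "gaba_spec",
    "conductance_step",
    "sample_release",
    "replenish",
    "generate_train",
    "poisson_train",
    "generate_background",
    "place_uniform",
]


@dataclass(frozen=True)
class SynapseSpec:
    """Kinetic description of one synaptic conductance at one location."""

    kind: str  # "AMPA" | "NMDA" | "GABA_A"
    g_unit: float  # nS, conductance of a full-pool release
    tau_rise: float  # ms; 0 = instantaneous rise
    tau_decay: float  # ms
    E_rev: float  # mV
    location: DendriticLocation

    def __post_init__(self) -> None:
        if self.kind not in ("AMPA", "NMDA", "GABA_A"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if self.g_unit < 0:
            raise ValueError("g_unit must be >= 0")
        if not self.tau_decay > self.tau_rise >= 0:
            raise ValueError("require tau_decay > tau_rise >= 0")

    @property
    def is_nmda(self) -> bool:
        return self.kind == "NMDA"

    @property
    def waveform_norm(self) -> float:
        """Scale factor giving a unit-peak waveform for a unit release."""
        if self.tau_rise == 0.0:
            return 1.0
        tr, td = self.tau_rise, self.tau_decay
        tp = tr * td / (td - tr) * math.log(td / tr)
        return 1.0 / (math.exp(-tp / td) - math.exp(-tp / tr))


def ampa_spec(location: DendriticLocation, g_unit: float = 1.0) -> SynapseSpec:
    return SynapseSpec("AMPA", g_unit, 0.0, 1.5, 0.0, location)


def nmda_spec(location: DendriticLocation, g_unit: float = 2.0) -> SynapseSpec:
    return SynapseSpec("NMDA", g_unit, 2.0, 80.0, 0.0, location)


def gaba_spec(location: DendriticLocation, g_unit: float = 2.0) -> SynapseSpec:
    return SynapseSpec("GABA_A", g_unit, 0.0, 7.0, -70.0, location)


def conductance_step(
    spec: SynapseSpec,
    released_fraction,
    elapsed,
    Vm: float = -70.0,
) -> float:
    """Instantaneous conductance (nS) from past release events.

    ``elapsed`` holds the times (ms) since each release event and
    ``released_fraction`` the fraction of the full pool released in each
    (scalar broadcasts).  Events superpose additively; the NMDA magnesium
    factor multiplies the summed conductance at the compartment potential.
    """
    elapsed = np.atleast_1d(np.asarray(elapsed, dtype=float))
    frac = np.broadcast_to(
        np.asarray(released_fraction, dtype=float), elapsed.shape
    )
    live = elapsed >= 0.0
    t = elapsed[live]
    f = frac[live]
    if spec.tau_rise == 0.0:
        wave = np.exp(-t / spec.tau_decay)
    else:
        wave = spec.waveform_norm * (
            np.exp(-t / spec.tau_decay) - np.exp(-t / spec.tau_rise)
        )
    g = spec.g_unit * float(np.sum(f * wave))
    if spec.is_nmda:
        g *= float(nmda_gating(Vm))
    return g


# ---------------------------------------------------------------------------
# vesicular release
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReleaseState:
    """State of one synapse's presynaptic vesicle pool."""

    n_slots: int = 5
    available: int = 5
    Pr: float = 0.1
    replenish_rate: float = 100.0  # s⁻¹ per empty slot

    def __post_init__(self) -> None:
        if not 0 <= self.available <= self.n_slots:
            raise ValueError("available must lie in [0, n_slots]")
        if not 0.0 <= self.Pr <= 1.0:
            raise ValueError("Pr must lie in [0, 1]")
        if self.replenish_rate < 0:
            raise ValueError("replenish_rate must be >= 0")


def sample_release(
    state: ReleaseState, rng: np.random.Generator
) -> tuple[int, ReleaseState]:
    """Binomial release over the available vesicles at a presynaptic spike."""
    released = int(rng.binomial(state.available, state.Pr))
    return released, replace(state, available=state.available - released)


def replenish(
    state: ReleaseState, dt: float, rng: np.random.Generator
) -> ReleaseState:
    """Refill empty slots over an interval ``dt`` (ms).

    Each empty slot refills independently with probability
    ``1 − exp(−rate·dt)`` (memoryless waiting time at the stated rate).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    empty = state.n_slots - state.available
    if empty == 0 or state.replenish_rate == 0.0:
        return state
    p = 1.0 - math.exp(-state.replenish_rate * dt * 1e-3)
    refilled = int(rng.binomial(empty, p))
    return replace(state, available=state.available + refilled)


def release_sequence(
    spike_times: np.ndarray,
    state: ReleaseState,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vesicles released at each spike of a train (depletion + replenishment)."""
    out = np.zeros(len(spike_times), dtype=np.int64)
    prev_t = None
    for i, t in enumerate(spike_times):
        if prev_t is not None and t > prev_t:
            state = replenish(state, float(t - prev_t), rng)
        out[i], state = sample_release(state, rng)
        prev_t = t
    return out


# ---------------------------------------------------------------------------
# presynaptic trains
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PresynTrain:
    """Sorted presynaptic spike times (ms) with generator metadata."""

    times: tuple[float, ...]
    meta: dict | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("spike times must be strictly increasing and >= 0")

    def shifted(self, dt_ms: float) -> "PresynTrain":
        return PresynTrain(tuple(t + dt_ms for t in self.times), self.meta)


@dataclass(frozen=True)
class TrainParams:
    start_mean: float = 100.0  # ms
    start_sd: float = 6.0
    isi_mean: float = 8.0  # ms
    isi_sd: float = 5.0
    count_mean: float = 5.0
    count_sd: float = 3.0


#: excitatory (LOT / IC) odor-response train statistics
EXC_TRAIN = TrainParams()
#: inhibitory trains start 10 ms later and fire about twice as many spikes
INH_TRAIN = TrainParams(start_mean=110.0, count_mean=10.0)

_MIN_ISI = 0.1  # ms floor on sampled inter-spike intervals


def generate_train(
    params: TrainParams | None = None,
    seed: int | np.random.Generator = 0,
    **overrides,
) -> PresynTrain:
    """Draw one presynaptic spike train from normal start/ISI/count statistics.

    The spike count is a rounded normal clipped at zero; ISIs are normal
    draws floored at 0.1 ms, so the mean realized ISI sits slightly above the
    nominal mean.  Deterministic for a fixed seed.
    """
    p = params or TrainParams()
    if overrides:
        p = replace(p, **overrides)
    if min(p.start_sd, p.isi_sd, p.count_sd) < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    count = max(0, int(round(rng.normal(p.count_mean, p.count_sd))))
    if count == 0:
        return PresynTrain((), meta={"params": p.__dict__.copy()})
    start = max(0.0, rng.normal(p.start_mean, p.start_sd))
    isis = np.maximum(rng.normal(p.isi_mean, p.isi_sd, size=count - 1), _MIN_ISI)
    times = start + np.concatenate([[0.0], np.cumsum(isis)])
    return PresynTrain(tuple(times), meta={"params": p.__dict__.copy()})


def poisson_train(
    rate_hz: float, duration_ms: float, rng: np.random.Generator
) -> PresynTrain:
    """Homogeneous Poisson spike train on [0, duration)."""
    if rate_hz < 0 or duration_ms < 0:
        raise ValueError("rate and duration must be >= 0")
    if rate_hz == 0.0:
        return PresynTrain(())
    n = rng.poisson(rate_hz * duration_ms * 1e-3)
    times = np.sort(rng.uniform(0.0, duration_ms, size=n))
    # enforce strict monotonicity (ties have probability ~0 but cost nothing)
    times = times + np.arange(n) * 1e-9
    return PresynTrain(tuple(times))


# ---------------------------------------------------------------------------
# placement and background population
# ---------------------------------------------------------------------------


def place_uniform(
    grid: CompartmentGrid,
    n: int,
    rng: np.random.Generator,
    zone: str | None = None,
    lot_band_start: float = 250.0,
) -> list[DendriticLocation]:
    """Draw locations uniformly over dendritic membrane area.

    ``zone`` restricts placement to one of ``'LOT' | 'IC' | 'perisomatic'``.
    """
    from piriform.morphology import classify_zone

    comps = [
        (i, c)
        for i, c in enumerate(grid.compartments)
        if c.section >= 0
    ]
    if zone is not None:
        comps = [
            (i, c)
            for i, c in comps
            if classify_zone(
                grid, DendriticLocation(c.section, c.arc_mid), lot_band_start
            )
            == zone
        ]
        if not comps:
            raise ValueError(f"no dendritic membrane in zone {zone!r}")
    areas = np.array([c.area for _, c in comps])
    probs = areas / areas.sum()
    picks = rng.choice(len(comps), size=n, p=probs)
    out = []
    for k in picks:
        _, c = comps[k]
        arc = c.arc_mid + (rng.uniform(-0.5, 0.5) * c.length) / (
            grid.morphology.sections[c.section].length
        )
        out.append(DendriticLocation(c.section, float(np.clip(arc, 0.0, 1.0))))
    return out


def generate_background(
    grid: CompartmentGrid,
    n_exc: int = 100,
    n_inh: int = 20,
    rate_hz: float = 10.0,
    duration_ms: float = 600.0,
    seed: int | np.random.Generator = 0,
    exc_g_unit: float = 1.0,
) -> list[tuple[SynapseSpec, PresynTrain]]:
    """Background synaptic population: AMPA-only excitation plus inhibition.

    Returns ``n_exc + n_inh`` (spec, train) pairs placed uniformly over the
    apical membrane, each driven by an independent Poisson train at
    ``rate_hz``.  Excitatory background synapses carry no NMDA component.
    ``exc_g_unit`` scales the excitatory conductance (the unitary-input
    calibration applies to all excitatory presynaptic cells).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    locs = place_uniform(grid, n_exc + n_inh, rng)
    out: list[tuple[SynapseSpec, PresynTrain]] = []
    for i in range(n_exc):
        out.append(
            (ampa_spec(locs[i], g_unit=exc_g_unit), poisson_train(rate_hz, duration_ms, rng))
        )
    for i in range(n_inh):
        out.append(
            (gaba_spec(locs[n_exc + i]), poisson_train(rate_hz, duration_ms, rng))
        )
    return out
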