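"""Assemble and integrate the compartmental electrical system.

A :class:`CompartmentalSystem` couples a discretized morphology with passive
membrane, somatic Hodgkin–Huxley channels, and a population of stochastic
synapses.  :func:`integrate` advances the branched cable equation

    C_i dV_i/dt = −I_leak − I_channels − I_syn + I_axial + I_inj

with an unconditionally stable implicit scheme (backward Euler with an exact
tree-ordered direct solve, see ``_kernel``).  Presynaptic release is sampled
before integration — release depends only on the presynaptic train and the
vesicle pool, never on postsynaptic voltage — from one independent random
substream per synapse, so results are reproducible bit-for-bit for a fixed
seed regardless of synapse iteration order.

Default integration step is 0.025 ms.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from piriform.biophysics import ChannelSet, PassiveParams
from piriform.morphology import CompartmentGrid, DendriticLocation
from piriform.synapses import (
    PresynTrain,
    ReleaseState,
    SynapseSpec,
    release_sequence,
)

__all__ = [
    "Synapse",
    "CurrentInjection",
    "VoltageClamp",
    "CompartmentalSystem",
    "SimResult",
    "IntegrationError",
    "integrate",
    "voltage_clamp",
]

DEFAULT_DT = 0.025  # ms

#: series conductance of the ideal voltage clamp (µS); large enough that the
#: residual series error on a 100 pA synaptic current is < 1e-4 mV
CLAMP_G = 1.0e4


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Synapse:
    """One presynaptic cell's synapse: co-located conductance channels
    sharing a single vesicle pool and spike train.

    ``scale`` multiplies the conductance contributed per released vesicle
    (the unitary-input calibration adjusts it).  With ``deterministic`` set,
    every presynaptic spike releases the full pool — used by analytic tests
    and the Ohmic/passive oracles.
    """

    channels: tuple[SynapseSpec, ...]
    train: PresynTrain
    release: ReleaseState = ReleaseState()
    scale: float = 1.0
    deterministic: bool = False


@dataclass(frozen=True)
class CurrentInjection:
    location: DendriticLocation | None  # None = soma
    amplitude_nA: float
    start_ms: float
    end_ms: float


@dataclass(frozen=True)
class VoltageClamp:
    location: DendriticLocation | None  # None = soma
    hold_mV: float


@dataclass(frozen=True)
class CompartmentalSystem:
    grid: CompartmentGrid
    passive: PassiveParams = PassiveParams()
    channels: ChannelSet = ChannelSet()
    synapses: tuple[Synapse, ...] = ()
    clamp: VoltageClamp | None = None
    injection: CurrentInjection | None = None
    ohmic_nmda: bool = False
    v_ohmic: float = -70.0  # mV at which the frozen NMDA gating is evaluated
    #: alternative reading of "unitary conductance": per released vesicle
    #: rather than per full pool
    g_unit_per_vesicle: bool = False

    def with_synapses(self, synapses: Sequence[Synapse]) -> "CompartmentalSystem":
        return replace(self, synapses=tuple(synapses))

    def add_synapses(self, synapses: Sequence[Synapse]) -> "CompartmentalSystem":
        return replace(self, synapses=self.synapses + tuple(synapses))

    def comp_of(self, loc: DendriticLocation | None) -> int:
        return 0 if loc is None else self.grid.comp_index(loc)


def set_ohmic_nmda(system: CompartmentalSystem, flag: bool) -> CompartmentalSystem:
    """Freeze (or unfreeze) the NMDA voltage dependence at ``v_ohmic``.

    With the flag on, the magnesium-block factor is evaluated at a fixed
    −70 mV for the whole simulation, which removes the regenerative NMDA
    nonlinearity while leaving the kinetic waveform untouched.
    """
    return replace(system, ohmic_nmda=bool(flag))


@dataclass
class SimResult:
    """Voltage (and clamp-current) traces with trial metadata."""

    t: np.ndarray  # ms, uniform grid
    traces: dict[str, np.ndarray]  # mV, keyed by record-site name
    clamp_current_pA: np.ndarray | None
    seed: int
    dt: float
    released: np.ndarray  # total vesicles released per synapse
    config_hash: str = ""

    def v(self, site: str = "soma") -> np.ndarray:
        return self.traces[site]

    def to_hdf5(self, path: str) -> None:
        """Write the time base, traces and metadata to an HDF5 file."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("time_ms", data=self.t)
            grp = fh.create_group("voltage_mV")
            for name, trace in self.traces.items():
                grp.create_dataset(name, data=trace)
            if self.clamp_current_pA is not None:
                fh.create_dataset("clamp_current_pA", data=self.clamp_current_pA)
            fh.create_dataset("released", data=self.released)
            fh.attrs["seed"] = self.seed
            fh.attrs["dt_ms"] = self.dt
            fh.attrs["config_hash"] = self.config_hash

    def to_csv(self, path: str) -> None:
        """Write the recorded traces as a tidy CSV (one column per site)."""
        import pandas as pd

        cols = {"time_ms": self.t, **{f"v_{k}_mV": v for k, v in self.traces.items()}}
        if self.clamp_current_pA is not None:
            cols["clamp_current_pA"] = self.clamp_current_pA
        pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# array assembly
# ---------------------------------------------------------------------------


def _passive_arrays(system: CompartmentalSystem):
    grid = system.grid
    p = system.passive
    n = grid.n_comp
    area_um2 = np.array([c.area for c in grid.compartments])
    cap = p.Cm * area_um2 * 1e-5  # nF
    g_leak = area_um2 * 1e-2 / p.Rm  # µS

    # axial half-resistances (Ω); the soma is isopotential with no axial term
    r_half = np.zeros(n)
    for i, c in enumerate(grid.compartments):
        if c.section < 0:
            continue
        r_half[i] = (2.0 * p.Ra * c.length / (math.pi * c.diameter**2)) * 1e4
    parent = np.array(grid.parent_comp, dtype=np.int64)
    g_ax = np.zeros(n)
    for i in range(1, n):
        g_ax[i] = 1e6 / (r_half[i] + r_half[parent[i]])
    return parent, g_ax, cap, g_leak


def _channel_arrays(system: CompartmentalSystem):
    grid = system.grid
    ch = system.channels
    n = grid.n_comp
    area_um2 = np.array([c.area for c in grid.compartments])
    mask = np.zeros(n, dtype=bool)
    if ch.placement == "soma":
        mask[0] = True
    else:
        mask[:] = True
    dens_to_uS = area_um2 * 1e-5  # mS/cm² × µm² → µS
    gbar_na = np.where(mask, ch.gNa * dens_to_uS, 0.0)
    gbar_kdr = np.where(mask, ch.gKdr * dens_to_uS, 0.0)
    gbar_ks = np.where(mask, ch.gKs * dens_to_uS, 0.0)
    return gbar_na, gbar_kdr, gbar_ks


def _synapse_arrays(system: CompartmentalSystem, duration: float, dt: float, seed: int):
    """Per-channel kinetic arrays and the presampled release event list."""
    grid = system.grid
    chan_comp: list[int] = []
    chan_e: list[float] = []
    chan_taur: list[float] = []
    chan_taud: list[float] = []
    chan_norm: list[float] = []
    chan_is_nmda: list[int] = []
    events: list[tuple[int, int, float]] = []  # (step, chan, weight µS)
    released_totals = np.zeros(len(system.synapses), dtype=np.int64)

    for j, syn in enumerate(system.synapses):
        times = np.array([t for t in syn.train.times if 0.0 <= t < duration])
        if syn.deterministic:
            rel = np.full(len(times), syn.release.n_slots, dtype=np.int64)
        else:
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=int(seed), spawn_key=(j,))
            )
            rel = release_sequence(times, syn.release, rng)
        released_totals[j] = rel.sum()
        base = len(chan_comp)
        for spec in syn.channels:
            chan_comp.append(grid.comp_index(spec.location))
            chan_e.append(spec.E_rev)
            chan_taur.append(spec.tau_rise)
            chan_taud.append(spec.tau_decay)
            chan_norm.append(spec.waveform_norm)
            chan_is_nmda.append(1 if spec.is_nmda else 0)
        for t, nves in zip(times, rel):
            if nves == 0:
                continue
            step = int(round(t / dt))
            for ci, spec in enumerate(syn.channels):
                if system.g_unit_per_vesicle:
                    w = syn.scale * spec.g_unit * nves
                else:
                    w = syn.scale * spec.g_unit * nves / syn.release.n_slots
                events.append((step, base + ci, w * 1e-3))  # nS → µS

    events.sort(key=lambda e: e[0])
    ev_step = np.array([e[0] for e in events], dtype=np.int64)
    ev_chan = np.array([e[1] for e in events], dtype=np.int64)
    ev_w = np.array([e[2] for e in events], dtype=float)
    return (
        np.array(chan_comp, dtype=np.int64),
        np.array(chan_e, dtype=float),
        np.array(chan_taur, dtype=float),
        np.array(chan_taud, dtype=float),
        np.array(chan_norm, dtype=float),
        np.array(chan_is_nmda, dtype=np.uint8),
        ev_step,
        ev_chan,
        ev_w,
        released_totals,
    )


def _config_hash(system: CompartmentalSystem, duration: float, dt: float, seed: int) -> str:
    payload = {
        "n_comp": system.grid.n_comp,
        "total_length": round(system.grid.morphology.total_length, 6),
        "passive": [system.passive.Rm, system.passive.Ra, system.passive.Cm,
                    system.passive.E_rest],
        "channels": [system.channels.gNa, system.channels.gKdr, system.channels.gKs],
        "n_syn": len(system.synapses),
        "ohmic": system.ohmic_nmda,
        "duration": duration,
        "dt": dt,
        "seed": seed,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def integrate(
    system: CompartmentalSystem,
    duration: float,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    record: dict[str, DendriticLocation | None] | None = None,
) -> SimResult:
    """Integrate the system for ``duration`` ms and return recorded traces.

    ``record`` maps trace names to dendritic locations (``None`` = soma);
    the soma is always recorded.  Raises :class:`IntegrationError` if the
    state diverges (non-finite voltage), reporting the failure time.
    """
    if not 0.0 < dt <= 0.1:
        raise ValueError("dt must lie in (0, 0.1] ms")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    from piriform._kernel import run_kernel

    grid = system.grid
    n_steps = int(round(duration / dt))
    parent, g_ax, cap, g_leak = _passive_arrays(system)
    gbar_na, gbar_kdr, gbar_ks = _channel_arrays(system)
    (
        chan_comp, chan_e, chan_taur, chan_taud, chan_norm, chan_is_nmda,
        ev_step, ev_chan, ev_w, released,
    ) = _synapse_arrays(system, duration, dt, seed)

    rec_map: dict[str, DendriticLocation | None] = {"soma": None}
    if record:
        rec_map.update(record)
    rec_idx = np.array([system.comp_of(loc) for loc in rec_map.values()], dtype=np.int64)

    if system.clamp is not None:
        clamp_comp = system.comp_of(system.clamp.location)
        clamp_hold = system.clamp.hold_mV
    else:
        clamp_comp, clamp_hold = -1, 0.0

    if system.injection is not None:
        inj = system.injection
        inj_comp = system.comp_of(inj.location)
        inj_amp = inj.amplitude_nA
        inj_start = int(round(inj.start_ms / dt))
        inj_end = int(round(inj.end_ms / dt))
    else:
        inj_comp, inj_amp, inj_start, inj_end = -1, 0.0, 0, 0

    v_init = np.full(grid.n_comp, system.passive.E_rest)

    rec_v, clamp_i, fail_step = run_kernel(
        n_steps, dt, parent, g_ax, cap, g_leak, system.passive.E_rest,
        gbar_na, gbar_kdr, gbar_ks,
        system.channels.ENa, system.channels.EK,
        system.channels.na_shift, system.channels.kdr_shift,
        system.channels.ks_vhalf, system.channels.ks_slope, system.channels.ks_tau,
        chan_comp, chan_e, chan_taur, chan_taud, chan_norm, chan_is_nmda,
        ev_step, ev_chan, ev_w,
        system.ohmic_nmda, system.v_ohmic,
        clamp_comp, clamp_hold, CLAMP_G,
        inj_comp, inj_amp, inj_start, inj_end,
        rec_idx, v_init,
    )
    if fail_step:
        raise IntegrationError(
            f"integration diverged at t = {fail_step * dt:.3f} ms"
        )

    t = np.arange(n_steps + 1) * dt
    traces = {name: rec_v[i] for i, name in enumerate(rec_map)}
    return SimResult(
        t=t,
        traces=traces,
        clamp_current_pA=(clamp_i * 1e3 if clamp_comp >= 0 else None),
        seed=int(seed),
        dt=dt,
        released=released,
        config_hash=_config_hash(system, duration, dt, seed),
    )


def voltage_clamp(
    system: CompartmentalSystem,
    site: DendriticLocation | None,
    hold: float,
    duration: float,
    dt: float = DEFAULT_DT,
    seed: int = 0,
) -> SimResult:
    """Run with an ideal voltage clamp at ``site`` held at ``hold`` mV.

    The clamp current trace (pA) is the current injected to hold the site:
    inward synaptic current appears as a negative deflection.
    """
    clamped = replace(system, clamp=VoltageClamp(site, hold))
    return integrate(clamped, duration, dt=dt, seed=seed)
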