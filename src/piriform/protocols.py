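"""The model's in-silico experiments.

Implements the stimulation protocols used to probe dendritic integration:

* unitary-input calibration (single presynaptic cell → ~30 pA somatic EPSC),
* input–output curves for clustered synaptic drive at one dendritic site,
* pairing of a driver input with a subthreshold bias input on the same,
  a sister, or a different branch (threshold left-shift),
* clustered versus dispersed distribution of signal inputs over the
  LOT-recipient tree with in-vivo-like background,
* glomerular combinations (A+B on one terminal dendrite vs A+C split
  across primary dendrites),
* the Ohmic-NMDA control that freezes the NMDA voltage dependence.

Stimulus "intensity" is the number of co-activated calibrated synapses at a
site; each synapse fires a burst of 3 pulses at 50 Hz (the standard
stimulus) unless driven by explicit in-vivo-like trains.  Protocol
simulations run with a passive soma: every measured quantity is a
subthreshold EPSP or a clamp current, and somatic Na/K spikes would
contaminate them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from piriform.biophysics import ChannelSet, PassiveParams
from piriform.engine import (
    CompartmentalSystem,
    SimResult,
    Synapse,
    VoltageClamp,
    integrate,
    set_ohmic_nmda,
)
from piriform.morphology import (
    CompartmentGrid,
    DendriticLocation,
    branch_relation,
    classify_zone,
    path_distance,
)
from piriform.stats import (
    DEFAULT_RESPONSE_WINDOW,
    IOCurve,
    NonlinearityResult,
    ThresholdFit,
    detect_threshold,
    pairing_nonlinearity,
    peak_and_area,
    threshold_reduction,
)
from piriform.synapses import (
    EXC_TRAIN,
    INH_TRAIN,
    PresynTrain,
    ampa_spec,
    gaba_spec,
    generate_background,
    generate_train,
    nmda_spec,
    place_uniform,
)

__all__ = [
    "ProtocolError",
    "StimulusSite",
    "GlomerulusSpec",
    "CalibrationResult",
    "PairingResult",
    "ClusteredDispersedResult",
    "GlomerularResult",
    "standard_sites",
    "site_at_distance",
    "calibrate_unitary_input",
    "calibrate_bias_intensity",
    "io_curve",
    "pairing_experiment",
    "clustered_vs_dispersed",
    "glomerular_combination",
    "background_depolarization",
    "set_ohmic_nmda",
]

#: burst stimulus: 3 pulses at 50 Hz
BURST_PULSES = (0.0, 20.0, 40.0)
STIM_ONSET = 100.0  # ms into the simulation
BASELINE_WINDOW = (STIM_ONSET - 50.0, STIM_ONSET - 2.0)
RESPONSE_WINDOW = (STIM_ONSET, STIM_ONSET + DEFAULT_RESPONSE_WINDOW)
SIM_DURATION = STIM_ONSET + DEFAULT_RESPONSE_WINDOW + 20.0

#: experimental bias-input somatic EPSP amplitude the pairing protocol mirrors
BIAS_TARGET_EPSP = 3.8  # mV


class ProtocolError(RuntimeError):
    pass


@dataclass(frozen=True)
class StimulusSite:
    """A stimulated dendritic site: location, synapse count and pulse burst."""

    location: DendriticLocation
    n_synapses: int = 1
    pulse_times: tuple[float, ...] = BURST_PULSES  # ms relative to onset
    intensity_scale: float = 1.0  # multiplier on the calibrated synapse scale

    def __post_init__(self) -> None:
        if self.intensity_scale < 0:
            raise ValueError("intensity scale must be >= 0")


@dataclass(frozen=True)
class GlomerulusSpec:
    """One glomerulus: a labelled set of LOT inputs converging on a branch."""

    label: str
    target: DendriticLocation
    n_inputs: int = 6

    def __post_init__(self) -> None:
        if self.n_inputs <= 0:
            raise ValueError("n_inputs must be > 0")


# ---------------------------------------------------------------------------
# site selection helpers
# ---------------------------------------------------------------------------


def _deepest_terminal(grid: CompartmentGrid, root_id: int) -> int:
    morph = grid.morphology
    best, best_d = -1, -1.0
    for t in morph.terminal_sections():
        sec = morph.sections[t]
        if sec.root_id != root_id:
            continue
        d = morph.section_path_start(t) + sec.length
        if d > best_d:
            best, best_d = t, d
    if best < 0:
        raise KeyError(f"no terminal section under primary dendrite {root_id}")
    return best


def site_at_distance(
    grid: CompartmentGrid, distance_um: float, root_id: int = 0
) -> DendriticLocation:
    """Location at a given path distance on the deepest path of a primary."""
    morph = grid.morphology
    sec_idx = _deepest_terminal(grid, root_id)
    # walk up until the section spans the requested distance
    while sec_idx >= 0:
        sec = morph.sections[sec_idx]
        start = morph.section_path_start(sec_idx)
        if start <= distance_um <= start + sec.length:
            return DendriticLocation(sec_idx, (distance_um - start) / sec.length)
        sec_idx = sec.parent
    raise ValueError(f"distance {distance_um} µm not reachable on primary {root_id}")


def standard_sites(grid: CompartmentGrid, distal_um: float = 350.0) -> dict:
    """The canonical stimulation sites the pairing protocols use.

    ``driver``: distal LOT site on the deepest terminal of primary 0;
    ``same``: 35 µm proximal to the driver on the same branch path
    (the experimental inter-electrode distance);
    ``sister``: matched distance on another terminal of primary 0;
    ``different``: matched distance on a terminal of another primary;
    ``ic_same``: IC-zone site on the driver's path.
    """
    morph = grid.morphology
    driver_term = _deepest_terminal(grid, 0)
    term_start = morph.section_path_start(driver_term)
    driver_end = term_start + morph.sections[driver_term].length
    d_um = min(distal_um, driver_end - 5.0)
    driver = site_at_distance(grid, d_um, 0)

    # bias electrode ~35 µm proximal on the driver's branch path (the
    # paired-electrode inter-site distance)
    same = site_at_distance(grid, d_um - 35.0, 0)

    # sister: a different terminal under primary 0, taking the one most
    # separated from the driver (branches diverging at the root dendrite)
    def _path_separation(t: int) -> float:
        a, anc = t, set()
        while a >= 0:
            anc.add(a)
            a = morph.sections[a].parent
        b = driver_term
        while b not in anc:
            b = morph.sections[b].parent
        junction_end = morph.section_path_start(b) + morph.sections[b].length
        return 2.0 * (d_um - junction_end)

    sisters = [
        t
        for t in morph.terminal_sections()
        if morph.sections[t].root_id == 0 and t != driver_term
        and branch_relation(morph, DendriticLocation(t, 0.9), driver) == "sister"
    ]
    if not sisters:
        raise ProtocolError("no sister terminal available on primary 0")
    sister = _loc_near_distance(
        grid, max(sisters, key=_path_separation), d_um
    )

    other_roots = sorted(
        {s.root_id for s in morph.sections if s.root_id != 0}
    )
    if not other_roots:
        raise ProtocolError("need at least two primary dendrites")
    diff_term = _deepest_terminal(grid, other_roots[-1])
    different = _loc_near_distance(grid, diff_term, d_um)

    # IC-zone sites on each branch's own (unshared) path, so the branch
    # relation to the driver is same / sister / different respectively
    sister_term = sister.section
    ic_same = _ic_site_on_path(grid, driver_term)
    ic_sister = _ic_site_on_path(grid, sister_term)
    ic_different = _ic_site_on_path(grid, diff_term)
    return {
        "driver": driver,
        "same": same,
        "sister": sister,
        "different": different,
        "ic_same": ic_same,
        "ic_sister": ic_sister,
        "ic_different": ic_different,
    }


def _ic_site_on_path(
    grid: CompartmentGrid,
    terminal_section: int,
    lo: float = 100.0,
    hi: float = 250.0,
) -> DendriticLocation:
    """Deepest IC-zone point on the path from a terminal to the soma."""
    morph = grid.morphology
    s = terminal_section
    while s >= 0:
        sec = morph.sections[s]
        start = morph.section_path_start(s)
        end = start + sec.length
        span_lo, span_hi = max(start, lo), min(end, hi)
        if span_hi - span_lo > 2.0:
            d = 0.5 * (span_lo + span_hi)
            return DendriticLocation(s, (d - start) / sec.length)
        s = sec.parent
    raise ProtocolError("no IC-zone segment on this path")


def _loc_near_distance(
    grid: CompartmentGrid, section: int, distance_um: float
) -> DendriticLocation:
    morph = grid.morphology
    sec = morph.sections[section]
    start = morph.section_path_start(section)
    arc = (distance_um - start) / sec.length
    return DendriticLocation(section, float(np.clip(arc, 0.05, 0.95)))


# ---------------------------------------------------------------------------
# synapse construction
# ---------------------------------------------------------------------------


def excitatory_synapse(
    loc: DendriticLocation, train: PresynTrain, scale: float = 1.0,
    deterministic: bool = False,
) -> Synapse:
    """AMPA+NMDA synapse of one excitatory presynaptic cell."""
    return Synapse(
        (ampa_spec(loc), nmda_spec(loc)), train, scale=scale,
        deterministic=deterministic,
    )


#: conductance multiplier of odor-driven inhibitory synapses.  Release stays
#: stochastic (5 vesicles, Pr 0.1); the weight is set so a presynaptic spike
#: delivers ~1 nS of GABA-A conductance on average, which balances the
#: calibrated odor excitation the way in-vivo co-tuned inhibition does.
INHIBITORY_SCALE = 2.0


def inhibitory_synapse(
    loc: DendriticLocation, train: PresynTrain, scale: float | None = None
) -> Synapse:
    """Stochastic GABA-A synapse of one odor-driven inhibitory interneuron."""
    return Synapse(
        (gaba_spec(loc),), train,
        scale=INHIBITORY_SCALE if scale is None else scale,
    )


def _cluster_locations(
    grid: CompartmentGrid,
    site: DendriticLocation,
    n: int,
    rng: np.random.Generator,
    spread_um: float = 20.0,
) -> list[DendriticLocation]:
    """Spread ``n`` synapses over ~``spread_um`` µm around a site."""
    sec = grid.morphology.sections[site.section]
    span = spread_um / sec.length
    offsets = rng.uniform(-span / 2.0, span / 2.0, size=n)
    return [
        DendriticLocation(site.section, float(np.clip(site.arc + o, 0.0, 1.0)))
        for o in offsets
    ]


def _site_synapses(
    grid: CompartmentGrid,
    site: StimulusSite,
    n: int,
    scale: float,
    rng: np.random.Generator,
    time_shift: float = 0.0,
    onset: float = STIM_ONSET,
) -> list[Synapse]:
    """``n`` burst-driven calibrated synapses clustered at a stimulus site.

    An ``n`` of zero still returns zero synapses; callers that need matched
    random substreams across conditions should instead pass empty trains.
    """
    locs = _cluster_locations(grid, site.location, n, rng)
    train = PresynTrain(
        tuple(onset + time_shift + t for t in site.pulse_times)
    )
    return [
        excitatory_synapse(loc, train, scale=scale * site.intensity_scale)
        for loc in locs
    ]


# ---------------------------------------------------------------------------
# unitary-input calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    scale: float  # conductance multiplier applied to excitatory synapses
    mean_epsc_pA: float  # success-conditioned mean peak somatic clamp current
    mean_epsp_mV: float  # success-conditioned mean peak somatic EPSP
    n_successes: int
    n_trials: int


def _unitary_trial_system(
    base: CompartmentalSystem, loc: DendriticLocation, scale: float
) -> CompartmentalSystem:
    syn = excitatory_synapse(loc, PresynTrain((STIM_ONSET,)), scale=scale)
    return base.with_synapses([syn])


def _mean_unitary_epsc(
    base: CompartmentalSystem, loc: DendriticLocation, scale: float,
    trials: int, seed: int,
) -> tuple[float, int]:
    vals = []
    sys_c = replace(
        _unitary_trial_system(base, loc, scale),
        clamp=VoltageClamp(None, base.passive.E_rest),
    )
    for k in range(trials):
        r = integrate(sys_c, STIM_ONSET + 60.0, seed=seed + k)
        if r.released[0] == 0:
            continue
        i = r.clamp_current_pA
        base_i = float(np.median(i[: int((STIM_ONSET - 5.0) / r.dt)]))
        vals.append(-(float(np.min(i - base_i))))
    if not vals:
        return 0.0, 0
    return float(np.mean(vals)), len(vals)


def calibrate_unitary_input(
    system: CompartmentalSystem,
    site: DendriticLocation,
    target_epsc_pA: float = 30.0,
    tolerance: float = 0.10,
    trials: int = 100,
    seed: int = 0,
    max_scale: float = 200.0,
) -> CalibrationResult:
    """Find the synaptic scale at which a single presynaptic cell at ``site``
    produces a mean somatic voltage-clamp EPSC of ``target_epsc_pA``.

    The mean is taken over release successes (trials with at least one
    vesicle released).  Secant iteration on the scale; raises
    :class:`ProtocolError` when the target is unreachable within
    ``(0, max_scale]``.  Also reports the associated current-clamp EPSP.
    """
    if classify_zone(system.grid, site) != "LOT":
        raise ProtocolError("calibration site must lie in the LOT zone")
    base = replace(system, synapses=(), channels=ChannelSet.passive())

    s1 = 1.0
    e1, _ = _mean_unitary_epsc(base, site, s1, trials, seed)
    if e1 <= 0.0:
        raise ProtocolError("calibration failed: no synaptic current at scale 1")
    s2 = min(s1 * target_epsc_pA / e1, max_scale)
    e2 = e1
    for _ in range(8):
        e2, n_succ = _mean_unitary_epsc(base, site, s2, trials, seed)
        if abs(e2 - target_epsc_pA) <= tolerance * target_epsc_pA:
            break
        if e2 == e1 or s2 == s1:
            break
        s_next = s2 + (target_epsc_pA - e2) * (s2 - s1) / (e2 - e1)
        s1, e1 = s2, e2
        s2 = float(np.clip(s_next, 1e-6, max_scale))
    else:
        n_succ = 0
    if abs(e2 - target_epsc_pA) > tolerance * target_epsc_pA:
        raise ProtocolError(
            f"calibration could not reach {target_epsc_pA} pA within bounds "
            f"(best {e2:.1f} pA at scale {s2:.2f})"
        )

    # current-clamp EPSP with the calibrated scale, same release seeds
    epsps = []
    sys_cc = _unitary_trial_system(base, site, s2)
    for k in range(trials):
        r = integrate(sys_cc, STIM_ONSET + 100.0, seed=seed + k)
        if r.released[0] == 0:
            continue
        v = r.v("soma")
        b = float(np.mean(v[: int((STIM_ONSET - 5.0) / r.dt)]))
        epsps.append(float(np.max(v) - b))
    return CalibrationResult(
        scale=float(s2),
        mean_epsc_pA=float(e2),
        mean_epsp_mV=float(np.mean(epsps)) if epsps else math.nan,
        n_successes=len(epsps),
        n_trials=trials,
    )


# ---------------------------------------------------------------------------
# input–output curves
# ---------------------------------------------------------------------------


def io_curve(
    system: CompartmentalSystem,
    site: StimulusSite,
    intensities: Sequence[int],
    trials: int = 3,
    seed: int = 0,
    scale: float = 1.0,
    extra_synapses: tuple[Synapse, ...] = (),
) -> IOCurve:
    """Mean somatic (and local dendritic) response versus synapse count.

    Intensity is the number of co-activated calibrated synapses at the site,
    each firing the site's pulse burst; stochastic release makes trials
    differ.  ``extra_synapses`` ride along in every simulation (used by the
    pairing protocol for the bias input).
    """
    intensities = list(intensities)
    if len(intensities) < 4:
        raise ValueError("need at least 4 intensities")
    if sorted(intensities) != intensities:
        raise ValueError("intensities must be ascending")

    peaks = np.zeros((len(intensities), trials))
    areas = np.zeros_like(peaks)
    dend_peaks = np.zeros_like(peaks)
    for ii, inten in enumerate(intensities):
        for k in range(trials):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=int(seed), spawn_key=(ii, k))
            )
            syns = _site_synapses(system.grid, site, int(inten), scale, rng)
            sys_k = system.add_synapses(tuple(syns) + extra_synapses)
            r = integrate(
                sys_k, SIM_DURATION, seed=seed + 7919 * k + inten,
                record={"dend": site.location},
            )
            pk, ar = peak_and_area(r.t, r.v("soma"), BASELINE_WINDOW, RESPONSE_WINDOW)
            dpk, _ = peak_and_area(
                r.t, r.traces["dend"], BASELINE_WINDOW, RESPONSE_WINDOW
            )
            peaks[ii, k], areas[ii, k], dend_peaks[ii, k] = pk, ar, dpk
    return IOCurve(
        intensities=np.asarray(intensities, dtype=float),
        peak_mean=peaks.mean(axis=1),
        peak_sd=peaks.std(axis=1),
        area_mean=areas.mean(axis=1),
        area_sd=areas.std(axis=1),
        dend_peak_mean=dend_peaks.mean(axis=1),
        site=site,
    )


# ---------------------------------------------------------------------------
# pairing experiment
# ---------------------------------------------------------------------------


@dataclass
class PairingResult:
    unpaired: IOCurve
    paired: IOCurve
    theta_unpaired: float
    theta_paired: float
    reduction_pct: float
    relation: str
    time_shift: float
    bias_epsp_mV: float


def _crossing_intensity(curve: IOCurve, v_threshold: float) -> float | None:
    """First (interpolated) intensity whose mean peak reaches a voltage."""
    x = np.asarray(curve.intensities, dtype=float)
    y = np.asarray(curve.peak_mean, dtype=float)
    above = np.flatnonzero(y >= v_threshold)
    if above.size == 0:
        return None
    i = int(above[0])
    if i == 0:
        return float(x[0])
    frac = (v_threshold - y[i - 1]) / (y[i] - y[i - 1])
    return float(x[i - 1] + frac * (x[i] - x[i - 1]))


def calibrate_bias_intensity(
    system: CompartmentalSystem,
    site: StimulusSite,
    scale: float,
    target_epsp: float = BIAS_TARGET_EPSP,
    max_n: int = 12,
    trials: int = 4,
    seed: int = 0,
) -> tuple[int, float]:
    """Smallest synapse count whose mean burst EPSP reaches ``target_epsp``.

    Mirrors the experimental bias input (constant-intensity second electrode,
    somatic EPSP ≈ 3.8 mV).  Returns (count, mean EPSP).
    """
    best: tuple[int, float] | None = None
    for n in range(1, max_n + 1):
        pk = _mean_burst_epsp(system, site, n, scale, trials, seed)
        if best is None or abs(pk - target_epsp) < abs(best[1] - target_epsp):
            best = (n, pk)
        if pk >= target_epsp:
            break
    return best


def _mean_burst_epsp(
    system: CompartmentalSystem, site: StimulusSite, n: int, scale: float,
    trials: int, seed: int,
) -> float:
    pks = []
    for k in range(trials):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(99, n, k))
        )
        syns = _site_synapses(system.grid, site, n, scale, rng)
        r = integrate(
            system.add_synapses(syns), SIM_DURATION, seed=seed + 31 * k + n
        )
        pk, _ = peak_and_area(r.t, r.v("soma"), BASELINE_WINDOW, RESPONSE_WINDOW)
        pks.append(pk)
    return float(np.mean(pks))


def pairing_experiment(
    system: CompartmentalSystem,
    driver: StimulusSite,
    bias: StimulusSite,
    bias_intensity: int,
    scale: float = 1.0,
    time_shift: float = 0.0,
    intensities: Sequence[int] = (0, 2, 4, 6, 8, 10, 12),
    trials: int = 3,
    seed: int = 0,
    suprathreshold_epsp: float = 12.0,
    unpaired: IOCurve | None = None,
) -> PairingResult:
    """Driver input–output curves without and with a subthreshold bias input.

    The bias is ``bias_intensity`` calibrated synapses at the bias site,
    burst-activated with an optional ``time_shift`` (ms) relative to the
    driver.  Returns the percent reduction of the driver's spike threshold
    caused by the bias; raises :class:`ProtocolError` when the bias alone is
    suprathreshold (mean somatic EPSP above ``suprathreshold_epsp``).
    """
    bias_epsp = 0.0
    bias_syns: tuple[Synapse, ...] = ()
    if bias_intensity > 0:
        bias_epsp = _mean_burst_epsp(
            system, bias, bias_intensity, scale, trials, seed
        )
        if bias_epsp > suprathreshold_epsp:
            raise ProtocolError(
                f"bias input is suprathreshold alone ({bias_epsp:.1f} mV)"
            )
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(7,))
        )
        bias_syns = tuple(
            _site_synapses(
                system.grid, bias, bias_intensity, scale, rng,
                time_shift=time_shift,
            )
        )

    if unpaired is None:
        unpaired = io_curve(
            system, driver, intensities, trials=trials, seed=seed, scale=scale
        )
    paired = io_curve(
        system, driver, intensities, trials=trials, seed=seed, scale=scale,
        extra_synapses=bias_syns,
    )

    fit_u = detect_threshold(unpaired)
    fit_p = detect_threshold(paired)
    if not fit_u.spike_detected:
        raise ProtocolError("driver never crossed threshold in unpaired curve")
    theta_u = fit_u.threshold_intensity
    if fit_p.spike_detected:
        theta_p = fit_p.threshold_intensity
    else:
        # a strong bias can wash the paired sigmoid out entirely; fall back
        # to where the paired curve first reaches the unpaired threshold
        # voltage, corrected for the bias's own vertical lift (a purely
        # linear bias shifts the curve up without changing the threshold)
        lift = float(paired.peak_mean[0] - unpaired.peak_mean[0])
        theta_p = _crossing_intensity(
            paired, fit_u.threshold_voltage + max(lift, 0.0)
        )
        if theta_p is None:
            theta_p = theta_u
    relation = branch_relation(
        system.grid.morphology, driver.location, bias.location
    )
    return PairingResult(
        unpaired=unpaired,
        paired=paired,
        theta_unpaired=theta_u,
        theta_paired=theta_p,
        reduction_pct=threshold_reduction(theta_u, theta_p),
        relation=relation,
        time_shift=time_shift,
        bias_epsp_mV=bias_epsp,
    )


def _background_synapse(spec, train) -> Synapse:
    """Background inputs release their full unitary conductance per event.

    The vesicle-pool release model applies to the signal-bearing presynaptic
    cells; the background population stands for the aggregate in-vivo
    bombardment and delivers unitary-sized conductance events at its Poisson
    times.  With the printed kinetics this reproduces the ~11 mV tonic
    depolarization of the cell.
    """
    return Synapse((spec,), train, scale=1.0, deterministic=True)


# ---------------------------------------------------------------------------
# clustered vs dispersed drive with background
# ---------------------------------------------------------------------------


@dataclass
class ClusteredDispersedResult:
    peaks_clustered: np.ndarray  # per-trial peak somatic EPSP above baseline
    peaks_dispersed: np.ndarray
    clustering_fraction: float
    ohmic: bool


def _signal_population(
    grid: CompartmentGrid,
    n_exc: int,
    n_inh: int,
    clustering_fraction: float,
    scale: float,
    rng: np.random.Generator,
    target_branch: DendriticLocation,
    exc_trains: Sequence[PresynTrain],
    inh_trains: Sequence[PresynTrain],
    inh_split: float = 0.5,
    lot_band_start: float = 250.0,
) -> list[Synapse]:
    """Signal synapses: a clustered pool on one terminal branch plus a
    dispersed pool over the whole LOT-recipient zone, and inhibition split
    between the LOT band (feedforward) and the perisomatic region (feedback).
    """
    n_clustered = int(round(clustering_fraction * n_exc))
    sec = grid.morphology.sections[target_branch.section]
    capacity = max(1, int(sec.length / 0.25))
    if n_clustered > capacity:
        raise ProtocolError(
            f"clustered pool of {n_clustered} exceeds target-branch capacity"
        )
    locs: list[DendriticLocation] = []
    if n_clustered:
        locs += _cluster_locations(
            grid, target_branch, n_clustered, rng, spread_um=min(30.0, sec.length)
        )
    if n_exc - n_clustered:
        locs += place_uniform(
            grid, n_exc - n_clustered, rng, zone="LOT",
            lot_band_start=lot_band_start,
        )
    syns = [
        excitatory_synapse(loc, train, scale=scale)
        for loc, train in zip(locs, exc_trains)
    ]
    n_ff = int(round(inh_split * n_inh))
    inh_locs = (
        place_uniform(grid, n_ff, rng, zone="LOT", lot_band_start=lot_band_start)
        + place_uniform(grid, n_inh - n_ff, rng, zone="perisomatic")
        if n_inh
        else []
    )
    syns += [
        inhibitory_synapse(loc, train) for loc, train in zip(inh_locs, inh_trains)
    ]
    return syns


def clustered_vs_dispersed(
    system: CompartmentalSystem,
    n_signal_exc: int = 20,
    n_signal_inh: int = 40,
    clustering_fraction: float = 1.0,
    ohmic: bool = False,
    trials: int = 20,
    seed: int = 0,
    scale: float = 1.0,
    n_bg_exc: int = 100,
    n_bg_inh: int = 20,
    bg_rate_hz: int = 10.0,
    duration: float = SIM_DURATION,
) -> ClusteredDispersedResult:
    """Peak somatic EPSP for clustered versus dispersed signal placement.

    Per trial the presynaptic trains (signal and background) are identical
    between the clustered and dispersed arms; only the excitatory placements
    differ: the clustered pool sits on a single terminal LOT branch, the
    dispersed pool anywhere in the LOT zone.  Peaks are measured above the
    trial's own background-driven pre-stimulus baseline.
    """
    sys0 = set_ohmic_nmda(replace(system, channels=ChannelSet.passive()), ohmic)
    grid = system.grid
    terminals = [
        t
        for t in grid.morphology.terminal_sections()
        if classify_zone(grid, DendriticLocation(t, 0.7)) == "LOT"
    ]
    if not terminals:
        raise ProtocolError("no terminal LOT branch available")

    pk_c = np.zeros(trials)
    pk_d = np.zeros(trials)
    for k in range(trials):
        ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(k,))
        rng_place, rng_train = [np.random.default_rng(s) for s in ss.spawn(2)]
        target = DendriticLocation(
            terminals[int(rng_place.integers(len(terminals)))], 0.7
        )
        exc_trains = [
            generate_train(EXC_TRAIN, rng_train) for _ in range(n_signal_exc)
        ]
        inh_trains = [
            generate_train(INH_TRAIN, rng_train) for _ in range(n_signal_inh)
        ]
        background = generate_background(
            grid, n_bg_exc, n_bg_inh, bg_rate_hz, duration,
            seed=np.random.default_rng(ss.spawn(1)[0]),
        )
        bg_syns = [_background_synapse(spec, train) for spec, train in background]
        for arm, frac in (("c", clustering_fraction), ("d", 0.0)):
            rng_arm = np.random.default_rng(
                np.random.SeedSequence(entropy=int(seed), spawn_key=(k, 17))
            )
            signal = _signal_population(
                grid, n_signal_exc, n_signal_inh, frac, scale, rng_arm,
                target, exc_trains, inh_trains,
            )
            sys_k = sys0.with_synapses(bg_syns + signal)
            r = integrate(sys_k, duration, seed=seed * 1_000 + k)
            pk, _ = peak_and_area(
                r.t, r.v("soma"), BASELINE_WINDOW,
                (STIM_ONSET, duration - 5.0),
            )
            if arm == "c":
                pk_c[k] = pk
            else:
                pk_d[k] = pk
    return ClusteredDispersedResult(pk_c, pk_d, clustering_fraction, ohmic)


# ---------------------------------------------------------------------------
# glomerular combinations
# ---------------------------------------------------------------------------


@dataclass
class GlomerularResult:
    nonlinearity: dict[str, NonlinearityResult]  # keyed by pair label, e.g. "AB"
    peaks: dict[str, np.ndarray]  # per-trial background-subtracted peaks
    areas: dict[str, np.ndarray]
    trials: int


def default_glomeruli(
    grid: CompartmentGrid, distance_um: float = 300.0
) -> list[GlomerulusSpec]:
    """A and B on one terminal LOT dendrite of primary 0; C on a terminal of
    a different primary dendrite.

    The three glomerular targets sit at matched path distances so that B and
    C deliver equivalent drive and differ only in branch identity.
    """
    sites = standard_sites(grid)
    term_a = sites["driver"].section
    morph = grid.morphology
    start = morph.section_path_start(term_a)
    length = morph.sections[term_a].length
    d_a = float(np.clip(distance_um, start + 2.0, start + length - 2.0))
    a = DendriticLocation(term_a, (d_a - start) / length)
    b = DendriticLocation(
        term_a, float(np.clip((d_a + 25.0 - start) / length, 0.0, 1.0))
    )
    c = _loc_near_distance(grid, sites["different"].section, d_a)
    return [
        GlomerulusSpec("A", a),
        GlomerulusSpec("B", b),
        GlomerulusSpec("C", c),
    ]


def glomerular_combination(
    system: CompartmentalSystem,
    gloms: Sequence[GlomerulusSpec] | None = None,
    pairs: Sequence[str] = ("AB", "AC"),
    trials: int = 20,
    seed: int = 0,
    scale: float = 1.0,
    n_inh: int = 24,
    inh_split: float = 1.0,  # fraction of inhibition in the LOT band
    n_bg_exc: int = 100,
    n_bg_inh: int = 20,
    duration: float = SIM_DURATION,
) -> GlomerularResult:
    """Single-glomerulus and paired responses on a common background.

    Per trial every condition (background-only, each single glomerulus, each
    pair) shares the same background activity, inhibitory drive and
    presynaptic trains; inactive glomeruli keep their synapses with empty
    trains so the per-synapse release substreams stay aligned across
    conditions.  Pairing nonlinearity follows the area-ratio definition.
    """
    grid = system.grid
    sys0 = replace(system, channels=ChannelSet.passive())
    gloms = list(gloms) if gloms is not None else default_glomeruli(grid)
    by_label = {g.label: g for g in gloms}
    for pair in pairs:
        for lab in pair:
            if lab not in by_label:
                raise KeyError(f"unknown glomerulus label {lab!r}")

    singles = sorted({lab for pair in pairs for lab in pair})
    ratios: dict[str, list[float]] = {p: [] for p in pairs}
    excluded: dict[str, int] = {p: 0 for p in pairs}
    peaks: dict[str, list[float]] = {p: [] for p in pairs}
    areas: dict[str, list[float]] = {p: [] for p in pairs}

    window = (STIM_ONSET, duration - 5.0)
    for k in range(trials):
        ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(k,))
        s_place, s_train, s_bg = ss.spawn(3)
        rng_place = np.random.default_rng(s_place)
        rng_train = np.random.default_rng(s_train)

        background = generate_background(
            grid, n_bg_exc, n_bg_inh, 10.0, duration,
            seed=np.random.default_rng(s_bg),
        )
        bg_syns = [_background_synapse(spec, train) for spec, train in background]
        # odor-unselective inhibition: active in every odor condition
        n_ff = int(round(inh_split * n_inh))
        inh_locs = place_uniform(grid, n_ff, rng_place, zone="LOT") + (
            place_uniform(grid, n_inh - n_ff, rng_place, zone="perisomatic")
            if n_inh - n_ff
            else []
        )
        inh_trains = [generate_train(INH_TRAIN, rng_train) for _ in inh_locs]

        glom_locs: dict[str, list[DendriticLocation]] = {}
        glom_trains: dict[str, list[PresynTrain]] = {}
        for g in gloms:
            glom_locs[g.label] = _cluster_locations(
                grid, g.target, g.n_inputs, rng_place, spread_um=25.0
            )
            glom_trains[g.label] = [
                generate_train(EXC_TRAIN, rng_train) for _ in range(g.n_inputs)
            ]

        def run(active: set[str]) -> SimResult:
            syns = list(bg_syns)
            empty = PresynTrain(())
            for g in gloms:
                for loc, train in zip(glom_locs[g.label], glom_trains[g.label]):
                    syns.append(
                        excitatory_synapse(
                            loc, train if g.label in active else empty, scale=scale
                        )
                    )
            for loc, train in zip(inh_locs, inh_trains):
                syns.append(
                    inhibitory_synapse(loc, train if active else empty)
                )
            return integrate(
                sys0.with_synapses(syns), duration, seed=seed * 1_000 + k
            )

        r_bg = run(set())
        r_single = {lab: run({lab}) for lab in singles}
        for pair in pairs:
            r_pair = run(set(pair))
            ratio = pairing_nonlinearity(
                r_pair.t,
                r_pair.v("soma"),
                r_single[pair[0]].v("soma"),
                r_single[pair[1]].v("soma"),
                r_bg.v("soma"),
                window,
                # near-zero expected areas produce unstable ratios; such
                # trials are excluded and counted rather than clipped
                min_expected_auc=10.0,
            )
            if ratio is None:
                excluded[pair] += 1
            else:
                ratios[pair].append(ratio)
            sub = r_pair.v("soma") - r_bg.v("soma")
            pk, ar = peak_and_area(r_pair.t, sub, BASELINE_WINDOW, window)
            peaks[pair].append(pk)
            areas[pair].append(ar)

    return GlomerularResult(
        nonlinearity={
            p: NonlinearityResult(np.asarray(ratios[p]), excluded[p])
            for p in pairs
        },
        peaks={p: np.asarray(peaks[p]) for p in pairs},
        areas={p: np.asarray(areas[p]) for p in pairs},
        trials=trials,
    )


# ---------------------------------------------------------------------------
# background depolarization check
# ---------------------------------------------------------------------------


def background_depolarization(
    system: CompartmentalSystem,
    trials: int = 20,
    duration: float = 600.0,
    seed: int = 0,
    scale: float = 1.0,
    settle_ms: float = 150.0,
) -> dict:
    """Mean somatic depolarization produced by the background population.

    100 AMPA-only excitatory plus 20 inhibitory synapses at 10 Hz; the
    depolarization is the time-averaged somatic voltage above rest after a
    settling period, averaged across trials.
    """
    sys0 = replace(system, channels=ChannelSet.passive())
    depols = []
    for k in range(trials):
        background = generate_background(
            system.grid, duration_ms=duration, seed=seed + 7000 + k
        )
        syns = [_background_synapse(spec, train) for spec, train in background]
        r = integrate(sys0.with_synapses(syns), duration, seed=seed + k)
        v = r.v("soma")
        w = v[int(settle_ms / r.dt):]
        depols.append(float(np.mean(w)) - system.passive.E_rest)
    return {
        "mean_depolarization_mV": float(np.mean(depols)),
        "sd_mV": float(np.std(depols, ddof=1)) if trials > 1 else 0.0,
        "trials": trials,
        "per_trial": depols,
    }
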