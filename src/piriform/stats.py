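"""Trace-derived measurements: peaks, areas, pairing nonlinearity, thresholds.

These mirror the quantification used on the recorded and simulated voltage
traces: response peak and area above a pre-stimulus baseline, background
subtraction on trial-matched traces, the pairing-nonlinearity ratio (actual
paired response area over the expected linear sum; 1 = linear, >1 =
supralinear), and the percent threshold reduction produced by a bias input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "IOCurve",
    "NonlinearityResult",
    "ThresholdFit",
    "peak_and_area",
    "background_subtract",
    "pairing_nonlinearity",
    "threshold_reduction",
    "detect_threshold",
]

#: default measurement windows (ms relative to stimulus onset): response
#: covers the burst plus three NMDA decay constants; baseline precedes onset
DEFAULT_RESPONSE_WINDOW = 300.0
DEFAULT_BASELINE_WINDOW = 50.0


def _window_slice(t: np.ndarray, lo: float, hi: float) -> slice:
    i0 = int(np.searchsorted(t, lo, side="left"))
    i1 = int(np.searchsorted(t, hi, side="right"))
    if i1 <= i0:
        raise ValueError(f"empty window [{lo}, {hi}] ms")
    return slice(i0, i1)


def peak_and_area(
    t: np.ndarray,
    v: np.ndarray,
    baseline_window: tuple[float, float],
    response_window: tuple[float, float],
) -> tuple[float, float]:
    """Peak (mV) and area (mV·ms) of a response above its baseline mean.

    Peak is the maximum of ``v − mean(baseline)`` inside the response
    window; area is the trapezoidal integral of the same quantity (negative
    excursions included).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.shape != v.shape:
        raise ValueError("time base and trace must have equal length")
    if baseline_window[0] > response_window[0]:
        raise ValueError("baseline window must precede the response window")
    base = float(np.mean(v[_window_slice(t, *baseline_window)]))
    sl = _window_slice(t, *response_window)
    dv = v[sl] - base
    peak = float(np.max(dv))
    area = float(np.trapezoid(dv, t[sl]))
    return peak, area


def background_subtract(
    t: np.ndarray, v: np.ndarray, v_background: np.ndarray
) -> np.ndarray:
    """Pointwise difference of a trace and its trial-matched background trace."""
    v = np.asarray(v, dtype=float)
    v_background = np.asarray(v_background, dtype=float)
    if v.shape != v_background.shape or len(v) != len(t):
        raise ValueError("traces must share one time base")
    return v - v_background


def _auc(t: np.ndarray, dv: np.ndarray, window: tuple[float, float]) -> float:
    sl = _window_slice(np.asarray(t, dtype=float), *window)
    return float(np.trapezoid(np.asarray(dv, dtype=float)[sl], t[sl]))


def pairing_nonlinearity(
    t: np.ndarray,
    actual_pair: np.ndarray,
    single_1: np.ndarray,
    single_2: np.ndarray,
    background: np.ndarray,
    window: tuple[float, float],
    min_expected_auc: float = 1e-9,
) -> float | None:
    """Ratio of paired-response area to the expected linear sum of singles.

    All traces must come from trials sharing the same background (and time
    base).  Returns ``None`` when the expected linear area is non-positive
    (the trial is excluded from summaries rather than clipped).
    """
    pair = background_subtract(t, actual_pair, background)
    s1 = background_subtract(t, single_1, background)
    s2 = background_subtract(t, single_2, background)
    expected = _auc(t, s1 + s2, window)
    if expected <= min_expected_auc:
        return None
    return _auc(t, pair, window) / expected


def threshold_reduction(theta_unpaired: float, theta_paired: float) -> float:
    """Percent decrease of spike threshold in the paired condition."""
    if theta_unpaired <= 0:
        raise ValueError("unpaired threshold must be > 0")
    return 100.0 * (theta_unpaired - theta_paired) / theta_unpaired


# ---------------------------------------------------------------------------
# input–output curves and threshold detection
# ---------------------------------------------------------------------------


@dataclass
class IOCurve:
    """Mean response peak/area versus stimulus intensity at one site."""

    intensities: np.ndarray
    peak_mean: np.ndarray  # mV, somatic
    peak_sd: np.ndarray
    area_mean: np.ndarray  # mV·ms, somatic
    area_sd: np.ndarray
    dend_peak_mean: np.ndarray | None = None  # local dendritic response
    site: object | None = None

    def __post_init__(self) -> None:
        n = len(self.intensities)
        for arr in (self.peak_mean, self.peak_sd, self.area_mean, self.area_sd):
            if len(arr) != n:
                raise ValueError("curve arrays must be congruent")
        if np.any(np.diff(self.intensities) <= 0):
            raise ValueError("intensities must be ascending")


@dataclass
class ThresholdFit:
    """Outcome of sigmoidal threshold detection on an IO curve."""

    spike_detected: bool
    threshold_intensity: float = math.nan
    threshold_voltage: float = math.nan  # mean peak at last subthreshold point
    params: tuple | None = None  # (floor, amplitude, inflection, slope)


@dataclass
class NonlinearityResult:
    """Per-trial pairing-nonlinearity ratios with exclusion bookkeeping."""

    ratios: np.ndarray  # defined ratios only
    n_excluded: int
    peaks_actual: np.ndarray = field(default_factory=lambda: np.array([]))
    peaks_expected: np.ndarray = field(default_factory=lambda: np.array([]))
    areas_actual: np.ndarray = field(default_factory=lambda: np.array([]))
    areas_expected: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(self.ratios)) if self.ratios.size else math.nan


def _logistic(x, floor, amp, x0, k):
    z = np.clip((x - x0) / k, -500.0, 500.0)
    return floor + amp / (1.0 + np.exp(-z))


def detect_threshold(curve: IOCurve, use_dendritic: bool = False) -> ThresholdFit:
    """Fit a four-parameter logistic to peak-vs-intensity; the fitted
    inflection is the threshold intensity.

    The threshold voltage is the mean (somatic) peak at the largest measured
    intensity below the inflection.  When the logistic fit is no better than
    a straight line (by AIC on the residual sum of squares), the curve is
    declared spikeless.  Deterministic given the curve.
    """
    x = np.asarray(curve.intensities, dtype=float)
    y = np.asarray(
        curve.dend_peak_mean if use_dendritic and curve.dend_peak_mean is not None
        else curve.peak_mean,
        dtype=float,
    )
    if len(x) < 4:
        raise ValueError("need at least 4 intensities to detect a threshold")

    # straight-line reference fit
    lin = np.polyfit(x, y, 1)
    rss_lin = float(np.sum((np.polyval(lin, x) - y) ** 2))

    span = float(y.max() - y.min())
    if span <= 0:
        return ThresholdFit(False)
    # grid of inflection starts makes the fit robust to the initial guess
    best = None
    for x0 in x[1:-1]:
        try:
            p, _ = curve_fit(
                _logistic,
                x, y,
                p0=[float(y.min()), span, float(x0), (x[-1] - x[0]) / 10.0],
                bounds=(
                    [y.min() - span, 0.0, x[0], 1e-3],
                    [y.max(), 10.0 * span, x[-1], x[-1] - x[0]],
                ),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((_logistic(x, *p) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, p)
    if best is None:
        return ThresholdFit(False)
    rss_sig, p = best

    n = len(x)
    eps = 1e-12
    aic_lin = n * math.log(rss_lin / n + eps) + 2 * 2
    aic_sig = n * math.log(rss_sig / n + eps) + 2 * 4
    if aic_sig >= aic_lin:
        return ThresholdFit(False)

    x0 = float(p[2])
    below = np.flatnonzero(x < x0)
    v_thresh = float(curve.peak_mean[below[-1]]) if below.size else float(
        curve.peak_mean[0]
    )
    return ThresholdFit(True, x0, v_thresh, tuple(float(q) for q in p))
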