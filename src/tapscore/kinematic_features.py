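"""Per-frame, per-tap and aggregate kinematics: the 65-feature inventory.

Base measurements
-----------------
* **speed** (deg/s, per frame): absolute change of the tapping angle between
  consecutive frames divided by the frame duration;
* **acceleration** (deg/s^2, per frame): absolute change of speed;
* **period** (s, per tap): time between consecutive detected peaks;
* **frequency** (Hz, per tap): inverse of the period;
* **amplitude** (deg, per tap): angle value at each peak — the maximal
  aperture reached during that tap;
* **wrist motion** (dimensionless, per frame): displacement of the wrist in
  coordinates normalized per frame by the wrist-to-thumb-CMC distance, as the
  axis components |dx|, |dy| and the Euclidean magnitude.

Each of the five tapping measurements takes seven statistical aggregates
(median, IQR, mean, min, max, std, distribution entropy) = 35 features; the
three wrist measurements take six aggregates (the same minus the mean) = 18.
Twelve rhythm/hesitation features (spectral aperiodicity, interruption and
freezing counts, longest freeze, period-line fit R^2/slope, period polynomial
fit complexity, three amplitude-decrement measures, normalized period
variance, tap count) complete the 47-feature tapping group, for 65 in total.

The inventory is a versioned constant (:data:`FEATURE_NAMES`); feature tables
always carry these column names in this order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import FeatureError
from .landmark_io import THUMB_CMC, WRIST, LandmarkTimeSeries
from .tapping_signal import CleanSignal

REGISTRY_VERSION = "1.0"

_TAP_METRICS = ("speed", "acceleration", "period", "frequency", "amplitude")
_TAP_AGGS = ("median", "iqr", "mean", "min", "max", "std", "entropy")
_WRIST_METRICS = ("wrist_dx", "wrist_dy", "wrist_disp")
_WRIST_AGGS = ("median", "iqr", "min", "max", "std", "entropy")

_EXTRA_FEATURES = (
    "aperiodicity",
    "interruption_count",
    "freeze_count",
    "freeze_longest_s",
    "period_linearity_r2",
    "period_linearity_slope",
    "period_fit_complexity",
    "amplitude_end_minus_mean",
    "amplitude_end_minus_begin",
    "amplitude_decrement_slope",
    "period_variance_norm",
    "tap_count",
)

TAPPING_FEATURES: tuple[str, ...] = tuple(
    f"{m}_{a}" for m in _TAP_METRICS for a in _TAP_AGGS
) + _EXTRA_FEATURES
WRIST_FEATURES: tuple[str, ...] = tuple(f"{m}_{a}" for m in _WRIST_METRICS for a in _WRIST_AGGS)
#: the full, ordered 65-name inventory
FEATURE_NAMES: tuple[str, ...] = TAPPING_FEATURES + WRIST_FEATURES

assert len(TAPPING_FEATURES) == 47 and len(WRIST_FEATURES) == 18 and len(FEATURE_NAMES) == 65


@dataclass
class TapMetrics:
    """Per-tap periods (s), frequencies (Hz) and amplitudes (deg)."""

    periods: np.ndarray
    frequencies: np.ndarray
    amplitudes: np.ndarray


@dataclass
class WristMotion:
    """Per-frame normalized wrist displacements: |dx|, |dy| and magnitude."""

    dx: np.ndarray
    dy: np.ndarray
    disp: np.ndarray


def compute_speed(signal: CleanSignal) -> np.ndarray:
    """Per-frame tapping speed |X_i - X_{i-1}| / t_frame in deg/s."""
    x = signal.values
    if len(x) < 2:
        raise FeatureError("speed needs at least 2 frames")
    return np.abs(np.diff(x)) / signal.t_frame


def compute_acceleration(speed: np.ndarray, t_frame: float) -> np.ndarray:
    """Per-frame acceleration |s_i - s_{i-1}| / t_frame in deg/s^2."""
    s = np.asarray(speed, dtype=float)
    if len(s) < 2:
        raise FeatureError("acceleration needs at least 2 speed values")
    return np.abs(np.diff(s)) / t_frame


def compute_tap_metrics(signal: CleanSignal) -> TapMetrics:
    """Periods, frequencies and amplitudes from the retained peaks."""
    k = len(signal.peaks)
    if k < 2:
        raise FeatureError("tap metrics need at least 2 peaks")
    idx = signal.peaks.indices
    periods = np.diff(idx) * signal.t_frame
    return TapMetrics(periods=periods, frequencies=1.0 / periods, amplitudes=signal.values[idx])


def compute_wrist_motion(series: LandmarkTimeSeries, start: int, length: int) -> WristMotion:
    """Normalized wrist displacements over ``length`` frames from ``start``.

    Each frame's wrist coordinates are divided by that frame's wrist-to-
    THUMB_CMC distance, cancelling camera distance.  Frames without a
    detection (or with a degenerate zero reference distance) are skipped and
    displacements are taken between consecutive *available* frames.
    """
    coords = []
    for _, det in series.frames[start : start + length]:
        if det is None:
            continue
        kp = det.keypoints
        ref = float(np.hypot(*(kp[WRIST] - kp[THUMB_CMC])))
        if ref == 0.0:
            continue
        coords.append(kp[WRIST] / ref)
    if len(coords) < 2:
        raise FeatureError("wrist motion needs at least 2 frames with detections")
    w = np.asarray(coords)
    d = np.diff(w, axis=0)
    # displacements below float resolution of the coordinates are rounding
    # residue of the per-frame normalization, not motion
    d[np.abs(d) < 1e-9 * max(1.0, float(np.abs(w).max()))] = 0.0
    return WristMotion(dx=np.abs(d[:, 0]), dy=np.abs(d[:, 1]), disp=np.hypot(d[:, 0], d[:, 1]))


def distribution_entropy(values: np.ndarray, bins: int = 10) -> float:
    """Shannon entropy (nats) of a fixed-bin histogram spanning [min, max]."""
    v = np.asarray(values, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    # a range below float resolution is a constant sequence in all but name
    if (hi - lo) / bins <= np.spacing(max(abs(lo), abs(hi))):
        return 0.0
    counts, _ = np.histogram(v, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def aggregate_stats(values, bins: int = 10) -> dict[str, float]:
    """The seven named aggregates of a numeric sequence."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise FeatureError("cannot aggregate an empty sequence")
    q75, q25 = np.percentile(v, [75, 25])
    return {
        "median": float(np.median(v)),
        "iqr": float(q75 - q25),
        "mean": float(np.mean(v)),
        "min": float(np.min(v)),
        "max": float(np.max(v)),
        "std": float(np.std(v)),
        "entropy": distribution_entropy(v, bins=bins),
    }


def aperiodicity(values: np.ndarray) -> float:
    """Shannon entropy of the normalized FFT power spectrum.

    The mean-removed signal is transformed with a real FFT; the power at each
    frequency bin is normalized to sum to one and its Shannon entropy (nats)
    is returned.  A single pure tone concentrates the power in one bin (low
    entropy); arrhythmic tapping spreads it (high entropy).  A constant
    signal returns 0 by convention.
    """
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    if np.allclose(x, 0.0):
        return 0.0
    power = np.abs(np.fft.rfft(x)) ** 2
    p = power / power.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _slow_runs(speed: np.ndarray, threshold: float) -> list[int]:
    """Lengths of maximal runs with speed strictly below ``threshold``."""
    runs, run = [], 0
    for s in speed:
        if s < threshold:
            run += 1
        elif run:
            runs.append(run)
            run = 0
    if run:
        runs.append(run)
    return runs


def count_interruptions(
    speed: np.ndarray, t_frame: float, threshold: float = 50.0, min_dur_s: float = 0.010
) -> int:
    """Number of hesitations: sub-threshold speed runs lasting >= 10 ms."""
    return sum(1 for r in _slow_runs(speed, threshold) if r * t_frame >= min_dur_s)


def count_freezing(
    speed: np.ndarray, t_frame: float, threshold: float = 50.0, min_dur_s: float = 0.020
) -> tuple[int, float]:
    """Freezing events (sub-threshold runs lasting > 20 ms) and longest duration."""
    durs = [r * t_frame for r in _slow_runs(speed, threshold) if r * t_frame > min_dur_s]
    return len(durs), (max(durs) if durs else 0.0)


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return 1.0  # zero-variance convention: any constant fit is perfect
    ss_res = float(((y - fitted) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def period_linearity(periods) -> tuple[float, float]:
    """(R^2, slope) of the least-squares line through period vs tap index."""
    y = np.asarray(periods, dtype=float)
    if len(y) < 3:
        raise FeatureError("period linearity needs at least 3 periods")
    x = np.arange(len(y), dtype=float)
    if np.ptp(y) == 0.0:
        return 1.0, 0.0
    slope, intercept = np.polyfit(x, y, 1)
    return _r_squared(y, slope * x + intercept), float(slope)


def period_fit_complexity(periods, r2_threshold: float = 0.9, max_degree: int = 10) -> int:
    """Smallest polynomial degree (1..max) reaching R^2 >= threshold, else max+1."""
    y = np.asarray(periods, dtype=float)
    if len(y) < 3:
        raise FeatureError("fit complexity needs at least 3 periods")
    if np.ptp(y) == 0.0:
        return 1
    x = np.arange(len(y), dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        for deg in range(1, max_degree + 1):
            coeffs = np.polyfit(x, y, deg)
            if _r_squared(y, np.polyval(coeffs, x)) >= r2_threshold:
                return deg
    return max_degree + 1


def amplitude_decrement(amplitudes) -> tuple[float, float, float]:
    """(last - mean, last - first, per-tap slope) of the amplitude sequence.

    Negative values indicate shrinking aperture across successive taps
    (decrementing amplitude, a core MDS-UPDRS scoring criterion).
    """
    a = np.asarray(amplitudes, dtype=float)
    if len(a) < 3:
        raise FeatureError("amplitude decrement needs at least 3 amplitudes")
    x = np.arange(len(a), dtype=float)
    slope = 0.0 if np.ptp(a) == 0.0 else float(np.polyfit(x, a, 1)[0])
    return float(a[-1] - a.mean()), float(a[-1] - a[0]), slope


def featurize(
    signal: CleanSignal,
    series: LandmarkTimeSeries,
    speed_threshold: float = 50.0,
    interruption_min_dur_s: float = 0.010,
    freeze_min_dur_s: float = 0.020,
    entropy_bins: int = 10,
) -> dict[str, float]:
    """Assemble the full 65-entry feature mapping for one hand-video.

    ``signal`` is the cleaned/trimmed angle signal; ``series`` is the source
    landmark series, needed for wrist motion over the same retained segment
    (``signal.series.start_frame`` keeps the two aligned).  Requires at least
    4 retained peaks so every per-tap feature is defined.
    """
    if len(signal.peaks) < 4:
        raise FeatureError(f"featurize needs >= 4 retained peaks, got {len(signal.peaks)}")
    t_frame = signal.t_frame
    speed = compute_speed(signal)
    accel = compute_acceleration(speed, t_frame)
    taps = compute_tap_metrics(signal)
    wrist = compute_wrist_motion(series, signal.series.start_frame, len(signal.values))

    feats: dict[str, float] = {}
    for name, vals in (
        ("speed", speed),
        ("acceleration", accel),
        ("period", taps.periods),
        ("frequency", taps.frequencies),
        ("amplitude", taps.amplitudes),
    ):
        stats = aggregate_stats(vals, bins=entropy_bins)
        for agg in _TAP_AGGS:
            feats[f"{name}_{agg}"] = stats[agg]

    feats["aperiodicity"] = aperiodicity(signal.values)
    feats["interruption_count"] = float(
        count_interruptions(speed, t_frame, speed_threshold, interruption_min_dur_s)
    )
    n_freeze, longest = count_freezing(speed, t_frame, speed_threshold, freeze_min_dur_s)
    feats["freeze_count"] = float(n_freeze)
    feats["freeze_longest_s"] = longest
    r2, slope = period_linearity(taps.periods)
    feats["period_linearity_r2"] = r2
    feats["period_linearity_slope"] = slope
    feats["period_fit_complexity"] = float(period_fit_complexity(taps.periods))
    end_mean, end_begin, amp_slope = amplitude_decrement(taps.amplitudes)
    feats["amplitude_end_minus_mean"] = end_mean
    feats["amplitude_end_minus_begin"] = end_begin
    feats["amplitude_decrement_slope"] = amp_slope
    feats["period_variance_norm"] = float(np.var(taps.periods) / np.mean(taps.periods))
    feats["tap_count"] = float(len(signal.peaks))

    for name, vals in (("wrist_dx", wrist.dx), ("wrist_dy", wrist.dy), ("wrist_disp", wrist.disp)):
        stats = aggregate_stats(vals, bins=entropy_bins)
        for agg in _WRIST_AGGS:
            feats[f"{name}_{agg}"] = stats[agg]

    assert tuple(feats) == FEATURE_NAMES
    return feats
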