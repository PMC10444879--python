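"""From landmark series to a clean tapping-angle signal.

The finger-tapping angle is the angle at the wrist subtended by the thumb tip
and the index fingertip.  Unlike a fingertip distance it is invariant to how
far the subject sits from the camera, which makes it a robust aperture proxy
for webcam recordings.  The cleaning pipeline is:

1. :func:`build_angle_series` — per-frame angle, ``-1.0`` sentinel for frames
   with no confident detection (presence score below 0.90);
2. :func:`interpolate_missing` — fill isolated sentinel frames whose
   neighbourhood is mostly visible, using a low-order polynomial fitted to
   the whole visible signal;
3. :func:`longest_visible_segment` — keep the longest run without sentinels
   (drops pre/post-task positioning);
4. :func:`detect_peaks` — custom peak detection with three task-specific
   rules (trough between taps, minimum inter-peak gap, amplitude floor);
5. :func:`trim_first_last_tap` — drop the (noisy) first and last tap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DegenerateGeometryError,
    EmptySegmentError,
    InsufficientTapsError,
    ValidationError,
)
from .landmark_io import INDEX_TIP, THUMB_TIP, WRIST, LandmarkTimeSeries

log = logging.getLogger(__name__)

#: sentinel for frames with a missing hand
SENTINEL = -1.0


@dataclass
class AngleSeries:
    """Tapping-angle trace in degrees with ``-1.0`` marking missing frames.

    ``start_frame`` is the offset of ``values[0]`` into the source landmark
    series, so cleaned signals can be mapped back onto landmark frames.
    """

    values: np.ndarray
    t_frame: float
    start_frame: int = 0
    video_id: str = ""
    hand: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValidationError("angle series must be a non-empty 1-D array")
        if self.t_frame <= 0:
            raise ValidationError("t_frame must be positive")
        valid = self.values[self.values != SENTINEL]
        if len(valid) and ((valid < 0) | (valid > 180)).any():
            raise ValidationError("non-sentinel angles must lie in [0, 180] degrees")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.values == SENTINEL


@dataclass
class PeakSet:
    """Strictly increasing peak indices into an :class:`AngleSeries`."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.indices) > 1 and not (np.diff(self.indices) > 0).all():
            raise ValidationError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)

    def values(self, series: AngleSeries) -> np.ndarray:
        return series.values[self.indices]


@dataclass
class CleanSignal:
    """Trimmed, sentinel-free angle signal with its retained peaks."""

    series: AngleSeries
    peaks: PeakSet

    def __post_init__(self) -> None:
        if self.series.missing_mask.any():
            raise ValidationError("clean signal must not contain sentinels")

    @property
    def values(self) -> np.ndarray:
        return self.series.values

    @property
    def t_frame(self) -> float:
        return self.series.t_frame


def compute_angle(wrist, thumb_tip, index_tip) -> float:
    """Angle (degrees, in [0, 180]) at the wrist between thumb tip and index tip.

    arccos of the normalized dot product of the wrist->thumb-tip and
    wrist->index-tip vectors; invariant under rotation, translation and
    uniform scaling of the three points.
    """
    w = np.asarray(wrist, dtype=float)
    vt = np.asarray(thumb_tip, dtype=float) - w
    vi = np.asarray(index_tip, dtype=float) - w
    nt = math.hypot(*vt)
    ni = math.hypot(*vi)
    if nt == 0.0 or ni == 0.0:
        raise DegenerateGeometryError("zero-length vector: fingertip coincides with wrist")
    c = float(np.dot(vt, vi)) / (nt * ni)
    c = min(1.0, max(-1.0, c))
    return math.degrees(math.acos(c))


def build_angle_series(series: LandmarkTimeSeries, presence_threshold: float = 0.90) -> AngleSeries:
    """Per-frame tapping angle; frames without a confident hand become ``-1.0``.

    A frame contributes an angle only when it holds a selected detection with
    presence score at or above ``presence_threshold``; degenerate geometry
    (coincident keypoints) also yields the sentinel and is logged.
    """
    values = np.full(len(series), SENTINEL)
    n_degenerate = 0
    for pos, (_, det) in enumerate(series.frames):
        if det is None or det.presence_score < presence_threshold:
            continue
        kp = det.keypoints
        try:
            values[pos] = compute_angle(kp[WRIST], kp[THUMB_TIP], kp[INDEX_TIP])
        except DegenerateGeometryError:
            n_degenerate += 1
    if n_degenerate:
        log.warning("%s: %d frames with degenerate keypoint geometry set to missing",
                    series.video_id, n_degenerate)
    return AngleSeries(values, series.t_frame, 0, series.video_id, series.hand)


def interpolate_missing(series: AngleSeries, window: int = 5, degree: int = 3) -> AngleSeries:
    """Fill sentinel frames that sit inside a mostly-visible neighbourhood.

    A sentinel at index *i* is filled when strictly more than half of the up
    to ``2*window`` surrounding frames (``window`` on each side, fewer at the
    boundaries) are non-negative.  The fill value comes from a degree-
    ``degree`` polynomial least-squares fitted to *all* non-negative samples
    of the signal, clamped to [0, 180].  The visibility mask used for the
    majority rule is the original one (single pass).
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    x = series.values
    miss = series.missing_mask
    if not miss.any():
        return replace(series, values=x.copy())
    good = ~miss
    if not good.any():
        log.warning("%s: all frames missing; nothing to interpolate", series.video_id)
        return replace(series, values=x.copy())
    idx_good = np.nonzero(good)[0]
    deg = min(degree, len(idx_good) - 1)
    coeffs = np.polyfit(idx_good, x[idx_good], deg)
    out = x.copy()
    n = len(x)
    for i in np.nonzero(miss)[0]:
        lo, hi = max(0, i - window), min(n, i + window + 1)
        neigh = good[lo:i].sum() + good[i + 1 : hi].sum()
        total = (i - lo) + (hi - i - 1)
        if neigh * 2 > total:
            out[i] = float(np.clip(np.polyval(coeffs, i), 0.0, 180.0))
    return replace(series, values=out)


def longest_visible_segment(series: AngleSeries) -> AngleSeries:
    """The longest run of consecutive non-sentinel frames (earliest on ties)."""
    good = ~series.missing_mask
    if not good.any():
        raise EmptySegmentError(f"{series.video_id}: no visible frames")
    best_start = best_len = 0
    start = None
    for i, g in enumerate(good):
        if g and start is None:
            start = i
        elif not g and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    if start is not None and len(good) - start > best_len:
        best_start, best_len = start, len(good) - start
    return replace(
        series,
        values=series.values[best_start : best_start + best_len].copy(),
        start_frame=series.start_frame + best_start,
    )


def _percentile(x: np.ndarray, q: float) -> float:
    return float(np.percentile(x, q))


def detect_peaks(
    series: AngleSeries,
    min_gap_s: float = 0.1,
    amplitude_floor_quantile: float = 0.25,
    trough_iqr_fraction: float = 0.2,
) -> PeakSet:
    """Task-aware peak detection on a sentinel-free angle signal.

    Rules, applied in order (all deterministic):

    1. candidates are strict interior local maxima
       (``x[i-1] < x[i] > x[i+1]``);
    2. amplitude floor: a peak value must exceed the signal's
       ``amplitude_floor_quantile`` percentile (default: the smallest 25% of
       values cannot be peaks);
    3. minimum gap: scanning left to right, a candidate closer than
       ``min_gap_s`` to the last accepted peak replaces it if larger,
       otherwise it is dropped (ties keep the earlier peak);
    4. trough rule: between consecutive accepted peaks there must be a sample
       below ``min(peak values) - trough_iqr_fraction * IQR`` of the signal;
       while any adjacent pair violates this, the smaller peak of the pair is
       removed (ties remove the later one) and the scan restarts.

    A constant signal has no local maxima and yields an empty peak set.
    """
    if series.missing_mask.any():
        raise ValidationError("detect_peaks requires a sentinel-free signal")
    x = series.values
    n = len(x)
    if n < 3:
        return PeakSet(np.empty(0, dtype=int))
    cand = [i for i in range(1, n - 1) if x[i - 1] < x[i] > x[i + 1]]
    floor = _percentile(x, 100.0 * amplitude_floor_quantile)
    cand = [i for i in cand if x[i] > floor]

    min_gap_frames = min_gap_s / series.t_frame
    accepted: list[int] = []
    for c in cand:
        if accepted and (c - accepted[-1]) < min_gap_frames:
            if x[c] > x[accepted[-1]]:
                accepted[-1] = c
        else:
            accepted.append(c)

    depth = trough_iqr_fraction * (_percentile(x, 75) - _percentile(x, 25))
    changed = True
    while changed and len(accepted) > 1:
        changed = False
        for j in range(len(accepted) - 1):
            p, q = accepted[j], accepted[j + 1]
            between = x[p + 1 : q]
            need = min(x[p], x[q]) - depth
            if len(between) == 0 or between.min() >= need:
                drop = j if x[p] < x[q] else j + 1
                del accepted[drop]
                changed = True
                break
    return PeakSet(np.asarray(accepted, dtype=int))


def trim_first_last_tap(series: AngleSeries, peaks: PeakSet) -> CleanSignal:
    """Drop the signal before the 2nd and after the 2nd-last peak.

    The first and last taps are contaminated by hand positioning before and
    after the task, so the retained signal runs from peak 2 through peak k-1
    inclusive, and exactly two peaks are removed.
    """
    k = len(peaks)
    if k < 4:
        raise InsufficientTapsError(
            f"{series.video_id or 'signal'}: need at least 4 detected taps, found {k}"
        )
    p2 = int(peaks.indices[1])
    p_second_last = int(peaks.indices[-2])
    trimmed = replace(
        series,
        values=series.values[p2 : p_second_last + 1].copy(),
        start_frame=series.start_frame + p2,
    )
    new_peaks = PeakSet(peaks.indices[1:-1] - p2)
    return CleanSignal(trimmed, new_peaks)


def clean_pipeline(
    series: LandmarkTimeSeries,
    presence_threshold: float = 0.90,
    window: int = 5,
    degree: int = 3,
    min_gap_s: float = 0.1,
    amplitude_floor_quantile: float = 0.25,
    trough_iqr_fraction: float = 0.2,
) -> CleanSignal:
    """Full cleaning chain: build -> interpolate -> segment -> peaks -> trim."""
    angles = build_angle_series(series, presence_threshold)
    angles = interpolate_missing(angles, window=window, degree=degree)
    segment = longest_visible_segment(angles)
    peaks = detect_peaks(
        segment,
        min_gap_s=min_gap_s,
        amplitude_floor_quantile=amplitude_floor_quantile,
        trough_iqr_fraction=trough_iqr_fraction,
    )
    return trim_first_last_tap(segment, peaks)


# ---------------------------------------------------------------------------
# CSV export of angle traces and peaks
# ---------------------------------------------------------------------------

def write_angle_series(series: AngleSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write("video_id,hand,frame,t_frame,angle_deg\n")
        for i, v in enumerate(series.values):
            fh.write(
                f"{series.video_id},{series.hand},{series.start_frame + i},"
                f"{float(series.t_frame)!r},{float(v)!r}\n"
            )


def write_peaks(series: AngleSeries, peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("video_id,hand,peak_frame,peak_angle_deg\n")
        for i in peaks.indices:
            fh.write(
                f"{series.video_id},{series.hand},{series.start_frame + int(i)},"
                f"{float(series.values[int(i)])!r}\n"
            )
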