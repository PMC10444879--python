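"""Hand-landmark time series: containers, target-hand selection and file I/O.

A *landmark time series* is the per-frame output of a 21-keypoint hand-pose
estimator restricted to the hand being assessed (left or right).  Coordinates
are normalized image coordinates: origin top-left, x rightwards, y downwards.
All downstream angle features are invariant to this convention.

Only four of the 21 keypoints drive the analysis:

====== ================  =========================================
index  name              role
====== ================  =========================================
0      WRIST             vertex of the finger-tapping angle
1      THUMB_CMC         per-frame scale reference for wrist motion
4      THUMB_TIP         one ray of the tapping angle
8      INDEX_FINGER_TIP  the other ray of the tapping angle
====== ================  =========================================

Frames where the estimator lost the hand are represented by ``None`` (the
MISSING marker).  File dialects (CSV and JSONL) encode missing frames as rows
with empty label/score/coordinate fields.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CapabilityError, SchemaError, ValidationError

log = logging.getLogger(__name__)

N_LANDMARKS = 21
#: keypoint indices the analysis cannot run without
REQUIRED_LANDMARKS = (0, 1, 4, 8)

WRIST, THUMB_CMC, THUMB_TIP, INDEX_TIP = 0, 1, 4, 8

#: marker for frames with no usable detection
MISSING = None


@dataclass
class HandDetection:
    """One hand detected in one frame.

    ``keypoints`` is a ``(21, 2)`` float array of normalized image
    coordinates; landmarks that a file did not provide are NaN, but the four
    required landmarks (0, 1, 4, 8) must always be finite.
    """

    hand_label: str
    detection_score: float
    presence_score: float
    keypoints: np.ndarray

    def validate(self, frame: int | None = None) -> None:
        where = "" if frame is None else f" at frame {frame}"
        kp = np.asarray(self.keypoints, dtype=float)
        if kp.shape != (N_LANDMARKS, 2):
            raise ValidationError(
                f"detection{where} has keypoint array of shape {kp.shape}, "
                f"expected ({N_LANDMARKS}, 2)"
            )
        if self.hand_label not in ("left", "right"):
            raise ValidationError(f"detection{where}: unknown hand label {self.hand_label!r}")
        for name, s in (("detection", self.detection_score), ("presence", self.presence_score)):
            if not (0.0 <= s <= 1.0):
                raise ValidationError(f"detection{where}: {name} score {s} outside [0, 1]")
        for i in REQUIRED_LANDMARKS:
            if not np.all(np.isfinite(kp[i])):
                raise ValidationError(f"detection{where}: required landmark {i} is not finite")


@dataclass
class LandmarkTimeSeries:
    """Per-frame selected hand detections for one hand-video."""

    video_id: str
    participant_id: str
    hand: str
    t_frame: float
    frames: list[tuple[int, HandDetection | None]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.t_frame <= 0:
            raise ValidationError(f"{self.video_id}: t_frame must be positive, got {self.t_frame}")
        idx = [i for i, _ in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(f"{self.video_id}: frame indices are not strictly increasing")
        for i, det in self.frames:
            if det is not None:
                det.validate(frame=i)
                if det.hand_label != self.hand:
                    raise ValidationError(
                        f"{self.video_id}: frame {i} detection labelled "
                        f"{det.hand_label!r}, series hand is {self.hand!r}"
                    )

    def __len__(self) -> int:
        return len(self.frames)


def _wrist_thumbtip_distance(det: HandDetection) -> float:
    kp = det.keypoints
    return float(math.dist(kp[WRIST], kp[THUMB_TIP]))


def select_target_hand(
    detections: list[HandDetection],
    hand: str,
    score_threshold: float = 0.9,
    frame: int | None = None,
) -> HandDetection | None:
    """Pick the detection to analyse among possibly several detected hands.

    A detection is a candidate when its handedness label matches ``hand`` and
    its handedness-classification score exceeds ``score_threshold``.  With
    several candidates (multiple people in frame), the subject performing the
    task is assumed closest to the camera and therefore to have the largest
    hand: the candidate with the greatest wrist-to-thumb-tip distance wins.
    Exact distance ties keep the earliest-listed candidate (determinism).

    Returns ``None`` (MISSING) when no candidate exists.
    """
    candidates = []
    for det in detections:
        det.validate(frame=frame)
        if det.hand_label == hand and det.detection_score > score_threshold:
            candidates.append(det)
    if not candidates:
        return MISSING
    if len(candidates) == 1:
        return candidates[0]
    best = candidates[0]
    best_d = _wrist_thumbtip_distance(best)
    for det in candidates[1:]:
        d = _wrist_thumbtip_distance(det)
        if d > best_d:
            best, best_d = det, d
    return best


def mean_presence_score(series: LandmarkTimeSeries) -> float | None:
    """Mean hand-presence score after dropping leading/trailing MISSING runs.

    The boundary frames where the hand was not yet (or no longer) in view are
    excluded, mirroring how per-video tracking confidence is summarised.
    Interior MISSING frames carry no score and are excluded from the mean.
    Returns ``None`` when every frame is MISSING.
    """
    if len(series) == 0:
        raise ValidationError(f"{series.video_id}: empty series")
    dets = [det for _, det in series.frames]
    first = next((i for i, d in enumerate(dets) if d is not None), None)
    if first is None:
        return None
    last = max(i for i, d in enumerate(dets) if d is not None)
    scores = [d.presence_score for d in dets[first : last + 1] if d is not None]
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_META_COLS = ["video_id", "participant_id", "hand", "frame", "t_frame", "label", "det_score", "presence"]


def _landmark_cols() -> list[str]:
    cols = []
    for i in range(N_LANDMARKS):
        cols += [f"lm{i}_x", f"lm{i}_y"]
    return cols


def _row_of(series: LandmarkTimeSeries, frame: int, det: HandDetection | None) -> dict:
    row: dict = {
        "video_id": series.video_id,
        "participant_id": series.participant_id,
        "hand": series.hand,
        "frame": frame,
        "t_frame": series.t_frame,
    }
    if det is None:
        row.update({"label": "", "det_score": "", "presence": ""})
        row.update({c: "" for c in _landmark_cols()})
    else:
        row.update(
            {"label": det.hand_label, "det_score": det.detection_score, "presence": det.presence_score}
        )
        for i in range(N_LANDMARKS):
            x, y = det.keypoints[i]
            row[f"lm{i}_x"] = "" if not np.isfinite(x) else float(x)
            row[f"lm{i}_y"] = "" if not np.isfinite(y) else float(y)
    return row


def write_landmark_series(series: LandmarkTimeSeries, path: str | Path, dialect: str = "csv") -> None:
    """Write a series as landmark CSV or JSONL (one row/object per frame)."""
    path = Path(path)
    rows = [_row_of(series, f, det) for f, det in series.frames]
    if dialect == "csv":
        cols = _META_COLS + _landmark_cols()
        with open(path, "w") as fh:
            fh.write(",".join(cols) + "\n")
            for row in rows:
                fh.write(",".join(_fmt(row[c]) for c in cols) + "\n")
    elif dialect == "jsonl":
        with open(path, "w") as fh:
            for row in rows:
                fh.write(json.dumps({k: v for k, v in row.items() if v != ""}) + "\n")
    else:
        raise SchemaError(f"unknown dialect {dialect!r}")


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


def read_landmark_series(path: str | Path, dialect: str | None = None) -> LandmarkTimeSeries:
    """Read a landmark CSV/JSONL file written by :func:`write_landmark_series`.

    Round-trips bit-exactly for finite coordinate values.  Raises
    :class:`SchemaError` on unknown columns, non-monotone frame indices,
    missing required landmarks or non-positive ``t_frame``.
    """
    path = Path(path)
    if dialect is None:
        dialect = "jsonl" if path.suffix == ".jsonl" else "csv"
    if dialect == "csv":
        rows = _read_csv_rows(path)
    elif dialect == "jsonl":
        rows = [json.loads(line) for line in open(path) if line.strip()]
    else:
        raise SchemaError(f"unknown dialect {dialect!r}")
    if not rows:
        raise SchemaError(f"{path}: no frame rows")
    return _series_from_rows(rows, str(path))


def _read_csv_rows(path: Path) -> list[dict]:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        known = set(_META_COLS) | set(_landmark_cols())
        unknown = [c for c in header if c not in known]
        if unknown:
            raise SchemaError(f"{path}: unknown columns {unknown}")
        rows = []
        for line in fh:
            if not line.strip():
                continue
            vals = line.rstrip("\n").split(",")
            rows.append({c: v for c, v in zip(header, vals) if v != ""})
    return rows


def _series_from_rows(rows: list[dict], source: str) -> LandmarkTimeSeries:
    present_lms = {
        i
        for i in range(N_LANDMARKS)
        if any(f"lm{i}_x" in r for r in rows) or any(f"lm{i}_y" in r for r in rows)
    }
    for i in REQUIRED_LANDMARKS:
        if i not in present_lms:
            raise SchemaError(f"{source}: required landmark {i} columns are absent")
    first = rows[0]
    try:
        t_frame = float(first["t_frame"])
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"{source}: missing or invalid t_frame") from exc
    if t_frame <= 0:
        raise SchemaError(f"{source}: t_frame must be > 0, got {t_frame}")
    frames: list[tuple[int, HandDetection | None]] = []
    prev = None
    n_partial = 0
    for r in rows:
        idx = int(r["frame"])
        if prev is not None and idx <= prev:
            raise SchemaError(f"{source}: frame indices not strictly increasing at frame {idx}")
        prev = idx
        if "label" not in r or r["label"] == "":
            frames.append((idx, MISSING))
            continue
        kp = np.full((N_LANDMARKS, 2), np.nan)
        for i in range(N_LANDMARKS):
            if f"lm{i}_x" in r:
                kp[i, 0] = float(r[f"lm{i}_x"])
            if f"lm{i}_y" in r:
                kp[i, 1] = float(r[f"lm{i}_y"])
        if not all(np.all(np.isfinite(kp[i])) for i in REQUIRED_LANDMARKS):
            # estimator glitch: a reported hand without its required keypoints
            n_partial += 1
            frames.append((idx, MISSING))
            continue
        det = HandDetection(
            hand_label=r["label"],
            detection_score=float(r.get("det_score", 1.0)),
            presence_score=float(r.get("presence", 1.0)),
            keypoints=kp,
        )
        frames.append((idx, det))
    if n_partial:
        log.warning("%s: %d frames had a hand with incomplete keypoints; treated as MISSING",
                    source, n_partial)
    try:
        return LandmarkTimeSeries(
            video_id=str(first["video_id"]),
            participant_id=str(first.get("participant_id", "")),
            hand=str(first["hand"]),
            t_frame=t_frame,
            frames=frames,
        )
    except ValidationError as exc:
        raise SchemaError(f"{source}: {exc}") from exc


def extract_from_video(video_path: str | Path, hand: str, score_threshold: float = 0.9):
    """Adapter around an external 21-landmark hand-pose estimator (optional).

    Requires ``mediapipe`` and ``opencv-python`` at run time; neither is a
    package dependency.  Raises :class:`CapabilityError` when unavailable.
    """
    try:
        import cv2  # noqa: F401
        import mediapipe  # noqa: F401
    except ImportError as exc:
        raise CapabilityError(
            "video extraction needs the optional 'mediapipe' and 'opencv-python' "
            "packages; install them or supply landmark CSV/JSONL input instead"
        ) from exc
    raise CapabilityError("video extraction adapter is not configured in this build")
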