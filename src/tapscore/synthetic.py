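"""Synthetic finger-tapping data with known ground truth.

The generator emulates the signal the video pipeline extracts from a real
recording: a quasi-periodic tapping-angle trace (one arch per tap), with
controllable amplitude, per-tap amplitude decrement, tap rate, period jitter,
inserted freezing/interruption episodes, wrist drift, landmark noise, missing
frames, and lead-in/lead-out segments where the hand is not yet in view.

Waveform.  Each tap is a piecewise-linear arch: the angle ramps linearly from
the baseline up to ``baseline + amplitude`` and back, with the apex forced
onto a sampled frame.  Linear strokes keep the sampled per-frame speed
constant and far above the 50 deg/s hesitation threshold everywhere except at
deliberately inserted events — a smooth (e.g. sinusoidal) arch sampled at
video frame rates necessarily produces a near-zero frame difference at every
apex, which the freezing detector would count as one spurious event per tap.
An optional shaping exponent ``gamma`` (> 1 rounds the valleys) is available
for stress-testing; the default 1 keeps events exactly countable.

Events.  Freezes and interruptions are inserted at inter-tap valleys (so the
peak structure stays intact) as runs of constant baseline angle.  Durations
are quantised to whole frames; the truth record stores the *realised*
duration of every event and the event counts expected from the trimmed
segment the pipeline analyses, so recovery tests are honest at any frame
rate.

Cohorts.  :func:`gen_cohort` draws participants with severity-dependent
parameter regimes (higher severity: smaller and slower taps, more jitter and
hesitation, stronger decrement — matching the MDS-UPDRS rubric's emphasis on
speed, amplitude, hesitations and decrementing amplitude) plus three
simulated expert raters and optional non-expert raters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .landmark_io import N_LANDMARKS, HandDetection, LandmarkTimeSeries
from .tapping_signal import SENTINEL, AngleSeries


@dataclass
class TapParams:
    """Parameters of one synthetic hand-video.

    ``freeze_events`` / ``interruption_events`` are lists of
    ``(gap_index, duration_s)`` pairs; ``gap_index`` g inserts the event at
    the valley between tap g and tap g+1 (0-based, so valid gaps are
    ``0 .. n_taps - 2``).  The pipeline trims the first and last tap, so only
    events in gaps ``1 .. n_taps - 3`` survive into the analysed segment.
    """

    n_taps: int = 10
    base_amplitude: float = 80.0     # degrees above baseline
    amplitude_slope: float = 0.0     # degrees per tap (negative = decrement)
    tap_frequency: float = 2.0       # Hz
    period_jitter_cv: float = 0.0    # coefficient of variation of tap periods
    freeze_events: tuple = ()
    interruption_events: tuple = ()
    missing_frame_prob: float = 0.0
    landmark_noise_sd: float = 0.0   # normalized image units
    wrist_drift_sd: float = 0.0      # per-frame random-walk step, normalized units
    baseline_angle: float = 10.0     # degrees, valley angle
    gamma: float = 1.0               # arch shaping exponent
    frame_rate: float = 30.0         # Hz (study videos averaged 30 fps)
    lead_in_s: float = 0.3
    lead_out_s: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_taps < 1:
            raise ValidationError("n_taps must be >= 1")
        if not (0 < self.baseline_angle < 180 and 0 < self.baseline_angle + self.base_amplitude < 180):
            raise ValidationError("angles must stay inside (0, 180) degrees")
        if self.tap_frequency <= 0 or self.frame_rate <= 0:
            raise ValidationError("frequencies must be positive")
        if not (0.0 <= self.missing_frame_prob <= 1.0):
            raise ValidationError("missing_frame_prob must be in [0, 1]")
        period = 1.0 / self.tap_frequency
        for gap, dur in tuple(self.freeze_events) + tuple(self.interruption_events):
            if dur <= 0:
                raise ValidationError("event durations must be positive")
            if dur >= period:
                raise ValidationError(
                    f"event of {dur} s at gap {gap} is not shorter than the tap period {period} s"
                )
            if not (0 <= gap <= self.n_taps - 2):
                raise ValidationError(f"event gap index {gap} outside 0..{self.n_taps - 2}")


def _tap_arch(m: int, amplitude: float, baseline: float, gamma: float) -> tuple[np.ndarray, int]:
    """One tap of ``m`` samples; apex exactly at sample ``round(m/2)``."""
    a = max(1, min(m - 1, round(m / 2)))
    vals = np.empty(m)
    for i in range(m):
        u = i / a if i <= a else (m - i) / (m - a)
        vals[i] = baseline + amplitude * u**gamma
    return vals, a


def _realize_trace(params: TapParams, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Active-segment angle samples plus the truth record (no lead-in/out)."""
    params.validate()
    fr, t_frame = params.frame_rate, 1.0 / params.frame_rate
    events = sorted(
        [(int(g), float(d), "freeze") for g, d in params.freeze_events]
        + [(int(g), float(d), "interruption") for g, d in params.interruption_events]
    )
    samples: list[float] = []
    apex_idx: list[int] = []
    apex_val: list[float] = []
    realized_events: list[dict] = []
    for j in range(params.n_taps):
        period = (1.0 / params.tap_frequency) * max(
            0.3, 1.0 + params.period_jitter_cv * rng.standard_normal()
        )
        m = max(4, round(period * fr))
        amp = float(np.clip(params.base_amplitude + params.amplitude_slope * j,
                            1.0, 179.0 - params.baseline_angle))
        arch, a = _tap_arch(m, amp, params.baseline_angle, params.gamma)
        apex_idx.append(len(samples) + a)
        apex_val.append(float(arch[a]))
        samples.extend(arch)
        for gap, dur, kind in events:
            if gap == j and j < params.n_taps - 1:
                m_f = round(dur * fr)
                realized_events.append(
                    {"gap": gap, "kind": kind, "requested_s": dur, "realized_s": m_f * t_frame}
                )
                samples.extend([params.baseline_angle] * m_f)
    x = np.asarray(samples)
    if params.missing_frame_prob > 0:
        miss = rng.random(len(x)) < params.missing_frame_prob
        x = np.where(miss, SENTINEL, x)

    # expected event counts inside the trimmed segment (gaps 1 .. n_taps-3).
    # events at the same gap are contiguous baseline runs and merge into one
    # detectable episode, so expectations are per gap over realised durations
    per_gap: dict[int, float] = {}
    for e in realized_events:
        if 1 <= e["gap"] <= params.n_taps - 3:
            per_gap[e["gap"]] = per_gap.get(e["gap"], 0.0) + e["realized_s"]
    truth = {
        "apex_indices": np.asarray(apex_idx),
        "apex_values": np.asarray(apex_val),
        "periods_s": np.diff(apex_idx) * t_frame,
        "events": realized_events,
        "expected_freeze_count": sum(1 for d in per_gap.values() if d > 0.020),
        "expected_interruption_count": sum(1 for d in per_gap.values() if d >= 0.010),
        "t_frame": t_frame,
        "n_taps": params.n_taps,
    }
    return x, truth


def gen_angle_series(params: TapParams, video_id: str = "sim", hand: str = "right"):
    """Generate an :class:`AngleSeries` plus its truth record."""
    ss = np.random.SeedSequence(params.seed)
    rng_trace, _ = (np.random.default_rng(s) for s in ss.spawn(2))
    x, truth = _realize_trace(params, rng_trace)
    n_in = round(params.lead_in_s * params.frame_rate)
    n_out = round(params.lead_out_s * params.frame_rate)
    values = np.concatenate([np.full(n_in, SENTINEL), x, np.full(n_out, SENTINEL)])
    truth["active_start"] = n_in
    truth["apex_indices"] = truth["apex_indices"] + n_in
    series = AngleSeries(values, 1.0 / params.frame_rate, 0, video_id, hand)
    return series, truth


# canonical unit offsets (relative to the wrist, in units of the wrist->CMC
# distance) for the 17 landmarks the analysis does not use
_TEMPLATE = np.array(
    [[0.3 * math.cos(2 * math.pi * i / 17), -1.2 - 0.4 * math.sin(2 * math.pi * i / 17)]
     for i in range(17)]
)


def gen_landmark_series(
    params: TapParams,
    video_id: str = "sim",
    participant_id: str = "p0",
    hand: str = "right",
) -> tuple[LandmarkTimeSeries, dict]:
    """Generate a 21-landmark series whose tapping angle follows the trace.

    The wrist, thumb tip and index fingertip are placed so the wrist angle
    equals the intended trace exactly (before noise); the wrist-to-THUMB_CMC
    distance is constant, so normalized wrist motion reflects only the
    injected drift.  Presence and detection scores are 1.0 on visible frames.
    """
    ss = np.random.SeedSequence(params.seed)
    rng_trace, rng_lm = (np.random.default_rng(s) for s in ss.spawn(2))
    x, truth = _realize_trace(params, rng_trace)
    n_in = round(params.lead_in_s * params.frame_rate)
    n_out = round(params.lead_out_s * params.frame_rate)
    values = np.concatenate([np.full(n_in, SENTINEL), x, np.full(n_out, SENTINEL)])
    truth["active_start"] = n_in
    truth["apex_indices"] = truth["apex_indices"] + n_in
    truth["angles"] = values

    n = len(values)
    d0, r_t, r_i = 0.12, 0.25, 0.30
    theta0 = -math.pi / 2  # hand pointing up in image coordinates
    drift = rng_lm.normal(0.0, params.wrist_drift_sd, (n, 2)).cumsum(axis=0) \
        if params.wrist_drift_sd > 0 else np.zeros((n, 2))
    noise = rng_lm.normal(0.0, params.landmark_noise_sd, (n, N_LANDMARKS, 2)) \
        if params.landmark_noise_sd > 0 else np.zeros((n, N_LANDMARKS, 2))

    frames: list[tuple[int, HandDetection | None]] = []
    for i in range(n):
        if values[i] == SENTINEL:
            frames.append((i, None))
            continue
        wrist = np.array([0.5, 0.6]) + drift[i]
        half = math.radians(values[i]) / 2.0
        kp = np.empty((N_LANDMARKS, 2))
        kp[0] = wrist
        kp[1] = wrist + d0 * np.array([math.cos(theta0 - half / 2), math.sin(theta0 - half / 2)])
        kp[4] = wrist + r_t * np.array([math.cos(theta0 - half), math.sin(theta0 - half)])
        kp[8] = wrist + r_i * np.array([math.cos(theta0 + half), math.sin(theta0 + half)])
        others = [j for j in range(N_LANDMARKS) if j not in (0, 1, 4, 8)]
        kp[others] = wrist + d0 * _TEMPLATE
        kp += noise[i]
        frames.append(
            (i, HandDetection(hand_label=hand, detection_score=1.0, presence_score=1.0, keypoints=kp))
        )
    series = LandmarkTimeSeries(
        video_id=video_id,
        participant_id=participant_id,
        hand=hand,
        t_frame=1.0 / params.frame_rate,
        frames=frames,
    )
    return series, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: central (noise-free) regime values per severity class; median sampled
#: tapping speed of a linear arch is 2 * amplitude * frequency
REGIME_TABLE = pd.DataFrame(
    {
        "severity": [0, 1, 2, 3, 4],
        "base_amplitude": [85.0, 71.0, 57.0, 43.0, 29.0],
        "tap_frequency": [2.2, 1.95, 1.7, 1.45, 1.2],
        "period_jitter_cv": [0.02, 0.07, 0.12, 0.17, 0.22],
        "amplitude_slope": [0.0, -0.45, -0.9, -1.35, -1.8],
        "freeze_rate": [0.0, 0.8, 1.6, 2.4, 3.2],
        "interruption_rate": [0.0, 0.5, 1.0, 1.5, 2.0],
        "missing_frame_prob": [0.01, 0.02, 0.03, 0.04, 0.05],
    }
).set_index("severity")
REGIME_TABLE["median_speed"] = 2 * REGIME_TABLE.base_amplitude * REGIME_TABLE.tap_frequency


@dataclass
class CohortSpec:
    """Study-sized synthetic cohort: participants, regimes and raters.

    Class proportions default to the severity distribution of the study
    videos (108/181/141/54/5 out of 489).  Each participant contributes one
    video per hand at the participant's severity.  Three simulated experts
    rate every video (truth plus or minus 1 with probability
    ``rater_flip_prob``); ``n_nonexperts`` noisier raters are added for
    agreement analyses only.
    """

    n_participants: int = 100
    class_proportions: tuple = (0.221, 0.370, 0.288, 0.110, 0.011)
    rater_flip_prob: float = 0.2
    difficulty_flag_prob: float = 0.08
    n_nonexperts: int = 2
    nonexpert_flip_prob: float = 0.45
    n_taps: int = 10
    frame_rate: float = 30.0
    landmark_noise_sd: float = 0.0015
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-6:
            raise ValidationError("class proportions must sum to 1")
        if self.n_participants < 1:
            raise ValidationError("need at least one participant")


def _severity_counts(spec: CohortSpec) -> list[int]:
    raw = [p * spec.n_participants for p in spec.class_proportions]
    counts = [int(math.floor(r)) for r in raw]
    remainder = spec.n_participants - sum(counts)
    order = sorted(range(5), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _draw_params(severity: int, spec: CohortSpec, rng: np.random.Generator, seed: int) -> TapParams:
    reg = REGIME_TABLE.loc[severity]
    n_gaps = spec.n_taps - 1
    freeze = [
        (int(rng.integers(0, n_gaps)), float(rng.uniform(0.025, 0.07)))
        for _ in range(rng.poisson(reg.freeze_rate))
    ]
    interruptions = [
        (int(rng.integers(0, n_gaps)), float(rng.uniform(0.012, 0.020)))
        for _ in range(rng.poisson(reg.interruption_rate))
    ]
    return TapParams(
        n_taps=spec.n_taps,
        base_amplitude=float(np.clip(rng.normal(reg.base_amplitude, 4.0), 15.0, 110.0)),
        amplitude_slope=float(np.clip(rng.normal(reg.amplitude_slope, 0.12), -4.0, 0.3)),
        tap_frequency=float(np.clip(rng.normal(reg.tap_frequency, 0.08), 0.9, 3.0)),
        period_jitter_cv=float(reg.period_jitter_cv),
        freeze_events=tuple(freeze),
        interruption_events=tuple(interruptions),
        missing_frame_prob=float(reg.missing_frame_prob),
        landmark_noise_sd=spec.landmark_noise_sd,
        wrist_drift_sd=0.0008 + 0.0004 * severity,
        frame_rate=spec.frame_rate,
        seed=seed,
    )


def _rate(truth: int, flip_prob: float, rng: np.random.Generator) -> int:
    u = rng.random()
    if u < flip_prob / 2:
        return int(np.clip(truth - 1, 0, 4))
    if u < flip_prob:
        return int(np.clip(truth + 1, 0, 4))
    return truth


def gen_cohort(spec: CohortSpec):
    """Generate a cohort: (landmark series list, ratings table, truth table).

    Returns
    -------
    videos : list[LandmarkTimeSeries]
        two hand-videos per participant, severity-dependent kinematics
    ratings : pandas.DataFrame
        long table ``video_id, hand, rater_id, role, rating, difficulty_flag``
    truth : pandas.DataFrame
        ``video_id, participant_id, hand, severity`` (the planted severity)
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    counts = _severity_counts(spec)
    severities = np.repeat(np.arange(5), counts)
    rng.shuffle(severities)

    videos, rating_rows, truth_rows = [], [], []
    for p_idx, severity in enumerate(severities):
        pid = f"p{p_idx:03d}"
        for hand in ("left", "right"):
            vid = f"{pid}_{hand}"
            seed = int(rng.integers(0, 2**31 - 1))
            params = _draw_params(int(severity), spec, rng, seed)
            series, _ = gen_landmark_series(params, video_id=vid, participant_id=pid, hand=hand)
            series.metadata.update({"severity_truth": int(severity), "sex": "m" if rng.random() < 0.55 else "f"})
            videos.append(series)
            truth_rows.append(
                {"video_id": vid, "participant_id": pid, "hand": hand, "severity": int(severity)}
            )
            flag_p = min(0.6, spec.difficulty_flag_prob + 0.03 * severity)
            for r in range(3):
                rating_rows.append(
                    {
                        "video_id": vid,
                        "hand": hand,
                        "rater_id": f"expert{r + 1}",
                        "role": "expert",
                        "rating": _rate(int(severity), spec.rater_flip_prob, rng),
                        "difficulty_flag": bool(rng.random() < flag_p),
                    }
                )
            for r in range(spec.n_nonexperts):
                rating_rows.append(
                    {
                        "video_id": vid,
                        "hand": hand,
                        "rater_id": f"nonexpert{r + 1}",
                        "role": "nonexpert",
                        "rating": _rate(int(severity), spec.nonexpert_flip_prob, rng),
                        "difficulty_flag": bool(rng.random() < flag_p),
                    }
                )
    return videos, pd.DataFrame(rating_rows), pd.DataFrame(truth_rows)
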