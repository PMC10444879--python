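"""High-level wiring: simulate -> angles -> featurize -> evaluate -> raters.

These functions are what the command-line interface calls; they are equally
usable from Python and return the objects they write.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import rater_analysis, severity_model, synthetic, tapping_signal
from .config import RunConfig
from .errors import TapscoreError
from .kinematic_features import FEATURE_NAMES, REGISTRY_VERSION, featurize
from .landmark_io import LandmarkTimeSeries, read_landmark_series, write_landmark_series

log = logging.getLogger(__name__)


def process_video(series: LandmarkTimeSeries, cfg: RunConfig) -> dict[str, float]:
    """Landmark series -> cleaned signal -> 65-feature record for one video."""
    signal = tapping_signal.clean_pipeline(
        series,
        presence_threshold=cfg.presence_threshold,
        window=cfg.interpolation_window,
        degree=cfg.interpolation_degree,
        min_gap_s=cfg.min_gap_s,
        amplitude_floor_quantile=cfg.amplitude_floor_quantile,
        trough_iqr_fraction=cfg.trough_iqr_fraction,
    )
    feats = featurize(
        signal,
        series,
        speed_threshold=cfg.speed_threshold_deg_s,
        interruption_min_dur_s=cfg.interruption_min_dur_s,
        freeze_min_dur_s=cfg.freeze_min_dur_s,
        entropy_bins=cfg.entropy_bins,
    )
    return feats


def build_feature_table(
    videos: list[LandmarkTimeSeries], cfg: RunConfig
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Feature rows for every processable video; (table, skipped videos).

    Videos that fail cleaning (e.g. too few detectable taps) are skipped and
    reported, not fatal.
    """
    rows, skipped = [], []
    for series in videos:
        try:
            feats = process_video(series, cfg)
        except TapscoreError as exc:
            skipped.append((series.video_id, str(exc)))
            log.warning("skipping %s: %s", series.video_id, exc)
            continue
        row = {
            "participant_id": series.participant_id,
            "video_id": series.video_id,
            "hand": series.hand,
            **feats,
        }
        for key, val in series.metadata.items():
            row.setdefault(key, val)
        rows.append(row)
    return pd.DataFrame(rows), skipped


def cohort_feature_table(
    spec: synthetic.CohortSpec, cfg: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and featurize it: (features+labels, ratings, truth).

    Labels are the expert-derived ground truth (majority / rounded mean),
    exactly as a real study would label its videos.
    """
    videos, ratings, truth = synthetic.gen_cohort(spec)
    table, skipped = build_feature_table(videos, cfg)
    if skipped:
        log.info("cohort: %d/%d videos skipped", len(skipped), len(videos))
    gt = rater_analysis.ground_truth_table(ratings)[["video_id", "severity"]]
    table = table.merge(gt.rename(columns={"severity": "label"}), on="video_id", how="inner")
    return table, ratings, truth


def run_simulate(spec: synthetic.CohortSpec, outdir: str | Path) -> dict:
    """Write a cohort to disk: landmark CSVs, ratings CSV, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    videos, ratings, truth = synthetic.gen_cohort(spec)
    lm_dir = outdir / "landmarks"
    lm_dir.mkdir(exist_ok=True)
    for series in videos:
        write_landmark_series(series, lm_dir / f"{series.video_id}.csv")
    ratings.to_csv(outdir / "ratings.csv", index=False)
    truth.to_json(outdir / "truth.json", orient="records", indent=1)
    return {"n_videos": len(videos), "outdir": str(outdir)}


def run_angles(landmark_path: str | Path, out_prefix: str | Path, cfg: RunConfig) -> None:
    """One landmark file -> cleaned angle CSV + peaks CSV."""
    series = read_landmark_series(landmark_path)
    angles = tapping_signal.build_angle_series(series, cfg.presence_threshold)
    angles = tapping_signal.interpolate_missing(
        angles, cfg.interpolation_window, cfg.interpolation_degree
    )
    segment = tapping_signal.longest_visible_segment(angles)
    peaks = tapping_signal.detect_peaks(
        segment, cfg.min_gap_s, cfg.amplitude_floor_quantile, cfg.trough_iqr_fraction
    )
    out_prefix = Path(out_prefix)
    tapping_signal.write_angle_series(segment, out_prefix.with_suffix(".angles.csv"))
    tapping_signal.write_peaks(segment, peaks, out_prefix.with_suffix(".peaks.csv"))


def run_featurize(landmark_dir: str | Path, out_csv: str | Path, cfg: RunConfig) -> dict:
    """All landmark files in a directory -> one feature-table CSV."""
    paths = sorted(Path(landmark_dir).glob("*.csv")) + sorted(Path(landmark_dir).glob("*.jsonl"))
    videos = [read_landmark_series(p) for p in paths]
    table, skipped = build_feature_table(videos, cfg)
    if len(table) == 0:
        raise TapscoreError("no video could be featurized")
    table.to_csv(out_csv, index=False)
    return {"n_rows": len(table), "n_skipped": len(skipped), "skipped": skipped}


def run_evaluate(
    features_csv: str | Path, outdir: str | Path, cfg: RunConfig, labels_csv: str | Path | None = None
) -> severity_model.CVResult:
    """LOPO evaluation of a feature table; writes metrics/predictions/report."""
    table = pd.read_csv(features_csv)
    if labels_csv is not None:
        gt = pd.read_csv(labels_csv)
        orphans = set(table.video_id) ^ set(gt.video_id)
        if orphans:
            raise TapscoreError(f"feature/label key mismatch: {sorted(orphans)[:10]}")
        table = table.merge(
            gt[["video_id", "severity"]].rename(columns={"severity": "label"}), on="video_id"
        )
    if "label" not in table.columns:
        raise TapscoreError("feature table has no 'label' column and no labels file was given")
    cv = severity_model.lopo_cv(
        table,
        seed=cfg.seed,
        k=cfg.n_selected_features,
        r_threshold=cfg.redundancy_r_threshold,
        alpha=cfg.significance_alpha,
        scaling=cfg.scaling,
        regressor=cfg.regressor,
        rfe_step=cfg.rfe_step,
        paper_mode=cfg.paper_mode,
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cv.predictions.to_csv(outdir / "predictions.csv", index=False)
    meta = {
        "metrics": cv.metrics,
        "config_hash": config_hash(cfg),
        "registry_version": REGISTRY_VERSION,
        "seed": cfg.seed,
        "paper_mode": cfg.paper_mode,
    }
    (outdir / "metrics.json").write_text(json.dumps(meta, indent=1))
    # whole-table screening report (always written for the record)
    filtered, report = severity_model.redundancy_filter(table, cfg.redundancy_r_threshold)
    report.screen = severity_model.significance_screen(filtered, cfg.significance_alpha).screen
    report.to_frame().to_csv(outdir / "selection_report.csv", index=False)
    return cv


def run_raters(ratings_csv: str | Path, outdir: str | Path, cfg: RunConfig) -> dict:
    """Ratings CSV -> ground truth CSV + agreement reports."""
    ratings = pd.read_csv(ratings_csv)
    missing = [c for c in rater_analysis.RATING_COLS if c not in ratings.columns]
    if missing:
        raise TapscoreError(f"ratings file lacks columns: {missing}")
    n_experts = ratings.loc[ratings.role == "expert", "rater_id"].nunique()
    if n_experts < 3:
        raise TapscoreError(f"ground truth needs 3 expert raters, found {n_experts}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gt = rater_analysis.ground_truth_table(ratings)
    gt.to_csv(outdir / "ground_truth.csv", index=False)
    wide = rater_analysis.ratings_wide(ratings, role="expert")
    icc_res = rater_analysis.icc(wide, cfg.icc_variant)
    alpha = rater_analysis.krippendorff_alpha(wide, cfg.krippendorff_level)
    pairs = rater_analysis.pairwise_agreement(wide, gt.set_index("video_id")["severity"])
    quality = rater_analysis.agreement_vs_quality(ratings, cfg.icc_variant)
    report = {
        "icc": {"estimate": icc_res.estimate, "ci95": list(icc_res.ci95), "variant": icc_res.variant},
        "krippendorff_alpha": alpha,
        "krippendorff_level": cfg.krippendorff_level,
        "within_one_pct": pairs.get("within_one_pct"),
        "provenance_counts": gt["provenance"].value_counts().to_dict(),
        "quality_counts": quality["counts"],
        "chi2_majority_vs_quality": quality["chi2"],
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
    }
    pairs["pairs"].to_csv(outdir / "pairwise_agreement.csv", index=False)
    (outdir / "rater_report.json").write_text(json.dumps(report, indent=1))
    return report


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration, for artifact logs."""
    payload = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def shuffled_label_control(
    table: pd.DataFrame, cfg: RunConfig, seed_offset: int = 1000
) -> severity_model.CVResult:
    """LOPO on participant-permuted labels: the no-signal baseline.

    Labels are permuted *across participants* (all of a participant's videos
    keep a common, reassigned label), preserving the label distribution
    while destroying the feature-label link.
    """
    rng = np.random.default_rng(cfg.seed + seed_offset)
    per_part = table.groupby("participant_id")["label"].first()
    permuted = pd.Series(
        rng.permutation(per_part.to_numpy()), index=per_part.index, name="label"
    )
    shuffled = table.drop(columns="label").merge(
        permuted.reset_index(), on="participant_id", how="left"
    )
    return severity_model.lopo_cv(
        shuffled,
        seed=cfg.seed,
        k=cfg.n_selected_features,
        r_threshold=cfg.redundancy_r_threshold,
        scaling=cfg.scaling,
        regressor=cfg.regressor,
        rfe_step=cfg.rfe_step,
        paper_mode=cfg.paper_mode,
    )
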