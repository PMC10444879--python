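"""Ground-truth derivation and inter-rater agreement statistics.

Each hand-video is rated 0-4 by three expert neurologists (plus optional
non-expert raters used only for comparison).  The ground-truth label is the
modal expert rating when at least two experts agree (provenance
``majority``), otherwise the mean of the three ratings rounded to the
nearest integer (provenance ``averaged``; with three integer ratings the
mean is a multiple of 1/3, so the half-point case cannot occur).

Agreement statistics:

* :func:`icc` — intraclass correlation (two-way random effects by default,
  absolute agreement, single rater: ICC2), with the F-based 95% CI;
* :func:`krippendorff_alpha` — chance-corrected agreement tolerant of
  missing ratings, at the ordinal level by default (the 0-4 scale is
  ordinal);
* :func:`pairwise_agreement` — exact-agreement %, MAE and Pearson r per
  rater pair, plus each rater's within-1-point rate against ground truth;
* :func:`agreement_vs_quality` — agreement stratified by video quality
  (low quality: at least one expert flagged the video as difficult to
  rate), with a chi-square independence test of majority-found x quality.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

log = logging.getLogger(__name__)

RATING_COLS = ("video_id", "hand", "rater_id", "role", "rating", "difficulty_flag")


def derive_ground_truth(expert_ratings) -> tuple[int, str]:
    """(severity, provenance) from exactly three expert ratings.

    provenance is ``"majority"`` when some value occurs at least twice,
    otherwise ``"averaged"`` (rounded mean).
    """
    r = list(expert_ratings)
    if len(r) != 3 or any(pd.isna(v) for v in r):
        raise ValidationError(f"need exactly 3 expert ratings, got {expert_ratings!r}")
    r = [int(v) for v in r]
    if any(not 0 <= v <= 4 for v in r):
        raise ValidationError(f"ratings must be integers 0..4, got {r}")
    vals, counts = np.unique(r, return_counts=True)
    if counts.max() >= 2:
        return int(vals[np.argmax(counts)]), "majority"
    return int(np.floor(np.mean(r) + 0.5)), "averaged"


def ratings_wide(ratings: pd.DataFrame, role: str | None = None) -> pd.DataFrame:
    """Pivot a long ratings table to videos x raters (NaN = missing)."""
    df = ratings if role is None else ratings[ratings["role"] == role]
    return df.pivot_table(index="video_id", columns="rater_id", values="rating", aggfunc="first")


def ground_truth_table(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-video ground truth from the three expert ratings.

    Non-expert ratings never enter the ground truth.  Videos without exactly
    three expert ratings raise a validation error (they should have been
    excluded upstream).
    """
    experts = ratings[ratings["role"] == "expert"]
    rows = []
    for vid, grp in experts.groupby("video_id", sort=False):
        if len(grp) != 3:
            raise ValidationError(f"video {vid}: expected 3 expert ratings, found {len(grp)}")
        severity, provenance = derive_ground_truth(grp["rating"].tolist())
        rows.append(
            {
                "video_id": vid,
                "hand": grp["hand"].iloc[0],
                "severity": severity,
                "provenance": provenance,
            }
        )
    return pd.DataFrame(rows)


def video_quality(ratings: pd.DataFrame) -> pd.Series:
    """'low' for videos at least one expert flagged as difficult, else 'high'."""
    experts = ratings[ratings["role"] == "expert"]
    flagged = experts.groupby("video_id")["difficulty_flag"].any()
    return flagged.map({True: "low", False: "high"}).rename("quality")


@dataclass
class ICCResult:
    estimate: float
    ci95: tuple[float, float]
    variant: str
    degenerate: bool = False


def icc(wide: pd.DataFrame, variant: str = "ICC2") -> ICCResult:
    """Intraclass correlation on a complete-case videos x raters table.

    ``variant`` is one of ICC1/ICC2/ICC3 (single rater) or ICC1k/ICC2k/ICC3k
    (average of k raters); 2 = two-way random effects, absolute agreement.
    The 95% CI comes from the standard F-distribution construction.
    """
    import pingouin as pg

    complete = wide.dropna()
    if complete.shape[0] < 5 or complete.shape[1] < 2:
        raise ValidationError("ICC needs >= 5 complete videos and >= 2 raters")
    long = complete.reset_index().melt(id_vars="video_id", var_name="rater", value_name="rating")
    res = pg.intraclass_corr(
        data=long, targets="video_id", raters="rater", ratings="rating"
    ).set_index("Type")
    aliases = {  # 1 = one-way random; 2 = two-way random, absolute; 3 = two-way mixed
        "ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)",
        "ICC1k": "ICC(1,k)", "ICC2k": "ICC(A,k)", "ICC3k": "ICC(C,k)",
    }
    key = aliases.get(variant, variant)
    if key not in res.index:
        raise ValidationError(f"unknown ICC variant {variant!r}")
    row = res.loc[key]
    degenerate = bool(np.var(complete.mean(axis=1)) == 0.0)
    if degenerate:
        log.warning("zero between-video variance; ICC is degenerate")
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = (float(v) for v in row[ci_col])
    est = float(row["ICC"])
    if np.isnan(est) and not degenerate and complete.var(axis=1).sum() == 0.0:
        est, lo, hi = 1.0, 1.0, 1.0  # perfect agreement: zero residual variance
    return ICCResult(est, (lo, hi), variant, degenerate)


def krippendorff_alpha(wide: pd.DataFrame | np.ndarray, level: str = "ordinal") -> float:
    """Krippendorff's alpha for a videos x raters table with missing entries.

    Coincidence-matrix formulation: every ordered pair of ratings within a
    unit (video) rated by m >= 2 raters contributes 1/(m-1).  The difference
    function is squared-interval, ordinal (cumulative-margin) or nominal.
    """
    arr = np.asarray(wide, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValidationError("alpha needs a 2-D videos x raters table with >= 2 raters")
    units = [row[~np.isnan(row)] for row in arr]
    units = [u for u in units if len(u) >= 2]
    if not units:
        raise ValidationError("no unit was rated by two or more raters")
    values = np.unique(np.concatenate(units))
    v_index = {v: i for i, v in enumerate(values)}
    q = len(values)
    o = np.zeros((q, q))
    for u in units:
        m = len(u)
        for a, b in itertools.permutations(range(m), 2):
            o[v_index[u[a]], v_index[u[b]]] += 1.0 / (m - 1)
    n_c = o.sum(axis=1)
    n_total = n_c.sum()

    delta = np.zeros((q, q))
    for c in range(q):
        for k in range(q):
            if c == k:
                continue
            lo, hi = min(c, k), max(c, k)
            if level == "ordinal":
                d = n_c[lo : hi + 1].sum() - (n_c[lo] + n_c[hi]) / 2.0
                delta[c, k] = d**2
            elif level == "interval":
                delta[c, k] = (values[c] - values[k]) ** 2
            elif level == "nominal":
                delta[c, k] = 1.0
            else:
                raise ValidationError(f"unknown measurement level {level!r}")
    d_o = (o * delta).sum()
    e = np.outer(n_c, n_c) / (n_total - 1.0)
    d_e = (e * delta).sum() - (n_c * np.diag(delta)).sum() / (n_total - 1.0)
    if d_e == 0.0:
        if d_o == 0.0:
            return 1.0
        raise ValidationError("expected disagreement is zero but observed is not")
    return float(1.0 - d_o / d_e)


def pairwise_agreement(
    wide: pd.DataFrame, ground_truth: pd.Series | None = None
) -> dict:
    """Pairwise rater agreement and per-rater deviation from ground truth.

    Returns a dict with ``pairs`` (tidy DataFrame: exact-agreement %, MAE and
    Pearson r per rater pair over co-rated videos; NaN when none) and, when
    ``ground_truth`` is given, ``within_one_pct`` per rater (share of videos
    rated within 1 point of the ground truth).
    """
    raters = list(wide.columns)
    if len(raters) < 2:
        raise ValidationError("pairwise agreement needs >= 2 raters")
    rows = []
    for a, b in itertools.combinations(raters, 2):
        co = wide[[a, b]].dropna()
        if len(co) == 0:
            rows.append({"rater_a": a, "rater_b": b, "exact_pct": np.nan,
                         "mae": np.nan, "pcc": np.nan, "n": 0})
            continue
        diff = co[a] - co[b]
        pcc = np.nan
        if len(co) >= 2 and co[a].std() > 0 and co[b].std() > 0:
            pcc = float(stats.pearsonr(co[a], co[b]).statistic)
        rows.append(
            {
                "rater_a": a,
                "rater_b": b,
                "exact_pct": float((diff == 0).mean() * 100.0),
                "mae": float(diff.abs().mean()),
                "pcc": pcc,
                "n": int(len(co)),
            }
        )
    out = {"pairs": pd.DataFrame(rows)}
    if ground_truth is not None:
        within = {}
        for r in raters:
            co = pd.concat([wide[r], ground_truth], axis=1, join="inner").dropna()
            within[r] = float((co.iloc[:, 0] - co.iloc[:, 1]).abs().le(1).mean() * 100.0)
        out["within_one_pct"] = within
    return out


def agreement_vs_quality(ratings: pd.DataFrame, variant: str = "ICC2") -> dict:
    """Expert agreement stratified by video quality.

    Computes the expert ICC per quality group and a chi-square independence
    test (dof = 1, no continuity correction) of whether finding a majority
    agreement is associated with video quality.
    """
    quality = video_quality(ratings)
    wide = ratings_wide(ratings, role="expert")
    gt = ground_truth_table(ratings).set_index("video_id")
    majority_found = gt["provenance"] == "majority"

    out: dict = {"icc_by_group": {}, "counts": {}}
    for grp in ("high", "low"):
        vids = quality[quality == grp].index
        out["counts"][grp] = int(len(vids))
        if len(vids) == 0:
            log.warning("quality group %r is empty; partial result", grp)
            continue
        try:
            out["icc_by_group"][grp] = icc(wide.loc[wide.index.intersection(vids)], variant)
        except ValidationError as exc:
            log.warning("ICC for group %r unavailable: %s", grp, exc)
    tab = pd.crosstab(majority_found, quality.reindex(majority_found.index))
    if tab.shape == (2, 2):
        chi2, p, dof, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
        out["chi2"] = {"statistic": float(chi2), "p_value": float(p), "dof": int(dof)}
    else:
        out["chi2"] = None
    return out
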