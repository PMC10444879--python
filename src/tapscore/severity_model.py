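"""Feature screening, severity regression and leave-one-patient-out evaluation.

The model maps the 65 kinematic features of a hand-video to a continuous
severity in [0, 4] (MDS-UPDRS item 3.4 scale).  The default regressor is a
gradient-boosted tree ensemble with leaf-wise growth (LightGBM); support-
vector and random-forest alternates are pluggable.  Evaluation is
leave-one-patient-out (LOPO): all of a participant's hand-videos are held
out together, so performance reflects unseen patients.

Screening is two-stage and report-oriented:

* :func:`redundancy_filter` drops the later member of every feature pair with
  |Pearson r| above a threshold (default 0.85), scanning in registry order;
* :func:`significance_screen` reports each surviving feature's correlation
  with the severity labels and its two-sided p-value at a configurable alpha
  (no multiplicity correction); all survivors remain model candidates.

Recursive feature elimination with the boosted-tree learner then keeps the
top-k features (default 22).  By default all screening and selection is
re-fit inside every cross-validation fold (the leakage-safe protocol);
``paper_mode=True`` screens once on the whole table instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import TapscoreError, ValidationError
from .kinematic_features import FEATURE_NAMES, REGISTRY_VERSION

log = logging.getLogger(__name__)

KEY_COLS = ("participant_id", "video_id", "hand")
METRIC_KEYS = ("mae", "mse", "accuracy_pct", "kendall_tau", "mape_pct", "pcc", "spearman_rho")

DEFAULT_LGBM_PARAMS = {
    "n_estimators": 200,
    "learning_rate": 0.05,
    "num_leaves": 31,
    "min_child_samples": 5,
    "deterministic": True,
    "force_row_wise": True,
    "n_jobs": 1,
    "verbosity": -1,
}


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Registry feature columns present in a table, in registry order."""
    cols = [c for c in FEATURE_NAMES if c in table.columns]
    if not cols:
        raise ValidationError("table contains no registry feature columns")
    return cols


@dataclass
class SelectionReport:
    """Everything the screening/selection stage decided, for the record."""

    dropped_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    constant_features: list[str] = field(default_factory=list)
    screen: pd.DataFrame | None = None
    selected: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Flat per-feature report: r, p, significance, what dropped it."""
        rows = []
        dropped_for = {d: (k, r) for k, d, r in self.dropped_pairs}
        screen = self.screen if self.screen is not None else pd.DataFrame(columns=["feature"])
        screened = set(screen["feature"]) if len(screen) else set()
        for name in FEATURE_NAMES:
            if name not in screened and name not in dropped_for:
                continue
            row = {"feature": name, "r": np.nan, "p": np.nan, "significant": False,
                   "dropped_for": "", "selected": name in self.selected}
            if name in dropped_for:
                row["dropped_for"] = dropped_for[name][0]
                row["r"] = dropped_for[name][1]
            elif len(screen):
                rec = screen[screen.feature == name]
                if len(rec):
                    row.update(r=float(rec.r.iloc[0]), p=float(rec.p.iloc[0]),
                               significant=bool(rec.significant.iloc[0]))
            rows.append(row)
        return pd.DataFrame(rows)


def redundancy_filter(
    table: pd.DataFrame, r_threshold: float = 0.85, cols: list[str] | None = None
) -> tuple[pd.DataFrame, SelectionReport]:
    """Drop the later feature of every highly inter-correlated pair.

    Greedy scan in registry column order: each column is kept unless its
    |Pearson r| with an already-kept column exceeds ``r_threshold``.
    Constant columns have undefined r and are treated as uncorrelated
    (kept, flagged in the report).
    """
    if len(table) < 3:
        raise ValidationError("redundancy filter needs at least 3 rows")
    cols = cols or feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    constant = [c for c, r in zip(cols, np.ptp(X, axis=0)) if r == 0.0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    if constant:
        const_idx = [j for j, c in enumerate(cols) if c in constant]
        corr[const_idx, :] = np.nan  # r undefined: treated as uncorrelated
        corr[:, const_idx] = np.nan
    report = SelectionReport(constant_features=constant)
    kept: list[int] = []
    for j, name in enumerate(cols):
        partner = None
        for i in kept:
            r = corr[i, j]
            if np.isfinite(r) and abs(r) > r_threshold:
                partner = (cols[i], float(r))
                break
        if partner is None:
            kept.append(j)
        else:
            report.dropped_pairs.append((partner[0], name, partner[1]))
    kept_names = [cols[j] for j in kept]
    other = [c for c in table.columns if c not in cols]
    return table[other + kept_names], report


def significance_screen(
    table: pd.DataFrame, alpha: float = 0.01, cols: list[str] | None = None,
    label_col: str = "label",
) -> SelectionReport:
    """Per-feature Pearson correlation with the labels (report only).

    Every feature stays a model candidate regardless of significance; strong
    non-linear relations can matter even when the linear correlation does not
    reach ``alpha``.
    """
    if len(table) < 3:
        raise ValidationError("significance screen needs at least 3 rows")
    y = table[label_col].to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        raise ValidationError("labels are constant; correlations undefined")
    cols = cols or feature_columns(table)
    rows = []
    for c in cols:
        x = table[c].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            rows.append({"feature": c, "r": np.nan, "p": np.nan, "significant": False,
                         "reason": "constant feature"})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"feature": c, "r": float(r), "p": float(p),
                     "significant": bool(p < alpha), "reason": ""})
    report = SelectionReport(screen=pd.DataFrame(rows))
    return report


def _make_regressor(name: str, seed: int, hyper: dict | None = None):
    hyper = hyper or {}
    if name == "lightgbm":
        from lightgbm import LGBMRegressor

        params = {**DEFAULT_LGBM_PARAMS, **hyper, "random_state": seed}
        return LGBMRegressor(**params)
    if name == "random_forest":
        from sklearn.ensemble import RandomForestRegressor

        return RandomForestRegressor(
            n_estimators=hyper.get("n_estimators", 300), random_state=seed, n_jobs=1
        )
    if name == "svr":
        from sklearn.svm import SVR

        return SVR(C=hyper.get("C", 10.0), epsilon=hyper.get("epsilon", 0.1))
    raise TapscoreError(f"unknown regressor family {name!r}")


def _make_scaler(scaling: str):
    from sklearn.preprocessing import MinMaxScaler, StandardScaler

    if scaling == "standard":
        return StandardScaler()
    if scaling == "minmax":
        return MinMaxScaler()
    raise TapscoreError(f"unknown scaling {scaling!r}")


def select_features(
    table: pd.DataFrame,
    k: int = 22,
    seed: int = 0,
    step: int = 2,
    cols: list[str] | None = None,
    label_col: str = "label",
    hyper: dict | None = None,
) -> list[str]:
    """Top-k features by recursive elimination with a boosted-tree ranker.

    Repeatedly fits the learner, ranks features by importance and drops the
    weakest ``step`` until ``k`` remain.  Deterministic given the seed.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    cols = cols or feature_columns(table)
    if k >= len(cols):
        return list(cols)
    from sklearn.feature_selection import RFE

    X = table[cols].to_numpy(dtype=float)
    y = table[label_col].to_numpy(dtype=float)
    rfe = RFE(_make_regressor("lightgbm", seed, hyper), n_features_to_select=k, step=step)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rfe.fit(X, y)
    return [c for c, keep in zip(cols, rfe.support_) if keep]


@dataclass
class TrainedModel:
    """A fitted scaler + regressor bound to an ordered feature list."""

    scaler: object
    regressor: object
    feature_names: list[str]
    regressor_name: str
    scaling: str
    seed: int
    registry_version: str = REGISTRY_VERSION

    def matrix(self, rows: pd.DataFrame | dict) -> np.ndarray:
        if isinstance(rows, dict):
            rows = pd.DataFrame([rows])
        missing = [c for c in self.feature_names if c not in rows.columns]
        if missing:
            raise ValidationError(f"missing features: {missing}")
        return self.scaler.transform(rows[self.feature_names].to_numpy(dtype=float))


def train(
    table: pd.DataFrame,
    feature_names: list[str] | None = None,
    label_col: str = "label",
    scaling: str = "standard",
    regressor: str = "lightgbm",
    seed: int = 0,
    hyper: dict | None = None,
) -> TrainedModel:
    """Fit scaler (training rows only) and regressor on selected features."""
    cols = feature_names or feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        bad = [c for c in cols if not np.all(np.isfinite(table[c].to_numpy(dtype=float)))]
        raise ValidationError(f"non-finite values in features: {bad}")
    y = table[label_col].to_numpy(dtype=float)
    scaler = _make_scaler(scaling)
    Xs = scaler.fit_transform(X)
    reg = _make_regressor(regressor, seed, hyper)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reg.fit(Xs, y)
    return TrainedModel(scaler, reg, list(cols), regressor, scaling, seed)


def predict(model: TrainedModel, rows: pd.DataFrame | dict) -> np.ndarray:
    """Continuous severity prediction, clipped to [0, 4]."""
    raw = model.regressor.predict(model.matrix(rows))
    return np.clip(raw, 0.0, 4.0)


def to_class(pred) -> np.ndarray | int:
    """Round a continuous severity to the nearest class; .5 rounds half-up."""
    arr = np.clip(np.floor(np.asarray(pred, dtype=float) + 0.5), 0, 4).astype(int)
    return int(arr) if np.isscalar(pred) or arr.ndim == 0 else arr


def compute_metrics(preds, truth) -> dict:
    """The seven regression/agreement metrics between predictions and labels.

    MAPE is computed over rows with truth > 0 only (division by zero);
    the count of excluded rows is reported.  Correlation metrics are NaN
    when the truth is constant.
    """
    p = np.asarray(preds, dtype=float)
    t = np.asarray(truth, dtype=float)
    if len(p) != len(t) or len(p) < 2:
        raise ValidationError("predictions and truth must have equal length >= 2")
    err = p - t
    out = {
        "mae": float(np.abs(err).mean()),
        "mse": float((err**2).mean()),
        "accuracy_pct": float((to_class(p) == t.astype(int)).mean() * 100.0),
        "n": int(len(p)),
    }
    pos = t > 0
    out["mape_n_excluded"] = int((~pos).sum())
    out["mape_pct"] = (
        float((np.abs(err[pos]) / t[pos]).mean() * 100.0) if pos.any() else float("nan")
    )
    if np.ptp(t) == 0.0 or np.ptp(p) == 0.0:
        out.update(kendall_tau=float("nan"), pcc=float("nan"), spearman_rho=float("nan"))
    else:
        out["kendall_tau"] = float(stats.kendalltau(p, t).statistic)
        out["pcc"] = float(stats.pearsonr(p, t).statistic)
        out["spearman_rho"] = float(stats.spearmanr(p, t).statistic)
    return out


@dataclass
class CVResult:
    """Out-of-fold predictions and metrics of a LOPO evaluation."""

    predictions: pd.DataFrame
    metrics: dict
    fold_features: dict = field(default_factory=dict)
    report: SelectionReport | None = None


def lopo_cv(
    table: pd.DataFrame,
    seed: int = 0,
    k: int = 22,
    r_threshold: float = 0.85,
    alpha: float = 0.01,
    scaling: str = "standard",
    regressor: str = "lightgbm",
    hyper: dict | None = None,
    rfe_step: int = 2,
    paper_mode: bool = False,
    label_col: str = "label",
) -> CVResult:
    """Leave-one-patient-out cross-validation.

    One fold per participant; both of a participant's hand-videos are held
    out together.  With ``paper_mode=False`` (default) the redundancy filter
    and recursive feature elimination are re-fit on every training fold —
    the leakage-safe protocol.  ``paper_mode=True`` screens and selects once
    on the whole table before iterating folds.
    """
    participants = table["participant_id"].unique()
    if len(participants) < 3:
        raise ValidationError("LOPO needs at least 3 participants")
    report = None
    global_selected = None
    if paper_mode:
        filtered, report = redundancy_filter(table, r_threshold)
        report.screen = significance_screen(filtered, alpha, label_col=label_col).screen
        global_selected = select_features(
            filtered, k=k, seed=seed, step=rfe_step, label_col=label_col, hyper=hyper
        )
        report.selected = global_selected

    rows = []
    fold_features: dict[str, list[str]] = {}
    for pid in participants:
        test_mask = table["participant_id"] == pid
        train_df, test_df = table[~test_mask], table[test_mask]
        if len(test_df) == 0:
            log.warning("participant %s has no rows; skipped", pid)
            continue
        if paper_mode:
            selected = global_selected
        else:
            filtered, _ = redundancy_filter(train_df, r_threshold)
            selected = select_features(
                filtered, k=k, seed=seed, step=rfe_step, label_col=label_col, hyper=hyper
            )
        fold_features[str(pid)] = selected
        model = train(
            train_df, selected, label_col=label_col, scaling=scaling,
            regressor=regressor, seed=seed, hyper=hyper,
        )
        preds = predict(model, test_df)
        for (_, row), pred in zip(test_df.iterrows(), preds):
            rows.append(
                {
                    "participant_id": row["participant_id"],
                    "video_id": row["video_id"],
                    "hand": row.get("hand", ""),
                    "truth": int(row[label_col]),
                    "pred": float(pred),
                    "pred_class": int(to_class(float(pred))),
                }
            )
    pred_df = pd.DataFrame(rows)
    metrics = compute_metrics(pred_df["pred"], pred_df["truth"])
    return CVResult(pred_df, metrics, fold_features, report)


def explain(model: TrainedModel, rows: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-row, per-feature additive attributions (exact TreeSHAP).

    For the boosted-tree regressor the attributions are Shapley values
    computed by the tree path-dependent algorithm; per row they sum to the
    unclipped prediction minus the expected baseline.  Returns
    ``(contributions, baseline)`` where ``contributions`` has one column per
    selected feature.
    """
    if model.regressor_name != "lightgbm":
        raise TapscoreError(
            f"attributions are only available for the boosted-tree family, "
            f"not {model.regressor_name!r}"
        )
    X = model.matrix(rows)
    contrib = model.regressor.predict(X, pred_contrib=True)
    return (
        pd.DataFrame(contrib[:, :-1], columns=model.feature_names, index=rows.index),
        contrib[:, -1],
    )


def global_importance(contribs: pd.DataFrame) -> pd.Series:
    """Mean |attribution| per feature, sorted descending."""
    return contribs.abs().mean(axis=0).sort_values(ascending=False)


def metrics_by_group(
    predictions: pd.DataFrame,
    grouping: str,
    groups: tuple[str, str] | None = None,
    equal_var: bool = True,
) -> dict:
    """Per-group absolute-error summary plus a two-sample comparison.

    ``predictions`` is a LOPO prediction table that also carries the
    metadata column ``grouping``.  Groups with fewer than 2 rows are
    excluded with a warning.  The two-sided t-test compares the two named
    groups (default: the two largest).
    """
    if grouping not in predictions.columns:
        raise ValidationError(f"grouping column {grouping!r} not present")
    err = (predictions["pred"] - predictions["truth"]).abs()
    per_group = {}
    for g, idx in predictions.groupby(grouping).groups.items():
        e = err.loc[idx]
        if len(e) < 2:
            log.warning("group %r has < 2 rows; excluded", g)
            continue
        per_group[g] = {"mae": float(e.mean()), "std": float(e.std(ddof=1)), "n": int(len(e))}
    result = {"groups": per_group, "p_value": float("nan"), "compared": None}
    if groups is None:
        ranked = sorted(per_group, key=lambda g: per_group[g]["n"], reverse=True)
        groups = tuple(ranked[:2]) if len(ranked) >= 2 else None
    if groups and all(g in per_group for g in groups):
        a = err[predictions[grouping] == groups[0]]
        b = err[predictions[grouping] == groups[1]]
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        result.update(p_value=float(p), t_statistic=float(t), compared=list(groups))
    return result
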