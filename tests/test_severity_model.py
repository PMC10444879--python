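"""Feature screening, regression, LOPO evaluation and attribution."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import kendall_tau_oracle, pearson_oracle, ranks
from tapscore import severity_model as sm
from tapscore.errors import TapscoreError, ValidationError
from tapscore.kinematic_features import FEATURE_NAMES

warnings.filterwarnings("ignore", message=".*force_row_wise.*")


def synthetic_table(rng, n_rows=120, n_participants=60, informative=5, noise_sd=0.3):
    """A feature table over the registry names with a planted linear signal."""
    labels = rng.integers(0, 5, n_participants)
    rows = []
    for p in range(n_participants):
        for hand in ("left", "right")[: n_rows // n_participants]:
            row = {
                "participant_id": f"p{p:03d}",
                "video_id": f"p{p:03d}_{hand}",
                "hand": hand,
                "label": int(labels[p]),
            }
            for j, name in enumerate(FEATURE_NAMES):
                if j < informative:
                    row[name] = labels[p] * (1 + 0.2 * j) + rng.normal(0, noise_sd)
                else:
                    row[name] = rng.normal(0, 1)
            rows.append(row)
    return pd.DataFrame(rows)


class TestRedundancyFilter:
    def test_duplicate_column_dropped_once(self, rng):
        df = synthetic_table(rng, informative=0)
        df[FEATURE_NAMES[1]] = df[FEATURE_NAMES[0]]
        out, report = sm.redundancy_filter(df)
        dropped = [d for _, d, _ in report.dropped_pairs]
        assert dropped == [FEATURE_NAMES[1]]
        assert FEATURE_NAMES[0] in out.columns and FEATURE_NAMES[1] not in out.columns

    def test_three_mutual_duplicates_keep_first(self, rng):
        df = synthetic_table(rng, informative=0)
        df[FEATURE_NAMES[1]] = df[FEATURE_NAMES[0]]
        df[FEATURE_NAMES[2]] = df[FEATURE_NAMES[0]]
        _, report = sm.redundancy_filter(df)
        assert {d for _, d, _ in report.dropped_pairs} == set(FEATURE_NAMES[1:3])
        assert all(k == FEATURE_NAMES[0] for k, _, _ in report.dropped_pairs)

    def test_independent_noise_nothing_dropped(self, rng):
        df = synthetic_table(rng, n_rows=500, n_participants=500, informative=0)
        # confirm below threshold by direct sample correlation
        X = df[list(FEATURE_NAMES)].to_numpy()
        corr = np.corrcoef(X, rowvar=False)
        assert np.abs(corr[np.triu_indices_from(corr, 1)]).max() < 0.85
        _, report = sm.redundancy_filter(df)
        assert report.dropped_pairs == []

    def test_constant_column_kept_and_flagged(self, rng):
        df = synthetic_table(rng, informative=0)
        df[FEATURE_NAMES[3]] = 1.23
        out, report = sm.redundancy_filter(df)
        assert FEATURE_NAMES[3] in report.constant_features
        assert FEATURE_NAMES[3] in out.columns


class TestSignificanceScreen:
    def test_feature_equal_to_label(self, rng):
        df = synthetic_table(rng, informative=0)
        df[FEATURE_NAMES[0]] = df["label"].astype(float)
        report = sm.significance_screen(df)
        row = report.screen[report.screen.feature == FEATURE_NAMES[0]].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert bool(row.significant)

    def test_null_feature_rarely_significant(self):
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 5, 489)
            x = rng.normal(0, 1, 489)
            _, p = stats.pearsonr(x, y)
            hits += p < 0.01
        # package screen agrees with the direct test on one of the seeds
        rng = np.random.default_rng(0)
        df = synthetic_table(rng, n_rows=489, n_participants=489, informative=0)
        report = sm.significance_screen(df)
        assert hits <= int(0.05 * n_seeds)
        assert report.screen.significant.mean() < 0.2

    def test_strong_signal_significant(self, rng):
        df = synthetic_table(rng, informative=1, noise_sd=0.1)
        report = sm.significance_screen(df)
        row = report.screen[report.screen.feature == FEATURE_NAMES[0]].iloc[0]
        assert bool(row.significant)

    def test_constant_feature_flagged(self, rng):
        df = synthetic_table(rng, informative=0)
        df[FEATURE_NAMES[0]] = 0.0
        report = sm.significance_screen(df)
        row = report.screen[report.screen.feature == FEATURE_NAMES[0]].iloc[0]
        assert not bool(row.significant) and row.reason == "constant feature"


class TestSelectFeatures:
    def test_k_equal_to_all_is_identity(self, rng):
        df = synthetic_table(rng)
        assert sm.select_features(df, k=65, seed=0) == list(FEATURE_NAMES)

    def test_planted_signal_recovered(self, rng):
        # the label is driven by 5 independent features: elimination must keep them
        n = 400
        X = rng.normal(0, 1, (n, 50))
        label = np.clip(np.round(X[:, :5].sum(axis=1) / 2 + 2), 0, 4)
        df = pd.DataFrame(X, columns=list(FEATURE_NAMES[:50]))
        df["label"] = label
        selected = sm.select_features(df, k=5, seed=0, cols=list(FEATURE_NAMES[:50]))
        assert len(set(selected) & set(FEATURE_NAMES[:5])) >= 4

    def test_deterministic(self, rng):
        df = synthetic_table(rng)
        a = sm.select_features(df, k=10, seed=42)
        b = sm.select_features(df, k=10, seed=42)
        assert a == b

    def test_invalid_k_errors(self, rng):
        with pytest.raises(ValidationError):
            sm.select_features(synthetic_table(rng), k=0, seed=0)


class TestTrainPredict:
    def test_same_seed_identical_predictions(self, rng):
        df = synthetic_table(rng)
        probe = df.head(10)
        preds = [
            sm.predict(sm.train(df, seed=7), probe) for _ in range(2)
        ]
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_noiseless_linear_rule_learned(self, rng):
        df = synthetic_table(rng, n_rows=200, n_participants=200, informative=1, noise_sd=0.0)
        model = sm.train(df, seed=0)
        preds = sm.predict(model, df)
        assert np.abs(preds - df["label"]).mean() < 0.1

    def test_constant_labels(self, rng):
        df = synthetic_table(rng)
        df["label"] = 2
        model = sm.train(df, seed=0)
        np.testing.assert_allclose(sm.predict(model, df.head(5)), 2.0, atol=1e-6)

    def test_nonfinite_feature_names_column(self, rng):
        df = synthetic_table(rng)
        df.loc[df.index[0], FEATURE_NAMES[2]] = np.inf
        with pytest.raises(ValidationError, match=FEATURE_NAMES[2]):
            sm.train(df, seed=0)

    def test_missing_feature_named_at_predict(self, rng):
        df = synthetic_table(rng)
        model = sm.train(df, seed=0)
        with pytest.raises(ValidationError, match=FEATURE_NAMES[0]):
            sm.predict(model, df.drop(columns=[FEATURE_NAMES[0]]))

    def test_prediction_clipped_to_range(self):
        class Raw:
            def predict(self, X):
                return np.array([4.3, -0.2, 1.7])

        class Identity:
            def transform(self, X):
                return np.asarray(X, dtype=float)

        model = sm.TrainedModel(Identity(), Raw(), ["a"], "stub", "standard", 0)
        out = sm.predict(model, pd.DataFrame({"a": [0.0, 0.0, 0.0]}))
        np.testing.assert_allclose(out, [4.0, 0.0, 1.7])


class TestToClass:
    @pytest.mark.parametrize("value,expected", [(1.6, 2), (2.5, 3), (0.0, 0), (3.49, 3), (4.0, 4)])
    def test_rounding_half_up(self, value, expected):
        assert sm.to_class(value) == expected

    def test_array_input(self):
        np.testing.assert_array_equal(sm.to_class(np.array([0.4, 0.5, 3.9])), [0, 1, 4])


class TestComputeMetrics:
    def test_perfect_predictions(self):
        t = np.array([0, 1, 2, 3, 4, 2])
        m = sm.compute_metrics(t.astype(float), t)
        assert m["mae"] == 0 and m["mse"] == 0 and m["accuracy_pct"] == 100
        assert m["pcc"] == pytest.approx(1) and m["kendall_tau"] == pytest.approx(1)
        assert m["spearman_rho"] == pytest.approx(1)

    def test_constant_offset(self):
        t = np.array([0, 1, 2, 3])
        m = sm.compute_metrics(t + 1.0, t)
        assert m["mae"] == 1.0 and m["mse"] == 1.0

    def test_matches_textbook_formulas(self, rng):
        t = rng.integers(0, 5, 60).astype(float)
        p = np.clip(t + rng.normal(0, 0.8, 60), 0, 4)
        m = sm.compute_metrics(p, t)
        a, b = list(p), list(t)
        assert m["mae"] == pytest.approx(sum(abs(x - y) for x, y in zip(a, b)) / 60)
        assert m["mse"] == pytest.approx(sum((x - y) ** 2 for x, y in zip(a, b)) / 60)
        assert m["pcc"] == pytest.approx(pearson_oracle(a, b), abs=1e-10)
        assert m["kendall_tau"] == pytest.approx(kendall_tau_oracle(a, b), abs=1e-10)
        assert m["spearman_rho"] == pytest.approx(
            pearson_oracle(ranks(a), ranks(b)), abs=1e-10
        )
        pos = [(x, y) for x, y in zip(a, b) if y > 0]
        assert m["mape_pct"] == pytest.approx(
            100 * sum(abs(x - y) / y for x, y in pos) / len(pos)
        )
        assert m["mape_n_excluded"] == sum(1 for y in b if y == 0)

    def test_constant_truth_marks_correlations(self):
        m = sm.compute_metrics(np.array([1.0, 2.0, 1.5]), np.array([2, 2, 2]))
        assert np.isnan(m["pcc"]) and np.isnan(m["kendall_tau"])
        assert m["mae"] == pytest.approx(0.5)

    def test_mae_not_above_rmse(self, rng):
        t = rng.integers(0, 5, 50).astype(float)
        p = np.clip(t + rng.normal(0, 1.0, 50), 0, 4)
        m = sm.compute_metrics(p, t)
        assert m["mae"] <= np.sqrt(m["mse"]) + 1e-12


class TestLopoCV:
    def test_fold_structure(self, rng):
        df = synthetic_table(rng, n_rows=10, n_participants=5)
        cv = sm.lopo_cv(df, seed=0, k=5)
        assert len(cv.fold_features) == 5
        assert sorted(cv.predictions.video_id) == sorted(df.video_id)
        assert cv.predictions.video_id.is_unique

    def test_predictions_in_range(self, rng):
        df = synthetic_table(rng, n_rows=20, n_participants=10)
        cv = sm.lopo_cv(df, seed=0, k=5)
        assert cv.predictions.pred.between(0, 4).all()
        assert cv.predictions.pred_class.isin(range(5)).all()

    def test_no_leakage_into_scaler(self, rng, monkeypatch):
        df = synthetic_table(rng, n_rows=10, n_participants=5)
        marker_col = FEATURE_NAMES[0]
        df[marker_col] = np.arange(len(df), dtype=float) * 1000.0  # unique per row
        seen: list[set] = []
        from sklearn.preprocessing import StandardScaler

        class Recording(StandardScaler):
            def fit(self, X, y=None):
                seen.append(set(np.asarray(X)[:, 0].tolist()))
                return super().fit(X, y)

        def make_scaler(name):
            return Recording()

        monkeypatch.setattr(sm, "_make_scaler", make_scaler)
        cv = sm.lopo_cv(df, seed=0, k=65)  # k=all so the marker is always col 0
        markers = df.set_index("participant_id")[marker_col]
        assert len(seen) == 5
        for pid, fitted in zip(df["participant_id"].unique(), seen):
            held_out = set(markers.loc[[pid]].tolist())
            assert not (held_out & fitted)

    def test_too_few_participants(self, rng):
        df = synthetic_table(rng, n_rows=4, n_participants=2)
        with pytest.raises(ValidationError):
            sm.lopo_cv(df, seed=0)

    def test_paper_mode_selects_once(self, rng):
        df = synthetic_table(rng, n_rows=20, n_participants=10)
        cv = sm.lopo_cv(df, seed=0, k=5, paper_mode=True)
        sets = {tuple(v) for v in cv.fold_features.values()}
        assert len(sets) == 1
        assert cv.report is not None and len(cv.report.selected) == 5


class TestExplain:
    def _model_and_table(self, rng):
        df = synthetic_table(rng, n_rows=200, n_participants=200, informative=1, noise_sd=0.1)
        cols = list(FEATURE_NAMES[:20])
        model = sm.train(df, cols, seed=0)
        return model, df

    def test_additivity(self, rng):
        model, df = self._model_and_table(rng)
        probe = df.head(20)
        contribs, base = sm.explain(model, probe)
        raw = model.regressor.predict(model.matrix(probe))
        np.testing.assert_allclose(contribs.sum(axis=1) + base, raw, atol=1e-6)

    def test_planted_feature_dominates(self, rng):
        model, df = self._model_and_table(rng)
        contribs, _ = sm.explain(model, df.head(100))
        importance = sm.global_importance(contribs)
        assert importance.index[0] == FEATURE_NAMES[0]

    def test_deterministic(self, rng):
        df = synthetic_table(rng)
        probe = df.head(10)
        a = sm.explain(sm.train(df, seed=3), probe)[0]
        b = sm.explain(sm.train(df, seed=3), probe)[0]
        pd.testing.assert_frame_equal(a, b)

    def test_unsupported_family_errors(self, rng):
        df = synthetic_table(rng, n_rows=30, n_participants=30)
        model = sm.train(df, seed=0, regressor="svr")
        with pytest.raises(TapscoreError, match="svr"):
            sm.explain(model, df.head(5))


class TestMetricsByGroup:
    def _preds(self, rng, n=300, shift=0.0):
        truth = rng.integers(0, 5, n)
        pred = np.clip(truth + rng.normal(0, 0.5, n), 0, 4)
        group = np.where(rng.random(n) < 0.55, "m", "f")
        pred = np.where(group == "m", np.clip(pred + shift, 0, 4), pred)
        return pd.DataFrame(
            {"participant_id": [f"p{i}" for i in range(n)], "video_id": range(n),
             "truth": truth, "pred": pred, "sex": group}
        )

    def test_identical_distributions_large_p(self, rng):
        out = sm.metrics_by_group(self._preds(rng), "sex")
        assert out["p_value"] > 0.05

    def test_counts_echoed(self, rng):
        df = self._preds(rng)
        out = sm.metrics_by_group(df, "sex")
        for g in ("m", "f"):
            assert out["groups"][g]["n"] == int((df.sex == g).sum())

    def test_tiny_group_excluded(self, rng):
        df = self._preds(rng, n=50)
        df.loc[df.index[0], "sex"] = "x"
        out = sm.metrics_by_group(df, "sex")
        assert "x" not in out["groups"]

    def test_missing_column_errors(self, rng):
        with pytest.raises(ValidationError):
            sm.metrics_by_group(self._preds(rng), "ethnicity")
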