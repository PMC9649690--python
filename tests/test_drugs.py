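"""Transcript-drug association: prefilter, elastic net, bootstrap scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from txaxes import (
    ElasticNetConfig,
    ExpressionAtlas,
    bootstrap_predictive_scores,
    build_prediction_matrix,
    call_associations,
    predictive_score,
    spearman_prefilter,
    tune_elastic_net,
)


def _atlas_from(X, tids=None):
    n, k = X.shape  # cells x transcripts
    cells = [f"C{i}" for i in range(n)]
    tids = tids or [f"T{j}" for j in range(k)]
    values = pd.DataFrame(X.T, index=tids, columns=cells)
    lineage = pd.Series("l1", index=cells)
    return ExpressionAtlas(values, lineage), cells


class TestPredictiveScore:
    @pytest.mark.parametrize(
        "f_pos,f_neg,B,score,direction",
        [
            (1000, 0, 1000, 1.0, "positive"),
            (850, 50, 1000, 0.8, "positive"),
            (50, 850, 1000, 0.8, "negative"),
            (400, 400, 1000, 0.0, "none"),
            (0, 0, 1000, 0.0, "none"),
            (140, 0, 200, 0.7, "positive"),
        ],
    )
    def test_worked_values(self, f_pos, f_neg, B, score, direction):
        got_score, got_dir = predictive_score(f_pos, f_neg, B)
        assert got_score == pytest.approx(score)
        assert got_dir == direction

    @settings(max_examples=200, deadline=None)
    @given(st.integers(1, 1000), st.integers(0, 1000), st.integers(0, 1000))
    def test_symmetry_and_bounds(self, B, f_pos, f_neg):
        if f_pos + f_neg > B:
            return
        s1, d1 = predictive_score(f_pos, f_neg, B)
        s2, d2 = predictive_score(f_neg, f_pos, B)
        assert s1 == s2
        assert 0.0 <= s1 <= 1.0
        if d1 == "positive":
            assert d2 == "negative"
        if s1 == 1.0:
            assert f_pos + f_neg == B and (f_pos == 0 or f_neg == 0)


class TestSpearmanPrefilter:
    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        atlas, cells = _atlas_from(np.abs(X))
        auc = pd.DataFrame({"D": y}, index=cells)
        out = spearman_prefilter(atlas, auc).set_index("transcript_id")
        for j, tid in enumerate(atlas.transcript_ids):
            rho, p = stats.spearmanr(np.abs(X)[:, j], y)
            assert out.loc[tid, "rho"] == pytest.approx(rho, abs=1e-12)
            assert out.loc[tid, "pvalue"] == pytest.approx(p, rel=1e-9)

    def test_hand_ranked_pair(self):
        # x=(1..5), y=(2,1,4,3,5): sum d^2 = 4, rho = 1 - 6*4/(5*24) = 0.8
        X = np.array([[1, 2, 3, 4, 5.0]]).T
        atlas, cells = _atlas_from(X)
        auc = pd.DataFrame({"D": [2, 1, 4, 3, 5.0]}, index=cells)
        out = spearman_prefilter(atlas, auc)
        assert out["rho"].iloc[0] == pytest.approx(0.8)

    def test_monotone_driver_passes(self):
        X = np.linspace(1, 10, 40).reshape(-1, 1)
        atlas, cells = _atlas_from(X)
        auc = pd.DataFrame({"D": X[:, 0] ** 2}, index=cells)  # monotone
        out = spearman_prefilter(atlas, auc)
        assert out["rho"].iloc[0] == pytest.approx(1.0)
        assert bool(out["passes"].iloc[0])

    def test_constant_transcript_skipped(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        atlas, cells = _atlas_from(X)
        auc = pd.DataFrame({"D": np.arange(10.0)}, index=cells)
        out = spearman_prefilter(atlas, auc).set_index("transcript_id")
        assert bool(out.loc["T0", "skipped"])
        assert not bool(out.loc["T1", "skipped"])

    def test_missing_auc_uses_complete_cases(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(1, 5, size=(20, 3))
        atlas, cells = _atlas_from(X)
        y = rng.normal(size=20)
        y[:5] = np.nan
        auc = pd.DataFrame({"D": y}, index=cells)
        out = spearman_prefilter(atlas, auc)
        assert (out["n"] == 15).all()
        rho, _ = stats.spearmanr(X[5:, 0], y[5:])
        assert out["rho"].iloc[0] == pytest.approx(rho, abs=1e-12)

    def test_too_few_observations_skipped(self):
        X = np.arange(8.0).reshape(-1, 1) + 1
        atlas, cells = _atlas_from(X)
        y = np.full(8, np.nan)
        y[:2] = [1.0, 2.0]
        out = spearman_prefilter(atlas, pd.DataFrame({"D": y}, index=cells))
        assert bool(out["skipped"].all())


class TestPredictionMatrix:
    def test_columns_standardized(self):
        rng = np.random.default_rng(0)
        atlas, cells = _atlas_from(rng.uniform(1, 9, size=(25, 4)))
        X = build_prediction_matrix(atlas, atlas.transcript_ids)
        assert np.allclose(X.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(X.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_constant_column_dropped_with_warning(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        atlas, cells = _atlas_from(X)
        with pytest.warns(UserWarning, match="zero-variance"):
            M = build_prediction_matrix(atlas, atlas.transcript_ids)
        assert list(M.columns) == ["T1"]

    def test_standardization_idempotent(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(30, 2))
        z = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=0)
        atlas, cells = _atlas_from(z - z.min() + 1.0)  # keep TPM nonnegative
        M = build_prediction_matrix(atlas, atlas.transcript_ids)
        assert np.allclose(M.to_numpy(), z, atol=1e-9)


class TestTuneElasticNet:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 5))
        y = X[:, 0] + rng.normal(0, 0.5, 60)
        cfg = ElasticNetConfig(search_seed=9)
        a1, l1, t1 = tune_elastic_net(X, y, cfg)
        a2, l2, t2 = tune_elastic_net(X, y, cfg)
        assert (a1, l1) == (a2, l2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_noiseless_signal_recovered(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 4))
        y = 2.0 * X[:, 2]
        _, _, table = tune_elastic_net(X, y, ElasticNetConfig(search_seed=0))
        assert table["cv_rmse"].min() < 0.1 * y.std()

    def test_pure_noise_rmse_near_sd(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 5))
        y = rng.normal(size=100)
        _, _, table = tune_elastic_net(X, y, ElasticNetConfig(search_seed=0))
        assert table["cv_rmse"].min() == pytest.approx(y.std(), rel=0.25)

    def test_small_n_reduces_folds_with_warning(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        with pytest.warns(UserWarning, match="fold"):
            tune_elastic_net(X, y, ElasticNetConfig(search_seed=0))


class TestBootstrapScores:
    def _setup(self, seed=0, n=60, k=6):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(n, k)), columns=[f"T{j}" for j in range(k)]
        )
        y = X["T0"].to_numpy() - X["T1"].to_numpy() + rng.normal(0, 0.5, n)
        return X, y

    def test_strong_signals_score_high(self):
        X, y = self._setup()
        out = bootstrap_predictive_scores(X, y, 0.5, 0.01, B=100, seed=1)
        assert out.loc["T0", "score"] >= 0.9
        assert out.loc["T0", "direction"] == "positive"
        assert out.loc["T1", "direction"] == "negative"

    def test_negation_swaps_frequencies_exactly(self):
        X, y = self._setup()
        a = bootstrap_predictive_scores(X, y, 0.5, 0.01, B=100, seed=2)
        b = bootstrap_predictive_scores(X, -y, 0.5, 0.01, B=100, seed=2)
        assert (a["f_pos"].to_numpy() == b["f_neg"].to_numpy()).all()
        assert (a["f_neg"].to_numpy() == b["f_pos"].to_numpy()).all()
        assert (a["score"].to_numpy() == b["score"].to_numpy()).all()

    def test_seeded_determinism(self):
        X, y = self._setup()
        a = bootstrap_predictive_scores(X, y, 0.5, 0.05, B=50, seed=3)
        b = bootstrap_predictive_scores(X, y, 0.5, 0.05, B=50, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestCallAssociations:
    def _scores(self, values):
        return pd.DataFrame({
            "transcript_id": [f"t{i}" for i in range(len(values))],
            "score": values,
        })

    def test_inclusive_at_exact_threshold(self):
        out = call_associations(self._scores([0.70, 0.699, 0.8]))
        assert set(out["transcript_id"]) == {"t0", "t2"}

    def test_empty_input(self):
        assert call_associations(self._scores([])).empty

    def test_monotone_thresholding(self):
        scores = self._scores([0.1, 0.5, 0.7, 0.9])
        lower = set(call_associations(scores, 0.5)["transcript_id"])
        higher = set(call_associations(scores, 0.8)["transcript_id"])
        assert higher <= lower
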