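"""Expression atlas loading, prevalence filtering, and specificity scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txaxes import (
    DataError,
    ExpressionAtlas,
    aggregate_by_lineage,
    call_lineage_specific,
    load_expression,
    prevalence_filter,
    specificity_scores,
)
from txaxes.atlas import LineageProfile, write_expression


def _profile_from_ratios(rows, lineages=None):
    p = pd.DataFrame(rows, columns=lineages or [f"l{i}" for i in range(len(rows[0]))])
    x = p * 10.0
    return LineageProfile(x=x, p=p, undefined=pd.Series(False, index=p.index))


class TestLoading:
    def test_write_then_load_round_trip(self, small_atlas, tmp_path):
        write_expression(small_atlas, tmp_path / "m.tsv", tmp_path / "l.tsv")
        back = load_expression(tmp_path / "m.tsv", tmp_path / "l.tsv")
        pd.testing.assert_frame_equal(
            back.values, small_atlas.values, check_names=False
        )
        pd.testing.assert_series_equal(
            back.lineage_of, small_atlas.lineage_of, check_names=False
        )

    def test_negative_values_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("transcript_id\tCL1\tCL2\nt1\t1.0\t-0.5\n")
        (tmp_path / "l.tsv").write_text("cell_line\tlineage\nCL1\ta\nCL2\tb\n")
        with pytest.raises(DataError, match="negative"):
            load_expression(path, tmp_path / "l.tsv")

    def test_missing_lineage_label_rejected(self, small_atlas):
        with pytest.raises(DataError, match="lineage"):
            ExpressionAtlas(small_atlas.values, small_atlas.lineage_of.drop("CL4"))

    def test_duplicate_transcript_ids_rejected(self, small_atlas):
        values = pd.concat([small_atlas.values, small_atlas.values.iloc[[0]]])
        with pytest.raises(DataError, match="duplicate"):
            ExpressionAtlas(values, small_atlas.lineage_of)


class TestPrevalenceFilter:
    def test_inclusive_keeps_exact_threshold(self, small_atlas):
        # transcript with max TPM exactly 0.1 is retained in atlas mode
        values = small_atlas.values.copy()
        values.loc["tE"] = [0.1, 0.0, 0.0, 0.0]
        atlas = ExpressionAtlas(values, small_atlas.lineage_of)
        kept = prevalence_filter(atlas, 0.1, min_cells=1, mode="inclusive")
        assert "tE" in kept.transcript_ids

    def test_strict_drops_exact_threshold(self, small_atlas):
        # TPM exactly 0.1 everywhere fails the strict (> 0.1) drug-mode filter
        values = small_atlas.values.copy()
        values.loc["tE"] = [0.1] * 4
        atlas = ExpressionAtlas(values, small_atlas.lineage_of)
        kept = prevalence_filter(atlas, 0.1, min_fraction=0.2, mode="strict")
        assert "tE" not in kept.transcript_ids

    def test_zero_threshold_inclusive_is_identity(self, small_atlas):
        kept = prevalence_filter(small_atlas, 0.0, min_cells=1, mode="inclusive")
        pd.testing.assert_frame_equal(kept.values, small_atlas.values)

    def test_input_untouched(self, small_atlas):
        before = small_atlas.values.copy()
        prevalence_filter(small_atlas, 0.5, min_cells=2, mode="strict")
        pd.testing.assert_frame_equal(small_atlas.values, before)


class TestAggregation:
    def test_single_cell_lineages_equal_raw_columns(self, small_atlas):
        one_each = ExpressionAtlas(
            small_atlas.values[["CL1", "CL3"]],
            small_atlas.lineage_of[["CL1", "CL3"]],
        )
        prof = aggregate_by_lineage(one_each)
        assert np.allclose(
            prof.x["lung"], small_atlas.values["CL1"]
        ) and np.allclose(prof.x["skin"], small_atlas.values["CL3"])

    def test_all_zero_transcript_flagged(self, small_atlas):
        prof = aggregate_by_lineage(small_atlas)
        assert bool(prof.undefined["tC"]) and not bool(prof.undefined["tA"])

    def test_ratio_arithmetic(self):
        prof = _profile_from_ratios([[0.8, 0.1, 0.1, 0.0]])
        # built from x=(8,1,1,0): recompute p from x
        p = prof.x.div(prof.x.sum(axis=1), axis=0)
        assert np.allclose(p.iloc[0], [0.8, 0.1, 0.1, 0.0])

    def test_ratio_rows_sum_to_one(self, small_atlas):
        prof = aggregate_by_lineage(small_atlas)
        sums = prof.p.loc[~prof.undefined].sum(axis=1)
        assert np.allclose(sums, 1.0)


class TestSpecificityScores:
    def test_uniform_profile_scores_zero(self):
        prof = _profile_from_ratios([[0.25] * 4])
        assert specificity_scores(prof)["score"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_lineage_scores_log2_n(self):
        prof = _profile_from_ratios([[0.0, 0.0, 1.0, 0.0]])
        assert specificity_scores(prof)["score"].iloc[0] == pytest.approx(2.0)

    def test_worked_profile(self, specificity_oracle):
        p = [0.8, 0.1, 0.1, 0.0]
        expected = specificity_oracle(p)  # direct summation: ~1.0781
        prof = _profile_from_ratios([p])
        got = specificity_scores(prof)["score"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(1.0781, abs=1e-4)

    def test_matches_oracle_on_random_profiles(self, specificity_oracle):
        rng = np.random.default_rng(42)
        raw = rng.dirichlet(np.ones(22) * 0.3, size=1000)
        prof = _profile_from_ratios(list(raw))
        scores = specificity_scores(prof)["score"].to_numpy()
        expected = np.array([specificity_oracle(row) for row in raw])
        assert np.max(np.abs(scores - expected)) < 1e-9
        assert (scores >= 0).all() and (scores <= np.log2(22)).all()

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(2.0, size=(5, 8))
        p1 = x / x.sum(axis=1, keepdims=True)
        p2 = (x * 137.0) / (x * 137.0).sum(axis=1, keepdims=True)
        s1 = specificity_scores(_profile_from_ratios(list(p1)))
        s2 = specificity_scores(_profile_from_ratios(list(p2)))
        assert np.allclose(s1["score"], s2["score"])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(6), size=10)
        perm = rng.permutation(6)
        s1 = specificity_scores(_profile_from_ratios(list(p)))
        s2 = specificity_scores(_profile_from_ratios(list(p[:, perm])))
        assert np.allclose(s1["score"], s2["score"])
        assert np.allclose(s1["top_ratio"], s2["top_ratio"])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=30))
    def test_score_bounds_property(self, xs):
        arr = np.array(xs)
        p = arr / arr.sum()
        prof = _profile_from_ratios([list(p)])
        score = specificity_scores(prof)["score"].iloc[0]
        assert 0.0 <= score <= np.log2(len(xs)) + 1e-9

    def test_undefined_transcripts_skipped(self, small_atlas):
        prof = aggregate_by_lineage(small_atlas)
        scores = specificity_scores(prof)
        assert np.isnan(scores.loc["tC", "score"])


class TestLineageCall:
    def _scores(self, score, top, second):
        return pd.DataFrame(
            {"score": [score], "top_lineage": ["lung"], "top_ratio": [top],
             "second_ratio": [second], "undefined": [False]},
            index=["t"],
        )

    def test_worked_profile_is_called(self, specificity_oracle):
        s = specificity_oracle([0.8, 0.1, 0.1, 0.0])
        out = call_lineage_specific(self._scores(s, 0.8, 0.1))
        assert bool(out["is_specific"].iloc[0])
        assert out["called_lineage"].iloc[0] == "lung"

    def test_exact_double_ratio_not_called(self):
        out = call_lineage_specific(self._scores(1.5, 0.5, 0.25))
        assert not bool(out["is_specific"].iloc[0])

    def test_score_exactly_one_not_called(self):
        out = call_lineage_specific(self._scores(1.0, 0.9, 0.05))
        assert not bool(out["is_specific"].iloc[0])

    def test_zero_second_ratio_satisfies_ratio_rule(self):
        out = call_lineage_specific(self._scores(2.0, 0.4, 0.0))
        assert bool(out["is_specific"].iloc[0])

    def test_rule_without_ratio_clause(self):
        out = call_lineage_specific(
            self._scores(1.5, 0.5, 0.3), require_ratio=False
        )
        assert bool(out["is_specific"].iloc[0])
        strict = call_lineage_specific(self._scores(1.5, 0.5, 0.3))
        assert not bool(strict["is_specific"].iloc[0])
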