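import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tp53tme.scoring import (
    ScoringConfig,
    ScoringError,
    classify_groups,
    enrichment_score,
    rank_transform,
    tp53_score,
)
from tp53tme.signature import GeneSignature

from conftest import es_bruteforce, random_rank_instance


class TestRankTransform:
    def test_strictly_ordered_sample(self):
        expr = pd.DataFrame({"s": [5.0, 3.0, 1.0]}, index=["g1", "g2", "g3"])
        ranks = rank_transform(expr)
        assert ranks["s"].tolist() == [1.0, 2.0, 3.0]

    def test_tie_symmetry_average(self):
        expr = pd.DataFrame({"s": [2.0, 2.0]}, index=["g1", "g2"])
        assert rank_transform(expr, "average_rank")["s"].tolist() == [1.5, 1.5]

    def test_total_tie_average(self):
        expr = pd.DataFrame({"s": [1.0] * 5}, index=[f"g{i}" for i in range(5)])
        assert (rank_transform(expr)["s"] == 3.0).all()

    def test_stable_order_is_permutation(self):
        expr = pd.DataFrame({"s": [2.0, 2.0, 1.0]}, index=["g1", "g2", "g3"])
        ranks = rank_transform(expr, "stable_order")["s"]
        assert sorted(ranks) == [1.0, 2.0, 3.0]
        assert ranks["g1"] < ranks["g2"]  # ties broken by input order

    def test_nonfinite_raises_with_location(self):
        expr = pd.DataFrame({"bad_sample": [1.0, np.nan]}, index=["gA", "gB"])
        with pytest.raises(ScoringError, match="gB.*bad_sample"):
            rank_transform(expr)


class TestEnrichmentScore:
    def test_top_ranked_singleton_alpha0(self):
        assert enrichment_score({"g1": 1, "g2": 2, "g3": 3}, {"g1"}, alpha=0) == pytest.approx(1.5)

    def test_bottom_ranked_singleton_alpha0(self):
        assert enrichment_score({"g1": 1, "g2": 2, "g3": 3}, {"g3"}, alpha=0) == pytest.approx(-1.5)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_matches_bruteforce_oracle(self, alpha):
        rng = np.random.default_rng(42)
        for _ in range(200):
            ranks, gene_set = random_rank_instance(rng)
            got = enrichment_score(ranks, gene_set, alpha=alpha)
            want = es_bruteforce(ranks, gene_set, alpha=alpha)
            assert got == pytest.approx(want, abs=1e-12)

    def test_antisymmetry_alpha0(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            ranks, gene_set = random_rank_instance(rng)
            n = len(ranks)
            reversed_ranks = {g: n - r + 1 for g, r in ranks.items()}
            assert enrichment_score(ranks, gene_set, 0.0) == pytest.approx(
                -enrichment_score(reversed_ranks, gene_set, 0.0), abs=1e-10
            )

    def test_disjoint_set_raises(self):
        with pytest.raises(ScoringError, match="ZZZ"):
            enrichment_score({"g1": 1, "g2": 2}, {"ZZZ"})

    def test_full_universe_set_raises(self):
        with pytest.raises(ScoringError, match="universe"):
            enrichment_score({"g1": 1, "g2": 2}, {"g1", "g2"})


class TestTp53Score:
    def test_score_identity(self, small_expr):
        sig = GeneSignature(("g0", "g1"), ("g3", "g4"))
        table = tp53_score(small_expr, sig)
        assert (table["score"] == table["s_induce"] - table["s_repress"]).all()

    def test_symmetric_sets_score_zero(self):
        # induced and repressed genes have identical values pairwise: the two
        # directions are interchangeable by relabeling, so the score is 0
        rng = np.random.default_rng(0)
        vals = rng.lognormal(size=(3, 6))
        expr = pd.DataFrame(
            np.vstack([vals, vals]),
            index=[f"i{k}" for k in range(3)] + [f"r{k}" for k in range(3)],
            columns=[f"s{j}" for j in range(6)],
        )
        sig = GeneSignature(tuple(f"i{k}" for k in range(3)), tuple(f"r{k}" for k in range(3)))
        table = tp53_score(expr, sig)
        assert np.allclose(table["score"], 0.0, atol=1e-12)

    def test_monotone_in_induced_expression(self, small_expr):
        sig = GeneSignature(("g0",), ("g4",))
        base = tp53_score(small_expr, sig)
        boosted = small_expr.copy()
        boosted.loc["g0", "s0"] *= 100.0  # pushes g0 to the top of s0
        after = tp53_score(boosted, sig)
        assert after.loc["s0", "s_induce"] >= base.loc["s0", "s_induce"] - 1e-12
        assert after.loc["s0", "score"] >= base.loc["s0", "score"] - 1e-12

    def test_sample_permutation_invariance(self, small_expr):
        sig = GeneSignature(("g0", "g1"), ("g3", "g4"))
        table = tp53_score(small_expr, sig)
        shuffled = tp53_score(small_expr[["s2", "s0", "s3", "s1"]], sig)
        pd.testing.assert_frame_equal(table.loc[shuffled.index], shuffled)

    def test_missing_direction_raises(self, small_expr):
        sig = GeneSignature(("absent1",), ("g4",))
        with pytest.raises(ScoringError, match="induced"):
            tp53_score(small_expr, sig)

    def test_missing_genes_warned_and_scored_on_intersection(self, small_expr, caplog):
        sig = GeneSignature(("g0", "NOT_THERE"), ("g4",))
        with caplog.at_level("WARNING"):
            table = tp53_score(small_expr, sig)
        assert "NOT_THERE" in caplog.text
        assert len(table) == 4

    def test_range_normalization_preserves_ordering(self, small_expr):
        sig = GeneSignature(("g0", "g1"), ("g3", "g4"))
        raw = tp53_score(small_expr, sig, ScoringConfig(normalize="none"))
        norm = tp53_score(small_expr, sig, ScoringConfig(normalize="range"))
        assert (
            raw["s_induce"].rank().tolist() == norm["s_induce"].rank().tolist()
        )


class TestClassifyGroups:
    def test_median_split(self):
        scores = pd.DataFrame({"score": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        out = classify_groups(scores)
        assert out["group"].tolist() == ["low", "low", "high", "high"]

    def test_explicit_cut(self):
        scores = pd.DataFrame({"score": [-1.0, 1.0]}, index=["a", "b"])
        out = classify_groups(scores, cut=0.0)
        assert out["group"].tolist() == ["low", "high"]

    def test_degenerate_median_raises(self):
        scores = pd.DataFrame({"score": [0.5, 0.5, 0.5]})
        with pytest.raises(ScoringError, match="explicit cut"):
            classify_groups(scores)

    @given(
        st.lists(
            st.integers(-1000, 1000).map(float), min_size=2, max_size=30, unique=True
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_median_split_balance(self, values):
        scores = pd.DataFrame({"score": values})
        out = classify_groups(scores)
        n_high = (out["group"] == "high").sum()
        # strictly-greater-than-median rule: high gets at most half
        assert 0 < n_high <= len(values) / 2 + 1
        assert (out["group"] == "low").sum() + n_high == len(values)


def test_config_validation():
    with pytest.raises(ScoringError):
        ScoringConfig(alpha=-0.1)
    with pytest.raises(ScoringError):
        ScoringConfig(normalize="zscore")
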