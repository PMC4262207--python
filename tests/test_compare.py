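"""Standardisation, inter-metric distances, clustering, consensus, subsets."""

import numpy as np
import pandas as pd
import pytest

import phyloisolation as pi
from phyloisolation import compare

from conftest import make_trees


def tables_for(n_trees, seed, n_tips=60, death=0.25):
    return [
        compare.standardize_scores(pi.compute_all(t))
        for t in make_trees(n_trees, n_tips, death=death, seed=seed)
    ]


class TestStandardize:
    def test_t3_fair_proportion(self, t3):
        table = compare.standardize_scores(pi.compute_all(t3))
        np.testing.assert_allclose(table["ED"], [0.9, 0.9, 1.2])

    def test_constant_column_becomes_ones(self):
        tab = pd.DataFrame({"x": [2.0, 2.0, 2.0]})
        np.testing.assert_allclose(compare.standardize_scores(tab)["x"], 1.0)

    def test_idempotent(self, t3):
        once = compare.standardize_scores(pi.compute_all(t3))
        twice = compare.standardize_scores(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), rtol=1e-12)

    def test_zero_mean_refused(self):
        tab = pd.DataFrame({"x": [0.0, 0.0]})
        with pytest.raises(ValueError, match="non-positive mean"):
            compare.standardize_scores(tab)


class TestDistanceMatrix:
    def test_identical_vectors_at_zero_distance(self, t3):
        # FP and ES coincide on T3
        table = compare.standardize_scores(pi.compute_all(t3))
        d = compare.metric_distance_matrix(table, normalise=False, scale="mean")
        assert d.loc["ED", "ES"] == pytest.approx(0.0, abs=1e-12)

    def test_t3_fp_pe_mean_scale_hand_value(self, t3):
        table = compare.standardize_scores(pi.compute_all(t3))[["ED", "PE"]]
        d = compare.metric_distance_matrix(table, normalise=False, scale="mean")
        # ED std (0.9,0.9,1.2); PE std (0.75,0.75,1.5) -> sqrt(0.135)
        assert d.loc["ED", "PE"] == pytest.approx(np.sqrt(0.135), abs=1e-12)

    def test_linear_transforms_collapse_under_unit_variance_scale(self, t3):
        # PE and ED are perfectly correlated on T3: distance 0 when scaled
        table = compare.standardize_scores(pi.compute_all(t3))[["ED", "PE", "APD"]]
        d = compare.metric_distance_matrix(table, normalise=False)
        assert d.loc["ED", "PE"] == pytest.approx(0.0, abs=1e-9)

    def test_normalised_mean_offdiagonal_is_one(self):
        for tab in tables_for(3, seed=20):
            for scale in ("unit-variance", "mean"):
                d = compare.metric_distance_matrix(tab, scale=scale).to_numpy()
                k = d.shape[0]
                assert d.sum() / (k * (k - 1)) == pytest.approx(1.0, abs=1e-9)
                assert np.allclose(d, d.T)
                assert np.diagonal(d).max() == 0.0

    def test_vw_mvw_distance_is_exactly_zero(self):
        for tab in tables_for(2, seed=21):
            d = compare.metric_distance_matrix(tab)
            assert d.loc["VW", "MVW"] == pytest.approx(0.0, abs=1e-9)


class TestClustering:
    def test_zero_distance_pair_merges_first(self):
        tab = tables_for(1, seed=22)[0]
        dg = compare.hierarchical_cluster(compare.metric_distance_matrix(tab))
        assert frozenset({"VW", "MVW"}) in dg.clades()
        assert dg.heights()[0] == pytest.approx(0.0, abs=1e-9)

    def test_average_linkage_arithmetic(self):
        d = pd.DataFrame(
            [[0, 1, 10], [1, 0, 10], [10, 10, 0]],
            index=list("abc"),
            columns=list("abc"),
            dtype=float,
        )
        dg = compare.hierarchical_cluster(d)
        assert frozenset({"a", "b"}) in dg.clades()
        np.testing.assert_allclose(dg.heights(), [1.0, 10.0])

    def test_label_permutation_invariance(self):
        tab = tables_for(1, seed=23)[0]
        d = compare.metric_distance_matrix(tab)
        perm = list(d.columns[::-1])
        dg1 = compare.hierarchical_cluster(d)
        dg2 = compare.hierarchical_cluster(d.loc[perm, perm])
        assert dg1.clades() == dg2.clades()
        np.testing.assert_allclose(sorted(dg1.heights()), sorted(dg2.heights()))

    def test_heights_monotone(self):
        for tab in tables_for(3, seed=24):
            dg = compare.hierarchical_cluster(compare.metric_distance_matrix(tab))
            h = dg.heights()
            assert (np.diff(h) >= -1e-12).all()


class TestConsensus:
    def test_identical_inputs_full_support(self):
        dgs = [
            compare.hierarchical_cluster(compare.metric_distance_matrix(tab))
            for tab in [tables_for(1, seed=25)[0]] * 3
        ]
        cons = compare.majority_consensus(dgs)
        assert cons.supports
        assert all(s == pytest.approx(1.0) for s in cons.supports.values())
        assert cons.contains(dgs[0].clades().pop())

    def test_two_thirds_support(self):
        def dg(dmat):
            return compare.hierarchical_cluster(
                pd.DataFrame(dmat, index=list("abcd"), columns=list("abcd"), dtype=float)
            )

        near_ab = [[0, 1, 9, 9], [1, 0, 9, 9], [9, 9, 0, 2], [9, 9, 2, 0]]
        near_ac = [[0, 9, 1, 9], [9, 0, 9, 2], [1, 9, 0, 9], [9, 2, 9, 0]]
        cons = compare.majority_consensus([dg(near_ab), dg(near_ab), dg(near_ac)])
        assert cons.support({"a", "b"}) == pytest.approx(2 / 3)
        assert not cons.contains({"a", "c"})

    def test_conflicting_pair_gives_star(self):
        def dg(dmat):
            return compare.hierarchical_cluster(
                pd.DataFrame(dmat, index=list("abc"), columns=list("abc"), dtype=float)
            )

        ab = [[0, 1, 9], [1, 0, 9], [9, 9, 0]]
        bc = [[0, 9, 9], [9, 0, 1], [9, 1, 0]]
        cons = compare.majority_consensus([dg(ab), dg(bc)])
        assert cons.supports == {}
        assert cons.to_newick() == "(a,b,c);"

    def test_mismatched_leaf_sets_rejected(self):
        a = tables_for(1, seed=26)[0]
        dg1 = compare.hierarchical_cluster(compare.metric_distance_matrix(a))
        dg2 = compare.hierarchical_cluster(
            compare.metric_distance_matrix(a[["PE", "ED", "SV"]])
        )
        with pytest.raises(ValueError):
            compare.majority_consensus([dg1, dg2])

    def test_supports_match_independent_recount(self):
        tabs = tables_for(12, seed=27)
        dgs = [
            compare.hierarchical_cluster(compare.metric_distance_matrix(tab))
            for tab in tabs
        ]
        cons = compare.majority_consensus(dgs)
        for clade, support in cons.supports.items():
            count = sum(clade in dg.clades() for dg in dgs)
            assert support == pytest.approx(count / len(dgs))
            assert support > 0.5

    def test_newick_contains_supports(self):
        tabs = tables_for(5, seed=28)
        dgs = [
            compare.hierarchical_cluster(compare.metric_distance_matrix(tab))
            for tab in tabs
        ]
        text = compare.majority_consensus(dgs).to_newick()
        assert text.endswith(";")
        assert "MVW" in text and "(" in text


class TestVariationCaptured:
    def test_full_set_captures_everything(self):
        tabs = tables_for(2, seed=29)
        for method in ("variance-share", "regression"):
            assert compare.variation_captured(
                tabs, pi.CANONICAL_METRICS, method=method
            ) == pytest.approx(1.0, abs=1e-9)

    def test_regression_captures_linear_transforms(self):
        # MVW = VW/2 exactly, so VW alone explains MVW completely
        tab = tables_for(1, seed=30)[0][["VW", "MVW"]]
        assert compare.variation_captured(tab, ["VW"], method="regression") == pytest.approx(
            1.0, abs=1e-9
        )

    def test_monotone_in_subset_inclusion(self):
        tabs = tables_for(3, seed=31)
        rng = np.random.default_rng(0)
        for method in ("variance-share", "regression"):
            subset = ["QE"]
            prev = compare.variation_captured(tabs, subset, method=method)
            pool = [m for m in pi.CANONICAL_METRICS if m not in subset]
            for m in rng.permutation(pool):
                subset.append(m)
                cur = compare.variation_captured(tabs, subset, method=method)
                assert cur >= prev - 1e-9
                prev = cur

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            compare.variation_captured(tables_for(1, seed=32), [])


class TestSubsetSelection:
    def test_k_equal_eleven_returns_all(self):
        tabs = tables_for(1, seed=33)
        got = compare.select_dissimilar_subset(tabs, 11, mode="greedy")
        assert set(got) == set(pi.CANONICAL_METRICS)

    def test_k1_greedy_is_best_single(self):
        tabs = tables_for(2, seed=34)
        best = compare.select_dissimilar_subset(tabs, 1, mode="greedy")
        scores = {
            m: compare.variation_captured(tabs, [m]) for m in pi.CANONICAL_METRICS
        }
        assert scores[best[0]] == max(scores.values())

    def test_greedy_never_selects_a_duplicate_metric(self):
        # VW and MVW are at distance zero; regression gains nothing from both
        tabs = tables_for(2, seed=35)
        got = compare.select_dissimilar_subset(tabs, 2, mode="greedy", method="regression")
        assert not {"VW", "MVW"} <= set(got)

    def test_one_per_group_draw(self):
        tabs = tables_for(4, seed=36)
        dists = [compare.metric_distance_matrix(t) for t in tabs]
        mean_d = sum(dists) / len(dists)
        groups = compare.major_groups(mean_d, 3)
        assert len(groups) == 3
        assert frozenset().union(*groups) == frozenset(pi.CANONICAL_METRICS)
        got = compare.select_dissimilar_subset(
            tabs, 3, mode="one-per-group", groups=groups, rng=1
        )
        assert len(got) == 3
        for g in groups:
            assert len(set(got) & g) == 1
        again = compare.select_dissimilar_subset(
            tabs, 3, mode="one-per-group", groups=groups, rng=1
        )
        assert got == again  # seeded

    def test_group_count_mismatch(self):
        tabs = tables_for(1, seed=37)
        with pytest.raises(ValueError):
            compare.select_dissimilar_subset(
                tabs, 2, mode="one-per-group", groups=[frozenset({"PE"})] * 3
            )


class TestCladeScaling:
    def test_profile_consistency_and_pe_constancy(self):
        tree = make_trees(1, 80, seed=38)[0]
        tip = tree.tip_labels[10]
        raw = compare.clade_scaling_profile(tree, tip, scale_by_max=False)
        full = pi.compute_all(tree, include_apdpd=True).loc[tip]
        np.testing.assert_allclose(raw.iloc[-1].to_numpy(), full.to_numpy(), rtol=1e-9)
        assert raw["PE"].nunique() == 1  # pendant edge never changes
        scaled = compare.clade_scaling_profile(tree, tip, scale_by_max=True)
        assert (scaled.max(axis=0) <= 1.0 + 1e-12).all()

    def test_apd_over_pd_flattens_where_apd_does_not(self):
        tree = make_trees(1, 300, seed=39)[0]
        tip = tree.tip_labels[0]
        prof = compare.clade_scaling_profile(tree, tip)
        sizes = prof.index.to_numpy()
        half = sizes.max() / 2
        sub = prof[prof.index >= half]
        d_apd = abs(sub["APD"].iloc[-1] - sub["APD"].iloc[0])
        d_apdpd = abs(sub["APDPD"].iloc[-1] - sub["APDPD"].iloc[0])
        assert d_apdpd <= d_apd + 1e-12

    def test_asymptote_slope_examples(self):
        prof = pd.DataFrame(
            {"flat": [1.0, 1.0], "line": [1.0, 2.0]},
            index=pd.Index([300, 600], name="clade_size"),
        )
        slopes = compare.asymptote_slope(prof, (200, 700))
        assert slopes["flat"] == pytest.approx(0.0, abs=1e-12)
        assert slopes["line"] == pytest.approx(1 / 300)
        with pytest.raises(ValueError):
            compare.asymptote_slope(prof, (400, 500))
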