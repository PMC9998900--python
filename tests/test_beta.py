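import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import multidiv as md
from multidiv.core import ValidationError


class TestAbcCounts:
    @pytest.mark.parametrize(
        "si, sj, expected",
        [
            ([1, 1, 1, 0], [0, 1, 1, 1], (2, 1, 1)),
            ([1, 1, 0, 0], [1, 1, 0, 0], (2, 0, 0)),
            ([1, 1, 0, 0], [0, 0, 1, 1], (0, 2, 2)),
        ],
    )
    def test_set_algebra(self, si, sj, expected):
        assert md.abc_counts(np.array(si), np.array(sj)) == expected


class TestPairwisePartition:
    @pytest.mark.parametrize(
        "abc, expected",
        [
            ((2, 1, 1), (1 / 3, 1 / 3, 0.0)),
            ((2, 2, 0), (1 / 3, 0.0, 1 / 3)),
            ((0, 3, 2), (1.0, 1.0, 0.0)),
        ],
    )
    def test_formulas(self, abc, expected):
        sor, sim, sne = md.pairwise_partition(*abc)
        assert sor == pytest.approx(expected[0])
        assert sim == pytest.approx(expected[1])
        assert sne == pytest.approx(expected[2], abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)
    )
    def test_additivity_and_bounds(self, a, b, c):
        if a + b + c == 0:
            return
        sor, sim, sne = md.pairwise_partition(a, b, c)
        assert sor == pytest.approx(sim + sne, abs=1e-12)
        assert 0 <= sim <= sor <= 1
        assert sne >= -1e-12


class TestSharedBranch:
    def test_hand_edge_accounting(self, toy_tree):
        tips = toy_tree.tip_labels
        pi = np.array([t in ("A", "B") for t in tips])
        pj = np.array([t in ("A", "C") for t in tips])
        a, b, c = md.shared_branch_abc(toy_tree, pi, pj)
        assert (a, b, c) == pytest.approx((2.0, 1.0, 1.5))

    def test_identical_tip_sets(self, toy_tree):
        pi = np.array([t in ("A", "D") for t in toy_tree.tip_labels])
        a, b, c = md.shared_branch_abc(toy_tree, pi, pi)
        assert b == 0 and c == 0
        assert a == pytest.approx(md.faith_pd(pi, toy_tree))

    def test_pd_consistency(self, toy_tree):
        tips = toy_tree.tip_labels
        pi = np.array([t in ("A", "B", "C") for t in tips])
        pj = np.array([t in ("B", "D") for t in tips])
        a, b, c = md.shared_branch_abc(toy_tree, pi, pj)
        assert a + b == pytest.approx(md.faith_pd(pi, toy_tree))
        assert a + c == pytest.approx(md.faith_pd(pj, toy_tree))

    def test_star_tree_equals_species_counts(self):
        star = md.read_tree("(A:1,B:1,C:1,D:1,E:1);")
        pi = np.array([1, 1, 1, 0, 0], bool)
        pj = np.array([0, 1, 1, 1, 1], bool)
        assert md.shared_branch_abc(star, pi, pj) == pytest.approx((2.0, 1.0, 2.0))


class TestFunctionalHull:
    def _scores(self):
        # unit square and unit square shifted by 0.5 in x
        sq1 = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        sq2 = sq1 + np.array([0.5, 0.0])
        return np.vstack([sq1, sq2])

    def test_shifted_unit_squares(self):
        scores = self._scores()
        pi = np.array([1] * 4 + [0] * 4, bool)
        pj = np.array([0] * 4 + [1] * 4, bool)
        a, b, c = md.functional_abc(scores, pi, pj, k=2)
        assert a == pytest.approx(0.5, abs=1e-9)
        assert b == pytest.approx(0.5, abs=1e-9)
        assert c == pytest.approx(0.5, abs=1e-9)

    def test_matches_shapely_polygon_oracle(self):
        from shapely.geometry import MultiPoint

        rng = np.random.default_rng(8)
        pts = rng.uniform(size=(14, 2))
        pi = np.zeros(14, bool)
        pi[:7] = True
        pj = ~pi
        a, b, c = md.functional_abc(pts, pi, pj, k=2)
        h1 = MultiPoint(pts[pi]).convex_hull
        h2 = MultiPoint(pts[pj]).convex_hull
        inter = h1.intersection(h2).area
        assert a == pytest.approx(inter, abs=1e-9)
        assert b == pytest.approx(h1.area - inter, abs=1e-9)
        assert c == pytest.approx(h2.area - inter, abs=1e-9)

    def test_nested_hulls_pure_nestedness(self):
        big = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], dtype=float)
        small = np.array([[0.5, 0.5], [1, 0.5], [1, 1], [0.5, 1]])
        scores = np.vstack([big, small])
        pi = np.array([1] * 4 + [0] * 4, bool)
        pj = ~pi
        a, b, c = md.functional_abc(scores, pi, pj, k=2)
        sor, sim, sne = md.pairwise_partition(a, b, c)
        assert min(b, c) == pytest.approx(0.0, abs=1e-9)
        assert sim == pytest.approx(0.0, abs=1e-9)
        assert sne > 0

    def test_too_few_species_errors(self):
        scores = np.array([[0, 0], [1, 0], [0, 1], [2, 2]], dtype=float)
        pi = np.array([1, 1, 0, 0], bool)
        pj = np.array([0, 0, 1, 1], bool)
        with pytest.raises(ValidationError, match="dendrogram"):
            md.functional_abc(scores, pi, pj, k=2)


def _brute_multisite(occ):
    """Direct evaluation of the multiple-site Sorensen-family formulas from
    the enumerated pairwise b_ij tables (species counts)."""
    n = occ.shape[0]
    s_i = occ.sum(axis=1)
    s_t = occ.any(axis=0).sum()
    sum_min = sum_max = 0.0
    for i, j in itertools.combinations(range(n), 2):
        b_ij = np.sum(occ[i] & ~occ[j])
        b_ji = np.sum(occ[j] & ~occ[i])
        sum_min += min(b_ij, b_ji)
        sum_max += max(b_ij, b_ji)
    K = s_i.sum() - s_t
    SOR = (sum_min + sum_max) / (2 * K + sum_min + sum_max)
    SIM = sum_min / (K + sum_min)
    return SOR, SIM, SOR - SIM


class TestMultisite:
    def test_identical_sites_zero(self):
        occ = np.tile([1, 1, 0, 1], (3, 1)).astype(float)
        cm = md.CommunityMatrix(["a", "b", "c"], list("wxyz"), occ)
        p = md.taxonomic_beta(cm)
        assert p.multisite["SOR"] == 0.0
        assert p.multisite["SIM"] == 0.0

    def test_disjoint_sites_pure_turnover(self):
        occ = np.zeros((3, 6))
        occ[0, [0, 1]] = 1
        occ[1, [2, 3]] = 1
        occ[2, [4, 5]] = 1
        cm = md.CommunityMatrix(
            ["a", "b", "c"], [f"s{i}" for i in range(6)], occ
        )
        p = md.taxonomic_beta(cm)
        assert p.multisite["SIM"] == pytest.approx(p.multisite["SOR"])
        assert p.multisite["nestedness_pct"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_formulas(self):
        rng = np.random.default_rng(5)
        occ = (rng.uniform(size=(5, 12)) < 0.4)
        occ[occ.sum(axis=1) == 0, 0] = True
        cm = md.CommunityMatrix(
            [f"t{i}" for i in range(5)],
            [f"s{i}" for i in range(12)],
            occ.astype(float),
        )
        p = md.taxonomic_beta(cm)
        SOR, SIM, SNE = _brute_multisite(occ)
        assert p.multisite["SOR"] == pytest.approx(SOR, abs=1e-12)
        assert p.multisite["SIM"] == pytest.approx(SIM, abs=1e-12)
        assert p.multisite["SNE"] == pytest.approx(SNE, abs=1e-12)

    def test_invariant_to_site_order(self):
        rng = np.random.default_rng(6)
        occ = (rng.uniform(size=(6, 10)) < 0.5)
        occ[occ.sum(axis=1) == 0, 0] = True
        sites = [f"t{i}" for i in range(6)]
        sp = [f"s{i}" for i in range(10)]
        p1 = md.taxonomic_beta(md.CommunityMatrix(sites, sp, occ.astype(float)))
        perm = rng.permutation(6)
        p2 = md.taxonomic_beta(
            md.CommunityMatrix(
                [sites[i] for i in perm], sp, occ[perm].astype(float)
            )
        )
        for key in ("SOR", "SIM", "SNE"):
            assert p1.multisite[key] == pytest.approx(p2.multisite[key], abs=1e-12)


class TestDimensionEquivalences:
    def test_star_tree_phylo_equals_taxonomic(self):
        star = md.read_tree("(A:1,B:1,C:1,D:1,E:1);")
        rng = np.random.default_rng(3)
        occ = (rng.uniform(size=(4, 5)) < 0.6)
        occ[occ.sum(axis=1) == 0, 0] = True
        cm = md.CommunityMatrix(
            [f"t{i}" for i in range(4)], list("ABCDE"), occ.astype(float)
        )
        tax = md.taxonomic_beta(cm)
        phy = md.phylogenetic_beta(cm, star)
        np.testing.assert_allclose(tax.sor.values, phy.sor.values, atol=1e-12)
        np.testing.assert_allclose(tax.sim.values, phy.sim.values, atol=1e-12)
        for key in ("SOR", "SIM", "SNE"):
            assert tax.multisite[key] == pytest.approx(
                phy.multisite[key], abs=1e-12
            )

    def test_degenerate_functional_space_equals_taxonomic(self, toy_community):
        import pandas as pd

        # all species functionally identical -> all Gower distances zero
        traits = md.TraitTable(
            pd.DataFrame({"t": ["x"] * 4}, index=["A", "B", "C", "D"]),
            {"t": "categorical"},
        )
        dist = md.gower_distance(traits)
        assert np.all(dist.values == 0)
        tax = md.taxonomic_beta(toy_community)
        # with all Gower distances equal, every tip of the dendrogram
        # carries the same branch length, so the branch algebra reduces to
        # tip counts and the taxonomic partition is recovered
        eq = md.DistanceMatrix(
            ["A", "B", "C", "D"], 0.8 * (np.ones((4, 4)) - np.eye(4))
        )
        fun2 = md.functional_beta(toy_community, functional_dist=eq,
                                  include_root=False)
        tax_vals = tax.sor.values
        np.testing.assert_allclose(fun2.sor.values, tax_vals, atol=1e-9)

    def test_nested_gradient_pure_nestedness(self, toy_tree):
        # strict subset chain: sim = 0 everywhere, SNE = SOR
        occ = np.array(
            [[1, 1, 1, 1], [1, 1, 1, 0], [1, 1, 0, 0]], dtype=float
        )
        cm = md.CommunityMatrix(["a", "b", "c"], ["A", "B", "C", "D"], occ)
        p = md.taxonomic_beta(cm)
        assert np.all(p.sim.values == 0)
        assert p.multisite["SIM"] == 0
        assert p.multisite["SNE"] == pytest.approx(p.multisite["SOR"])


class TestBetaAll:
    def test_additivity_everywhere(self, neutral_bundle):
        parts = md.beta_all(neutral_bundle)
        for part in parts.values():
            np.testing.assert_allclose(
                part.sor.values, part.sim.values + part.sne.values, atol=1e-12
            )
            m = part.multisite
            assert m["SOR"] == pytest.approx(m["SIM"] + m["SNE"], abs=1e-12)
            assert m["turnover_pct"] + m["nestedness_pct"] == pytest.approx(100.0)

    def test_empty_site_rejected(self, toy_traits, toy_tree):
        cm = md.CommunityMatrix(
            ["a", "b"], ["A", "B", "C", "D"],
            np.array([[1, 1, 0, 0], [1, 0, 1, 0]], dtype=float),
        )
        cm.values[0] = 0  # sneak an empty site past the constructor
        with pytest.raises(ValidationError, match="empty site"):
            md.taxonomic_beta(cm)
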