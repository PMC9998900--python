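import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import multidiv as md
from multidiv.core import ValidationError


def _dm(values, labels=None):
    n = values.shape[0]
    labels = labels or [f"s{i}" for i in range(n)]
    return md.DistanceMatrix(labels, values)


class TestMantel:
    def test_affine_copy_r_one(self, random_distance):
        dx = random_distance(8, seed=1)
        dy = _dm(2.0 * dx.values)
        res = md.mantel(dx, dy, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_hand_matrix_pearson(self):
        x = np.array([[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6], [3, 5, 6, 0]],
                     dtype=float)
        y = np.array([[0, 2, 1, 5], [2, 0, 3, 4], [1, 3, 0, 2], [5, 4, 2, 0]],
                     dtype=float)
        res = md.mantel(_dm(x), _dm(y), n_perm=99, seed=0)
        expected = np.corrcoef([1, 2, 3, 4, 5, 6], [2, 1, 5, 3, 4, 2])[0, 1]
        assert res.r == pytest.approx(expected)

    def test_matches_reference_implementation(self, random_distance):
        import skbio

        dx = random_distance(10, seed=2)
        dy = random_distance(10, seed=3)
        r_ref, _, _ = skbio.stats.distance.mantel(
            dx.values, dy.values, permutations=0
        )
        res = md.mantel(dx, dy, n_perm=99, seed=0)
        assert res.r == pytest.approx(r_ref, abs=1e-12)

    def test_label_mismatch_rejected(self, random_distance):
        dx = random_distance(5, seed=1)
        dy = md.DistanceMatrix([f"x{i}" for i in range(5)], dx.values)
        with pytest.raises(ValidationError):
            md.mantel(dx, dy, n_perm=99)

    def test_affine_invariance_of_r(self, random_distance):
        dx = random_distance(7, seed=4)
        dy = random_distance(7, seed=5)
        r1 = md.mantel(dx, dy, n_perm=99, seed=0).r
        r2 = md.mantel(_dm(0.3 * dx.values), _dm(5 * dy.values + 0.0),
                       n_perm=99, seed=0).r
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestPartialMantel:
    def test_dy_equals_dz_partial_vanishes(self, random_distance):
        dx = random_distance(9, seed=6)
        dy = random_distance(9, seed=7)
        res = md.partial_mantel(dx, dy, dy, n_perm=99, seed=0)
        assert res.r == pytest.approx(0.0, abs=1e-10)

    def test_first_order_partial_formula(self, random_distance):
        dx = random_distance(10, seed=8)
        dy = random_distance(10, seed=9)
        dz = random_distance(10, seed=10)
        iu = np.triu_indices(10, 1)
        x, y, z = dx.values[iu], dy.values[iu], dz.values[iu]
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        res = md.partial_mantel(dx, dy, dz, n_perm=99, seed=0)
        assert res.r == pytest.approx(expected, abs=1e-10)

    def test_constant_dz_equals_plain_mantel(self, random_distance):
        dx = random_distance(8, seed=11)
        dy = random_distance(8, seed=12)
        dz = _dm(np.ones((8, 8)) - np.eye(8))
        plain = md.mantel(dx, dy, n_perm=99, seed=1)
        part = md.partial_mantel(dx, dy, dz, n_perm=99, seed=1)
        assert part.r == pytest.approx(plain.r, abs=1e-10)

    def test_uncorrelated_dz_barely_changes_r(self):
        rng = np.random.default_rng(13)
        n = 40
        base = rng.normal(size=(n, 2))
        dx = _dm(squareform(pdist(base)))
        dy = _dm(squareform(pdist(base + rng.normal(0, 0.4, size=(n, 2)))))
        dz = _dm(squareform(pdist(rng.normal(size=(n, 2)))))
        plain = md.mantel(dx, dy, n_perm=99, seed=0).r
        part = md.partial_mantel(dx, dy, dz, n_perm=99, seed=0).r
        assert part == pytest.approx(plain, abs=0.1)


class TestAdjustedR2:
    def test_ezekiel_formula(self):
        # build data with known raw R2 then compare against the formula
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(10, 2))
        X = rng.normal(size=(10, 2))
        from multidiv.inference import _r2

        r2 = _r2(Y, X)
        assert md.rda_adj_r2(Y, X) == pytest.approx(
            1 - (1 - r2) * 9 / 7, abs=1e-12
        )

    def test_exact_linear_response(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 2))
        Y = X @ rng.normal(size=(2, 3)) + 5.0
        assert md.rda_adj_r2(Y, X) == pytest.approx(1.0, abs=1e-10)

    def test_pure_noise_mean_near_zero(self):
        rng = np.random.default_rng(2)
        adj, raw = [], []
        from multidiv.inference import _r2

        for _ in range(300):
            Y = rng.normal(size=(20, 2))
            X = rng.normal(size=(20, 3))
            adj.append(md.rda_adj_r2(Y, X))
            raw.append(_r2(Y, X))
        assert np.mean(adj) == pytest.approx(0.0, abs=0.02)
        assert np.mean(raw) == pytest.approx(3 / 19, abs=0.02)

    def test_saturated_model_errors(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValidationError, match="saturated"):
            md.rda_adj_r2(rng.normal(size=(5, 1)), rng.normal(size=(5, 4)))


class TestForwardSelect:
    def test_recovers_causal_predictor(self):
        rng = np.random.default_rng(4)
        n = 40
        causal = rng.normal(size=n)
        Y = np.column_stack([2 * causal + rng.normal(0, 0.3, n),
                             -causal + rng.normal(0, 0.3, n)])
        cands = pd.DataFrame(
            {"causal": causal, "n1": rng.normal(size=n), "n2": rng.normal(size=n)}
        )
        sel = md.forward_select(Y, cands, n_perm=199, seed=0)
        assert sel[0] == "causal"

    def test_all_noise_rarely_selects(self):
        rng = np.random.default_rng(5)
        n_selected = 0
        for i in range(30):
            Y = rng.normal(size=(25, 2))
            cands = pd.DataFrame(rng.normal(size=(25, 4)),
                                 columns=list("abcd"))
            sel = md.forward_select(Y, cands, n_perm=99, seed=i)
            n_selected += len(sel) > 0
        assert n_selected <= 8  # ~alpha-level false selection

    def test_duplicate_column_never_added(self):
        rng = np.random.default_rng(6)
        n = 30
        causal = rng.normal(size=n)
        Y = np.column_stack([causal, causal]) + rng.normal(0, 0.2, (n, 2))
        cands = pd.DataFrame({"a": causal, "a_copy": causal})
        sel = md.forward_select(Y, cands, n_perm=199, seed=0)
        assert len(sel) <= 1


class TestVariancePartition:
    def _sets(self, n, rng, k=4):
        labels = [f"s{i}" for i in range(n)]
        names = ["IGs", "climate", "soil", "spatial"][:k]
        return {
            name: pd.DataFrame(
                rng.normal(size=(n, 2)), index=labels,
                columns=[f"{name}{j}" for j in range(2)]
            )
            for name in names
        }, labels

    def test_fractions_sum_to_global(self, random_distance):
        rng = np.random.default_rng(7)
        sets, labels = self._sets(25, rng)
        beta = random_distance(25, seed=20)
        beta = md.DistanceMatrix(labels, beta.values)
        vp = md.variance_partition(beta, sets)
        assert sum(vp.fractions.values()) == pytest.approx(
            vp.total_adj_r2, abs=1e-10
        )
        assert vp.residual == pytest.approx(1 - vp.total_adj_r2, abs=1e-12)

    def test_inclusion_exclusion_reconstructs_unions(self, random_distance):
        rng = np.random.default_rng(8)
        sets, labels = self._sets(30, rng, k=3)
        beta = md.DistanceMatrix(labels, random_distance(30, seed=21).values)
        vp = md.variance_partition(beta, sets)
        for union, adj in vp.union_adj_r2.items():
            total = sum(
                frac for sub, frac in vp.fractions.items() if sub & union
            )
            assert total == pytest.approx(adj, abs=1e-10)

    def test_signal_attributed_to_causal_set(self):
        rng = np.random.default_rng(9)
        n = 40
        labels = [f"s{i}" for i in range(n)]
        driver = rng.normal(size=(n, 2))
        coords = driver @ rng.normal(size=(2, 2))
        d = squareform(pdist(coords))
        beta = md.DistanceMatrix(labels, d / d.max())
        sets = {
            "A": pd.DataFrame(driver, index=labels, columns=["a1", "a2"]),
            "B": pd.DataFrame(rng.normal(size=(n, 2)), index=labels,
                              columns=["b1", "b2"]),
            "C": pd.DataFrame(rng.normal(size=(n, 2)), index=labels,
                              columns=["c1", "c2"]),
        }
        vp = md.variance_partition(beta, sets)
        assert vp.unique["A"] > 0.3
        assert abs(vp.unique["B"]) < 0.1
        assert abs(vp.unique["C"]) < 0.1

    def test_redundant_sets_share_signal(self):
        rng = np.random.default_rng(10)
        n = 35
        labels = [f"s{i}" for i in range(n)]
        driver = rng.normal(size=(n, 2))
        d = squareform(pdist(driver))
        beta = md.DistanceMatrix(labels, d / d.max())
        twin = pd.DataFrame(driver, index=labels, columns=["x1", "x2"])
        sets = {"A": twin, "B": twin.rename(columns={"x1": "y1", "x2": "y2"})}
        vp = md.variance_partition(beta, sets)
        joint = vp.fractions[frozenset(["A", "B"])]
        assert joint > 0.3
        assert abs(vp.unique["A"]) < 0.02
        assert abs(vp.unique["B"]) < 0.02

    def test_empty_set_degrades_with_warning(self, random_distance):
        rng = np.random.default_rng(11)
        sets, labels = self._sets(20, rng, k=2)
        sets["empty"] = pd.DataFrame(index=labels)
        beta = md.DistanceMatrix(labels, random_distance(20, seed=22).values)
        vp = md.variance_partition(beta, sets)
        assert "empty" not in vp.set_labels
        assert set(vp.set_labels) == {"IGs", "climate"}
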