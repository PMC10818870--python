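import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from micronet.io import AbundanceTable
from micronet.stats import (bh_adjust, bray_curtis, permanova,
                            spearman_screen, wilcoxon_fdr)


def rank_sum_enumeration_p(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of group
    assignments of the pooled sample (no ties)."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)

    def u_stat(ix):
        xs = pooled[list(ix)]
        ys = np.delete(pooled, list(ix))
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    u_obs = u_stat(range(nx))
    us = [u_stat(c) for c in itertools.combinations(range(n), nx)]
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def _frame(self, x, y):
        cols = [f"a{i}" for i in range(len(x))] + [f"b{i}" for i in range(len(y))]
        groups = pd.Series(["A"] * len(x) + ["B"] * len(y), index=cols)
        return pd.DataFrame([list(x) + list(y)], index=["f"], columns=cols), groups

    def test_small_sample_exact_p(self):
        df, groups = self._frame([1, 2], [3, 4])
        res = wilcoxon_fdr(df, groups)
        assert res.loc["f", "p"] == pytest.approx(1 / 3)

    def test_constant_feature_p_one(self):
        df, groups = self._frame([5, 5, 5], [5, 5, 5])
        assert wilcoxon_fdr(df, groups).loc["f", "p"] == 1.0

    def test_single_feature_adjustment_is_identity(self):
        df, groups = self._frame([1, 2, 5], [3, 4, 9])
        res = wilcoxon_fdr(df, groups)
        assert res.loc["f", "padj"] == res.loc["f", "p"]

    @pytest.mark.parametrize("nx,ny", [(2, 2), (3, 3), (4, 4), (3, 5), (5, 5)])
    def test_exact_branch_matches_enumeration(self, nx, ny):
        rng = np.random.default_rng(nx * 10 + ny)
        for _ in range(3):
            pooled = rng.choice(1000, size=nx + ny, replace=False).astype(float)
            x, y = pooled[:nx], pooled[nx:]
            df, groups = self._frame(x, y)
            res = wilcoxon_fdr(df, groups)
            assert res.loc["f", "p"] == pytest.approx(
                rank_sum_enumeration_p(x, y), abs=1e-12)

    def test_requires_two_groups(self):
        df, groups = self._frame([1, 2], [3, 4])
        with pytest.raises(ValueError):
            wilcoxon_fdr(df, pd.Series("A", index=groups.index))


class TestBHAdjust:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.04, 0.03]),
                                   [0.03, 0.04, 0.04])

    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_clamped_at_one(self):
        assert bh_adjust([0.5, 0.8, 0.99]).max() <= 1.0

    def test_preserves_pvalue_ordering(self):
        raw = np.array([0.001, 0.2, 0.04, 0.9, 0.04])
        adj = bh_adjust(raw)
        assert np.array_equal(np.argsort(adj, kind="stable"),
                              np.argsort(raw, kind="stable"))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_adjusted_at_least_raw(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)


class TestSpearmanScreen:
    def _screen(self, rows, phen, **kw):
        cols = [f"s{i}" for i in range(len(phen))]
        df = pd.DataFrame(rows, index=[f"f{i}" for i in range(len(rows))],
                          columns=cols)
        return spearman_screen(df, pd.Series(phen, index=cols), **kw)

    def test_monotone_pairs(self):
        res = self._screen([[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]],
                           [10, 20, 30, 40, 50])
        assert res.loc["f0", "rho"] == pytest.approx(1.0)
        assert res.loc["f1", "rho"] == pytest.approx(-1.0)

    def test_d_squared_worked_example(self):
        res = self._screen([[1, 2, 3, 4, 5]], [1, 3, 2, 5, 4])
        assert res.loc["f0", "rho"] == pytest.approx(0.8)

    def test_constant_feature_excluded(self):
        res = self._screen([[2, 2, 2, 2, 2], [1, 2, 3, 4, 5]],
                           [1, 2, 3, 4, 5])
        assert "f0" not in res.index

    def test_prevalence_gate(self):
        res = self._screen([[1, 0, 0, 0, 0, 0], [1, 2, 3, 4, 5, 6]],
                           [1, 2, 3, 4, 5, 6], min_prevalence=0.5)
        assert list(res.index) == ["f1"]

    def test_missing_phenotype_dropped_pairwise(self):
        res = self._screen([[1, 2, 3, 4, 99]],
                           [1, 2, 3, 4, np.nan])
        assert res.loc["f0", "rho"] == pytest.approx(1.0)


class TestBrayCurtis:
    def _table(self, cols):
        arr = np.asarray(cols, dtype=float).T
        return AbundanceTable(pd.DataFrame(
            arr, index=[f"t{i}" for i in range(arr.shape[0])],
            columns=[f"s{j}" for j in range(arr.shape[1])]))

    def test_identical_samples_distance_zero(self):
        dm = bray_curtis(self._table([[1, 2, 3], [1, 2, 3]]))
        assert dm[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_distance_one(self):
        dm = bray_curtis(self._table([[1, 0], [0, 3]]))
        assert dm[0, 1] == pytest.approx(1.0)

    def test_worked_example(self):
        dm = bray_curtis(self._table([[1, 1], [1, 3]]))
        assert dm[0, 1] == pytest.approx(1 / 3)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(self._table([[1, 1], [0, 0]]))

    @given(st.integers(0, 10_000))
    def test_bounds_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        dm = bray_curtis(self._table(rng.uniform(0.01, 5, size=(4, 6))))
        assert (dm.data >= 0).all() and (dm.data <= 1).all()
        np.testing.assert_allclose(dm.data, dm.data.T)
        assert np.diagonal(dm.data).max() == 0.0


def brute_force_permanova_p(dm, labels):
    """Enumerate every two-group assignment; p = fraction with F >= F_obs,
    recomputing F from scratch via within/total sums of squared distances."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n_a = (labels == uniq[0]).sum()
    d2 = dm.data ** 2
    n = len(labels)

    def pseudo_f(lab):
        ss_t = d2[np.triu_indices(n, 1)].sum() / n
        ss_w = 0.0
        for g in uniq:
            idx = np.flatnonzero(lab == g)
            ss_w += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() \
                / len(idx)
        return (ss_t - ss_w) / (ss_w / (n - 2))

    f_obs = pseudo_f(labels)
    fs = []
    for combo in itertools.combinations(range(n), int(n_a)):
        lab = np.full(n, uniq[1], dtype=object)
        lab[list(combo)] = uniq[0]
        fs.append(pseudo_f(lab))
    return np.mean(np.asarray(fs) >= f_obs - 1e-12)


class TestPermanova:
    def _dm_labels(self, seed=0, sep=0.0, n=6):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        pts[n // 2:] += sep
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(n)]
        labels = pd.Series(["A"] * (n // 2) + ["B"] * (n - n // 2), index=ids)
        return DistanceMatrix(d, ids=ids), labels

    def test_exact_enumeration_matches_brute_force(self):
        dm, labels = self._dm_labels(seed=1, sep=1.0)
        res = permanova(dm, labels, permutations="exact")
        assert res["n_permutations"] == 20
        assert res["p"] == pytest.approx(
            brute_force_permanova_p(dm, labels.to_numpy()))

    def test_pseudo_f_matches_skbio(self):
        dm, labels = self._dm_labels(seed=2, sep=0.5, n=10)
        res = permanova(dm, labels, permutations=99, seed=0)
        ref = skbio_permanova(dm, grouping=list(labels), permutations=9)
        assert res["pseudo_F"] == pytest.approx(ref["test statistic"])

    def test_separated_clusters_reach_minimum_p(self):
        dm, labels = self._dm_labels(seed=3, sep=50.0, n=12)
        res = permanova(dm, labels, permutations=199, seed=1)
        assert res["p"] == pytest.approx(1 / 200)

    def test_null_p_is_calibrated(self):
        ps = []
        for seed in range(100):
            dm, labels = self._dm_labels(seed=seed, sep=0.0, n=8)
            ps.append(permanova(dm, labels, permutations=49,
                                seed=seed)["p"])
        assert 0.35 < np.mean(ps) < 0.65

    def test_singleton_group_rejected(self):
        dm, _ = self._dm_labels(n=4)
        labels = pd.Series(["A", "B", "B", "B"], index=dm.ids)
        with pytest.raises(ValueError):
            permanova(dm, labels)

    def test_pseudo_f_invariant_under_consistent_permutation(self):
        dm, labels = self._dm_labels(seed=5, sep=0.7, n=8)
        perm = np.random.default_rng(0).permutation(8)
        ids = [dm.ids[i] for i in perm]
        dm2 = DistanceMatrix(dm.data[np.ix_(perm, perm)], ids=ids)
        res1 = permanova(dm, labels, permutations=9, seed=0)
        res2 = permanova(dm2, labels.loc[ids], permutations=9, seed=0)
        assert res1["pseudo_F"] == pytest.approx(res2["pseudo_F"])
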