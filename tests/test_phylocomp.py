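"""Phylogenetic covariance, K_mult, rate comparison and shift models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import blendevol as bv
from blendevol.io_peaktables import DegenerateStatisticError, ValidationError
from blendevol.phylocomp import (
    Phylogeny,
    compare_evol_rates,
    fit_bm,
    fit_clade_shift,
    kmult,
    phylo_cov,
    phylogenetic_mean,
    resolve_tips,
    search_rate_shifts,
)


def star_tree(n=6, depth=5.0):
    tips = ",".join(f"t{i}:{depth}" for i in range(n))
    return Phylogeny.from_newick(f"({tips});", is_path=False)


class TestPhyloCov:
    def test_star_tree_diagonal(self):
        C, labels = phylo_cov(star_tree(5, 3.0))
        np.testing.assert_allclose(C, 3.0 * np.eye(5))

    def test_sisters_share_stem_depth(self):
        phylo = Phylogeny.from_newick("((a:2,b:2):3,c:5);", is_path=False)
        C, labels = phylo_cov(phylo)
        i, j = labels.index("a"), labels.index("b")
        assert C[i, j] == pytest.approx(3.0)  # depth of the a-b ancestor
        assert C[i, labels.index("c")] == 0.0

    def test_four_tip_hand_computed(self, balanced_tree):
        C, labels = phylo_cov(balanced_tree)
        # ((a:2,b:2):3,(c:4,d:4):1): depths 5 everywhere, MRCA depths 3 and 1
        expect = {
            ("a", "a"): 5, ("b", "b"): 5, ("c", "c"): 5, ("d", "d"): 5,
            ("a", "b"): 3, ("c", "d"): 1,
            ("a", "c"): 0, ("a", "d"): 0, ("b", "c"): 0, ("b", "d"): 0,
        }
        for (x, y), v in expect.items():
            assert C[labels.index(x), labels.index(y)] == pytest.approx(v)

    def test_psd_on_random_trees(self):
        for seed in range(100):
            phylo = bv.simulate_tree(8, seed, depth=7.0)
            C = phylo.covariance()
            assert np.linalg.eigvalsh(C).min() > -1e-10

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValidationError):
            Phylogeny.from_newick("((a:1,b:-0.5):1,c:2);", is_path=False)


class TestPhylogeneticMean:
    def test_star_tree_reduces_to_column_means(self, rng):
        phylo = star_tree(6, 2.0)
        Y = rng.normal(size=(6, 3))
        a = phylogenetic_mean(Y, phylo.covariance())
        np.testing.assert_allclose(a, Y.mean(axis=0), atol=1e-12)

    def test_matches_direct_linear_algebra(self, balanced_tree, rng):
        C = balanced_tree.covariance()
        Y = rng.normal(size=(4, 2))
        ones = np.ones(4)
        Cinv = np.linalg.inv(C)
        expect = np.linalg.solve(
            np.atleast_2d(ones @ Cinv @ ones), np.atleast_2d(ones @ Cinv @ Y)
        )[0]
        np.testing.assert_allclose(phylogenetic_mean(Y, C), expect, atol=1e-10)


def blomberg_k_univariate(y, C):
    """Independent scalar implementation of Blomberg's K."""
    n = len(y)
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    a = (ones @ Cinv @ y) / (ones @ Cinv @ ones)
    e = y - a
    observed = (e @ e) / (e @ Cinv @ e)
    expected = (np.trace(C) - n / (ones @ Cinv @ ones)) / (n - 1)
    return observed / expected


class TestKmult:
    def test_star_tree_exactly_one(self, rng):
        phylo = star_tree(8, 4.0)
        Y = rng.normal(size=(8, 3))
        res = kmult(Y, phylo, n_perm=0, seed=0)
        assert res.k_mult == pytest.approx(1.0, abs=1e-10)

    def test_single_trait_equals_blomberg_k(self):
        for seed in range(20):
            phylo = bv.simulate_tree(10, seed, depth=6.0)
            rng = np.random.default_rng(seed + 1000)
            y = rng.normal(size=10)
            res = kmult(y[:, None], phylo, n_perm=0, seed=0)
            assert res.k_mult == pytest.approx(
                blomberg_k_univariate(y, phylo.covariance()), abs=1e-8
            )

    def test_scale_and_rotation_invariance(self, rng):
        phylo = bv.simulate_tree(12, 5, depth=6.0)
        Y = rng.normal(size=(12, 4))
        base = kmult(Y, phylo, n_perm=0).k_mult
        assert kmult(3.7 * Y, phylo, n_perm=0).k_mult == pytest.approx(base, rel=1e-10)
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        assert kmult(Y @ Q, phylo, n_perm=0).k_mult == pytest.approx(base, rel=1e-10)

    def test_bm_simulation_signal_significant(self, rng):
        phylo = bv.simulate_tree(20, 3, depth=8.0)
        L = np.linalg.cholesky(phylo.covariance() + 1e-10 * np.eye(20))
        Y = L @ rng.normal(size=(20, 4))
        res = kmult(Y, phylo, n_perm=199, seed=9)
        assert res.p <= 0.05

    def test_constant_traits_degenerate(self):
        phylo = star_tree(5)
        with pytest.raises(DegenerateStatisticError):
            kmult(np.ones((5, 2)), phylo, n_perm=9)


class TestCompareEvolRates:
    def _setup(self, seed=0, n=18):
        phylo = bv.simulate_tree(n, seed, depth=8.0)
        from blendevol.synthetic_data import default_pupal_node

        node = default_pupal_node(phylo)
        inside = set(phylo.clade_tips(node))
        groups = {t: ("in" if t in inside else "out") for t in phylo.tip_labels}
        return phylo, node, groups

    def test_single_group_consistency_with_pooled(self, rng):
        phylo, _, _ = self._setup()
        Y = rng.normal(size=(phylo.n_tips, 3))
        res = compare_evol_rates(
            Y, phylo, {t: "all" for t in phylo.tip_labels},
            n_iter=9, seed=0, allow_single_group=True,
        )
        assert res.sigma2["all"] == pytest.approx(res.sigma2_pooled, rel=1e-12)

    def test_group_rates_average_to_pooled(self, rng):
        phylo, _, groups = self._setup()
        Y = rng.normal(size=(phylo.n_tips, 3))
        res = compare_evol_rates(Y, phylo, groups, n_iter=9, seed=0)
        sizes = pd.Series(groups).value_counts()
        weighted = sum(res.sigma2[g] * sizes[g] for g in res.sigma2) / sizes.sum()
        assert weighted == pytest.approx(res.sigma2_pooled, rel=1e-10)

    def test_planted_rate_difference_detected(self, rng):
        phylo, node, groups = self._setup(seed=4, n=24)
        C = phylo.covariance()
        M = phylo.shift_component(node)
        L = np.linalg.cholesky(C + 7.0 * M + 1e-10 * np.eye(len(C)))
        Y = pd.DataFrame(L @ rng.normal(size=(len(C), 5)), index=phylo.tip_labels)
        res = compare_evol_rates(Y, phylo, groups, n_iter=199, seed=2)
        assert res.sigma2["in"] > res.sigma2["out"]
        assert res.p <= 0.05

    def test_permutation_null_available_and_recorded(self, rng):
        phylo, _, groups = self._setup()
        Y = rng.normal(size=(phylo.n_tips, 3))
        res = compare_evol_rates(
            Y, phylo, groups, n_iter=99, seed=1, null_method="permutation"
        )
        assert res.null_method == "permutation"
        assert 0.0 < res.p <= 1.0

    def test_identical_rows_degenerate(self):
        phylo, _, groups = self._setup()
        Y = np.ones((phylo.n_tips, 3))
        with pytest.raises(DegenerateStatisticError):
            compare_evol_rates(Y, phylo, groups, n_iter=9)

    def test_small_group_rejected(self, rng):
        phylo = bv.simulate_tree(8, 0, depth=5.0)
        groups = {t: ("a" if i < 2 else "b") for i, t in enumerate(phylo.tip_labels)}
        with pytest.raises(ValidationError):
            compare_evol_rates(rng.normal(size=(8, 2)), phylo, groups, n_iter=9)


class TestFitBM:
    def test_star_tree_iid_reduction(self, rng):
        depth = 4.0
        phylo = star_tree(12, depth)
        y = rng.normal(size=(12, 1))
        fit = fit_bm(y, phylo)
        e = y[:, 0] - y[:, 0].mean()
        assert fit.sigma2[0] == pytest.approx((e @ e) / 12 / depth, rel=1e-10)

    def test_doubling_branch_lengths_halves_rate(self, rng):
        phylo1 = bv.simulate_tree(10, 7, depth=5.0)
        phylo2 = Phylogeny.from_newick(phylo1.to_newick(), is_path=False)
        for e in phylo2.tree.preorder_edge_iter():
            if e.length:
                e.length *= 2.0
        phylo2 = Phylogeny(phylo2.tree)
        Y = rng.normal(size=(10, 3))
        f1, f2 = fit_bm(Y, phylo1), fit_bm(Y, phylo2)
        np.testing.assert_allclose(f2.sigma2, f1.sigma2 / 2.0, rtol=1e-10)

    def test_loglik_matches_multivariate_normal_density(self, rng):
        phylo = bv.simulate_tree(6, 2, depth=5.0)
        C = phylo.covariance()
        Y = rng.normal(size=(6, 2))
        fit = fit_bm(Y, phylo)
        ll = 0.0
        for j in range(2):
            mvn = stats.multivariate_normal(
                mean=np.full(6, fit.mean[j]), cov=fit.sigma2[j] * C
            )
            ll += mvn.logpdf(Y[:, j])
        assert fit.loglik == pytest.approx(ll, abs=1e-8)


class TestCladeShift:
    def _tree_and_node(self, seed=42, n=20):
        phylo = bv.simulate_tree(n, seed, depth=8.0)
        from blendevol.synthetic_data import default_pupal_node

        return phylo, default_pupal_node(phylo)

    def test_fixed_r_one_reproduces_single_rate_fit(self, rng):
        phylo, node = self._tree_and_node()
        Y = rng.normal(size=(phylo.n_tips, 3))
        shift = fit_clade_shift(Y, phylo, node, fixed_r=1.0)
        single = fit_bm(Y, phylo)
        assert shift.loglik == pytest.approx(single.loglik, abs=1e-8)

    def test_shift_loglik_never_below_single_rate(self, rng):
        phylo, node = self._tree_and_node()
        for _ in range(5):
            Y = rng.normal(size=(phylo.n_tips, 3))
            fit = fit_clade_shift(Y, phylo, node)
            assert fit.loglik >= fit.loglik_single - 1e-9

    def test_null_data_recover_r_near_one(self):
        phylo, node = self._tree_and_node()
        L = np.linalg.cholesky(phylo.covariance() + 1e-10 * np.eye(phylo.n_tips))
        rng = np.random.default_rng(0)
        log_rs = []
        for _ in range(50):
            Y = L @ rng.standard_normal((phylo.n_tips, 3))
            log_rs.append(np.log(fit_clade_shift(Y, phylo, node).rate_multiplier))
        assert abs(np.median(log_rs)) < 0.2

    def test_planted_multiplier_recovered(self):
        phylo, node = self._tree_and_node(seed=1, n=30)
        C = phylo.covariance()
        M = phylo.shift_component(node)
        L = np.linalg.cholesky(C + 2.0 * M + 1e-10 * np.eye(len(C)))  # r = 3
        rng = np.random.default_rng(5)
        rs = [
            fit_clade_shift(
                L @ rng.standard_normal((len(C), 5)), phylo, node
            ).rate_multiplier
            for _ in range(30)
        ]
        assert 2.0 <= np.median(rs) <= 4.5

    def test_root_shift_rejected(self, rng):
        phylo, _ = self._tree_and_node()
        with pytest.raises(ValidationError):
            fit_clade_shift(rng.normal(size=(phylo.n_tips, 2)), phylo, phylo.root_id)


class TestShiftSearch:
    def test_max_shifts_zero_returns_single_rate_only(self, rng):
        phylo = bv.simulate_tree(10, 3, depth=6.0)
        res = search_rate_shifts(
            rng.normal(size=(10, 2)), phylo, max_shifts=0, seed=0
        )
        assert res.best is None and not res.shift_supported

    def test_strong_shift_recovered_and_supported(self):
        phylo = bv.simulate_tree(24, 6, depth=8.0)
        from blendevol.synthetic_data import default_pupal_node

        node = default_pupal_node(phylo)
        C = phylo.covariance()
        M = phylo.shift_component(node)
        L = np.linalg.cholesky(C + 24.0 * M + 1e-10 * np.eye(len(C)))  # r = 25
        rng = np.random.default_rng(8)
        Y = L @ rng.standard_normal((len(C), 4))
        res = search_rate_shifts(Y, phylo, n_null=40, seed=2)
        assert res.best.node_id == node
        assert res.shift_supported
        assert res.node_table.iloc[0]["node_id"] == node


class TestResolveTips:
    def _meta(self, rows):
        df = pd.DataFrame(
            rows, columns=["sample_id", "species", "subspecies"]
        )
        return df.set_index("sample_id", drop=False)

    def test_exact_match(self):
        phylo = Phylogeny.from_newick("((spA:1,spB:1):1,spC:2);", is_path=False)
        meta = self._meta([("s1", "spA", ""), ("s2", "spB", "")])
        res = resolve_tips(meta, phylo)
        assert res.species_to_tip == {"spA": "spA", "spB": "spB"}

    def test_configured_subspecies_choice(self):
        phylo = Phylogeny.from_newick(
            "(('spA east':1,'spA west':1):1,spB:2);", is_path=False
        )
        meta = self._meta(
            [("s1", "spA", "east"), ("s2", "spA", "west"), ("s3", "spB", "")]
        )
        res = resolve_tips(meta, phylo, subspecies_choice={"spA": "east"})
        assert res.species_to_tip["spA"] == "spA east"
        assert list(res.samples["sample_id"]) == ["s1", "s3"]

    def test_unmatched_species_excluded(self):
        phylo = Phylogeny.from_newick("((spA:1,spB:1):1,spC:2);", is_path=False)
        meta = self._meta([("s1", "spA", ""), ("s2", "spZ", "")])
        res = resolve_tips(meta, phylo)
        assert "spZ" in res.excluded_species
        assert "spZ" not in res.species_to_tip
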