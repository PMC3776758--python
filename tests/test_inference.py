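"""Permutation tests, Kruskal-Wallis comparisons and phylogenetic signal."""

import subprocess
import sys
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import radcurve as rc
from radcurve.inference import (
    _k_statistic,
    bonferroni_alpha,
    tip_covariance,
)
from radcurve.superimposition import center_and_scale, gpa


def _pp_distance_svd(a, b):
    """Independent partial Procrustes distance via a 2x2 SVD rotation fit."""
    a = center_and_scale(a)
    b = center_and_scale(b)
    M = a.T @ b
    U, _, Vt = np.linalg.svd(M)
    # rotation only (no reflection): flip the smallest singular direction
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, d]) @ Vt
    return float(np.linalg.norm(a - b @ R.T))


def _goodall_oracle(A, B):
    """Sums-of-squares Goodall's F assembled with explicit loops."""
    na, nb = len(A), len(B)
    ma = center_and_scale(np.mean(A, axis=0))
    mb = center_and_scale(np.mean(B, axis=0))
    ss_between = _pp_distance_svd(ma, mb) ** 2
    ssw = 0.0
    for x in A:
        ssw += _pp_distance_svd(x, ma) ** 2
    for x in B:
        ssw += _pp_distance_svd(x, mb) ** 2
    return (ss_between / (1 / na + 1 / nb)) / (ssw / (na + nb - 2))


class TestGoodallF:
    def test_identical_groups_zero(self, rng):
        shape = center_and_scale(rng.normal(size=(21, 2)))
        X = np.stack([shape] * 6)
        assert rc.goodall_f(X[:3], X[3:]) == 0.0

    def test_zero_within_scatter_infinite(self, rng):
        a = center_and_scale(rng.normal(size=(21, 2)))
        b = center_and_scale(a + 0.3 * rng.normal(size=a.shape))
        with pytest.warns(UserWarning, match="infinite"):
            f = rc.goodall_f(np.stack([a, a]), np.stack([b, b]))
        assert np.isinf(f)

    def test_matches_sums_of_squares_oracle(self, aligned_toy):
        res, labels = aligned_toy
        A = res.aligned[labels == "sprawled"]
        B = res.aligned[labels == "parasagittal"]
        assert rc.goodall_f(A, B) == pytest.approx(_goodall_oracle(A, B), abs=1e-9)

    def test_label_exchange_and_rotation_invariance(self, aligned_toy, rng):
        res, labels = aligned_toy
        A = res.aligned[labels == "sprawled"]
        B = res.aligned[labels == "parasagittal"]
        f = rc.goodall_f(A, B)
        assert rc.goodall_f(B, A) == pytest.approx(f, rel=1e-12)
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        assert rc.goodall_f(A @ rot.T, B @ rot.T) == pytest.approx(f, rel=1e-9)

    def test_singleton_group_rejected(self, rng):
        X = rng.normal(size=(3, 8, 2))
        with pytest.raises(ValueError):
            rc.goodall_f(X[:1], X[1:])


class TestPermutationTest:
    def test_exhaustive_enumeration_3v3(self, rng):
        # complete separation: observed F is the maximum over all 20 splits
        base = center_and_scale(rng.normal(size=(12, 2)))
        far = center_and_scale(base + 0.5 * rng.normal(size=base.shape))
        X = np.stack(
            [base + 0.001 * rng.normal(size=base.shape) for _ in range(3)]
            + [far + 0.001 * rng.normal(size=base.shape) for _ in range(3)]
        )
        X = gpa(X).aligned
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = rc.permutation_test(X, labels, seed=0)
        assert res.exhaustive
        # independent full enumeration
        fs = []
        for idx in combinations(range(6), 3):
            m = np.zeros(6, bool)
            m[list(idx)] = True
            fs.append(rc.goodall_f(X[m], X[~m]))
        expected_p = np.mean(
            np.asarray(fs) >= res.statistic * (1 - 1e-9) - 1e-12
        )
        assert res.p_value == pytest.approx(expected_p)
        assert res.p_value == pytest.approx(2 / 20)  # split and its complement

    def test_p_value_bounds(self, aligned_toy):
        res_gpa, labels = aligned_toy
        res = rc.permutation_test(res_gpa.aligned, labels, n_permutations=199, seed=1)
        assert 1 / (res.n_permutations + 1) <= res.p_value <= 1.0

    def test_reproducible_under_seed(self, aligned_toy):
        res_gpa, labels = aligned_toy
        kw = dict(n_permutations=199, seed=7)
        p1 = rc.permutation_test(res_gpa.aligned, labels, **kw).p_value
        p2 = rc.permutation_test(res_gpa.aligned, labels, **kw).p_value
        assert p1 == p2

    def test_type_i_error_calibration(self):
        # identical-distribution groups: rejection rate at alpha=.05 must be
        # close to nominal (500 seeded simulations, exhaustive 4v4 splits)
        rng = np.random.default_rng(99)
        base = center_and_scale(rng.normal(size=(8, 2)))
        labels = np.array([0] * 4 + [1] * 4)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            X = np.stack([base + 0.05 * rng.normal(size=base.shape) for _ in range(8)])
            aligned = gpa(X).aligned
            p = rc.permutation_test(aligned, labels, seed=0).p_value
            if p < 0.05:
                hits += 1
        assert 0.03 <= hits / n_sim <= 0.07


class TestPairwiseShapeTests:
    def test_eight_groups_bonferroni(self):
        assert bonferroni_alpha(28) == pytest.approx(0.05 / 28)
        assert float(f"{bonferroni_alpha(28):.2g}") == 0.0018

    def test_battery_structure_and_symmetry(self, two_group_dataset):
        X, labels = two_group_dataset
        battery = rc.pairwise_shape_tests(X, labels, n_permutations=99, seed=3)
        F = battery.statistic_frame()
        assert np.allclose(F.to_numpy(), F.to_numpy().T, equal_nan=True)
        assert battery.alpha_corrected == pytest.approx(0.05)
        res = battery.get("sprawled", "parasagittal")
        assert res.statistic > 0
        assert res is battery.get("parasagittal", "sprawled")

    def test_singleton_group_skipped(self, rng):
        X = rng.normal(size=(5, 8, 2))
        labels = np.array(["a", "a", "b", "b", "c"])
        with pytest.warns(UserWarning, match="singleton"):
            battery = rc.pairwise_shape_tests(X, labels, n_permutations=99, seed=0)
        assert battery.get("a", "c") is None
        assert battery.get("b", "c") is None
        assert battery.get("a", "b") is not None

    def test_separated_groups_flagged_significant(self, two_group_dataset):
        X, labels = two_group_dataset
        battery = rc.pairwise_shape_tests(X, labels, n_permutations=999, seed=5)
        assert battery.significant_pairs() == [("parasagittal", "sprawled")]


class TestKruskalWallis:
    def test_constant_values_h_zero(self):
        battery = rc.kruskal_wallis_mc(
            np.full(9, 3.3), np.repeat(["a", "b", "c"], 3)
        )
        assert battery.overall.statistic == 0.0
        assert battery.significant_pairs() == []

    def test_h_matches_textbook_formula_tie_free(self):
        values = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
        groups = np.repeat(["A", "B", "C"], 3)
        battery = rc.kruskal_wallis_mc(values, groups)
        ranks = stats.rankdata(values)
        N = len(values)
        rbar = ranks.mean()
        h_oracle = 12 / (N * (N + 1)) * sum(
            3 * (ranks[groups == g].mean() - rbar) ** 2 for g in "ABC"
        )
        assert battery.overall.statistic == pytest.approx(h_oracle, abs=1e-10)

    def test_separated_pair_matches_exhaustive_rank_sum(self):
        values = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        battery = rc.kruskal_wallis_mc(values, groups)
        res = battery.get("a", "b")
        # exhaustive two-sided rank-sum enumeration: 2 extreme splits of 20
        assert res.p_value == pytest.approx(2 / 20)

    def test_mean_rank_criterion_flags_extremes(self):
        rng = np.random.default_rng(3)
        values = np.concatenate(
            [rng.normal(0, 1, 15), rng.normal(0, 1, 15), rng.normal(8, 1, 15)]
        )
        groups = np.repeat(["a", "b", "c"], 15)
        battery = rc.kruskal_wallis_mc(values, groups)
        flagged = {
            tuple(sorted(k))
            for k, r in battery.results.items()
            if r.extra["significant_by_criterion"]
        }
        assert flagged == {("a", "c"), ("b", "c")}


class TestBlombergK:
    def test_constant_trait_rejected(self):
        newick, traits = rc.generate_tree_and_traits(8, seed=0)
        with pytest.raises(ValueError, match="zero variance"):
            rc.blomberg_k(newick, pd.Series(1.0, index=traits.index))

    def test_matches_phytools_oracle(self, tmp_path):
        newick, traits = rc.generate_tree_and_traits(8, mode="bm", seed=11)
        ours = rc.blomberg_k(newick, traits, n_permutations=0).statistic
        tree_file = tmp_path / "t.nwk"
        tree_file.write_text(newick + "\n")
        trait_file = tmp_path / "x.csv"
        traits.to_csv(trait_file, header=["value"])
        rscript = (
            "suppressMessages(library(phytools));"
            f"tr <- read.tree('{tree_file}');"
            f"d <- read.csv('{trait_file}', row.names=1);"
            "x <- setNames(d$value, rownames(d));"
            "cat(sprintf('%.12f', phylosig(tr, x, method='K')))"
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        assert ours == pytest.approx(float(out.stdout.strip()), abs=1e-9)

    def test_brownian_recovery_and_white_noise(self):
        newick, _ = rc.generate_tree_and_traits(64, mode="bm", seed=7)
        taxa = [f"t{i + 1}" for i in range(64)]
        V = tip_covariance(newick, taxa)
        Vinv = np.linalg.inv(V)
        trV, s = float(np.trace(V)), float(Vinv.sum())
        L = np.linalg.cholesky(V)
        rng = np.random.default_rng(8)
        bm = [_k_statistic(L @ rng.normal(size=64), Vinv, trV, 64, s) for _ in range(200)]
        wn = [_k_statistic(rng.normal(size=64), Vinv, trV, 64, s) for _ in range(200)]
        assert 0.85 <= np.mean(bm) <= 1.15
        assert np.mean(wn) < 0.6

    def test_white_noise_p_uniform_and_bm_significant(self):
        newick, traits = rc.generate_tree_and_traits(48, mode="bm", seed=21)
        res = rc.blomberg_k(newick, traits, n_permutations=199, seed=2)
        assert res.p_value < 0.05
        # white noise: permutation p spread over (0, 1]
        rng = np.random.default_rng(5)
        ps = []
        for i in range(40):
            _, wn = rc.generate_tree_and_traits(48, mode="white", seed=100 + i)
            ps.append(
                rc.blomberg_k(newick, wn, n_permutations=99, seed=i).p_value
            )
        assert 0.25 <= np.mean(ps) <= 0.75
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_white_noise_k_below_bm_paired(self):
        newick, _ = rc.generate_tree_and_traits(32, mode="bm", seed=31)
        taxa = [f"t{i + 1}" for i in range(32)]
        V = tip_covariance(newick, taxa)
        Vinv = np.linalg.inv(V)
        trV, s = float(np.trace(V)), float(Vinv.sum())
        L = np.linalg.cholesky(V)
        rng = np.random.default_rng(17)
        wins = 0
        for _ in range(100):
            k_bm = _k_statistic(L @ rng.normal(size=32), Vinv, trV, 32, s)
            k_wn = _k_statistic(rng.normal(size=32), Vinv, trV, 32, s)
            wins += k_wn < k_bm
        assert wins >= 95


class TestMultivariateK:
    def test_single_axis_reduces_to_blomberg(self):
        newick, traits = rc.generate_tree_and_traits(16, mode="bm", seed=4)
        single = rc.blomberg_k(newick, traits, n_permutations=99, seed=9)
        multi = rc.multivariate_k(
            newick, traits.to_frame("RW1"), n_permutations=99, seed=9
        )
        assert multi["summary_k"] == pytest.approx(single.statistic, rel=1e-12)
        assert multi["per_axis"]["RW1"].statistic == pytest.approx(
            single.statistic, rel=1e-12
        )

    def test_bm_axes_recover_k_near_one(self):
        newick, _ = rc.generate_tree_and_traits(64, mode="bm", seed=13)
        taxa = [f"t{i + 1}" for i in range(64)]
        V = tip_covariance(newick, taxa)
        L = np.linalg.cholesky(V)
        rng = np.random.default_rng(14)
        # 100 reps x 3 BM axes, K averaged per axis position
        per_axis = np.zeros((100, 3))
        Vinv = np.linalg.inv(V)
        trV, s = float(np.trace(V)), float(Vinv.sum())
        for r in range(100):
            for a in range(3):
                per_axis[r, a] = _k_statistic(
                    L @ rng.normal(size=64), Vinv, trV, 64, s
                )
        assert np.all(per_axis.mean(axis=0) >= 0.85)
        assert np.all(per_axis.mean(axis=0) <= 1.15)

    def test_shuffled_tips_destroy_signal(self):
        newick, _ = rc.generate_tree_and_traits(24, mode="bm", seed=40)
        taxa = [f"t{i + 1}" for i in range(24)]
        V = tip_covariance(newick, taxa)
        L = np.linalg.cholesky(V)
        rng = np.random.default_rng(41)
        nonsig = 0
        for r in range(100):
            scores = pd.DataFrame(
                {f"RW{a + 1}": L @ rng.normal(size=24) for a in range(2)}, index=taxa
            )
            shuffled = scores.copy()
            shuffled.index = list(rng.permutation(taxa))
            out = rc.multivariate_k(newick, shuffled, n_permutations=49, seed=r)
            if out["summary_p"] > 0.05:
                nonsig += 1
        assert nonsig >= 90

    def test_zero_variance_axis_skipped(self):
        newick, traits = rc.generate_tree_and_traits(12, mode="bm", seed=6)
        scores = traits.to_frame("RW1")
        scores["RW2"] = 0.0
        with pytest.warns(UserWarning, match="zero variance"):
            out = rc.multivariate_k(newick, scores, n_permutations=49, seed=1)
        assert list(out["per_axis"]) == ["RW1"]
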