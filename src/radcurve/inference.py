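"""Group-difference and phylogenetic-signal statistics.

Two-group shape differences are tested with Goodall's F on partial Procrustes
distances,

    F = [ d^2(mean_a, mean_b) / (1/n_a + 1/n_b) ]
        / [ (sum_i d^2(a_i, mean_a) + sum_j d^2(b_j, mean_b)) / (n_a + n_b - 2) ],

with the group means taken as the re-normalized coordinate-wise means after a
joint superimposition of the two groups, and significance assessed by a label
permutation test (superimposition held fixed; only labels shuffle).  This
sidesteps the reduced degrees of freedom of sliding semi-landmark data and
the normality assumption.  Permutations are exhaustive whenever the number of
distinct label splits is small (<= 10000), otherwise uniformly sampled with a
seeded generator; the p estimator includes the observed statistic in both
numerator and denominator, so p >= 1/(n_permutations + 1).

Multi-group batteries run every unordered pair through a pairwise joint
superimposition and share a Bonferroni-corrected alpha = base / n_pairs.

Angle-of-curvature data are compared with a tie-corrected Kruskal-Wallis test
plus a mean-rank multiple-comparison procedure, and phylogenetic signal in
warp scores with Blomberg's K (K near 1 under Brownian motion; small K for
phylogenetically unstructured traits), with p from tip-shuffling permutations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .superimposition import gpa, procrustes_distance, _distances_to, _normalize_stack

__all__ = [
    "TestResult",
    "PairwiseMatrix",
    "goodall_f",
    "estimate_group_offset",
    "permutation_test",
    "pairwise_shape_tests",
    "bonferroni_alpha",
    "kruskal_wallis_mc",
    "blomberg_k",
    "multivariate_k",
    "tip_covariance",
    "load_tree",
]

EXHAUSTIVE_LIMIT = 10_000


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_per_group: tuple
    n_permutations: int = 0
    seed: int | None = None
    alpha: float = 0.05
    degenerate: bool = False
    exhaustive: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class PairwiseMatrix:
    """Symmetric battery of pairwise test results with a shared corrected alpha."""

    labels: list
    results: dict  # frozenset({a, b}) -> TestResult | None (skipped)
    alpha_corrected: float
    overall: TestResult | None = None

    def get(self, a, b) -> TestResult | None:
        return self.results.get(frozenset((a, b)))

    def statistic_frame(self) -> pd.DataFrame:
        return self._frame("statistic")

    def p_frame(self) -> pd.DataFrame:
        return self._frame("p_value")

    def _frame(self, attr: str) -> pd.DataFrame:
        df = pd.DataFrame(np.nan, index=self.labels, columns=self.labels)
        for key, res in self.results.items():
            if res is None:
                continue
            a, b = tuple(key)
            df.loc[a, b] = df.loc[b, a] = getattr(res, attr)
        return df

    def significant_pairs(self) -> list:
        return [
            tuple(sorted(k))
            for k, r in self.results.items()
            if r is not None and r.p_value < self.alpha_corrected
        ]


def bonferroni_alpha(n_comparisons: int, base_alpha: float = 0.05) -> float:
    """Shared significance level: base alpha divided by the number of pairs."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    return base_alpha / n_comparisons


def _group_mean(X: np.ndarray) -> np.ndarray:
    return _normalize_stack(X.mean(axis=0)[None])[0]


def estimate_group_offset(aligned: np.ndarray, labels) -> float:
    """Bias-corrected partial Procrustes distance between two group means.

    The naive distance between estimated means is inflated by the sampling
    noise of each mean (E d_naive^2 = delta^2 + tr cov(mean_a) + tr
    cov(mean_b)); each trace is estimated by the within-group sum of squared
    distances over n(n-1) and subtracted.  Clipped at zero.
    """
    X = np.asarray(aligned, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError("offset estimation requires exactly two groups")
    d2 = None
    correction = 0.0
    means = []
    for g in uniq:
        G = _normalize_stack(X[labels == g])
        m = _group_mean(G)
        means.append(m)
        n_g = G.shape[0]
        ss = float(np.sum(_distances_to(G, m) ** 2))
        correction += ss / (n_g * (n_g - 1))
    d2 = procrustes_distance(means[0], means[1]) ** 2
    return float(np.sqrt(max(0.0, d2 - correction)))


def goodall_f(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Goodall's F on two sets of jointly superimposed configurations."""
    A = np.asarray(group_a, dtype=float)
    B = np.asarray(group_b, dtype=float)
    na, nb = A.shape[0], B.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 specimens")
    ma, mb = _group_mean(A), _group_mean(B)
    d2_between = procrustes_distance(ma, mb) ** 2
    ssw = float(np.sum(_distances_to(_normalize_stack(A), ma) ** 2)) + float(
        np.sum(_distances_to(_normalize_stack(B), mb) ** 2)
    )
    num = d2_between / (1.0 / na + 1.0 / nb)
    den = ssw / (na + nb - 2)
    if den == 0.0:
        if num == 0.0:
            return 0.0
        warnings.warn("zero within-group variation with distinct means: F is infinite")
        return float("inf")
    return num / den


def _goodall_from_mask(X: np.ndarray, mask: np.ndarray) -> float:
    return goodall_f(X[mask], X[~mask])


def permutation_test(
    pooled,
    labels,
    n_permutations: int = 1999,
    seed: int | None = None,
    alpha: float = 0.05,
    presuperimposed: bool = True,
) -> TestResult:
    """Two-group Goodall's F permutation test on pooled configurations.

    ``labels`` must take exactly two values.  When ``presuperimposed`` is
    False a joint GPA of the pooled sample is run first; in either case the
    superimposition is held fixed while labels shuffle.  Exhaustive
    enumeration replaces sampling when the number of distinct splits is at
    most 10000.
    """
    X = np.asarray(pooled, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("permutation_test requires exactly two groups")
    if n_permutations < 99:
        warnings.warn("fewer than 99 permutations gives a coarse p-value")
    if not presuperimposed:
        X = gpa(X).aligned
    mask = labels == uniq[0]
    na, nb = int(mask.sum()), int((~mask).sum())
    observed = goodall_f(X[mask], X[~mask])
    thresh = observed - 1e-9 * max(1.0, abs(observed))
    n = na + nb
    n_splits = math.comb(n, na)
    if n_splits <= EXHAUSTIVE_LIMIT:
        count = 0
        for idx in combinations(range(n), na):
            m = np.zeros(n, dtype=bool)
            m[list(idx)] = True
            if _goodall_from_mask(X, m) >= thresh:
                count += 1
        p = count / n_splits
        return TestResult(
            statistic=observed,
            p_value=p,
            n_per_group=(na, nb),
            n_permutations=n_splits - 1,
            seed=seed,
            alpha=alpha,
            exhaustive=True,
        )
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        m = np.zeros(n, dtype=bool)
        m[perm[:na]] = True
        if _goodall_from_mask(X, m) >= thresh:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return TestResult(
        statistic=observed,
        p_value=p,
        n_per_group=(na, nb),
        n_permutations=n_permutations,
        seed=seed,
        alpha=alpha,
    )


def pairwise_shape_tests(
    configurations,
    grouping,
    n_permutations: int = 1999,
    seed: int | None = None,
    base_alpha: float = 0.05,
    slide: bool = False,
    global_superimposition: bool = False,
) -> PairwiseMatrix:
    """Goodall's F permutation battery over every unordered pair of groups.

    By default each pair is re-superimposed in isolation (the behavior of the
    classic two-group tools); ``global_superimposition`` instead slices one
    joint GPA of the full sample, for sensitivity analysis.  Pairs involving
    a singleton group are skipped with a warning.  The corrected alpha is
    ``base_alpha`` divided by the number of pairs attempted.
    """
    X = np.asarray(configurations, dtype=float) if not isinstance(
        configurations, np.ndarray
    ) else configurations
    X = np.asarray(X, dtype=float)
    grouping = np.asarray(grouping)
    labels = sorted(pd.unique(grouping).tolist())
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    pairs = list(combinations(labels, 2))
    alpha_c = bonferroni_alpha(len(pairs), base_alpha)
    rng = np.random.default_rng(seed)
    if global_superimposition:
        X = gpa(X, slide=slide).aligned
    results: dict = {}
    for a, b in pairs:
        ia = np.flatnonzero(grouping == a)
        ib = np.flatnonzero(grouping == b)
        if len(ia) < 2 or len(ib) < 2:
            warnings.warn(f"pair ({a}, {b}) skipped: singleton group")
            results[frozenset((a, b))] = None
            continue
        sub = X[np.concatenate([ia, ib])]
        lab = np.array([0] * len(ia) + [1] * len(ib))
        child_seed = int(rng.integers(0, 2**31 - 1))
        res = permutation_test(
            sub,
            lab,
            n_permutations=n_permutations,
            seed=child_seed,
            alpha=alpha_c,
            presuperimposed=global_superimposition,
        )
        results[frozenset((a, b))] = res
    return PairwiseMatrix(labels=labels, results=results, alpha_corrected=alpha_c)


def kruskal_wallis_mc(
    values,
    grouping,
    alpha: float = 0.05,
) -> PairwiseMatrix:
    """Kruskal-Wallis omnibus test plus mean-rank multiple comparisons.

    The omnibus H uses midranks with tie correction.  Pairwise decisions
    follow the large-sample mean-rank-difference criterion

        |Rbar_i - Rbar_j|  >  z_{1 - alpha'/2} sqrt(N(N+1)/12 (1/n_i + 1/n_j)),

    with alpha' Bonferroni-shared across pairs.  A per-pair p-value is also
    reported: the exact two-sided rank-sum p when the pair is small enough to
    enumerate, else the normal approximation from the criterion above.
    """
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    labels = sorted(pd.unique(grouping).tolist())
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    groups = [values[grouping == g] for g in labels]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(values) == 0:
        overall = TestResult(statistic=0.0, p_value=1.0, n_per_group=tuple(map(len, groups)))
    else:
        H, p = stats.kruskal(*groups)
        overall = TestResult(statistic=float(H), p_value=float(p), n_per_group=tuple(map(len, groups)))
    N = len(values)
    ranks = stats.rankdata(values)  # midranks
    mean_ranks = {g: ranks[grouping == g].mean() for g in labels}
    sizes = {g: int((grouping == g).sum()) for g in labels}
    pairs = list(combinations(labels, 2))
    alpha_c = bonferroni_alpha(len(pairs), alpha)
    z_crit = stats.norm.ppf(1 - alpha_c / 2)
    results: dict = {}
    for a, b in pairs:
        se = math.sqrt(N * (N + 1) / 12.0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        diff = abs(mean_ranks[a] - mean_ranks[b])
        significant_by_criterion = diff > z_crit * se
        if math.comb(sizes[a] + sizes[b], sizes[a]) <= EXHAUSTIVE_LIMIT:
            mw = stats.mannwhitneyu(
                values[grouping == a], values[grouping == b], method="exact"
            )
            p_pair = float(mw.pvalue)
        else:
            z = diff / se if se > 0 else 0.0
            p_pair = float(2 * stats.norm.sf(z))
        res = TestResult(
            statistic=diff,
            p_value=p_pair,
            n_per_group=(sizes[a], sizes[b]),
            alpha=alpha_c,
            extra={
                "critical_difference": z_crit * se,
                "significant_by_criterion": bool(significant_by_criterion),
            },
        )
        results[frozenset((a, b))] = res
    return PairwiseMatrix(
        labels=labels, results=results, alpha_corrected=alpha_c, overall=overall
    )


# --- phylogenetic signal -----------------------------------------------------


def load_tree(source: str | Path | dendropy.Tree) -> dendropy.Tree:
    """Load a rooted tree with branch lengths from newick or NEXUS."""
    if isinstance(source, dendropy.Tree):
        return source
    text = str(source)
    if "(" not in text and ";" not in text:  # a path, not tree text
        text = Path(text).read_text()
    else:
        try:
            if len(text) < 4096 and Path(text).exists():
                text = Path(text).read_text()
        except OSError:
            pass
    schema = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
    return dendropy.Tree.get(data=text, schema=schema, preserve_underscores=True)


def tip_covariance(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Brownian tip covariance: shared root-to-MRCA path length per tip pair."""
    tree = load_tree(tree)
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    missing = [t for t in taxa if t not in leaves]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    depths = {}
    for label in taxa:
        node = leaves[label]
        d = 0.0
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[label] = d
    pdm = tree.phylogenetic_distance_matrix()
    n = len(taxa)
    V = np.zeros((n, n))
    tax_objs = {lf.taxon.label: lf.taxon for lf in tree.leaf_node_iter()}
    for i, a in enumerate(taxa):
        V[i, i] = depths[a]
        for j in range(i + 1, n):
            b = taxa[j]
            dij = pdm.patristic_distance(tax_objs[a], tax_objs[b])
            V[i, j] = V[j, i] = 0.5 * (depths[a] + depths[b] - dij)
    return V


def _k_statistic(x: np.ndarray, Vinv: np.ndarray, trV: float, n: int, sum_vinv: float) -> float:
    one = np.ones(n)
    ahat = (one @ Vinv @ x) / sum_vinv
    dev = x - ahat
    mse0 = dev @ dev
    mse = dev @ Vinv @ dev
    if mse0 == 0:
        raise ValueError("trait has zero variance")
    expected = (trV - n / sum_vinv) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(
    tree,
    trait,
    n_permutations: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> TestResult:
    """Blomberg's K with a tip-shuffling permutation p-value.

    ``trait`` is a mapping / pandas Series from tip label to value.  K is the
    ratio of the observed MSE0/MSE (tip deviations from the phylogenetically
    weighted mean over the GLS error under the tree's Brownian covariance) to
    its Brownian-motion expectation; p is the proportion of tip shuffles with
    K at least as large as observed.
    """
    trait = pd.Series(trait, dtype=float)
    taxa = list(trait.index)
    x = trait.to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("trait has zero variance")
    V = tip_covariance(tree, taxa)
    n = len(taxa)
    Vinv = np.linalg.inv(V)
    trV = float(np.trace(V))
    sum_vinv = float(np.sum(Vinv))
    k_obs = _k_statistic(x, Vinv, trV, n, sum_vinv)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if _k_statistic(rng.permutation(x), Vinv, trV, n, sum_vinv) >= k_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return TestResult(
        statistic=k_obs,
        p_value=p,
        n_per_group=(n,),
        n_permutations=n_permutations,
        seed=seed,
        alpha=alpha,
    )


def multivariate_k(
    tree,
    score_matrix: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict:
    """Per-axis Blomberg's K on a taxa x axes score matrix, plus a
    variance-weighted summary K with a joint-permutation p-value.

    One plausible reading of matrix-input signal testing: each ordination
    axis is tested independently, and the summary weights per-axis K by the
    axis variance.  Zero-variance axes are skipped with a warning.  The
    summary p shuffles tip labels jointly across axes.
    """
    scores = pd.DataFrame(score_matrix)
    taxa = list(scores.index)
    V = tip_covariance(tree, taxa)
    n = len(taxa)
    Vinv = np.linalg.inv(V)
    trV = float(np.trace(V))
    sum_vinv = float(np.sum(Vinv))
    rng = np.random.default_rng(seed)
    per_axis: dict = {}
    cols = []
    variances = []
    for col in scores.columns:
        x = scores[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"axis {col!r} has zero variance; skipped")
            continue
        res = blomberg_k(
            tree,
            scores[col],
            n_permutations=n_permutations,
            seed=int(rng.integers(0, 2**31 - 1)),
            alpha=alpha,
        )
        per_axis[col] = res
        cols.append(col)
        variances.append(float(np.var(x, ddof=1)))
    if not cols:
        raise ValueError("no axis with positive variance")
    w = np.asarray(variances) / np.sum(variances)
    k_vals = np.array([per_axis[c].statistic for c in cols])
    summary_k = float(w @ k_vals)

    def weighted_k(mat: np.ndarray) -> float:
        ks = [
            _k_statistic(mat[:, j], Vinv, trV, n, sum_vinv) for j in range(mat.shape[1])
        ]
        return float(w @ np.asarray(ks))

    mat = scores[cols].to_numpy(dtype=float)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if weighted_k(mat[perm]) >= summary_k - 1e-12:
            count += 1
    summary_p = (1 + count) / (1 + n_permutations)
    return {
        "per_axis": per_axis,
        "summary_k": summary_k,
        "summary_p": summary_p,
        "weights": dict(zip(cols, w)),
    }
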