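"""Diversity and permutation statistics for microbiome group comparisons.

Implements, directly from their definitions: ASV richness, Faith's
phylogenetic diversity, Jaccard / Bray-Curtis / unweighted UniFrac
dissimilarities, PERMANOVA (Anderson's pseudo-F on a distance matrix),
PERMDISP (homogeneity of multivariate dispersions, with the
negative-eigenvalue correction in the principal-coordinate embedding),
group-equalized presence-absence indicator-value analysis (IndVal.g), and
Benjamini-Hochberg FDR adjustment.

Permutation p-values use the add-one convention p = (#{F_perm >= F_obs} + 1)
/ (n_perm + 1) for Monte-Carlo sampling; when the set of distinct label
arrangements is small (<= 10,000) the tests switch to exact full
enumeration, where p is the fraction of arrangements (including the
observed one) reaching the observed statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

from .table import AsvTable, total_sum_scale

__all__ = [
    "DistanceMatrix",
    "PermutationTestResult",
    "richness",
    "faith_pd",
    "beta_distance",
    "permanova",
    "permdisp",
    "indval",
    "prevalence_filter",
    "bh_fdr",
]

ENUMERATION_LIMIT = 10_000
_EPS = 1e-12

METRICS = ("jaccard", "bray_curtis", "unweighted_unifrac")


@dataclass
class DistanceMatrix:
    ids: list[str]
    data: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.data)) > 1e-10):
            raise ValueError("distance matrix diagonal must be zero")
        if self.data.min() < -1e-10 or self.data.max() > 1 + 1e-10:
            raise ValueError("distances must lie in [0, 1]")

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.data, ids=self.ids)


# ---------------------------------------------------------------------------
# alpha diversity


def richness(table: AsvTable) -> pd.Series:
    """Per-sample count of ASVs with count >= 1."""
    return (table.counts >= 1).sum(axis=1)


def _tree_edge_structure(tree: skbio.TreeNode, asv_ids: list[str]):
    """Edge incidence over the table's tips.

    Returns (edge_lengths, incidence) where incidence[e, j] is True when
    table column j descends through edge e (the edge above each non-root
    node).  Tree tips absent from the table simply never light up.
    """
    tip_index = {asv_id: j for j, asv_id in enumerate(asv_ids)}
    tree_tips = {tip.name for tip in tree.tips()}
    missing = [a for a in asv_ids if a not in tree_tips]
    if missing:
        raise ValueError(f"ASV(s) missing from tree: {missing[:5]}")
    nodes = [node for node in tree.postorder(include_self=False)]
    lengths = np.array([node.length or 0.0 for node in nodes])
    incidence = np.zeros((len(nodes), len(asv_ids)), dtype=bool)
    below: dict[int, np.ndarray] = {}
    for e, node in enumerate(nodes):
        if node.is_tip():
            row = np.zeros(len(asv_ids), dtype=bool)
            j = tip_index.get(node.name)
            if j is not None:
                row[j] = True
        else:
            row = np.zeros(len(asv_ids), dtype=bool)
            for child in node.children:
                row |= below[id(child)]
        below[id(node)] = row
        incidence[e] = row
    return lengths, incidence


def faith_pd(table: AsvTable, tree: skbio.TreeNode) -> pd.Series:
    """Faith's PD: branch length of the minimal rooted subtree spanning
    each sample's observed ASVs (root included)."""
    lengths, incidence = _tree_edge_structure(tree, table.asv_ids)
    presence = table.presence().to_numpy()
    observed_edges = incidence @ presence.T > 0  # edges x samples
    pd_values = lengths @ observed_edges
    return pd.Series(pd_values, index=table.sample_ids, name="faith_pd")


# ---------------------------------------------------------------------------
# beta diversity


def beta_distance(
    table: AsvTable, metric: str, tree: skbio.TreeNode | None = None
) -> DistanceMatrix:
    """Pairwise dissimilarity matrix under one of the three metrics.

    Jaccard and unweighted UniFrac work on presence/absence; Bray-Curtis
    works on total-sum-scaled proportions.  UniFrac needs a rooted tree.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    ids = table.sample_ids
    n = len(ids)
    if metric == "bray_curtis":
        x = total_sum_scale(table).to_numpy()
        d = np.zeros((n, n))
        for i in range(n):
            diff = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
            denom = (x[i] + x[i + 1 :]).sum(axis=1)
            d[i, i + 1 :] = d[i + 1 :, i] = diff / denom
        return DistanceMatrix(ids, d, metric)

    p = table.presence().to_numpy()
    if metric == "jaccard":
        inter = (p.astype(int) @ p.T.astype(int)).astype(float)
        sizes = p.sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - inter
        empty_pairs = union == 0
        np.fill_diagonal(empty_pairs, False)
        if empty_pairs.any():
            i, j = np.argwhere(empty_pairs)[0]
            raise ValueError(f"samples {ids[i]!r} and {ids[j]!r} are both empty")
        with np.errstate(invalid="ignore"):
            d = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(ids, d, metric)

    # unweighted UniFrac
    if tree is None:
        raise ValueError("unweighted_unifrac requires a rooted tree")
    lengths, incidence = _tree_edge_structure(tree, table.asv_ids)
    observed = incidence @ p.T > 0  # edges x samples
    d = np.zeros((n, n))
    for i in range(n):
        a = observed[:, i : i + 1]
        b = observed[:, i + 1 :]
        union = a | b
        unique = a ^ b
        denom = lengths @ union
        if np.any(denom == 0):
            j = int(np.argmax(denom == 0)) + i + 1
            raise ValueError(f"samples {ids[i]!r} and {ids[j]!r} are both empty")
        d[i, i + 1 :] = d[i + 1 :, i] = (lengths @ unique) / denom
    return DistanceMatrix(ids, d, metric)


# ---------------------------------------------------------------------------
# permutation machinery


def _as_labels(groups, ids) -> np.ndarray:
    if isinstance(groups, pd.Series):
        return groups.loc[list(ids)].to_numpy()
    groups = np.asarray(groups)
    if len(groups) != len(ids):
        raise ValueError("groups length does not match sample ids")
    return groups


def _n_arrangements(labels: np.ndarray) -> int:
    _, counts = np.unique(labels, return_counts=True)
    total = math.factorial(len(labels))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _distinct_arrangements(labels: np.ndarray):
    """All distinct orderings of a label multiset (lexicographic)."""
    seen_total = _n_arrangements(labels)
    out = np.empty((seen_total, len(labels)), dtype=labels.dtype)
    for k, perm in enumerate(_multiset_permutations(sorted(labels.tolist()))):
        out[k] = perm
    return out


def _multiset_permutations(items: list):
    if len(items) <= 1:
        yield list(items)
        return
    previous = object()
    for i in range(len(items)):
        if items[i] == previous:
            continue
        previous = items[i]
        rest = items[:i] + items[i + 1 :]
        for tail in _multiset_permutations(rest):
            yield [items[i]] + tail


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    method: str  # "exact" or "monte_carlo"
    r2: float | None = None

    @property
    def pseudo_F(self) -> float:
        return self.statistic


def _permanova_f(d2: np.ndarray, labels: np.ndarray, ss_total: float) -> tuple[float, float]:
    n = len(labels)
    ss_within = 0.0
    n_groups = 0
    for g in np.unique(labels):
        mask = labels == g
        n_g = int(mask.sum())
        n_groups += 1
        ss_within += d2[np.ix_(mask, mask)].sum() / (2 * n_g)
    ss_among = ss_total - ss_within
    # zero within-group scatter (perfect separation) gives F = inf
    with np.errstate(divide="ignore", invalid="ignore"):
        f = float((ss_among / (n_groups - 1)) / (ss_within / (n - n_groups)))
    return f, float(ss_among / ss_total)


def permanova(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    enumeration_limit: int = ENUMERATION_LIMIT,
) -> PermutationTestResult:
    """Permutational multivariate analysis of variance on a distance matrix.

    Pseudo-F follows the among/within partition of squared inter-point
    distances; group labels are permuted freely across samples.
    """
    labels = _as_labels(groups, dm.ids)
    uniques, counts = np.unique(labels, return_counts=True)
    if len(uniques) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two samples")
    d2 = dm.data**2
    n = len(labels)
    ss_total = d2.sum() / (2 * n)
    f_obs, r2 = _permanova_f(d2, labels, ss_total)

    n_total = _n_arrangements(labels)
    if n_total <= enumeration_limit:
        arrangements = _distinct_arrangements(labels)
        f_perm = np.array(
            [_permanova_f(d2, arr, ss_total)[0] for arr in arrangements]
        )
        p = float(np.mean(f_perm >= f_obs - _EPS))
        return PermutationTestResult(f_obs, p, n_total, "exact", r2)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_p, _ = _permanova_f(d2, rng.permutation(labels), ss_total)
        if f_p >= f_obs - _EPS:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermutationTestResult(f_obs, p, n_perm, "monte_carlo", r2)


def _centroid_distances(dm: DistanceMatrix, labels: np.ndarray) -> np.ndarray:
    """Distance from each sample to its group centroid in PCoA space,
    with Anderson's (2006) correction for negative eigenvalues."""
    d2 = dm.data**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    keep = np.abs(eigval) > 1e-10
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    coords = eigvec * np.sqrt(np.abs(eigval))
    sign = np.sign(eigval)
    z2 = np.zeros(n)
    for g in np.unique(labels):
        mask = labels == g
        centroid = coords[mask].mean(axis=0)
        delta2 = (coords[mask] - centroid) ** 2
        z2[mask] = delta2 @ sign
    return np.sqrt(np.clip(z2, 0.0, None))


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    ss_among = 0.0
    ss_within = 0.0
    n_groups = 0
    for g in np.unique(labels):
        group = values[labels == g]
        n_groups += 1
        ss_among += len(group) * (group.mean() - grand) ** 2
        ss_within += ((group - group.mean()) ** 2).sum()
    if ss_within == 0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / (n_groups - 1)) / (ss_within / (len(values) - n_groups))


def permdisp(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """Test for homogeneity of group dispersions.

    Computes each sample's distance to its group centroid in the
    principal-coordinate embedding, then permutes those distances across
    samples to build the null for the one-way F statistic.
    """
    labels = _as_labels(groups, dm.ids)
    uniques, counts = np.unique(labels, return_counts=True)
    if len(uniques) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two samples")
    z = _centroid_distances(dm, labels)
    f_obs = _anova_f(z, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _anova_f(z, rng.permutation(labels)) >= f_obs - _EPS:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermutationTestResult(f_obs, p, n_perm, "monte_carlo")


# ---------------------------------------------------------------------------
# indicator species analysis


def prevalence_filter(table: AsvTable, min_prevalence: float = 0.15) -> AsvTable:
    """Keep ASVs present in at least ``min_prevalence`` of samples."""
    frac = (table.counts >= 1).mean(axis=0)
    return table.subset_asvs(table.counts.columns[frac >= min_prevalence])


def indval_stat(presence: np.ndarray, mask1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Group-equalized indicator value for every taxon (two groups).

    ``B_g`` is the fraction of group-g samples containing the taxon
    (fidelity); ``A_g = B_g / (B_1 + B_2)`` is specificity equalized for
    group size; the statistic is ``max_g sqrt(A_g * B_g)``.  Returns
    (stat, best_group_index).
    """
    b1 = presence[mask1].mean(axis=0)
    b2 = presence[~mask1].mean(axis=0)
    total = b1 + b2
    with np.errstate(invalid="ignore", divide="ignore"):
        a1 = np.where(total > 0, b1 / total, 0.0)
        a2 = np.where(total > 0, b2 / total, 0.0)
    s1 = np.sqrt(a1 * b1)
    s2 = np.sqrt(a2 * b2)
    stat = np.maximum(s1, s2)
    return stat, (s2 > s1).astype(int)


def indval(
    table: AsvTable,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    stat_min: float = 0.7,
) -> pd.DataFrame:
    """Presence-absence IndVal.g for a two-group design, with BH-FDR.

    Returns one row per ASV: the preferred group, fidelity B, equalized
    specificity A, the statistic, the permutation p, the BH-adjusted q,
    and whether the ASV qualifies as an indicator (p < alpha and
    stat > stat_min).  More than two groups is unsupported.
    """
    labels = _as_labels(groups, table.sample_ids)
    uniques = np.unique(labels)
    if len(uniques) != 2:
        raise ValueError("indicator analysis supports exactly two groups")
    presence = table.presence().to_numpy()
    mask1 = labels == uniques[0]
    stat, best = indval_stat(presence, mask1)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(stat))
    for _ in range(n_perm):
        perm_stat, _ = indval_stat(presence, rng.permutation(mask1))
        exceed += perm_stat >= stat - _EPS
    p = (exceed + 1) / (n_perm + 1)
    q = bh_fdr(p)

    b1 = presence[mask1].mean(axis=0)
    b2 = presence[~mask1].mean(axis=0)
    b_best = np.where(best == 0, b1, b2)
    total = b1 + b2
    with np.errstate(invalid="ignore", divide="ignore"):
        a_best = np.where(total > 0, b_best / total, 0.0)
    return pd.DataFrame(
        {
            "group": np.asarray(uniques)[best],
            "A": a_best,
            "B": b_best,
            "stat": stat,
            "p_value": p,
            "q_value": q,
            "indicator": (p < alpha) & (stat > stat_min),
        },
        index=table.asv_ids,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
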