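"""Signed weighted co-expression network core.

Implements, from first principles, the module-detection stack used for
protein co-expression analysis: signed soft-threshold adjacency, scale-free
topology diagnostics, the topological overlap matrix (TOM), average-linkage
clustering, a hybrid dynamic tree cut with a medoid-style assignment stage,
module eigengenes (first principal component of the standardized module
submatrix), eigengene-correlation module merging, and module membership
(kME).  Modules are named by the conventional color sequence in decreasing
size, with grey reserved for unassigned proteins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

GREY = "grey"

# conventional module color order (decreasing module size)
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]


@dataclass
class NetworkParams:
    """Tuning knobs of the network/module stack (defaults follow common
    signed-WGCNA practice for proteomics)."""

    power: float = 2.0
    min_cluster_size: int = 30
    deep_split: int = 3
    pam_respects_dendro: bool = False
    merge_cut_height: float = 0.25
    kme_threshold: float = 0.8
    min_shared_samples: int = 3
    pam_slack: float = 0.5

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("power must be > 0")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must be in (0,1)")
        if not 0 < self.kme_threshold <= 1:
            raise ValueError("kme_threshold must be in (0,1]")
        if not 0 <= self.deep_split <= 4:
            raise ValueError("deep_split must be in 0..4")


@dataclass
class SoftThresholdReport:
    power: float
    scale_free_r2: float
    slope: float
    mean_connectivity: float


@dataclass
class EigengeneSet:
    """Eigengenes as a samples x modules frame (each column unit-norm),
    plus the variance fraction each explains in its module."""

    eigengenes: pd.DataFrame
    variance_explained: dict[str, float] = field(default_factory=dict)

    def modules(self) -> list[str]:
        return list(self.eigengenes.columns)


def pairwise_correlation(matrix: pd.DataFrame, min_periods: int = 3) -> pd.DataFrame:
    """Pearson correlation between protein profiles over pairwise-complete
    samples; pairs with fewer than ``min_periods`` shared observations get 0."""
    values = matrix.to_numpy(dtype=float)
    if not np.isnan(values).any():
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(values)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        return pd.DataFrame(corr, index=matrix.index, columns=matrix.index)
    corr = matrix.T.corr(min_periods=min_periods)
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def signed_adjacency(matrix: pd.DataFrame, beta: float, min_periods: int = 3) -> pd.DataFrame:
    """Signed adjacency a_ij = ((1 + cor)/2)^beta with unit diagonal."""
    if matrix.shape[1] < 3:
        raise ValueError("at least 3 samples are required")
    corr = pairwise_correlation(matrix, min_periods=min_periods)
    adj = ((1.0 + corr) / 2.0) ** beta
    np.fill_diagonal(adj.values, 1.0)
    return adj


def connectivity(adjacency: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    a = np.asarray(adjacency, dtype=float)
    return a.sum(axis=1) - np.diag(a)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit: regress log10 frequency on log10 mean
    connectivity over ``n_bins`` equal-width connectivity bins; returns
    (R^2, slope)."""
    k = np.asarray(k, dtype=float)
    if k.size < 2 or np.allclose(k, k[0]):
        warnings.warn("degenerate connectivity distribution; R^2 reported as 0")
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k = np.array([k[idx == b].mean() if (idx == b).any() else np.nan for b in range(n_bins)])
    freq = np.array([(idx == b).sum() for b in range(n_bins)], dtype=float) / k.size
    ok = (freq > 0) & np.isfinite(mean_k) & (mean_k > 0)
    if ok.sum() < 2:
        warnings.warn("fewer than 2 populated connectivity bins; R^2 reported as 0")
        return 0.0, 0.0
    fit = linregress(np.log10(mean_k[ok]), np.log10(freq[ok]))
    return float(fit.rvalue**2), float(fit.slope)


def soft_threshold_report(
    matrix: pd.DataFrame, powers: list[float], min_periods: int = 3
) -> list[SoftThresholdReport]:
    """Scale-free fit index and mean connectivity per candidate power."""
    if not powers:
        raise ValueError("powers must be nonempty")
    corr = pairwise_correlation(matrix, min_periods=min_periods)
    base = (1.0 + corr.to_numpy(dtype=float)) / 2.0
    np.fill_diagonal(base, 1.0)
    reports = []
    for beta in powers:
        adj = base**beta
        k = connectivity(adj)
        r2, slope = scale_free_fit(k)
        reports.append(
            SoftThresholdReport(
                power=float(beta),
                scale_free_r2=r2,
                slope=slope,
                mean_connectivity=float(k.mean()),
            )
        )
    return reports


def tom_similarity(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap ω_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 − a_ij)
    with l_ij = Σ_{u≠i,j} a_iu a_uj; ω_ii = 1."""
    a = np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a_od = a.copy()
    np.fill_diagonal(a_od, 0.0)
    l = a_od @ a_od
    k = a_od.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a_od
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = (l + a_od) / denom
    omega = np.nan_to_num(omega, nan=0.0)
    np.fill_diagonal(omega, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(omega, index=adjacency.index, columns=adjacency.columns)
    return omega


def tom_dissimilarity(adjacency: pd.DataFrame | np.ndarray):
    return 1.0 - tom_similarity(adjacency)


def cluster_tree(dissimilarity: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Average-linkage hierarchical clustering of a dissimilarity matrix;
    returns a scipy linkage matrix."""
    d = np.asarray(dissimilarity, dtype=float)
    if np.isnan(d).any():
        raise ValueError("dissimilarity contains NaN")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("dissimilarity diagonal must be zero")
    return linkage(squareform(d, checks=False), method="average")


# --- hybrid dynamic tree cut -------------------------------------------------

_DEEP_SPLIT_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)


def _core_size(branch_size: int, min_cluster_size: int) -> int:
    base = min_cluster_size // 2 + 1
    if base < branch_size:
        return base + int(math.sqrt(branch_size - base))
    return branch_size


class _Tree:
    """Flat arrays describing a scipy linkage tree of n leaves."""

    def __init__(self, Z: np.ndarray, n: int):
        self.n = n
        self.Z = Z
        self.height = np.concatenate([np.zeros(n), Z[:, 2]])
        self.leaves: list[list[int]] = [[i] for i in range(n)]
        self.merge_heights: list[list[float]] = [[] for _ in range(n)]
        for i in range(Z.shape[0]):
            a, b = int(Z[i, 0]), int(Z[i, 1])
            self.leaves.append(self.leaves[a] + self.leaves[b])
            self.merge_heights.append(
                sorted(self.merge_heights[a] + self.merge_heights[b] + [float(Z[i, 2])])
            )

    def children(self, node: int) -> tuple[int, int]:
        i = node - self.n
        return int(self.Z[i, 0]), int(self.Z[i, 1])

    def size(self, node: int) -> int:
        return len(self.leaves[node])

    def core_scatter(self, node: int, min_cluster_size: int) -> float:
        if node < self.n:
            return 0.0
        cs = _core_size(self.size(node), min_cluster_size)
        hs = self.merge_heights[node][: max(cs - 1, 1)]
        return float(np.mean(hs))


def dynamic_cut(
    dendrogram: np.ndarray,
    dissimilarity: pd.DataFrame | np.ndarray,
    params: NetworkParams | None = None,
) -> pd.Series:
    """Hybrid dynamic tree cut.

    Branches of the average-linkage tree are accepted as modules when they
    are large enough (``min_cluster_size``), tight enough (core scatter below
    a deep-split-dependent ceiling) and cleanly separated from their
    surroundings (merge gap above a deep-split-dependent floor).  Remaining
    proteins are assigned, ignoring dendrogram position, to the module with
    the smallest average dissimilarity — but only if they are no more
    dissimilar from it than a typical member pair — and are otherwise left
    grey.  Returns a protein -> color label series.
    """
    params = params or NetworkParams()
    if params.pam_respects_dendro:
        warnings.warn("pam_respects_dendro=True is not implemented; using False")
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    index = (
        dissimilarity.index
        if isinstance(dissimilarity, pd.DataFrame)
        else pd.RangeIndex(n)
    )
    if params.min_cluster_size > n:
        warnings.warn("min_cluster_size exceeds number of proteins; all grey")
        return pd.Series(GREY, index=index)

    Z = np.asarray(dendrogram, dtype=float)
    tree = _Tree(Z, n)
    heights = Z[:, 2]
    cut_height = 0.99 * float(heights.max())
    base = float(np.quantile(heights, 0.05))
    ms = _DEEP_SPLIT_CORE_SCATTER[params.deep_split]
    min_gap_rel = (1.0 - ms) * 3.0 / 4.0
    span = max(cut_height - base, 1e-12)
    max_abs_core_scatter = base + ms * span
    min_abs_gap = min_gap_rel * span

    # maximal subtrees entirely below the static cut height
    parent = np.full(2 * n - 1, -1)
    for i in range(Z.shape[0]):
        parent[int(Z[i, 0])] = n + i
        parent[int(Z[i, 1])] = n + i
    components = [
        node
        for node in range(2 * n - 1)
        if tree.height[node] <= cut_height
        and (parent[node] == -1 or tree.height[parent[node]] > cut_height)
    ]

    def qualifies(child: int, parent_height: float) -> bool:
        scatter = tree.core_scatter(child, params.min_cluster_size)
        return (
            tree.size(child) >= params.min_cluster_size
            and scatter <= max_abs_core_scatter
            and (parent_height - scatter) >= min_abs_gap
        )

    def split(node: int) -> list[int]:
        if node < n:
            return [node]
        left, right = tree.children(node)
        h = tree.height[node]
        if qualifies(left, h) or qualifies(right, h):
            return split(left) + split(right)
        return [node]

    candidates: list[int] = []
    for comp in components:
        candidates.extend(split(comp))

    labels = np.zeros(n, dtype=int)
    next_label = 1
    for node in candidates:
        if (
            tree.size(node) >= params.min_cluster_size
            and tree.core_scatter(node, params.min_cluster_size) <= max_abs_core_scatter
        ):
            labels[tree.leaves[node]] = next_label
            next_label += 1

    # medoid-style assignment of leftovers, ignoring dendrogram position.
    # A protein joins its nearest cluster only when its average dissimilarity
    # to that cluster sits in the cluster's neighborhood: below the midpoint
    # (pam_slack) between the cluster's own mean intra-cluster dissimilarity
    # and the matrix-wide mean dissimilarity.
    if next_label > 1:
        d_bar = float((d.sum() - np.trace(d)) / max(n * (n - 1), 1))
        cluster_members = {c: np.flatnonzero(labels == c) for c in range(1, next_label)}
        intra = {}
        for c, members in cluster_members.items():
            sub = d[np.ix_(members, members)]
            m = len(members)
            intra[c] = float(sub.sum() / (m * (m - 1))) if m > 1 else 0.0
        for i in np.flatnonzero(labels == 0):
            avg = {c: float(d[i, members].mean()) for c, members in cluster_members.items()}
            best = min(avg, key=lambda c: (avg[c], c))
            radius = intra[best] + params.pam_slack * max(d_bar - intra[best], 0.0)
            if avg[best] <= radius:
                labels[i] = best

    return assign_colors(pd.Series(labels, index=index))


def assign_colors(labels: pd.Series) -> pd.Series:
    """Map integer cluster labels to the color sequence by decreasing size
    (ties broken by first occurrence); 0 stays grey."""
    sizes: dict[int, int] = {}
    first_seen: dict[int, int] = {}
    for pos, lab in enumerate(labels):
        if lab == 0:
            continue
        sizes[lab] = sizes.get(lab, 0) + 1
        first_seen.setdefault(lab, pos)
    order = sorted(sizes, key=lambda c: (-sizes[c], first_seen[c]))
    if len(order) > len(MODULE_COLORS):
        raise ValueError("more modules than available color names")
    mapping = {lab: MODULE_COLORS[i] for i, lab in enumerate(order)}
    mapping[0] = GREY
    return labels.map(mapping)


def relabel_by_size(partition: pd.Series) -> pd.Series:
    """Re-issue color names so color order matches descending module size."""
    sizes: dict[str, int] = {}
    first_seen: dict[str, int] = {}
    for pos, lab in enumerate(partition):
        if lab == GREY:
            continue
        sizes[lab] = sizes.get(lab, 0) + 1
        first_seen.setdefault(lab, pos)
    order = sorted(sizes, key=lambda c: (-sizes[c], first_seen[c]))
    mapping = {lab: MODULE_COLORS[i] for i, lab in enumerate(order)}
    mapping[GREY] = GREY
    return partition.map(mapping)


# --- eigengenes, merging, membership ----------------------------------------


def _standardize_rows(sub: pd.DataFrame) -> np.ndarray:
    """Mean-impute missing cells per protein, then z-score each row
    (sample-size-1 denominator); all-missing or constant rows are dropped."""
    x = sub.to_numpy(dtype=float)
    keep = ~np.isnan(x).all(axis=1)
    if not keep.all():
        warnings.warn("proteins with all-missing profiles excluded from eigengene")
        x = x[keep]
    row_mean = np.nanmean(x, axis=1, keepdims=True)
    x = np.where(np.isnan(x), row_mean, x)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    ok = sd[:, 0] > 0
    x = (x[ok] - x[ok].mean(axis=1, keepdims=True)) / sd[ok]
    return x


def module_eigengenes(matrix: pd.DataFrame, partition: pd.Series) -> EigengeneSet:
    """First principal component per module.

    Each module's proteins are standardized over samples; the eigengene is
    the first right-singular vector of the resulting proteins x samples
    block (unit norm), with its sign oriented so that it correlates
    non-negatively with the module's average standardized profile.
    """
    eig = {}
    var_exp = {}
    for module in sorted(set(partition) - {GREY}):
        sub = matrix.loc[partition[partition == module].index]
        if len(sub) == 0:
            raise ValueError(f"module {module} is empty")
        x = _standardize_rows(sub)
        _, s, vt = np.linalg.svd(x, full_matrices=False)
        v = vt[0]
        avg = x.mean(axis=0)
        if np.dot(v, avg) < 0:
            v = -v
        eig[module] = v
        var_exp[module] = float(s[0] ** 2 / (s**2).sum())
    frame = pd.DataFrame(eig, index=matrix.columns)
    return EigengeneSet(eigengenes=frame, variance_explained=var_exp)


def merge_modules(
    matrix: pd.DataFrame,
    partition: pd.Series,
    eigengenes: EigengeneSet,
    merge_cut_height: float = 0.25,
) -> tuple[pd.Series, EigengeneSet]:
    """Merge modules whose eigengene dissimilarity (1 − cor) falls below
    ``merge_cut_height``, iterating until every non-grey eigengene pair is at
    least that dissimilar.  The largest module's color survives each merge;
    colors are re-issued by size at the end."""
    part = partition.copy()
    egs = eigengenes
    max_iter = max(len(egs.modules()), 1)
    for _ in range(max_iter):
        modules = egs.modules()
        if len(modules) < 2:
            break
        corr = egs.eigengenes.corr()
        diss = 1.0 - corr.to_numpy()
        np.fill_diagonal(diss, 0.0)
        Z = linkage(squareform(diss, checks=False), method="average")
        flat = fcluster(Z, t=np.nextafter(merge_cut_height, 0.0), criterion="distance")
        if len(set(flat)) == len(modules):
            break
        sizes = part.value_counts()
        for group in set(flat):
            members = [m for m, g in zip(modules, flat) if g == group]
            if len(members) < 2:
                continue
            target = max(members, key=lambda m: (sizes.get(m, 0), -modules.index(m)))
            part[part.isin(members)] = target
        egs = module_eigengenes(matrix, part)
    relabeled = relabel_by_size(part)
    egs = module_eigengenes(matrix, relabeled)
    return relabeled, egs


def module_membership(
    matrix: pd.DataFrame,
    eigengenes: EigengeneSet,
    partition: pd.Series,
    kme_threshold: float = 0.8,
    min_periods: int = 3,
) -> tuple[pd.DataFrame, set[str]]:
    """kME table (protein x module Pearson correlation with each eigengene,
    pairwise-complete) and the weighted-protein set: proteins whose kME with
    their OWN module's eigengene meets ``kme_threshold``."""
    kme = pd.DataFrame(index=matrix.index, columns=eigengenes.modules(), dtype=float)
    values = matrix.to_numpy(dtype=float)
    for module in eigengenes.modules():
        e = eigengenes.eigengenes[module].to_numpy()
        for i, acc in enumerate(matrix.index):
            x = values[i]
            mask = ~np.isnan(x)
            if mask.sum() < min_periods:
                continue
            xm = x[mask]
            em = e[mask]
            if xm.std() == 0 or em.std() == 0:
                continue
            kme.loc[acc, module] = float(np.corrcoef(xm, em)[0, 1])
    weighted = {
        acc
        for acc in matrix.index
        if partition[acc] != GREY
        and partition[acc] in kme.columns
        and pd.notna(kme.loc[acc, partition[acc]])
        and kme.loc[acc, partition[acc]] >= kme_threshold
    }
    return kme, weighted
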