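"""Spearman-distance average-linkage clustering with bootstrap support.

Genes are clustered on d = 1 - rho (Spearman) with UPGMA. Cluster
stability is assessed by resampling samples (columns) with replacement:
plain bootstrap probabilities (BP) as the fraction of replicate trees
containing each node's exact leaf set, and approximately-unbiased (AU)
p-values from a multiscale bootstrap in which the resample size is varied
over a grid of scale factors and the normal-quantile-transformed BP curve
is fitted by weighted least squares against (sqrt(r), 1/sqrt(r)).

Two UPGMA engines are provided: an exact implementation with documented
deterministic tie-breaking (used for reference trees and verified against
a brute-force oracle in the test suite) and scipy's C implementation
(used inside bootstrap loops; identical on tie-free input).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)

DEFAULT_SCALE_FACTORS = tuple(np.round(np.arange(0.5, 1.41, 0.1), 10))


class ClusteringError(ValueError):
    """Raised on invalid clustering inputs."""


# -- distances -------------------------------------------------------------


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return rankdata(values, axis=1, method="average")


def _spearman_from_ranks(ranks: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.nan_to_num(rho, nan=0.0)  # constant rows -> rho 0
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def spearman_distance_matrix(
    values: pd.DataFrame,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Pairwise distance d = 1 - Spearman rho between gene profiles.

    ``values`` is genes x samples. Ties are handled with average ranks.
    Constant genes (zero rank variance) are excluded with a warning.

    Raises
    ------
    ClusteringError
        With fewer than 3 samples, or if requested genes are missing.
    """
    if values.shape[1] < 3:
        raise ClusteringError("need >= 3 samples for rank correlation")
    if genes is not None:
        missing = [g for g in genes if g not in values.index]
        if missing:
            raise ClusteringError(f"genes absent from matrix: {missing[:10]}")
        values = values.loc[genes]
    arr = values.to_numpy(dtype=float)
    constant = np.ptp(arr, axis=1) == 0
    if constant.any():
        dropped = values.index[constant].tolist()
        warnings.warn(
            f"excluding {len(dropped)} constant gene(s) from distance matrix"
        )
        values = values.loc[~constant]
        arr = arr[~constant]
    rho = _spearman_from_ranks(_rank_rows(arr))
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=values.index, columns=values.index)


# -- trees -----------------------------------------------------------------


@dataclass
class ClusterTree:
    """UPGMA dendrogram with optional per-node support values.

    ``merges`` uses scipy linkage encoding: row k merges nodes
    ``left``/``right`` (indices < n are leaves, >= n internal) at
    ``height``, creating internal node ``n + k``.
    """

    leaves: list[str]
    merges: np.ndarray  # (n-1, 3): left, right, height
    bp: np.ndarray | None = None
    au: np.ndarray | None = None
    au_se: np.ndarray | None = None
    au_degenerate: np.ndarray | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def node_masks(self) -> list[int]:
        """Leaf-set bitmask per internal node, in merge order."""
        return _merge_masks(self.merges, self.n_leaves)

    def leaf_sets(self) -> list[frozenset[str]]:
        sets: list[frozenset[str]] = []
        for mask in self.node_masks():
            sets.append(
                frozenset(
                    self.leaves[i] for i in range(self.n_leaves) if mask >> i & 1
                )
            )
        return sets

    def heights(self) -> np.ndarray:
        return self.merges[:, 2].astype(float)

    def to_linkage(self) -> np.ndarray:
        """scipy-compatible (n-1, 4) linkage matrix."""
        n = self.n_leaves
        sizes = np.ones(2 * n - 1)
        z = np.zeros((n - 1, 4))
        for k, (left, right, height) in enumerate(self.merges):
            left, right = int(left), int(right)
            sizes[n + k] = sizes[left] + sizes[right]
            z[k] = (left, right, height, sizes[n + k])
        return z

    def to_newick(self, *, support: str | None = "au") -> str:
        """Newick string; internal node labels carry AU/BP when available."""
        n = self.n_leaves
        labels: dict[int, str] = {i: self.leaves[i] for i in range(n)}
        heights = {i: 0.0 for i in range(n)}
        for k, (left, right, height) in enumerate(self.merges):
            left, right = int(left), int(right)
            parts = []
            for child in (left, right):
                branch = max(height - heights[child], 0.0)
                parts.append(f"{labels[child]}:{branch:.6g}")
            node_label = ""
            if support == "au" and self.au is not None:
                node_label = f"{self.au[k]:.3f}"
            elif support == "bp" and self.bp is not None:
                node_label = f"{self.bp[k]:.3f}"
            labels[n + k] = f"({parts[0]},{parts[1]}){node_label}"
            heights[n + k] = float(height)
            del labels[left], labels[right]
        return labels[2 * n - 2] + ";"


def _merge_masks(merges: np.ndarray, n: int) -> list[int]:
    masks: list[int] = []
    for left, right, _ in merges:
        left, right = int(left), int(right)
        lm = (1 << left) if left < n else masks[left - n]
        rm = (1 << right) if right < n else masks[right - n]
        masks.append(lm | rm)
    return masks


def _validate_distance(dist: np.ndarray) -> None:
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ClusteringError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ClusteringError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-12):
        raise ClusteringError("distance matrix diagonal must be zero")


def average_linkage_tree(dist: pd.DataFrame) -> ClusterTree:
    """Exact UPGMA with deterministic tie-breaking.

    Inter-cluster distance is the arithmetic mean over cross pairs. When
    several pairs attain the minimum distance (within a 1e-9 tolerance, so
    floating-point summation noise cannot flip a tie), the pair whose
    clusters contain the alphabetically earliest leaves (compared as an
    index pair after sorting leaf ids) is merged first.

    Raises
    ------
    ClusteringError
        On non-symmetric input or fewer than 2 items.
    """
    labels = [str(x) for x in dist.index]
    d = dist.to_numpy(dtype=float).copy()
    _validate_distance(d)
    n = d.shape[0]
    if n < 2:
        raise ClusteringError("need >= 2 items to cluster")

    id_rank = {lab: r for r, lab in enumerate(sorted(labels))}
    # tie-break key per cluster: smallest id-rank among member leaves
    keys = [id_rank[lab] for lab in labels]
    sizes = np.ones(n)
    active = list(range(n))  # positions into d
    node_of = list(range(n))  # linkage node id per position
    merges = np.zeros((n - 1, 3))

    tol = 1e-9
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                value = d[i, j]
                ki, kj = sorted((keys[i], keys[j]))
                cand = (value, ki, kj, ai, bi)
                if (
                    best is None
                    or value < best[0] - tol
                    or (value <= best[0] + tol and (ki, kj) < best[1:3])
                ):
                    best = cand
        value, _, _, ai, bi = best
        i, j = active[ai], active[bi]
        # merged cluster occupies slot i
        for other in active:
            if other in (i, j):
                continue
            d[i, other] = d[other, i] = (
                sizes[i] * d[i, other] + sizes[j] * d[j, other]
            ) / (sizes[i] + sizes[j])
        merges[step] = (node_of[i], node_of[j], value)
        sizes[i] += sizes[j]
        keys[i] = min(keys[i], keys[j])
        node_of[i] = n + step
        active.pop(bi)

    return ClusterTree(leaves=labels, merges=merges)


def _fast_linkage(dist_condensed: np.ndarray) -> np.ndarray:
    z = _scipy_linkage(dist_condensed, method="average")
    return z[:, :3]


def tree_from_values(
    values: pd.DataFrame, *, engine: str = "exact"
) -> ClusterTree:
    """Spearman-distance UPGMA tree straight from a genes x samples matrix."""
    dist = spearman_distance_matrix(values)
    if engine == "exact":
        return average_linkage_tree(dist)
    condensed = squareform(dist.to_numpy(dtype=float), checks=False)
    return ClusterTree(
        leaves=[str(x) for x in dist.index], merges=_fast_linkage(condensed)
    )


# -- bootstrap support -----------------------------------------------------


def _bootstrap_counts(
    ranks_source: np.ndarray,
    ref_masks: list[int],
    nboot: int,
    sample_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Count replicate trees containing each reference node's leaf set."""
    n_genes, n_samples = ranks_source.shape
    ref_index = {mask: i for i, mask in enumerate(ref_masks)}
    counts = np.zeros(len(ref_masks))
    for _ in range(nboot):
        cols = rng.integers(0, n_samples, size=sample_size)
        resampled = ranks_source[:, cols]
        rho = _spearman_from_ranks(_rank_rows(resampled))
        dist = 1.0 - rho
        np.fill_diagonal(dist, 0.0)
        merges = _fast_linkage(squareform(dist, checks=False))
        for mask in _merge_masks(merges, n_genes):
            hit = ref_index.get(mask)
            if hit is not None:
                counts[hit] += 1
    return counts


def bootstrap_support(
    values: pd.DataFrame,
    tree: ClusterTree | None = None,
    *,
    nboot: int = 1000,
    seed: int = 0,
) -> ClusterTree:
    """Plain bootstrap probabilities for every internal node of the tree.

    Samples (columns) are resampled with replacement at the original size;
    BP(node) is the fraction of replicate UPGMA trees containing an
    internal node with the identical leaf set. Returns the tree with its
    ``bp`` array filled (a new tree is built when none is given).

    Raises
    ------
    ClusteringError
        If ``nboot < 1``.
    """
    if nboot < 1:
        raise ClusteringError("nboot must be >= 1")
    if tree is None:
        tree = tree_from_values(values)
    values = values.loc[tree.leaves]
    ranks_source = values.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    counts = _bootstrap_counts(
        ranks_source, tree.node_masks(), nboot, values.shape[1], rng
    )
    tree.bp = counts / nboot
    return tree


def au_pvalues(
    values: pd.DataFrame,
    tree: ClusterTree | None = None,
    *,
    scale_factors: tuple[float, ...] = DEFAULT_SCALE_FACTORS,
    nboot_per_scale: int = 100,
    seed: int = 0,
) -> ClusterTree:
    """Approximately-unbiased p-values via the multiscale bootstrap.

    For each scale factor r the columns are resampled with replacement at
    size max(3, round(r * n_samples)), giving BP_r per node. Per node the
    model z_r = v*sqrt(r) + c/sqrt(r), with z_r the standard-normal
    quantile of (1 - BP_r), v the signed distance and c the boundary
    curvature, is fitted by weighted least squares (weights = inverse
    asymptotic variance of z_r); then AU = 1 - Phi(v - c) and the standard
    error follows from the fit covariance. Nodes whose BP is 0 or 1 at
    every scale keep AU = BP with SE 0 and are flagged degenerate; nodes
    with fewer than 2 informative scales fall back to AU = BP at r = 1
    (flagged).
    """
    if len(scale_factors) < 2:
        raise ClusteringError("need >= 2 scale factors")
    if tree is None:
        tree = tree_from_values(values)
    values = values.loc[tree.leaves]
    ranks_source = values.to_numpy(dtype=float)
    n_samples = values.shape[1]
    masks = tree.node_masks()
    n_nodes = len(masks)

    rng = np.random.default_rng(seed)
    scales = np.asarray(scale_factors, dtype=float)
    bp_by_scale = np.zeros((len(scales), n_nodes))
    for si, r in enumerate(scales):
        size = max(3, int(round(r * n_samples)))
        counts = _bootstrap_counts(
            ranks_source, masks, nboot_per_scale, size, rng
        )
        bp_by_scale[si] = counts / nboot_per_scale

    # BP at (or nearest to) scale 1 doubles as the plain bootstrap value
    r1 = int(np.argmin(np.abs(scales - 1.0)))
    if tree.bp is None:
        tree.bp = bp_by_scale[r1].copy()

    au = np.zeros(n_nodes)
    se = np.zeros(n_nodes)
    degenerate = np.zeros(n_nodes, dtype=bool)
    for k in range(n_nodes):
        bps = bp_by_scale[:, k]
        usable = (bps > 0) & (bps < 1)
        if usable.sum() < 2:
            au[k] = bps[r1]
            se[k] = 0.0
            degenerate[k] = True
            continue
        r = scales[usable]
        bp = bps[usable]
        z = norm.ppf(1.0 - bp)
        # var(z) = var(BP) / phi(z)^2, var(BP) = BP(1-BP)/nboot
        weights = nboot_per_scale * norm.pdf(z) ** 2 / (bp * (1.0 - bp))
        design = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
        wdesign = design * weights[:, None]
        xtwx = design.T @ wdesign
        try:
            cov = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError:
            au[k] = bps[r1]
            degenerate[k] = True
            continue
        v_hat, c_hat = cov @ (wdesign.T @ z)
        au[k] = 1.0 - norm.cdf(v_hat - c_hat)
        grad_var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]  # var(v - c)
        se[k] = float(norm.pdf(v_hat - c_hat) * np.sqrt(max(grad_var, 0.0)))

    tree.au = au
    tree.au_se = se
    tree.au_degenerate = degenerate
    return tree


@dataclass(frozen=True)
class SignificantCluster:
    genes: frozenset[str]
    au: float
    bp: float


def significant_clusters(
    tree: ClusterTree, alpha: float = 0.95
) -> list[SignificantCluster]:
    """Maximal (non-nested) internal nodes with AU >= alpha.

    A passing node nested inside a passing ancestor is not reported.
    Clusters are returned largest-first.
    """
    if tree.au is None:
        raise ClusteringError("AU values not computed")
    masks = tree.node_masks()
    passing = [k for k in range(len(masks)) if tree.au[k] >= alpha]
    maximal: list[int] = []
    for k in sorted(passing, key=lambda k: -bin(masks[k]).count("1")):
        if not any(masks[k] & masks[m] == masks[k] for m in maximal):
            maximal.append(k)
    leaf_sets = tree.leaf_sets()
    bp = tree.bp if tree.bp is not None else np.zeros(len(masks))
    return [
        SignificantCluster(genes=leaf_sets[k], au=float(tree.au[k]), bp=float(bp[k]))
        for k in maximal
    ]


def support_table(tree: ClusterTree) -> pd.DataFrame:
    """Per-node TSV-ready table: size, AU, SE, BP, degeneracy, members."""
    leaf_sets = tree.leaf_sets()
    n_nodes = len(leaf_sets)

    def col(arr, default):
        return arr if arr is not None else np.full(n_nodes, default)

    return pd.DataFrame(
        {
            "node": np.arange(n_nodes),
            "size": [len(s) for s in leaf_sets],
            "height": tree.heights(),
            "au": col(tree.au, np.nan),
            "au_se": col(tree.au_se, np.nan),
            "bp": col(tree.bp, np.nan),
            "degenerate": col(tree.au_degenerate, False),
            "members": [";".join(sorted(s)) for s in leaf_sets],
        }
    )
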