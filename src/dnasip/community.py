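"""Community-ecology statistics for OTU count tables.

Equal-depth rarefaction (sampling without replacement), Bray-Curtis
dissimilarity on relative abundances, Shannon diversity, group-average
(UPGMA) dendrograms with newick export, nonmetric multidimensional
scaling (SMACOF with monotone regression, Kruskal stress-1) and the
one-way ANOSIM permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

VALID_ROLES = {"H", "L", "in-situ", "fraction"}


@dataclass
class OtuTable:
    """Samples × OTUs non-negative integer counts with sample metadata.

    ``counts`` rows are samples; ``sample_meta`` (same index) carries at
    least ``role`` ∈ {H, L, in-situ, fraction} plus treatment/timepoint
    where known; ``otu_meta`` optionally maps OTU id → taxonomy string.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    otu_meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("sample ids must be unique")
        if len(self.sample_meta) and not self.sample_meta.index.equals(self.counts.index):
            missing = set(self.counts.index) - set(self.sample_meta.index)
            if missing:
                raise ValueError(f"sample_meta missing samples {sorted(missing)}")
            self.sample_meta = self.sample_meta.loc[self.counts.index]

    def relative(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            bad = list(self.counts.index[totals == 0])
            raise ValueError(f"samples with zero total counts: {bad}")
        return self.counts.div(totals, axis=0)


@dataclass
class DissimilarityMatrix:
    """Symmetric dissimilarity matrix with sample labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        self.values = v

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def between(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def subsample_counts(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Rarefy every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    Sampling is multivariate hypergeometric, so retained rows sum to
    exactly ``depth`` and no count ever exceeds the original.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    keep = totals >= depth
    if not keep.all():
        dropped = list(table.counts.index[~keep])
        warnings.warn(f"dropping samples below depth {depth}: {dropped}", stacklevel=2)
    counts = table.counts.loc[keep]
    out = np.empty_like(counts.to_numpy())
    for i, row in enumerate(counts.to_numpy().astype(np.int64)):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    meta = table.sample_meta.loc[counts.index] if len(table.sample_meta) else table.sample_meta
    return OtuTable(
        counts=pd.DataFrame(out, index=counts.index, columns=counts.columns),
        sample_meta=meta,
        otu_meta=table.otu_meta,
    )


def bray_curtis_matrix(table: OtuTable, use_relative: bool = True) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    BC(a, b) = Σ|aᵢ − bᵢ| / Σ(aᵢ + bᵢ), computed on relative abundances
    by default (report similarity as 1 − BC).
    """
    if len(table.counts) < 2:
        raise ValueError("need at least 2 samples")
    data = table.relative() if use_relative else table.counts.astype(float)
    if not use_relative and (data.sum(axis=1) == 0).any():
        raise ValueError("sample with zero total")
    d = squareform(pdist(data.to_numpy(), metric="braycurtis"))
    return DissimilarityMatrix(labels=list(table.counts.index), values=d)


def shannon_index(counts: Sequence[float], base: float = np.e) -> float:
    """Shannon diversity H′ = −Σ pᵢ log pᵢ (natural log by default)."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("sample has no counts")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(base))


# ---------------------------------------------------------------------------
# UPGMA

@dataclass
class UpgmaTree:
    """Group-average dendrogram: scipy linkage plus labels."""

    labels: list[str]
    linkage: np.ndarray

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def two_group_cut(self) -> dict[str, int]:
        """Cut at the root into two groups; returns label → group (1/2)."""
        assign = hierarchy.fcluster(self.linkage, t=2, criterion="maxclust")
        return dict(zip(self.labels, map(int, assign)))

    def newick(self) -> str:
        """Newick string with branch lengths as height differences."""
        root = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = rec(root.left, root.dist)
        right = rec(root.right, root.dist)
        return f"({left},{right});"


def upgma_cluster(d: DissimilarityMatrix) -> UpgmaTree:
    """Agglomerative clustering with group-average (UPGMA) linkage.

    Labels are sorted lexicographically before linkage so equal-distance
    merges resolve deterministically.
    """
    if len(d.labels) < 2:
        raise ValueError("need at least 2 labels")
    order = np.argsort(np.asarray(d.labels, dtype=object))
    labels = [d.labels[i] for i in order]
    values = d.values[np.ix_(order, order)]
    Z = hierarchy.linkage(squareform(values, checks=False), method="average")
    return UpgmaTree(labels=labels, linkage=Z)


# ---------------------------------------------------------------------------
# NMDS

def _stress1(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = (dist**2).sum()
    if denom == 0:
        return np.inf
    return float(np.sqrt(((disp - dist) ** 2).sum() / denom))


def nmds_embed(
    d: DissimilarityMatrix,
    ndim: int = 2,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> tuple[pd.DataFrame, float]:
    """Nonmetric multidimensional scaling by SMACOF with monotone regression.

    Alternates a Guttman transform of the configuration with isotonic
    regression of the configuration distances on the rank order of the
    input dissimilarities (primary approach to ties), minimising Kruskal
    stress-1 = sqrt(Σ(d̂ᵢⱼ − dᵢⱼ*)² / Σdᵢⱼ*²).  The best of ``restarts``
    seeded random starts is returned.

    Returns (coordinates DataFrame indexed by label, stress).
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("need at least 3 samples for an ordination")
    diss = d.condensed()
    if np.allclose(diss, 0):
        raise ValueError("degenerate dissimilarity matrix (all zeros)")
    order = np.argsort(diss, kind="stable")
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression(increasing=True)
    best_X, best_stress = None, np.inf
    iu = np.triu_indices(n, k=1)
    for _ in range(max(1, restarts)):
        X = rng.normal(size=(n, ndim))
        prev = np.inf
        for _it in range(max_iter):
            dist = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
            dvec = dist[iu]
            scale = dvec.mean() or 1.0
            disp = iso.fit_transform(np.arange(len(diss)), dvec[order] / scale)
            dhat = np.empty_like(disp)
            dhat[order] = disp * scale
            stress = _stress1(dvec, dhat)
            if prev - stress < tol:
                break
            prev = stress
            # Guttman transform toward the disparities
            W = np.zeros((n, n))
            W[iu] = np.where(dvec > 0, dhat / np.maximum(dvec, 1e-12), 0.0)
            W = W + W.T
            B = -W
            np.fill_diagonal(B, W.sum(axis=1))
            X = B @ X / n
        if stress < best_stress:
            best_stress, best_X = stress, X.copy()
    coords = pd.DataFrame(
        best_X, index=d.labels, columns=[f"NMDS{i + 1}" for i in range(ndim)]
    )
    return coords, best_stress


def nmds_stress_path(
    d: DissimilarityMatrix, ndim: int = 2, seed: int = 0, max_iter: int = 100
) -> list[float]:
    """Stress-1 value after each iteration of a single SMACOF run
    (diagnostic; used to verify monotone convergence)."""
    n = len(d.labels)
    diss = d.condensed()
    order = np.argsort(diss, kind="stable")
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression(increasing=True)
    iu = np.triu_indices(n, k=1)
    X = rng.normal(size=(n, ndim))
    path: list[float] = []
    for _ in range(max_iter):
        dist = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        dvec = dist[iu]
        scale = dvec.mean() or 1.0
        disp = iso.fit_transform(np.arange(len(diss)), dvec[order] / scale)
        dhat = np.empty_like(disp)
        dhat[order] = disp * scale
        path.append(_stress1(dvec, dhat))
        W = np.zeros((n, n))
        W[iu] = np.where(dvec > 0, dhat / np.maximum(dvec, 1e-12), 0.0)
        W = W + W.T
        B = -W
        np.fill_diagonal(B, W.sum(axis=1))
        X = B @ X / n
    return path


# ---------------------------------------------------------------------------
# ANOSIM

def anosim_test(
    d: DissimilarityMatrix,
    groups: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """One-way analysis of similarities.

    Ranks all pairwise dissimilarities (mid-ranks on ties) and computes
    R = (mean between-group rank − mean within-group rank) / (M/2) with
    M = n(n−1)/2.  The p-value permutes group labels ``n_perm`` times
    and includes the observed statistic: p = (1 + #{R* ≥ R}) / (1 + n_perm).
    """
    labels = np.asarray(groups)
    n = len(d.labels)
    if len(labels) != n:
        raise ValueError("groups length must match matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"groups with fewer than 2 members: {small}")
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d.values[iu])
    M = len(ranks)

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (M / 2.0)

    observed = r_stat(labels)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(labels) for _ in range(n_perm)])
    within_all = perms[:, iu[0]] == perms[:, iu[1]]  # n_perm × M
    between_mean = np.where(~within_all, ranks, 0).sum(1) / (~within_all).sum(1)
    within_mean = np.where(within_all, ranks, 0).sum(1) / within_all.sum(1)
    r_perm = (between_mean - within_mean) / (M / 2.0)
    p = (1.0 + np.sum(r_perm >= observed)) / (1.0 + n_perm)
    return float(observed), float(p)


# ---------------------------------------------------------------------------
# I/O

def write_newick(tree: UpgmaTree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def write_dissimilarity(d: DissimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(d.values, index=d.labels, columns=d.labels).to_csv(path, sep="\t")
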