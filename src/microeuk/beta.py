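"""Between-sample dissimilarity, ordination, clustering, and permutation tests.

Bray-Curtis runs on square-root-transformed relative abundances (the
transform damps the influence of a few very abundant OTUs on the similarity
structure); unweighted UniFrac compares presence/absence tip sets on the
shared phylogeny. ANOSIM and the simple Mantel test use seeded permutation
null distributions with the conservative p = (1 + #{stat_perm >= stat_obs})
/ (n_perm + 1).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .io import CountTable, DistanceMatrix, PhyloTree, distance_matrix, tree_edge_matrix

logger = logging.getLogger("microeuk")

__all__ = [
    "bray_curtis",
    "unweighted_unifrac",
    "upgma",
    "pcoa",
    "anosim",
    "mantel",
]


def bray_curtis(table: CountTable, transform: str | None = "sqrt") -> DistanceMatrix:
    """Bray-Curtis dissimilarity on (optionally sqrt-transformed) relative
    abundances: d(x, y) = sum|u_i - v_i| / sum(u_i + v_i)."""
    totals = table.library_sizes().to_numpy()
    if (totals == 0).any():
        raise ValueError("zero-sum sample in Bray-Curtis input")
    rel = table.counts.to_numpy().T / totals[:, None]
    if transform == "sqrt":
        rel = np.sqrt(rel)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    condensed = pdist(rel, metric="braycurtis")
    return distance_matrix(squareform(condensed), table.sample_ids)


def unweighted_unifrac(
    table: CountTable, tree: PhyloTree, prune: bool = False
) -> DistanceMatrix:
    """Unweighted UniFrac: per pair, branch length unique to one sample's tip
    set over branch length covered by the union of both tip sets."""
    tips = {t.name for t in tree.tips()}
    observed = set(table.counts.index[(table.counts.sum(axis=1) > 0)])
    missing = observed - tips
    if missing and not prune:
        raise ValueError(f"observed OTUs not in tree: {sorted(missing)[:5]}")
    lengths, masks = tree_edge_matrix(tree, table.otu_ids)
    presence = table.counts.to_numpy() > 0  # otus x samples
    covered = (masks.astype(np.int8) @ presence.astype(np.int8)) > 0  # edges x samples
    n = len(table.sample_ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = covered[:, i] | covered[:, j]
            shared = covered[:, i] & covered[:, j]
            denom = lengths[union].sum()
            if denom == 0:
                d = 0.0
            else:
                d = float(lengths[union & ~shared].sum() / denom)
            out[i, j] = out[j, i] = d
    return distance_matrix(out, table.sample_ids)


def _linkage_to_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a SciPy linkage matrix as Newick with ultrametric heights."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    newicks = {i: labels[i] for i in range(n)}
    for k, (a, b, dist, _) in enumerate(z):
        a, b = int(a), int(b)
        h = dist / 2.0
        left = f"{newicks[a]}:{h - heights[a]:.10g}"
        right = f"{newicks[b]}:{h - heights[b]:.10g}"
        node = n + k
        newicks[node] = f"({left},{right})"
        heights[node] = h
    return newicks[n + len(z) - 1] + ";"


def upgma(dm: DistanceMatrix, method: str = "average") -> str:
    """Agglomerative clustering of a dissimilarity matrix; returns Newick.

    Group-average (UPGMA) linkage by default; ``complete`` and ``single``
    available. Node heights are half the merge dissimilarity so that
    tip-to-tip path lengths reproduce the cophenetic distances.
    """
    if len(dm.ids) < 2:
        raise ValueError("need >= 2 samples to cluster")
    z = linkage(dm.condensed_form(), method=method)
    return _linkage_to_newick(z, list(dm.ids))


def pcoa(dm: DistanceMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal Coordinate Analysis (classical scaling).

    Eigendecomposition of -1/2 J D^2 J with J the centering matrix.
    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for the ``k``
    leading positive eigenvalues; negative eigenvalues are reported in the
    returned eigenvalue vector but not corrected.
    """
    d = dm.data
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > 1e-12 * max(abs(evals[0]), 1.0)).sum())
    if k > n_pos:
        logger.warning("pcoa: only %d positive eigenvalues, truncating k=%d", n_pos, k)
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    df = pd.DataFrame(coords, index=list(dm.ids),
                      columns=[f"PC{i + 1}" for i in range(k)])
    return df, evals


def _condensed_group_masks(groups: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(len(groups), k=1)
    return groups[iu[0]] == groups[iu[1]]


def anosim(
    dm: DistanceMatrix,
    groups: Sequence,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Analysis of similarities.

    Ranks all pairwise dissimilarities (average ranks for ties) and computes
    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2; significance by permuting group labels.
    """
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 members")
    ranks = rankdata(dm.condensed_form())
    m = ranks.size

    def r_stat(g: np.ndarray) -> float:
        within = _condensed_group_masks(g)
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    r_obs = r_stat(groups)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(groups)) >= r_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return float(r_obs), float(p)


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Simple Mantel test: Pearson correlation of the lower triangles, with
    significance by jointly permuting rows+columns of the second matrix.
    The permutation p-value is one-sided (r_perm >= r_obs), like ANOSIM's."""
    if list(dm1.ids) != list(dm2.ids):
        raise ValueError("distance matrices must share sample ids and order")
    x = dm1.condensed_form()
    d2 = dm2.data
    y = dm2.condensed_form()
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("mantel: zero-variance distances, correlation undefined")
        return float("nan"), float("nan")

    def corr(yv: np.ndarray) -> float:
        return float(np.corrcoef(x, yv)[0, 1])

    r_obs = corr(y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = d2[np.ix_(perm, perm)][iu]
        if corr(yp) >= r_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return r_obs, float(p)
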