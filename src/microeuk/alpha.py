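"""Per-sample (alpha) diversity panel.

Notation: ``S_obs`` observed OTUs, ``F_i`` number of OTUs seen exactly ``i``
times, ``p_i`` relative abundances. Shannon entropy is reported in bits
(log2) by default: on subsampled libraries of ~1,000 OTUs published values
above ln-scale's ceiling (e.g. 8.06 for 1,092 OTUs > ln(1092) ~ 7.0) are only
attainable in base 2. Simpson is reported both as dominance D = sum p_i^2 and
its inverse. Faith PD sums branch lengths of the minimal subtree spanning the
observed tips and the root.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountTable, PhyloTree, tree_edge_matrix

__all__ = [
    "chao1",
    "ace",
    "shannon",
    "simpson",
    "faith_pd",
    "alpha_panel",
]


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.size and (np.any(arr < 0) or np.any(arr != np.floor(arr))):
        raise ValueError("counts must be non-negative integers")
    return arr.astype(np.int64)


def observed_otus(counts) -> int:
    return int(np.count_nonzero(_as_counts(counts)))


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate.

    Bias-corrected form (default) S_obs + F1(F1-1)/(2(F2+1)) is defined even
    when no doubletons exist; the classic form S_obs + F1^2/(2 F2) is
    available for comparison and returns inf when F2 = 0 with F1 > 0.
    """
    arr = _as_counts(counts)
    if arr.sum() == 0:
        return float("nan")
    s_obs = np.count_nonzero(arr)
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f1 and not f2:
        return float("inf")
    return s_obs + (f1 * f1 / (2.0 * f2) if f1 else 0.0)


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based Coverage Estimator with rare/abundant split at 10.

    When sample coverage of the rare class is zero (every rare OTU is a
    singleton) the estimator is undefined and the bias-corrected Chao1 is
    returned instead.
    """
    arr = _as_counts(counts)
    if arr.sum() == 0:
        return float("nan")
    rare = arr[(arr > 0) & (arr <= rare_cutoff)]
    s_abund = int((arr > rare_cutoff).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return chao1(arr)
    sum_i = sum(i * (i - 1) * int((rare == i).sum()) for i in range(1, rare_cutoff + 1))
    gamma2 = 0.0
    if n_rare > 1:
        gamma2 = max((s_rare / c_ace) * sum_i / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def shannon(counts, base: float = 2) -> float:
    """Shannon entropy H = -sum p_i log_base p_i over p_i > 0."""
    arr = _as_counts(counts)
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero sample")
    p = arr[arr > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def simpson(counts) -> tuple[float, float]:
    """Simpson dominance D = sum p_i^2 and its inverse 1/D."""
    arr = _as_counts(counts)
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero sample")
    p = arr / total
    d = float((p * p).sum())
    return d, 1.0 / d


def faith_pd(
    counts,
    otu_ids: Sequence[str],
    tree: PhyloTree,
    prune: bool = False,
) -> float:
    """Faith's phylogenetic diversity of one sample.

    Total branch length of the minimal subtree connecting the observed tips,
    including the path to the root. Observed OTUs missing from the tree raise
    unless ``prune`` is set, in which case they are ignored.
    """
    arr = _as_counts(counts)
    present = {o for o, c in zip(otu_ids, arr) if c > 0}
    tips = {t.name for t in tree.tips()}
    missing = present - tips
    if missing:
        if not prune:
            raise ValueError(f"observed OTUs not in tree: {sorted(missing)[:5]}")
        present -= missing
    lengths, masks = tree_edge_matrix(tree, sorted(present))
    if masks.size == 0:
        return 0.0
    return float(lengths[masks.any(axis=1)].sum())


def alpha_panel(
    table: CountTable,
    tree: PhyloTree | None = None,
    prune: bool = False,
    shannon_base: float = 2,
) -> pd.DataFrame:
    """Per-sample diversity panel over an already-rarefied table.

    Columns follow the survey's summary-table ordering: observed OTUs, Chao1,
    ACE, Shannon, Simpson dominance, inverse Simpson, and Faith PD (when a
    tree is given).
    """
    rows = []
    lengths = masks = None
    if tree is not None:
        lengths, masks = tree_edge_matrix(tree, table.otu_ids)
        tips = {t.name for t in tree.tips()}
        missing = [o for o in table.otu_ids if o not in tips]
        if missing and not prune:
            raise ValueError(f"OTUs not in tree: {missing[:5]}")
    for s in table.sample_ids:
        col = table.sample(s).to_numpy()
        d, inv_d = simpson(col) if col.sum() else (float("nan"),) * 2
        row = {
            "sample_id": s,
            "observed_otus": observed_otus(col),
            "chao1": chao1(col),
            "ace": ace(col),
            "shannon": shannon(col, base=shannon_base) if col.sum() else float("nan"),
            "simpson_D": d,
            "inverse_simpson": inv_d,
        }
        if tree is not None:
            covered = masks @ (col > 0) > 0
            row["faith_pd"] = float(lengths[covered].sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
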