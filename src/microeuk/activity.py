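"""RNA:DNA ratios as a proxy of relative metabolic activity.

For each co-extracted DNA/RNA library pair (one site x depth), only OTUs
present in BOTH libraries enter the analysis (the shared-OTU rule, which also
guarantees every ratio is finite without pseudo-counts). Each shared OTU
contributes one observation: the quotient of its RNA relative abundance over
its DNA relative abundance — at equal rarefied depth this is exactly the raw
count quotient. Observations are pooled by (major group, depth stratum); the
arithmetic mean per cell is the group's relative-activity proxy, and strata
are compared pairwise with a one-way two-level ANOVA F-test (equivalent to a
pooled-variance two-sided t-test).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import STRATA, CountTable, Lineage, SampleRecord

logger = logging.getLogger("microeuk")

__all__ = [
    "RatioObservation",
    "shared_otu_filter",
    "otu_ratios",
    "ratio_observations",
    "group_activity",
    "stratum_tests",
    "rna_dna_scatter",
]

_STRATUM_PAIRS = tuple(itertools.combinations(STRATA, 2))  # (S,M), (S,D), (M,D)


@dataclass(frozen=True)
class RatioObservation:
    """One shared OTU's RNA:DNA ratio within one library pair."""

    otu_id: str
    pair_id: tuple[str, float]
    major_group: str | None
    stratum: str
    rna_count: int
    dna_count: int
    ratio: float

    def __post_init__(self):
        if self.rna_count < 1 or self.dna_count < 1:
            raise ValueError("shared-OTU rule violated: both counts must be >= 1")
        if not (self.ratio > 0 and np.isfinite(self.ratio)):
            raise ValueError(f"ratio must be positive and finite, got {self.ratio}")


def shared_otu_filter(dna_col: pd.Series, rna_col: pd.Series) -> list[str]:
    """OTUs with at least one read in both the DNA and the RNA library."""
    shared = dna_col.index[(dna_col >= 1) & (rna_col >= 1)]
    return list(shared)


def otu_ratios(
    dna_col: pd.Series,
    rna_col: pd.Series,
    pair_id: tuple[str, float],
    stratum: str,
    taxonomy: Mapping[str, Lineage],
    require_equal_depth: bool = True,
) -> list[RatioObservation]:
    """Per-OTU RNA:DNA relative-abundance ratios for one library pair.

    ratio_i = (rna_i / rna_total) / (dna_i / dna_total); with both libraries
    rarefied to the same depth this reduces to rna_i / dna_i exactly.
    """
    dna_total, rna_total = int(dna_col.sum()), int(rna_col.sum())
    if require_equal_depth and dna_total != rna_total:
        raise ValueError(
            f"pair {pair_id}: library depths differ ({dna_total} vs {rna_total}); "
            "rarefy to a uniform depth first"
        )
    shared = shared_otu_filter(dna_col, rna_col)
    if not shared:
        logger.warning("pair %s: no shared OTUs, skipped", pair_id)
        return []
    obs = []
    for otu in shared:
        d, r = int(dna_col[otu]), int(rna_col[otu])
        ratio = (r / rna_total) / (d / dna_total)
        obs.append(
            RatioObservation(
                otu_id=otu,
                pair_id=pair_id,
                major_group=taxonomy[otu].major_group if otu in taxonomy else None,
                stratum=stratum,
                rna_count=r,
                dna_count=d,
                ratio=ratio,
            )
        )
    return obs


def ratio_observations(
    table: CountTable,
    pairs: Sequence[tuple[str, str]],
    metadata: Mapping[str, SampleRecord],
    taxonomy: Mapping[str, Lineage],
) -> pd.DataFrame:
    """Pool per-OTU ratio observations over all library pairs.

    Returns a tidy frame with one row per shared OTU per pair: otu_id, site,
    depth_m, stratum, major_group, dna_count, rna_count, ratio.
    """
    rows = []
    for dna_id, rna_id in pairs:
        rec = metadata[dna_id]
        obs = otu_ratios(
            table.sample(dna_id), table.sample(rna_id),
            rec.pair_id, rec.stratum, taxonomy,
        )
        for o in obs:
            rows.append(
                {
                    "otu_id": o.otu_id,
                    "site": rec.site,
                    "depth_m": rec.depth_m,
                    "stratum": o.stratum,
                    "major_group": o.major_group,
                    "dna_sample": dna_id,
                    "rna_sample": rna_id,
                    "dna_count": o.dna_count,
                    "rna_count": o.rna_count,
                    "ratio": o.ratio,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "otu_id", "site", "depth_m", "stratum", "major_group",
            "dna_sample", "rna_sample", "dna_count", "rna_count", "ratio",
        ],
    )
    return df


def stratum_tests(
    observations: pd.DataFrame,
    alpha: float = 0.05,
    log_ratios: bool = False,
) -> pd.DataFrame:
    """Pairwise stratum comparisons of pooled per-OTU ratios, per group.

    For each major group and each stratum pair, a one-way two-level ANOVA
    F-test on the pooled observations (identical to a two-sided
    pooled-variance t-test). Strata with fewer than 2 observations yield a
    missing p-value with a warning. ``log_ratios`` tests log-transformed
    ratios instead (ratios are right-skewed).
    """
    rows = []
    for group, sub in observations.groupby("major_group", dropna=False):
        vals = {
            s: sub.loc[sub["stratum"] == s, "ratio"].to_numpy() for s in STRATA
        }
        if log_ratios:
            vals = {s: np.log(v) for s, v in vals.items()}
        for a, b in _STRATUM_PAIRS:
            if len(vals[a]) < 2 or len(vals[b]) < 2:
                logger.warning(
                    "stratum_tests: %s %s-%s has a stratum with <2 observations",
                    group, a, b,
                )
                p = float("nan")
            elif np.ptp(np.concatenate([vals[a], vals[b]])) == 0:
                p = 1.0  # identical values: F = 0
            else:
                p = float(stats.f_oneway(vals[a], vals[b]).pvalue)
            rows.append(
                {
                    "major_group": group,
                    "comparison": f"{a}-{b}",
                    "p_value": p,
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                }
            )
    return pd.DataFrame(rows)


def group_activity(
    observations: pd.DataFrame,
    alpha: float = 0.05,
    per_sample_means: bool = False,
) -> pd.DataFrame:
    """Mean RNA:DNA ratio per (major group, stratum) with pairwise p-values.

    The pooling unit is the OTU-within-pair observation; ``per_sample_means``
    first averages within each library pair and pools those means instead.
    Output rows are one per major group with columns shallow/middle/deep mean
    ratios, per-cell observation counts, and the three pairwise p-values.
    """
    obs = observations
    if per_sample_means:
        obs = (
            observations.groupby(["major_group", "stratum", "site", "depth_m"],
                                 dropna=False, as_index=False)
            .agg(ratio=("ratio", "mean"))
        )
    tests = stratum_tests(obs, alpha=alpha)
    rows = []
    for group, sub in obs.groupby("major_group", dropna=False):
        row: dict = {"major_group": group}
        for s in STRATA:
            vals = sub.loc[sub["stratum"] == s, "ratio"]
            row[f"mean_{s}"] = float(vals.mean()) if len(vals) else float("nan")
            row[f"n_{s}"] = int(len(vals))
        tsub = tests[tests["major_group"].isna()] if pd.isna(group) else \
            tests[tests["major_group"] == group]
        for a, b in _STRATUM_PAIRS:
            match = tsub.loc[tsub["comparison"] == f"{a}-{b}", "p_value"]
            row[f"p_{a}_{b}"] = float(match.iloc[0]) if len(match) else float("nan")
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values("major_group", na_position="last").reset_index(drop=True)


def rna_dna_scatter(
    table: CountTable,
    pairs: Sequence[tuple[str, str]],
    metadata: Mapping[str, SampleRecord],
    taxonomy: Mapping[str, Lineage],
) -> pd.DataFrame:
    """Per-OTU (DNA, RNA) relative-abundance records for identity-line plots.

    One row per shared OTU per pair, annotated with its major group and a
    flag for points above the 1:1 line (ratio > 1).
    """
    obs = ratio_observations(table, pairs, metadata, taxonomy)
    if obs.empty:
        return obs.assign(dna_rel=[], rna_rel=[], above_line=[])
    totals = table.library_sizes()
    obs = obs.assign(
        dna_rel=obs["dna_count"].to_numpy()
        / totals[obs["dna_sample"]].to_numpy(),
        rna_rel=obs["rna_count"].to_numpy()
        / totals[obs["rna_sample"]].to_numpy(),
        above_line=obs["ratio"] > 1,
    )
    return obs
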