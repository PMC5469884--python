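"""Table-level filtering and rarefaction to a uniform sequencing depth.

Order of operations in the study design: remove OTUs affiliated with Metazoa
or Unassigned, remove singleton reads, then rarefy every library down to the
smallest remaining library size (20,204 reads in the original survey) so that
richness and ratio statistics are comparable across samples.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    DNA,
    RNA,
    CountTable,
    Lineage,
    SampleRecord,
    round_half_up,
    validate_taxonomy_cover,
)

logger = logging.getLogger("microeuk")


def remove_taxa(
    table: CountTable,
    taxonomy: Mapping[str, Lineage],
    labels: set[str] = frozenset({"Metazoa", "Unassigned"}),
) -> tuple[CountTable, pd.Series]:
    """Drop every OTU whose supergroup is in ``labels``.

    Returns the filtered table and the per-sample removed-read percentage
    (one decimal, half-up), mirroring how read accounting is reported.
    """
    if not labels:
        logger.warning("remove_taxa called with empty label set; no-op")
        return table.copy(), pd.Series(0.0, index=table.sample_ids)
    validate_taxonomy_cover(table, taxonomy)
    drop = [o for o in table.otu_ids if taxonomy[o].supergroup in labels]
    keep = [o for o in table.otu_ids if taxonomy[o].supergroup not in labels]
    totals = table.library_sizes().astype(float)
    removed = table.counts.loc[drop].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = (removed / totals * 100.0).fillna(0.0)
    pct = pct.map(lambda x: round_half_up(x, 1))
    logger.info("remove_taxa: dropped %d/%d OTUs (%s)", len(drop), table.shape[0],
                ",".join(sorted(labels)))
    return table.select_otus(keep), pct


def remove_singletons(table: CountTable, scope: str = "per_sample") -> CountTable:
    """Remove singleton reads.

    ``per_sample`` zeroes every cell equal to 1 (dereplication happens within
    each library); ``global`` drops OTUs whose total across all samples is 1.
    OTUs left with no reads anywhere are dropped from the table.
    """
    counts = table.counts.copy()
    if scope == "per_sample":
        counts[counts == 1] = 0
    elif scope == "global":
        counts = counts[counts.sum(axis=1) != 1]
    else:
        raise ValueError(f"unknown singleton scope {scope!r}")
    nonempty = counts.sum(axis=1) > 0
    if (~nonempty).any():
        logger.info("remove_singletons: %d OTUs emptied and dropped", int((~nonempty).sum()))
    return CountTable(counts[nonempty])


def min_library_size(table: CountTable) -> tuple[int, str]:
    """Smallest per-sample read total and its sample id (lexicographic ties)."""
    totals = table.library_sizes()
    if totals.empty:
        raise ValueError("empty table")
    m = int(totals.min())
    argmin = min(s for s, t in totals.items() if t == m)
    return m, argmin


def rarefy(
    table: CountTable,
    depth: int,
    seed: int | np.random.Generator,
    return_dropped: bool = False,
) -> CountTable | tuple[CountTable, list[str]]:
    """Subsample every library WITHOUT replacement to exactly ``depth`` reads.

    One multivariate-hypergeometric draw per sample, deterministic given the
    seed. Samples whose library is below ``depth`` are dropped with a warning
    rather than raising.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    totals = table.library_sizes()
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    if dropped:
        logger.warning("rarefy: dropping %d samples below depth %d: %s",
                       len(dropped), depth, ", ".join(dropped))
    kept = [s for s in table.sample_ids if totals[s] >= depth]
    out = {}
    for s in kept:
        col = table.counts[s].to_numpy()
        if totals[s] == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    rarefied = CountTable(pd.DataFrame(out, index=table.otu_ids, columns=kept))
    if return_dropped:
        return rarefied, dropped
    return rarefied


def pair_libraries(
    table: CountTable, metadata: Mapping[str, SampleRecord]
) -> list[tuple[str, str]]:
    """Match DNA and RNA libraries co-extracted from the same (site, depth).

    Returns (dna_sample_id, rna_sample_id) pairs sorted by (site, depth).
    Unpaired samples are logged and excluded; two libraries of the same acid
    at one key is an error.
    """
    if not metadata:
        logger.warning("pair_libraries: empty metadata, no pairs")
        return []
    missing = [s for s in table.sample_ids if s not in metadata]
    if missing:
        raise ValueError(f"metadata missing for samples: {missing}")
    by_key: dict[tuple[str, float], dict[str, str]] = {}
    for s in table.sample_ids:
        rec = metadata[s]
        slot = by_key.setdefault(rec.pair_id, {})
        if rec.acid in slot:
            raise ValueError(
                f"two {rec.acid} samples at {rec.pair_id}: {slot[rec.acid]}, {s}"
            )
        slot[rec.acid] = s
    pairs = []
    for key in sorted(by_key):
        slot = by_key[key]
        if DNA in slot and RNA in slot:
            pairs.append((slot[DNA], slot[RNA]))
        else:
            logger.info("pair_libraries: unpaired sample at %s (%s only)",
                        key, next(iter(slot)))
    return pairs
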