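"""Core data types and file formats for the paired DNA/RNA community pipeline.

The pipeline's central object is an integer OTU x sample count table; around
it sit per-sample metadata (site, depth, nucleic-acid source), a ranked
PR2-style taxonomy per OTU, and a rooted branch-length-bearing phylogeny over
OTU tips. On-disk formats are plain TSV (canonical), the BIOM v1 sparse JSON
dialect, and Newick.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import skbio
from skbio import TreeNode

logger = logging.getLogger("microeuk")

#: nucleic-acid sources
DNA = "DNA"
RNA = "RNA"

#: water-layer strata, ordered surface -> bottom
STRATA = ("shallow", "middle", "deep")

#: stratum boundaries (m): shallow <= 100 < middle <= 600 < deep
SHALLOW_MAX_M = 100.0
MIDDLE_MAX_M = 600.0

#: closed vocabulary of top-rank eukaryote clades, plus the two labels that
#: are screened out before protist-only analyses
SUPERGROUPS = frozenset(
    {
        "Alveolata",
        "Rhizaria",
        "Stramenopiles",
        "Opisthokonta",
        "Excavata",
        "Amoebozoa",
        "Hacrobia",
        "Archaeplastida",
        "Apusozoa",
        "Picozoa",
        "Metazoa",
        "Unassigned",
    }
)


class FormatError(ValueError):
    """Raised when an input file violates its dialect or an invariant."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching hand-formatted percentages."""
    scale = 10.0**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------


class CountTable:
    """Integer OTU x sample count matrix with aligned, unique identifiers.

    Parameters
    ----------
    counts
        DataFrame with OTU ids as the index and sample ids as columns.
        Values must be non-negative integers (or integral floats).
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            raise FormatError("duplicate OTU ids")
        if counts.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise FormatError("counts must be integral")
        if values.size and (values < 0).any():
            raise FormatError("counts must be non-negative")
        self._df = counts.astype(np.int64)
        self._df.index = self._df.index.astype(str)
        self._df.columns = self._df.columns.astype(str)

    # -- accessors ----------------------------------------------------------

    @property
    def otu_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def counts(self) -> pd.DataFrame:
        return self._df

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def library_sizes(self) -> pd.Series:
        """Per-sample read totals."""
        return self._df.sum(axis=0)

    def sample(self, sample_id: str) -> pd.Series:
        return self._df[sample_id]

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        return CountTable(self._df[list(sample_ids)])

    def select_otus(self, otu_ids: Sequence[str]) -> "CountTable":
        return CountTable(self._df.loc[list(otu_ids)])

    def copy(self) -> "CountTable":
        return CountTable(self._df.copy())

    def equals(self, other: "CountTable") -> bool:
        return self._df.equals(other._df)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountTable({self.shape[0]} OTUs x {self.shape[1]} samples)"

    # -- TSV dialect: first column OTU id, header row sample ids ------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if df.index.has_duplicates:
            raise FormatError(f"{path}: duplicate OTU ids")
        try:
            return cls(df)
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc

    def to_tsv(self, path: str | Path) -> None:
        out = self._df.copy()
        out.index.name = "otu_id"
        out.to_csv(path, sep="\t")

    # -- BIOM v1 sparse JSON dialect ----------------------------------------

    @classmethod
    def from_biom_json(cls, path: str | Path) -> "CountTable":
        with open(path) as fh:
            doc = json.load(fh)
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(otu_ids), len(sample_ids)), dtype=np.int64)
        for i, j, v in doc["data"]:
            if v != int(v):
                raise FormatError(f"{path}: non-integer count {v}")
            mat[int(i), int(j)] = int(v)
        return cls(pd.DataFrame(mat, index=otu_ids, columns=sample_ids))

    def to_biom_json(self, path: str | Path, table_id: str = "microeuk") -> None:
        mat = self._df.to_numpy()
        rows, cols = np.nonzero(mat)
        doc = {
            "id": table_id,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": list(mat.shape),
            "rows": [{"id": o, "metadata": None} for o in self.otu_ids],
            "columns": [{"id": s, "metadata": None} for s in self.sample_ids],
            "data": [[int(i), int(j), int(mat[i, j])] for i, j in zip(rows, cols)],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, sort_keys=True)


def read_count_table(path: str | Path, format: str = "tsv") -> CountTable:
    """Read an OTU count table in the TSV or BIOM sparse-JSON dialect."""
    if format == "tsv":
        return CountTable.from_tsv(path)
    if format in ("biom-json", "biom"):
        return CountTable.from_biom_json(path)
    raise ValueError(f"unknown table format: {format!r}")


def write_count_table(table: CountTable, path: str | Path, format: str = "tsv") -> None:
    if format == "tsv":
        table.to_tsv(path)
    elif format in ("biom-json", "biom"):
        table.to_biom_json(path)
    else:
        raise ValueError(f"unknown table format: {format!r}")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


def assign_stratum(depth_m: float) -> str:
    """Map a sampling depth (m) to its water-layer stratum.

    Boundaries sit at 100 m and 600 m, which cleanly separate the study
    design's enumerated depths (shallow 5-75 m, middle 200-500 m, deep
    1,000-3,900 m) while remaining total over any positive depth.
    """
    if not depth_m > 0:
        raise ValueError(f"depth must be positive, got {depth_m}")
    if depth_m <= SHALLOW_MAX_M:
        return "shallow"
    if depth_m <= MIDDLE_MAX_M:
        return "middle"
    return "deep"


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata with derived stratum and DNA/RNA pair key."""

    sample_id: str
    site: str
    depth_m: float
    acid: str
    stratum: str = field(init=False)
    pair_id: tuple[str, float] = field(init=False)

    def __post_init__(self):
        if self.acid not in (DNA, RNA):
            raise ValueError(f"acid must be DNA or RNA, got {self.acid!r}")
        object.__setattr__(self, "stratum", assign_stratum(self.depth_m))
        object.__setattr__(self, "pair_id", (self.site, float(self.depth_m)))


def read_metadata(path: str | Path) -> dict[str, SampleRecord]:
    """Read sample metadata TSV (columns sample_id, site, depth_m, acid).

    Duplicate sample ids or duplicate (site, depth, acid) keys are rejected
    rather than merged.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "site", "depth_m", "acid"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: metadata requires columns {sorted(required)}")
    records: dict[str, SampleRecord] = {}
    seen_keys: set[tuple] = set()
    for row in df.itertuples(index=False):
        rec = SampleRecord(row.sample_id, row.site, float(row.depth_m), row.acid)
        if rec.sample_id in records:
            raise FormatError(f"{path}: duplicate sample id {rec.sample_id}")
        key = (rec.site, rec.depth_m, rec.acid)
        if key in seen_keys:
            raise FormatError(f"{path}: duplicate sample key {key}")
        seen_keys.add(key)
        records[rec.sample_id] = rec
    return records


def write_metadata(records: Mapping[str, SampleRecord], path: str | Path) -> None:
    rows = [
        {"sample_id": r.sample_id, "site": r.site, "depth_m": r.depth_m, "acid": r.acid}
        for r in records.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Lineage:
    """Ranked PR2-style taxonomy for one OTU.

    ``supergroup`` is the second rank (the rank below Eukaryota);
    ``major_group`` is resolved by case-insensitive substring matching of an
    ordered pattern table against the lineage, first match wins, ``None`` if
    nothing matches.
    """

    otu_id: str
    ranks: tuple[str, ...]
    major_group: str | None = None

    @property
    def supergroup(self) -> str:
        # Metazoa sits below Opisthokonta in PR2 but is screened as its own
        # top-level label, as are entirely unassigned lineages.
        if any(r == "Metazoa" for r in self.ranks[:3]):
            return "Metazoa"
        if any(r.lower() == "unassigned" for r in self.ranks[:2]):
            return "Unassigned"
        return self.ranks[1]


def load_major_group_map(path: str | Path | None = None) -> list[tuple[str, str]]:
    """Load the ordered (pattern, major_group) table; ships with the package.

    The file is user-editable because PR2 rank spellings vary by version.
    """
    if path is None:
        src = resources.files("microeuk.data").joinpath("major_groups.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    mapping = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pattern, group = line.split("\t")
        mapping.append((pattern.lower(), group))
    return mapping


def resolve_major_group(
    ranks: Sequence[str], mapping: Sequence[tuple[str, str]]
) -> str | None:
    joined = ";".join(ranks).lower()
    for pattern, group in mapping:
        if pattern in joined:
            return group
    return None


def read_taxonomy(
    path: str | Path, mapping: Sequence[tuple[str, str]] | None = None
) -> dict[str, Lineage]:
    """Read a taxonomy TSV (otu_id TAB semicolon-separated lineage)."""
    if mapping is None:
        mapping = load_major_group_map()
    lineages: dict[str, Lineage] = {}
    with open(path) as fh:
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            try:
                otu_id, lineage_str = raw.split("\t")[:2]
            except ValueError as exc:
                raise FormatError(f"{path}: malformed row {raw!r}") from exc
            if otu_id in lineages:
                raise FormatError(f"{path}: repeated OTU id {otu_id}")
            ranks = tuple(r.strip() for r in lineage_str.split(";") if r.strip())
            if len(ranks) < 2:
                raise FormatError(f"{path}: fewer than 2 ranks for {otu_id}")
            lineages[otu_id] = Lineage(otu_id, ranks, resolve_major_group(ranks, mapping))
    return lineages


def write_taxonomy(lineages: Mapping[str, Lineage], path: str | Path) -> None:
    with open(path, "w") as fh:
        for otu_id, lin in lineages.items():
            fh.write(f"{otu_id}\t{';'.join(lin.ranks)}\n")


def validate_taxonomy_cover(table: CountTable, taxonomy: Mapping[str, Lineage]) -> None:
    """Every OTU used downstream must carry a lineage."""
    missing = [o for o in table.otu_ids if o not in taxonomy]
    if missing:
        raise FormatError(
            f"{len(missing)} OTUs lack a taxonomy entry (first: {missing[0]})"
        )


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

#: rooted, branch-length-bearing tree over OTU tips
PhyloTree = TreeNode


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted Newick tree; missing branch lengths become 0."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise FormatError(f"{path}: unparseable Newick: {exc}") from exc
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise FormatError(f"{path}: negative branch length on {node.name}")
    if n_missing:
        logger.warning("%s: %d missing branch lengths treated as 0", path, n_missing)
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise FormatError(f"{path}: duplicate tip labels")
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def total_branch_length(tree: TreeNode) -> float:
    return sum(n.length or 0.0 for n in tree.traverse(include_self=False))


def tree_edge_matrix(
    tree: TreeNode, tip_order: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Edge lengths and edge x tip incidence for vectorised PD / UniFrac.

    Returns ``(lengths, masks)`` where ``lengths[e]`` is the branch length of
    edge ``e`` (every non-root node contributes its stem edge) and
    ``masks[e, i]`` is True iff tip ``tip_order[i]`` lies below edge ``e``.
    Tips of the tree absent from ``tip_order`` simply yield empty columns.
    """
    tip_index = {name: i for i, name in enumerate(tip_order)}
    lengths: list[float] = []
    masks: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        mask = np.zeros(len(tip_order), dtype=bool)
        if node.is_tip():
            idx = tip_index.get(node.name)
            if idx is not None:
                mask[idx] = True
        else:
            for child in node.children:
                mask |= below[id(child)]
        below[id(node)] = mask
        if node.parent is not None:
            lengths.append(node.length or 0.0)
            masks.append(mask)
    return np.asarray(lengths, dtype=float), np.asarray(masks, dtype=bool)


def prune_to_tips(tree: TreeNode, keep: Iterable[str]) -> TreeNode:
    """Shear a tree down to the given tip set (copy; original untouched)."""
    return tree.shear(list(keep))


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

#: symmetric, hollow sample x sample dissimilarity matrix
DistanceMatrix = skbio.DistanceMatrix


def distance_matrix(values: np.ndarray, sample_ids: Sequence[str]) -> DistanceMatrix:
    """Build a validated DistanceMatrix (symmetric, zero diagonal, >= 0)."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative dissimilarity")
    return skbio.DistanceMatrix(arr, ids=list(sample_ids))


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return skbio.DistanceMatrix(df.to_numpy(), ids=list(df.index))
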