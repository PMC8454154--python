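"""Readers, writers and global filtering for OTU-table based datasets.

The central container is :class:`OtuTable`, a thin wrapper around a
``samples x OTUs`` integer count matrix with stable identifier order.
All downstream stages (diversity, ordination, neutral-model fitting,
networks) consume tables that have passed through the two global
preprocessing steps used throughout the pipeline:

1. :func:`filter_low_count_otus` — drop OTUs with fewer than ``min_total``
   reads summed over *all* samples (soils and animals alike);
2. :func:`rarefy` — seeded subsampling without replacement to a common
   depth, discarding samples that are too shallow.

Presence/detection downstream always means "count >= 1 in the
post-rarefaction table".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

#: Taxonomy labels treated as "unknown" (microbial dark matter) at any rank.
UNKNOWN_MARKERS = frozenset(
    {
        "unknown",
        "unassigned",
        "ambiguous taxa",
        "ambiguous_taxa",
        "uncultured",
        "uncultured bacterium",
        "uncultured_bacterium",
        "na",
        "",
    }
)

#: Canonical 7-rank lineage order.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


def is_unknown_label(label: str | None) -> bool:
    """True if a taxonomy label denotes an unidentified taxon.

    Matching is case-insensitive after stripping surrounding whitespace;
    missing labels (None/NaN) count as unknown.
    """
    if label is None or (isinstance(label, float) and np.isnan(label)):
        return True
    return str(label).strip().lower() in UNKNOWN_MARKERS


@dataclass
class OtuTable:
    """Sample x OTU count matrix with ordered, unique identifiers."""

    counts: np.ndarray  # (n_samples, n_otus) non-negative integers
    sample_ids: list[str]
    otu_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts).astype(np.int64)
            if not np.allclose(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"OTU {self.otu_ids[j]!r}"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        for name, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            seen: set[str] = set()
            for x in ids:
                if x in seen:
                    raise ValueError(f"duplicate {name} identifier: {x!r}")
                seen.add(x)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError("counts shape does not match identifier lists")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OtuTable":
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def otu_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalized counts; all-zero rows stay zero."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        totals[totals == 0] = 1.0
        return self.counts / totals

    def select_samples(self, ids: list[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in ids]
        return OtuTable(self.counts[idx], list(ids), list(self.otu_ids))

    def select_otus(self, ids: list[str]) -> "OtuTable":
        pos = {o: j for j, o in enumerate(self.otu_ids)}
        idx = [pos[o] for o in ids]
        return OtuTable(self.counts[:, idx], list(self.sample_ids), list(ids))


@dataclass
class SampleMetadata:
    """Per-sample host/site annotations driving every grouping.

    ``delta15N_animal`` is NaN for soil samples; ``delta15N_litter`` is the
    site-level plant-litter baseline used to adjust animal values.
    """

    frame: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("sample_type", "species", "site", "landuse")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        if self.frame.index.has_duplicates:
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        # litter delta15N must be constant within a site
        if "delta15N_litter" in self.frame.columns:
            per_site = self.frame.groupby("site")["delta15N_litter"].nunique(dropna=True)
            bad = per_site[per_site > 1]
            if len(bad):
                raise ValueError(f"litter delta15N varies within site {bad.index[0]!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    def soil_sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index[self.frame["sample_type"] == "soil"]]

    def faunal_sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index[self.frame["sample_type"] != "soil"]]

    def group_of(self, sample_id: str) -> str:
        return str(self.frame.loc[sample_id, "sample_type"])

    def aligned_to(self, table: OtuTable) -> "SampleMetadata":
        missing = [s for s in table.sample_ids if s not in self.frame.index]
        if missing:
            raise ValueError(f"metadata missing samples: {missing[:5]}")
        return SampleMetadata(self.frame.loc[table.sample_ids].copy())


class TaxonomyTable:
    """otu_id -> 7-rank lineage; OTUs absent from the map are fully unknown."""

    def __init__(self, lineages: dict[str, list[str]]):
        self.lineages = {
            str(o): list(ranks) + [""] * (len(RANKS) - len(ranks))
            for o, ranks in lineages.items()
        }

    def rank_label(self, otu_id: str, rank: str) -> str:
        """Label of ``otu_id`` at ``rank``; '' when absent/unresolved."""
        i = RANKS.index(rank)
        lineage = self.lineages.get(str(otu_id))
        if lineage is None:
            return ""
        return lineage[i].strip()

    def is_unknown_at(self, otu_id: str, rank: str) -> bool:
        return is_unknown_label(self.rank_label(otu_id, rank))

    def deepest_resolved(self, otu_id: str) -> str:
        """Deepest non-unknown rank label, or 'unknown' if none."""
        lineage = self.lineages.get(str(otu_id))
        if lineage is None:
            return "unknown"
        for label in reversed(lineage):
            if not is_unknown_label(label):
                return label.strip()
        return "unknown"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path, format: str = "tsv", transposed: bool = False) -> OtuTable:
    """Read an OTU table.

    TSV dialect: tab-separated, UTF-8, first column = OTU id, header row =
    sample ids (i.e. stored OTUs-as-rows; the in-memory orientation is
    samples x OTUs).  ``transposed=True`` flips the stored orientation
    explicitly; orientation is never guessed.

    BIOM-JSON: the classic dense/sparse JSON serialization ("format":
    "Biological Observation Matrix ...").
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        mat = np.empty(df.shape, dtype=np.int64)
        for j, col in enumerate(df.columns):
            for i, val in enumerate(df[col]):
                try:
                    x = int(float(val))
                    if float(val) != x:
                        raise ValueError
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric count {val!r} at row {df.index[i]!r}, "
                        f"column {col!r}"
                    ) from None
                if x < 0:
                    raise ValueError(
                        f"negative count {val!r} at row {df.index[i]!r}, "
                        f"column {col!r}"
                    )
                mat[i, j] = x
        if transposed:
            return OtuTable(mat, list(df.index), list(df.columns))
        return OtuTable(mat.T, list(df.columns), list(df.index))
    if format == "biom-json":
        doc = json.loads(path.read_text())
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(otu_ids), len(sample_ids)), dtype=np.int64)
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = int(v)
        else:
            mat[:] = np.asarray(doc["data"], dtype=np.int64)
        return OtuTable(mat.T, sample_ids, otu_ids)
    raise ValueError(f"unsupported format {format!r}")


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write TSV with OTUs as rows (round-trips with :func:`read_otu_table`)."""
    df = pd.DataFrame(table.counts.T, index=table.otu_ids, columns=table.sample_ids)
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read 'otu_id TAB semicolon-joined lineage' TSV (header optional)."""
    lineages: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            otu, _, lineage = line.partition("\t")
            if line_no == 0 and otu.lower() in {"otu_id", "#otu id", "otu"}:
                continue
            lineages[otu] = [part.strip() for part in lineage.split(";")]
    return TaxonomyTable(lineages)


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("otu_id\tlineage\n")
        for otu, lineage in tax.lineages.items():
            fh.write(f"{otu}\t{';'.join(lineage)}\n")


def read_metadata(path: str | Path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    out = meta.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_tree(path: str | Path) -> TreeNode:
    tree = TreeNode.read(str(path))
    for node in tree.traverse():
        if node.length is not None and not np.isfinite(node.length):
            raise ValueError("non-finite branch length in tree")
        if node.length is not None and node.length < 0:
            raise ValueError("negative branch length in tree")
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path))


# ---------------------------------------------------------------------------
# Global filters
# ---------------------------------------------------------------------------

def filter_low_count_otus(table: OtuTable, min_total: int = 100) -> OtuTable:
    """Remove OTUs with fewer than ``min_total`` reads summed over all samples.

    An OTU is retained iff its total across every sample (soils and animals)
    is >= ``min_total``; the sample set is unchanged.  Default 100 reads.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = table.otu_sums() >= min_total
    return OtuTable(
        table.counts[:, keep],
        list(table.sample_ids),
        [o for o, k in zip(table.otu_ids, keep) if k],
    )


def rarefy(
    table: OtuTable, depth: int, seed: int | np.random.Generator = 0
) -> tuple[OtuTable, list[str]]:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped and their identifiers
    returned as the second element.  Subsampling is multivariate
    hypergeometric, deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    kept_rows: list[np.ndarray] = []
    kept_ids: list[str] = []
    discarded: list[str] = []
    for i, sid in enumerate(table.sample_ids):
        row = table.counts[i]
        total = int(row.sum())
        if total < depth:
            discarded.append(sid)
            continue
        if total == depth:
            kept_rows.append(row.copy())
        else:
            kept_rows.append(rng.multivariate_hypergeometric(row, depth))
        kept_ids.append(sid)
    counts = (
        np.vstack(kept_rows) if kept_rows else np.zeros((0, table.n_otus), dtype=np.int64)
    )
    return OtuTable(counts, kept_ids, list(table.otu_ids)), discarded
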