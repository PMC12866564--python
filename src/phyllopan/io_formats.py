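"""Readers and writers for the tabular dialects the pipeline touches.

Supported dialects:

* OrthoFinder ``Orthogroups.GeneCount.tsv`` — orthogroups as rows, one
  column per isolate, optional trailing ``Total`` column that is
  validated and dropped. Internally the matrix is transposed to
  isolates x orthogroups because every statistic groups by isolate.
* eggNOG-mapper ``.annotations`` — ``#``-prefixed comment lines, columns
  addressed by name (``query``, ``COG_category``, ``KEGG_ko``), ``-`` as
  the missing value, KO entries like ``ko:K00001,ko:K00002``.
* Plain metadata TSV with one row per isolate.
* Pathway definitions as a 3-column TSV (id, name, definition string).
* ASV/genus abundance tables (samples x taxa counts) plus a
  sample-to-year mapping.

All identifiers are opaque, case-sensitive strings. Result tables are
written with a ``#``-prefixed provenance header; readers skip any
leading ``#`` lines so outputs round-trip.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"

#: Isolation-source vocabulary of the study design; extend via
#: ``allow_new_sources`` when reading metadata.
DEFAULT_SOURCES = ("leaf", "flower", "soil", "human", "water")


class FormatError(ValueError):
    """A file violated the dialect it claims to be in."""


@dataclass
class OrthogroupMatrix:
    """Isolates x orthogroups non-negative integer gene counts.

    ``counts`` is indexed by isolate id with one column per orthogroup.
    ``unassigned`` holds per-isolate counts of genes not placed in any
    orthogroup (defaults to zero; OrthoFinder reports them separately).
    """

    counts: pd.DataFrame
    unassigned: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise FormatError("duplicate isolate ids")
        if self.counts.columns.has_duplicates:
            raise FormatError("duplicate orthogroup ids")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative gene counts")
        if self.unassigned is None:
            object.__setattr__(
                self, "unassigned", pd.Series(0, index=self.counts.index, dtype=int)
            )
        else:
            self.unassigned = self.unassigned.reindex(self.counts.index).fillna(0).astype(int)

    @property
    def isolate_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def assigned_genes(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def total_genes(self) -> int:
        return self.assigned_genes + int(self.unassigned.sum())


@dataclass
class AbundanceTable:
    """Samples x taxa counts with a per-sample year label."""

    counts: pd.DataFrame
    sample_year: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise FormatError("duplicate sample or taxon ids")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative abundance counts")
        self.sample_year = self.sample_year.reindex(self.counts.index)
        if self.sample_year.isna().any():
            missing = list(self.sample_year.index[self.sample_year.isna()])
            raise FormatError(f"samples without a year: {missing}")


def _open_skipping_comments(path: str | Path) -> io.StringIO:
    with open(path, encoding="utf-8") as handle:
        lines = [ln for ln in handle if not ln.startswith("#")]
    return io.StringIO("".join(lines))


def read_genecount_table(path: str | Path) -> OrthogroupMatrix:
    """Read an OrthoFinder ``Orthogroups.GeneCount.tsv`` file.

    Validates the optional ``Total`` column against the row sum (hard
    error naming the offending orthogroup) and drops it; transposes to
    isolates x orthogroups.
    """
    df = pd.read_csv(_open_skipping_comments(path), sep="\t", dtype=str)
    if df.columns[0] != "Orthogroup":
        raise FormatError(
            f"{path}: first column must be 'Orthogroup', found {df.columns[0]!r}"
        )
    og_ids = df["Orthogroup"]
    if og_ids.duplicated().any():
        dups = sorted(og_ids[og_ids.duplicated()].unique())
        raise FormatError(f"{path}: duplicate orthogroup ids {dups}")
    body = df.set_index("Orthogroup")
    try:
        body = body.astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer gene count cell ({exc})") from exc
    if "Total" in body.columns:
        totals = body.pop("Total")
        row_sums = body.sum(axis=1)
        bad = row_sums.index[row_sums != totals]
        if len(bad):
            raise FormatError(
                f"{path}: Total column mismatch for orthogroup(s) {list(bad)}"
            )
    counts = body.T.rename_axis(index=None, columns=None)
    return OrthogroupMatrix(counts=counts)


def write_genecount_table(matrix: OrthogroupMatrix, path: str | Path,
                          provenance: str | None = None) -> None:
    df = matrix.counts.T.copy()
    df["Total"] = df.sum(axis=1)
    df.index.name = "Orthogroup"
    with open(path, "w", encoding="utf-8") as handle:
        if provenance:
            handle.write(f"# {provenance}\n")
        df.to_csv(handle, sep="\t")


_REQUIRED_ANNOTATION_COLUMNS = ("query", "COG_category", "KEGG_ko")


def _split_set(value: str, strip_prefix: str = "") -> frozenset[str]:
    if value in ("-", "", "nan"):
        return frozenset()
    items = [v.strip() for v in value.split(",") if v.strip() and v.strip() != "-"]
    if strip_prefix:
        items = [v[len(strip_prefix):] if v.startswith(strip_prefix) else v for v in items]
    return frozenset(items)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read an eggNOG-mapper ``.annotations`` table into a gene map.

    Returns a DataFrame with columns ``gene_id``, ``isolate_id``,
    ``orthogroup_id``, ``cog`` (frozenset of single letters) and ``kos``
    (frozenset of KO ids, ``ko:`` prefixes stripped). Multi-letter COG
    strings like ``GQ`` split into letter sets; ``-`` means empty.

    Standard eggNOG output carries no isolate or orthogroup mapping;
    optional ``isolate`` and ``orthogroup`` columns are honoured when
    present (the simulator writes them), otherwise the isolate is taken
    as the gene-id prefix before the first underscore and the orthogroup
    is :data:`UNASSIGNED`.
    """
    buf = _open_skipping_comments(path)
    text = buf.getvalue()
    if not text.strip():
        logger.warning("%s: annotation file has no data rows", path)
        return pd.DataFrame(
            columns=["gene_id", "isolate_id", "orthogroup_id", "cog", "kos"]
        )
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str).fillna("-")
    missing = [c for c in _REQUIRED_ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    out = pd.DataFrame({"gene_id": df["query"]})
    if "isolate" in df.columns:
        out["isolate_id"] = df["isolate"]
    else:
        out["isolate_id"] = df["query"].str.split("_", n=1).str[0]
    if "orthogroup" in df.columns:
        out["orthogroup_id"] = df["orthogroup"].replace("-", UNASSIGNED)
    else:
        out["orthogroup_id"] = UNASSIGNED
    cog = df["COG_category"].str.replace(",", "", regex=False).str.strip()
    out["cog"] = [
        frozenset() if v in ("-", "") else frozenset(v) for v in cog
    ]
    out["kos"] = [_split_set(v, strip_prefix="ko:") for v in df["KEGG_ko"]]
    dup = out.duplicated(subset=["isolate_id", "gene_id"])
    if dup.any():
        raise FormatError(f"{path}: duplicate gene ids within an isolate")
    return out


def write_annotations(ann: pd.DataFrame, path: str | Path,
                      provenance: str | None = None) -> None:
    """Write a gene map back out in the eggNOG-style dialect."""
    rows = pd.DataFrame({
        "query": ann["gene_id"],
        "isolate": ann["isolate_id"],
        "orthogroup": ann["orthogroup_id"].replace(UNASSIGNED, "-"),
        "COG_category": ["".join(sorted(s)) or "-" for s in ann["cog"]],
        "KEGG_ko": [
            ",".join("ko:" + k for k in sorted(s)) or "-" for s in ann["kos"]
        ],
    })
    with open(path, "w", encoding="utf-8") as handle:
        if provenance:
            handle.write(f"# {provenance}\n")
        rows.to_csv(handle, sep="\t", index=False)


_METADATA_COLUMNS = ("isolate_id", "genus", "species", "source", "year", "cluster")


@dataclass
class MetadataTable:
    """Per-isolate genus / species / source / year / cluster labels.

    ``source_vocabulary`` defaults to the labels observed in the table;
    passing an explicit vocabulary (as :func:`read_metadata` does with
    the study's declared sources) enforces it.
    """

    table: pd.DataFrame
    source_vocabulary: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = sorted(self.table.index[self.table.index.duplicated()].unique())
            raise FormatError(f"duplicate isolate ids {dups}")
        if self.source_vocabulary is None:
            self.source_vocabulary = tuple(dict.fromkeys(self.table["source"]))
        unknown = set(self.table["source"]) - set(self.source_vocabulary)
        if unknown:
            raise FormatError(
                f"source label(s) {sorted(unknown)} not in vocabulary "
                f"{list(self.source_vocabulary)}"
            )

    @property
    def isolate_ids(self) -> list[str]:
        return list(self.table.index)

    def genus(self) -> pd.Series:
        return self.table["genus"]

    def source(self) -> pd.Series:
        return self.table["source"]


def read_metadata(path: str | Path, allow_new_sources: bool = False) -> MetadataTable:
    df = pd.read_csv(_open_skipping_comments(path), sep="\t", dtype=str)
    if "isolate_id" not in df.columns or "source" not in df.columns:
        raise FormatError(
            f"{path}: metadata needs 'isolate_id' and 'source'; found {list(df.columns)}"
        )
    for col in _METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = "-"
    df = df[list(_METADATA_COLUMNS)].set_index("isolate_id")
    vocab: tuple[str, ...] = DEFAULT_SOURCES
    if allow_new_sources:
        vocab = tuple(dict.fromkeys(list(DEFAULT_SOURCES) + sorted(set(df["source"]))))
    return MetadataTable(df, source_vocabulary=vocab)


def write_metadata(meta: MetadataTable, path: str | Path,
                   provenance: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        if provenance:
            handle.write(f"# {provenance}\n")
        meta.table.reset_index().to_csv(handle, sep="\t", index=False)


def read_pathway_definitions(path: str | Path) -> pd.DataFrame:
    """3-column TSV: pathway_id, name, definition string."""
    df = pd.read_csv(_open_skipping_comments(path), sep="\t", dtype=str)
    needed = {"pathway_id", "name", "definition"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(needed)}")
    if df["pathway_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate pathway ids")
    return df[["pathway_id", "name", "definition"]]


def read_abundance_table(counts_path: str | Path, years_path: str | Path) -> AbundanceTable:
    """Counts TSV (first column ``sample``, one column per taxon) plus a
    two-column sample/year TSV."""
    counts = pd.read_csv(_open_skipping_comments(counts_path), sep="\t")
    counts = counts.set_index(counts.columns[0]).astype(int)
    counts = counts.rename_axis(index=None, columns=None)
    years = pd.read_csv(_open_skipping_comments(years_path), sep="\t", dtype=str)
    years = years.set_index(years.columns[0]).iloc[:, 0].astype(int)
    years = years.rename_axis(None).rename(None)
    return AbundanceTable(counts=counts, sample_year=years)


def write_abundance_table(table: AbundanceTable, counts_path: str | Path,
                          years_path: str | Path) -> None:
    out = table.counts.copy()
    out.index.name = "sample"
    out.to_csv(counts_path, sep="\t")
    years = table.sample_year.rename("year")
    years.index.name = "sample"
    years.to_csv(years_path, sep="\t")


def read_unassigned_sidecar(path: str | Path) -> pd.Series:
    """Two-column TSV (isolate, count) of genes outside every orthogroup."""
    df = pd.read_csv(_open_skipping_comments(path), sep="\t", dtype=str)
    series = df.set_index(df.columns[0]).iloc[:, 0].astype(int)
    if (series < 0).any():
        raise FormatError(f"{path}: negative unassigned gene count")
    return series


def write_result_table(df: pd.DataFrame, path: str | Path, provenance: str,
                       index: bool = False) -> None:
    """Write a results TSV with a ``#`` provenance header line."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"# {provenance}\n")
        df.to_csv(handle, sep="\t", index=index)
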