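"""Readers and writers for the standard formats the pipeline touches.

Covers 10x-dialect VDJ contig annotation tables, MatrixMarket gene-count
triplets with feature/barcode line lists, antibody-capture (ADT) count
tables, Adaptive-style bulk TCRbeta clone tables, and VDJdb-style
annotation tables.  Readers never filter: rows that downstream steps may
discard (non-productive contigs, duplicate clone rows) are returned as-is
so every QC decision is an explicit, auditable operation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ValidationError

ALLOWED_LOCI = frozenset({"TRA", "TRB", "TRG", "TRD"})

#: common spellings of the two annotation chains, normalized on read
_CHAIN_ALIASES = {
    "TRA": "TRA", "ALPHA": "TRA", "A": "TRA", "TCRA": "TRA",
    "TRB": "TRB", "BETA": "TRB", "B": "TRB", "TCRB": "TRB",
}

_MISSING_TOKENS = {"", "NONE", "NA", "NAN"}


@dataclass(frozen=True)
class ChainRecord:
    """One sequenced TCR chain contig for one cell barcode.

    ``productive`` is forced False when the CDR3 amino-acid sequence is
    missing: a chain without a CDR3 cannot take part in clonotype calling.
    """

    barcode: str
    chain_locus: str
    v_gene: str
    j_gene: str
    cdr3_aa: str
    cdr3_nt: str = ""
    productive: bool = False
    high_confidence: bool = True
    umis: int = 0

    def __post_init__(self) -> None:
        if not self.barcode:
            raise ValidationError("ChainRecord barcode must be non-empty")
        if self.chain_locus not in ALLOWED_LOCI:
            raise ValidationError(
                f"chain_locus {self.chain_locus!r} not in {sorted(ALLOWED_LOCI)}"
            )
        if self.productive and not self.cdr3_aa:
            raise ValidationError("productive chain requires a non-empty cdr3_aa")


@dataclass(frozen=True)
class BulkCloneRecord:
    """One row of a bulk TCRbeta clone table: a CDR3b with its template count."""

    cdr3b_aa: str
    templates: int
    sample_id: str
    tissue: str
    patient: str

    def __post_init__(self) -> None:
        if self.templates < 1:
            raise ValidationError("templates must be >= 1")


@dataclass(frozen=True)
class AnnotationRecord:
    """A CDR3 sequence with a known antigen association (VDJdb-style)."""

    chain_locus: str
    cdr3_aa: str
    antigen_species: str
    antigen_epitope: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValidationError("AnnotationRecord cdr3_aa must be non-empty")


@dataclass
class CountMatrix:
    """Sparse non-negative integer counts, oriented cells x genes."""

    cells: list[str]
    genes: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )


@dataclass
class ADTMatrix:
    """Antibody-derived-tag counts per cell; ``normalized`` filled by CLR."""

    cells: list[str]
    proteins: list[str]
    raw: np.ndarray
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw)
        if self.raw.shape != (len(self.cells), len(self.proteins)):
            raise FormatError(
                f"ADT matrix shape {self.raw.shape} inconsistent with "
                f"{len(self.cells)} cells x {len(self.proteins)} proteins"
            )
        if (self.raw < 0).any():
            raise ValidationError("ADT raw counts must be non-negative")


def _is_missing(value) -> bool:
    return pd.isna(value) or str(value).strip().upper() in _MISSING_TOKENS


def _parse_bool(value) -> bool:
    return str(value).strip().lower() in {"true", "t", "1", "yes"}


def read_contigs(path: str | Path, dialect: str = "tenx_filtered") -> list[ChainRecord]:
    """Read a 10x ``filtered_contig_annotations``-dialect VDJ contig table.

    Column order and extra columns are irrelevant; "None"/"" CDR3 entries
    are treated as missing.  Rows with chains outside the TRA/TRB/TRG/TRD
    loci (e.g. "Multi") are dropped with a warning; nothing else is
    filtered here.
    """
    if dialect != "tenx_filtered":
        raise FormatError(f"unknown contig dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"contig file not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty contig file: {path}", stacklevel=2)
        return []
    required = ["barcode", "chain", "v_gene", "j_gene", "cdr3", "productive"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"contig table {path} lacks mandatory column {col!r}")
    if df.empty:
        warnings.warn(f"contig file has a header but no rows: {path}", stacklevel=2)
        return []

    records: list[ChainRecord] = []
    n_dropped = 0
    for _, row in df.iterrows():
        locus = str(row["chain"]).strip().upper()
        if locus not in ALLOWED_LOCI:
            n_dropped += 1
            continue
        cdr3 = "" if _is_missing(row["cdr3"]) else str(row["cdr3"]).strip()
        cdr3_nt = row.get("cdr3_nt", "")
        cdr3_nt = "" if _is_missing(cdr3_nt) else str(cdr3_nt).strip()
        productive = _parse_bool(row["productive"]) and bool(cdr3)
        high_conf = row.get("high_confidence", "true")
        umis = row.get("umis", 0)
        records.append(
            ChainRecord(
                barcode=str(row["barcode"]).strip(),
                chain_locus=locus,
                v_gene="" if _is_missing(row["v_gene"]) else str(row["v_gene"]),
                j_gene="" if _is_missing(row["j_gene"]) else str(row["j_gene"]),
                cdr3_aa=cdr3,
                cdr3_nt=cdr3_nt,
                productive=productive,
                high_confidence=_parse_bool(high_conf),
                umis=0 if _is_missing(umis) else int(float(umis)),
            )
        )
    if n_dropped:
        warnings.warn(
            f"{n_dropped} contig rows with non-TR chains dropped from {path}",
            stacklevel=2,
        )
    return records


def _read_lines(path: str | Path, column: int | None = None) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if "\t" in line:
                parts = line.split("\t")
                if column is not None:
                    out.append(parts[min(column, len(parts) - 1)])
                else:
                    # 10x features.tsv: id, symbol, type -> use the symbol
                    out.append(parts[1] if len(parts) > 1 else parts[0])
            else:
                out.append(line)
    return out


def read_count_matrix(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> CountMatrix:
    """Read a MatrixMarket triplet plus feature/barcode lists.

    On-disk orientation is detected from the header dimensions against the
    two list lengths and normalized to cells x genes (10x writes
    genes x cells; either is accepted).
    """
    genes = _read_lines(features_path)
    cells = _read_lines(barcodes_path, column=0)
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # malformed triplets, out-of-range indices
        raise FormatError(f"cannot parse MatrixMarket file {mtx_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"non-integer entries in count matrix {mtx_path}")
    if (mat.data < 0).any():
        raise FormatError(f"negative entries in count matrix {mtx_path}")
    n_genes, n_cells = len(genes), len(cells)
    if mat.shape == (n_genes, n_cells):
        mat = mat.T  # 10x orientation
    elif mat.shape == (n_cells, n_genes):
        pass
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither {n_cells} cells x "
            f"{n_genes} genes nor its transpose"
        )
    counts = sp.csr_matrix(mat.astype(np.int64))
    return CountMatrix(cells=cells, genes=genes, counts=counts)


def read_bulk_clonetable(
    path: str | Path,
    *,
    cdr3_column: str = "cdr3_amino_acid",
    templates_column: str = "templates",
    sample_column: str = "sample_id",
    tissue_column: str = "tissue",
    patient_column: str = "patient",
) -> list[BulkCloneRecord]:
    """Read a tab-separated bulk TCRbeta clone table.

    Only the CDR3b amino-acid sequence and the template count feed the
    classifiers; any further vendor columns are ignored.  Duplicate CDR3
    rows are returned as-is (aggregation happens in ``bulk_classify``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (cdr3_column, templates_column):
        if col not in df.columns:
            raise FormatError(f"bulk clone table {path} lacks column {col!r}")
    bad_rows = []
    records = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        templates = int(float(row[templates_column]))
        if templates < 1:
            bad_rows.append(i)
            continue
        records.append(
            BulkCloneRecord(
                cdr3b_aa=str(row[cdr3_column]).strip(),
                templates=templates,
                sample_id=str(row[sample_column]) if sample_column in df.columns else "",
                tissue=str(row[tissue_column]) if tissue_column in df.columns else "",
                patient=str(row[patient_column]) if patient_column in df.columns else "",
            )
        )
    if bad_rows:
        raise ValidationError(
            f"non-positive template counts in {path} at data rows {bad_rows}"
        )
    return records


def read_annotation_db(path: str | Path) -> list[AnnotationRecord]:
    """Read a VDJdb-style tab-separated annotation table.

    Chain labels are normalized to TRA/TRB from the common spellings
    (TRA/alpha, TRB/beta); anything else is a validation error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower().replace(".", "_"): c for c in df.columns}
    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        raise FormatError(f"annotation table {path} lacks any of columns {names}")

    chain_col = pick("chain", "gene", "chain_locus")
    cdr3_col = pick("cdr3", "cdr3_aa")
    species_col = pick("antigen_species", "species", "epitope_species")
    epitope_col = None
    for n in ("antigen_epitope", "epitope", "antigen_gene"):
        if n in cols:
            epitope_col = cols[n]
            break
    source_col = cols.get("source") or cols.get("reference")

    records = []
    for _, row in df.iterrows():
        raw_chain = str(row[chain_col]).strip().upper()
        if raw_chain not in _CHAIN_ALIASES:
            raise ValidationError(f"unknown chain label {raw_chain!r} in {path}")
        records.append(
            AnnotationRecord(
                chain_locus=_CHAIN_ALIASES[raw_chain],
                cdr3_aa=str(row[cdr3_col]).strip(),
                antigen_species=str(row[species_col]).strip(),
                antigen_epitope=str(row[epitope_col]).strip() if epitope_col else "",
                source=str(row[source_col]).strip() if source_col else "",
            )
        )
    return records


def write_table(
    rows: pd.DataFrame,
    path: str | Path,
    fmt: str = "csv",
    *,
    sort_by: Sequence[str] | None = None,
) -> None:
    """Write a result table deterministically (sorted, no index).

    ``sort_by`` defaults to every column, giving byte-identical files for
    the same values in any input row order; pass an empty sequence to
    keep an order the caller already fixed.
    """
    if rows is None:
        raise ValidationError("rows must not be None")
    if fmt not in {"csv", "tsv"}:
        raise FormatError(f"unknown table format {fmt!r}")
    df = rows.copy()
    keys = list(df.columns) if sort_by is None else list(sort_by)
    if keys and not df.empty:
        df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="," if fmt == "csv" else "\t", index=False)
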