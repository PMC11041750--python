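"""Clonotype calling, expansion classification and paired-tissue enrichment.

A clonotype is the multiset of productive CDR3 amino-acid sequences a
cell carries, canonicalized as ``sorted TRA list | sorted TRB list``
(";"-separated within a side, "NA" for an absent side).  Abundance is the
percentage of TCR-bearing cells of the same patient, tissue and scope
that carry the clonotype.  Expansion levels: Single (one occurrence),
Small (<=0.1%), Medium (>0.1% and <=1%), Large (>1% and <=10%),
Hyperexpanded (>10%).  Tissue enrichment compares a clone's frequencies
across the two matched tissues of one patient: a clone seen once in
total is Single; otherwise it is tissue-/blood-enriched when its
frequency exceeds the other tissue's by the configured fold, and
Unenriched when the frequencies are similar.
"""

from __future__ import annotations

import warnings
from collections import defaultdict

import numpy as np
import pandas as pd

from .config import DEFAULT_TISSUES, EnrichmentParams, ExpansionThresholds
from .errors import ConfigurationError, ValidationError
from .io import AnnotationRecord, BulkCloneRecord, ChainRecord

SINGLE, SMALL, MEDIUM, LARGE, HYPER = "Single", "Small", "Medium", "Large", "Hyperexpanded"
ABSENT = "Absent"
EXPANSION_ORDER = (SINGLE, SMALL, MEDIUM, LARGE, HYPER)

TISSUE_ENRICHED, PBMC_ENRICHED, UNENRICHED = "TissueEnriched", "PBMCEnriched", "Unenriched"
ENRICHMENT_ORDER = (SINGLE, UNENRICHED, PBMC_ENRICHED, TISSUE_ENRICHED)

MISSING = ""  # clonotype value for cells with no qualifying TCR


def clonotype_key(
    tra: list[str], trb: list[str], *, v_genes: tuple[list[str], list[str]] | None = None
) -> str:
    """Canonical clonotype key from per-chain CDR3 amino-acid multisets.

    Duplicate sequences within a chain are collapsed, sides are sorted,
    an empty side renders as "NA".  With ``v_genes`` given, each CDR3 is
    prefixed by its V gene (the optional V/J-aware variant).
    """
    def side(seqs: list[str], vs: list[str] | None) -> str:
        if vs is not None:
            items = sorted({f"{v}:{s}" for v, s in zip(vs, seqs)})
        else:
            items = sorted(set(seqs))
        return ";".join(items) if items else "NA"

    va, vb = v_genes if v_genes is not None else (None, None)
    return side(tra, va) + "|" + side(trb, vb)


def build_clonotypes(
    chains: list[ChainRecord],
    cell_meta: pd.DataFrame,
    *,
    productive_only: bool = True,
    require_both_chains: bool = False,
    use_v_genes: bool = False,
) -> pd.DataFrame:
    """Assemble the cell-level repertoire frame.

    ``cell_meta`` has one row per cell with columns ``barcode``,
    ``patient``, ``tissue`` and optionally ``cluster`` and ``subset``;
    barcodes must be unique (cells of different samples must be suffixed
    before this call).  Cells present in the metadata but without
    qualifying chains keep an empty clonotype; chain records whose
    barcode is absent from the metadata are dropped with a warning.
    """
    required = {"barcode", "patient", "tissue"}
    if not required.issubset(cell_meta.columns):
        raise ConfigurationError(f"cell_meta must have columns {sorted(required)}")
    if cell_meta["barcode"].duplicated().any():
        raise ValidationError("cell_meta barcodes must be unique")

    known = set(cell_meta["barcode"])
    per_cell: dict[str, dict[str, list[str]]] = defaultdict(lambda: {"TRA": [], "TRB": [],
                                                                     "TRA_v": [], "TRB_v": []})
    n_dropped = 0
    for rec in chains:
        if rec.barcode not in known:
            n_dropped += 1
            continue
        if productive_only and not rec.productive:
            continue
        if not rec.cdr3_aa or rec.chain_locus not in ("TRA", "TRB"):
            continue
        per_cell[rec.barcode][rec.chain_locus].append(rec.cdr3_aa)
        per_cell[rec.barcode][rec.chain_locus + "_v"].append(rec.v_gene)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} chain records with barcodes absent from cell_meta dropped",
            stacklevel=2,
        )

    keys = []
    for bc in cell_meta["barcode"]:
        sides = per_cell.get(bc)
        if sides is None or (not sides["TRA"] and not sides["TRB"]):
            keys.append(MISSING)
            continue
        if require_both_chains and (not sides["TRA"] or not sides["TRB"]):
            keys.append(MISSING)
            continue
        vg = (sides["TRA_v"], sides["TRB_v"]) if use_v_genes else None
        keys.append(clonotype_key(sides["TRA"], sides["TRB"], v_genes=vg))

    frame = cell_meta.copy().reset_index(drop=True)
    frame["clonotype"] = keys
    if "cluster" not in frame.columns:
        frame["cluster"] = MISSING
    if "subset" not in frame.columns:
        frame["subset"] = "all"
    return frame


def classify_expansion(
    count: int, denominator: int, thresholds: ExpansionThresholds | None = None
) -> str:
    """Expansion level of one clone in one (patient, tissue, scope) stratum.

    A single occurrence is Single regardless of the percentage it
    represents; otherwise the percentage is binned with inclusive upper
    bounds (Small <= 0.1 < Medium <= 1 < Large <= 10 < Hyperexpanded).
    """
    thresholds = thresholds or ExpansionThresholds()
    if count < 1:
        raise ValidationError("classify_expansion requires count >= 1")
    if count > denominator:
        raise ValidationError("count cannot exceed denominator")
    if count == 1:
        return SINGLE
    pct = 100.0 * count / denominator
    if pct <= thresholds.small_max_pct:
        return SMALL
    if pct <= thresholds.medium_max_pct:
        return MEDIUM
    if pct <= thresholds.large_max_pct:
        return LARGE
    return HYPER


def compute_abundance(
    frame: pd.DataFrame,
    scope: str = "all",
    *,
    thresholds: ExpansionThresholds | None = None,
    tissues: tuple[str, str] = DEFAULT_TISSUES,
) -> pd.DataFrame:
    """Per-(patient, clonotype) counts, frequencies and expansion classes.

    ``scope`` restricts both numerator and denominator to the matching
    ``subset`` label ("all" keeps every cell), so CD4-scoped frequencies
    are percentages of CD4 TCR-bearing cells.  The denominator of a
    (patient, tissue) stratum is its number of TCR-bearing cells; strata
    with no such cells are omitted with a warning.  Output columns:
    patient, clonotype, scope, count_blood/count_tissue,
    freq_blood/freq_tissue (percent), expansion_blood/expansion_tissue.
    """
    thresholds = thresholds or ExpansionThresholds()
    blood, tissue = tissues
    sub = frame[frame["clonotype"] != MISSING]
    if scope != "all":
        sub = sub[sub["subset"] == scope]

    denoms: dict[tuple[str, str], int] = (
        sub.groupby(["patient", "tissue"], sort=False).size().to_dict()
    )
    for patient in frame["patient"].unique():
        for t in tissues:
            if (patient, t) not in denoms:
                warnings.warn(
                    f"no TCR-bearing cells for patient {patient!r} tissue {t!r} "
                    f"(scope {scope!r}); stratum omitted",
                    stacklevel=2,
                )

    counts = (
        sub.groupby(["patient", "clonotype", "tissue"], sort=False)
        .size()
        .unstack("tissue", fill_value=0)
    )
    for t in tissues:
        if t not in counts.columns:
            counts[t] = 0

    rows = []
    for (patient, key), row in counts.iterrows():
        cb, ct = int(row[blood]), int(row[tissue])
        db, dt = denoms.get((patient, blood), 0), denoms.get((patient, tissue), 0)
        fb = 100.0 * cb / db if db else 0.0
        ft = 100.0 * ct / dt if dt else 0.0
        rows.append(
            {
                "patient": patient,
                "clonotype": key,
                "scope": scope,
                "count_blood": cb,
                "count_tissue": ct,
                "freq_blood": fb,
                "freq_tissue": ft,
                "expansion_blood": classify_expansion(cb, db, thresholds) if cb else ABSENT,
                "expansion_tissue": classify_expansion(ct, dt, thresholds) if ct else ABSENT,
            }
        )
    ledger = pd.DataFrame(
        rows,
        columns=[
            "patient", "clonotype", "scope", "count_blood", "count_tissue",
            "freq_blood", "freq_tissue", "expansion_blood", "expansion_tissue",
        ],
    )
    return ledger.sort_values(["patient", "clonotype"], kind="mergesort").reset_index(drop=True)


def score_enrichment(
    ledger: pd.DataFrame, params: EnrichmentParams | None = None
) -> pd.DataFrame:
    """Add the per-clone ``enrichment`` column to an abundance ledger.

    A clone with one cell in total (across both tissues of its patient)
    is Single.  Otherwise it is TissueEnriched when its tissue frequency
    is at least ``fold_threshold`` times its blood frequency (absence
    from blood qualifies once the tissue count reaches
    ``min_cells_expanded``), PBMCEnriched by the mirrored rule, and
    Unenriched when neither side dominates.
    """
    params = params or EnrichmentParams()
    params.validate()
    out = ledger.copy()
    labels = []
    for row in out.itertuples(index=False):
        cb, ct = row.count_blood, row.count_tissue
        fb, ft = row.freq_blood, row.freq_tissue
        total = cb + ct
        if total == 0:
            raise ValidationError("clone present in neither tissue")
        if total == 1:
            labels.append(SINGLE)
            continue
        t_up = (fb > 0 and ft >= params.fold_threshold * fb) or (
            fb == 0 and ct >= params.min_cells_expanded
        )
        b_up = (ft > 0 and fb >= params.fold_threshold * ft) or (
            ft == 0 and cb >= params.min_cells_expanded
        )
        if t_up and not b_up:
            labels.append(TISSUE_ENRICHED)
        elif b_up and not t_up:
            labels.append(PBMC_ENRICHED)
        else:
            labels.append(UNENRICHED)
    out["enrichment"] = labels
    return out


def _cell_classes(frame: pd.DataFrame, ledger: pd.DataFrame,
                  tissues: tuple[str, str] = DEFAULT_TISSUES) -> pd.DataFrame:
    """Join each TCR-bearing cell to its clone's expansion (own tissue)
    and enrichment classes."""
    blood, tissue = tissues
    sub = frame[frame["clonotype"] != MISSING].copy()
    cols = ["patient", "clonotype", "expansion_blood", "expansion_tissue"]
    if "enrichment" in ledger.columns:
        cols.append("enrichment")
    merged = sub.merge(ledger[cols], on=["patient", "clonotype"], how="left", validate="m:1")
    if merged["expansion_blood"].isna().any():
        raise ValidationError("ledger does not cover every clonotype in the frame")
    merged["expansion"] = np.where(
        merged["tissue"] == blood, merged["expansion_blood"], merged["expansion_tissue"]
    )
    return merged


def quantify_by_group(
    frame: pd.DataFrame,
    ledger: pd.DataFrame,
    group_by: list[str],
    label: str = "expansion",
    *,
    tissues: tuple[str, str] = DEFAULT_TISSUES,
) -> pd.DataFrame:
    """Cell-weighted class proportions per group (the bar-plot numbers).

    ``label`` is "expansion" (each cell labelled by its clone's class in
    the cell's own tissue) or "enrichment".  Cells without a clonotype
    are excluded; proportions within a group sum to 1.
    """
    allowed = {"patient", "tissue", "cluster", "subset"}
    bad = set(group_by) - allowed
    if bad:
        raise ConfigurationError(f"unknown group keys {sorted(bad)}")
    if label not in {"expansion", "enrichment"}:
        raise ConfigurationError(f"unknown label {label!r}")
    merged = _cell_classes(frame, ledger, tissues)
    if label == "enrichment" and "enrichment" not in merged.columns:
        raise ConfigurationError("ledger lacks enrichment; run score_enrichment first")
    grouped = merged.groupby(group_by + [label], sort=True).size().rename("n_cells").reset_index()
    totals = grouped.groupby(group_by)["n_cells"].transform("sum")
    grouped["proportion"] = grouped["n_cells"] / totals
    grouped = grouped.rename(columns={label: "class"})
    return grouped.sort_values(group_by + ["class"], kind="mergesort").reset_index(drop=True)


def cluster_overlap(
    frame: pd.DataFrame, cluster_a: str, cluster_b: str
) -> pd.DataFrame:
    """Clonotypes shared between two clusters, with per-cluster and
    per-tissue cell counts, sorted by combined count descending (ties by
    key)."""
    present = set(frame["cluster"].unique())
    for c in (cluster_a, cluster_b):
        if c not in present:
            raise ConfigurationError(f"unknown cluster label {c!r}")
    sub = frame[frame["clonotype"] != MISSING]
    in_a = sub[sub["cluster"] == cluster_a]
    in_b = sub[sub["cluster"] == cluster_b]
    shared = sorted(set(in_a["clonotype"]) & set(in_b["clonotype"]))
    rows = []
    for key in shared:
        a_cells = in_a[in_a["clonotype"] == key]
        b_cells = in_b[in_b["clonotype"] == key]
        row = {
            "clonotype": key,
            "count_cluster_a": len(a_cells),
            "count_cluster_b": len(b_cells),
            "count_total": len(a_cells) + len(b_cells),
        }
        both = sub[sub["clonotype"] == key]
        for t in sorted(frame["tissue"].unique()):
            row[f"count_{t}"] = int((both["tissue"] == t).sum())
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["clonotype", "count_cluster_a", "count_cluster_b", "count_total"]
        )
    return out.sort_values(
        ["count_total", "clonotype"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def split_key(key: str) -> dict[str, list[str]]:
    """Invert ``clonotype_key`` into per-locus CDR3 lists."""
    tra_side, trb_side = key.split("|", 1)
    return {
        "TRA": [] if tra_side == "NA" else tra_side.split(";"),
        "TRB": [] if trb_side == "NA" else trb_side.split(";"),
    }


def match_annotations(
    frame: pd.DataFrame, db: list[AnnotationRecord], mode: str = "exact_cdr3"
) -> pd.DataFrame:
    """Locus-aware exact CDR3 matching of clonotypes against an
    annotation table; every hit is returned (a clonotype can match
    several epitopes)."""
    if mode != "exact_cdr3":
        raise ConfigurationError(f"unknown annotation mode {mode!r}")
    index: dict[tuple[str, str], list[AnnotationRecord]] = defaultdict(list)
    for rec in db:
        index[(rec.chain_locus, rec.cdr3_aa)].append(rec)
    rows = []
    for key in sorted(set(frame.loc[frame["clonotype"] != MISSING, "clonotype"])):
        for locus, seqs in split_key(key).items():
            for seq in seqs:
                for rec in index.get((locus, seq), []):
                    rows.append(
                        {
                            "clonotype": key,
                            "chain_locus": locus,
                            "cdr3_aa": seq,
                            "antigen_species": rec.antigen_species,
                            "antigen_epitope": rec.antigen_epitope,
                            "source": rec.source,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["clonotype", "chain_locus", "cdr3_aa",
                 "antigen_species", "antigen_epitope", "source"],
    )


def bulk_classify(
    clones: list[BulkCloneRecord],
    thresholds: ExpansionThresholds | None = None,
    params: EnrichmentParams | None = None,
    *,
    tissues: tuple[str, str] = DEFAULT_TISSUES,
) -> pd.DataFrame:
    """Expansion and enrichment classes for a bulk TCRbeta clone table.

    Rows are aggregated by (patient, tissue, CDR3b) summing template
    counts; the denominator is the total templates of the (patient,
    tissue) sample.  Classification semantics are identical to the
    single-cell path, with templates in place of cells.
    """
    thresholds = thresholds or ExpansionThresholds()
    params = params or EnrichmentParams()
    blood, tissue = tissues
    if not clones:
        return pd.DataFrame(
            columns=["patient", "clonotype", "scope", "count_blood", "count_tissue",
                     "freq_blood", "freq_tissue", "expansion_blood", "expansion_tissue",
                     "enrichment"]
        )
    df = pd.DataFrame(
        {
            "patient": [c.patient for c in clones],
            "tissue": [c.tissue for c in clones],
            "cdr3b_aa": [c.cdr3b_aa for c in clones],
            "templates": [c.templates for c in clones],
        }
    )
    unknown = set(df["tissue"]) - set(tissues)
    if unknown:
        raise ValidationError(f"unknown tissue labels in bulk table: {sorted(unknown)}")
    agg = df.groupby(["patient", "tissue", "cdr3b_aa"], sort=False)["templates"].sum()
    denoms = df.groupby(["patient", "tissue"], sort=False)["templates"].sum().to_dict()
    counts = agg.unstack("tissue", fill_value=0).reset_index()
    for t in tissues:
        if t not in counts.columns:
            counts[t] = 0
    rows = []
    for _, row in counts.iterrows():
        patient, key = row["patient"], row["cdr3b_aa"]
        cb, ct = int(row[blood]), int(row[tissue])
        db, dt = denoms.get((patient, blood), 0), denoms.get((patient, tissue), 0)
        rows.append(
            {
                "patient": patient,
                "clonotype": key,
                "scope": "bulk",
                "count_blood": cb,
                "count_tissue": ct,
                "freq_blood": 100.0 * cb / db if db else 0.0,
                "freq_tissue": 100.0 * ct / dt if dt else 0.0,
                "expansion_blood": classify_expansion(cb, db, thresholds) if cb else ABSENT,
                "expansion_tissue": classify_expansion(ct, dt, thresholds) if ct else ABSENT,
            }
        )
    ledger = pd.DataFrame(rows).sort_values(
        ["patient", "clonotype"], kind="mergesort"
    ).reset_index(drop=True)
    return score_enrichment(ledger, params)
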