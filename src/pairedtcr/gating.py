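"""Cell-level QC filtering and ADT-based T-cell / CD4-CD8 gating.

The QC rule keeps cells detecting between 200 and 5,000 genes (inclusive)
whose expression of each flagged lncRNA (KCNQ1OT1, UGDH-AS1, GHET1) stays
strictly below 2% of total counts — the published proxy for removing
apoptotic cells, low-quality cells and doublets.  Surface-protein gating
runs on CLR-normalized antibody counts: T cells are CD3-positive without
CD14, and CD4/CD8 single-positive labels use the published thresholds
CD4 > 0.75 and CD8 > 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import GateThresholds, QCThresholds
from .errors import ConfigurationError
from .io import ADTMatrix, CountMatrix

#: CD4/CD8 single-positive labels produced by :func:`gate_cd4_cd8`
CD4, CD8 = "CD4", "CD8"
DOUBLE_POSITIVE, DOUBLE_NEGATIVE = "double_positive", "double_negative"


@dataclass
class CellQCReport:
    barcode: str
    n_genes_detected: int
    pct_per_flagged_gene: dict[str, float]
    passed: bool
    failure_reasons: list[str] = field(default_factory=list)


def qc_filter(
    counts: CountMatrix, thresholds: QCThresholds | None = None
) -> tuple[list[str], list[CellQCReport]]:
    """Apply the cell QC rule; every cell gets a report.

    A cell passes iff min_genes <= detected genes <= max_genes (both
    inclusive) and every flagged gene contributes strictly less than
    ``max_flagged_pct`` percent of its total counts.  Flagged genes absent
    from the matrix contribute 0%.  Zero-count cells fail outright (the
    percentage is undefined).
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    mat = counts.counts.tocsr()
    n_detected = np.diff(mat.indptr)  # nonzeros per cell row
    totals = np.asarray(mat.sum(axis=1)).ravel()

    gene_index = {g: i for i, g in enumerate(counts.genes)}
    flagged_cols = {
        g: np.asarray(mat[:, gene_index[g]].todense()).ravel()
        for g in thresholds.flagged_genes
        if g in gene_index
    }

    passing: list[str] = []
    reports: list[CellQCReport] = []
    for i, barcode in enumerate(counts.cells):
        reasons: list[str] = []
        pcts: dict[str, float] = {}
        if totals[i] == 0:
            reasons.append("zero counts")
            pcts = {g: float("nan") for g in thresholds.flagged_genes}
        else:
            for g in thresholds.flagged_genes:
                col = flagged_cols.get(g)
                pct = 100.0 * float(col[i]) / float(totals[i]) if col is not None else 0.0
                pcts[g] = pct
                if pct >= thresholds.max_flagged_pct:
                    reasons.append(f"{g} at {pct:.3f}% >= {thresholds.max_flagged_pct}%")
            if not (thresholds.min_genes <= n_detected[i] <= thresholds.max_genes):
                reasons.append(
                    f"detected {int(n_detected[i])} genes outside "
                    f"[{thresholds.min_genes}, {thresholds.max_genes}]"
                )
        passed = not reasons
        if passed:
            passing.append(barcode)
        reports.append(
            CellQCReport(
                barcode=barcode,
                n_genes_detected=int(n_detected[i]),
                pct_per_flagged_gene=pcts,
                passed=passed,
                failure_reasons=reasons,
            )
        )
    return passing, reports


def clr_normalize(adt: ADTMatrix, axis: str = "per_feature") -> ADTMatrix:
    """Centered-log-ratio transform: ln((x+1) / geometric mean of (x+1)).

    ``per_feature`` centers each protein across cells (the feature-
    barcoding convention and this package's default); ``per_cell``
    centers each cell across its proteins.  An all-zero slice maps to
    zeros.  Monotone within each slice.
    """
    if axis not in {"per_feature", "per_cell"}:
        raise ConfigurationError(f"unknown CLR axis {axis!r}")
    logged = np.log(adt.raw.astype(float) + 1.0)
    if axis == "per_feature":
        center = logged.mean(axis=0, keepdims=True)
    else:
        center = logged.mean(axis=1, keepdims=True)
    return ADTMatrix(
        cells=list(adt.cells),
        proteins=list(adt.proteins),
        raw=adt.raw,
        normalized=logged - center,
    )


def _protein_column(adt: ADTMatrix, name: str) -> np.ndarray:
    if adt.normalized is None:
        raise ConfigurationError("ADT matrix is not normalized; run clr_normalize first")
    try:
        idx = adt.proteins.index(name)
    except ValueError:
        raise ConfigurationError(f"ADT matrix lacks required protein {name!r}") from None
    return adt.normalized[:, idx]


def gate_t_cells(adt: ADTMatrix, gates: GateThresholds | None = None) -> list[str]:
    """Keep cells with CD3 above ``cd3_min`` and CD14 at most ``cd14_max``."""
    gates = gates or GateThresholds()
    gates.validate()
    cd3 = _protein_column(adt, "CD3")
    cd14 = _protein_column(adt, "CD14")
    keep = (cd3 > gates.cd3_min) & (cd14 <= gates.cd14_max)
    return [bc for bc, k in zip(adt.cells, keep) if k]


def gate_cd4_cd8(adt: ADTMatrix, gates: GateThresholds | None = None) -> dict[str, str]:
    """Assign each cell exactly one of CD4 / CD8 / double_positive /
    double_negative from the published strict thresholds."""
    gates = gates or GateThresholds()
    gates.validate()
    cd4 = _protein_column(adt, "CD4") > gates.cd4_min
    cd8 = _protein_column(adt, "CD8") > gates.cd8_min
    labels = {}
    for bc, is4, is8 in zip(adt.cells, cd4, cd8):
        if is4 and is8:
            labels[bc] = DOUBLE_POSITIVE
        elif is4:
            labels[bc] = CD4
        elif is8:
            labels[bc] = CD8
        else:
            labels[bc] = DOUBLE_NEGATIVE
    return labels
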