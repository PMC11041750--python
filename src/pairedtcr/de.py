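"""Differential expression between clonality-defined cell groups.

The contrast engine is the two-sided Wilcoxon rank-sum test on
log-normalized expression, Bonferroni-corrected over the total number of
genes in the dataset; a gene is called significant at p < 1e-6 with an
absolute log2 fold change of at least 0.5 (both configurable).  Groups
are defined by expansion class (e.g. Single vs Small-Large), enrichment
class (blood- vs tissue-enriched), or tissue within one cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .clonality import MISSING, _cell_classes
from .config import DEFAULT_TISSUES
from .errors import ConfigurationError, ContrastError
from .io import CountMatrix

#: published significance rule
P_CUTOFF = 1e-6
LOG2FC_CUTOFF = 0.5


@dataclass(frozen=True)
class GroupSpec:
    """Selector pair for one contrast.

    kind "expansion": ``classes_a``/``classes_b`` are sets of expansion
    levels (a cell's level is its clone's level in the cell's own
    tissue).  kind "enrichment": sets of enrichment classes.  kind
    "tissue_in_cluster": cells of ``cluster`` split by tissue
    ``tissue_a`` vs ``tissue_b``.
    """

    name: str
    kind: str
    classes_a: frozenset[str] = frozenset()
    classes_b: frozenset[str] = frozenset()
    cluster: str = ""
    tissue_a: str = DEFAULT_TISSUES[0]
    tissue_b: str = DEFAULT_TISSUES[1]

    def __post_init__(self) -> None:
        if self.kind not in {"expansion", "enrichment", "tissue_in_cluster"}:
            raise ConfigurationError(f"unknown GroupSpec kind {self.kind!r}")
        if self.kind != "tissue_in_cluster" and self.classes_a & self.classes_b:
            raise ConfigurationError("contrast groups must be disjoint")


def define_groups(
    frame: pd.DataFrame, ledger: pd.DataFrame, spec: GroupSpec
) -> tuple[list[str], list[str]]:
    """Resolve a GroupSpec into two disjoint barcode lists."""
    merged = _cell_classes(frame, ledger)
    if spec.kind == "expansion":
        col = merged["expansion"]
        a = merged.loc[col.isin(spec.classes_a), "barcode"]
        b = merged.loc[col.isin(spec.classes_b), "barcode"]
    elif spec.kind == "enrichment":
        if "enrichment" not in merged.columns:
            raise ConfigurationError("ledger lacks enrichment classes")
        col = merged["enrichment"]
        a = merged.loc[col.isin(spec.classes_a), "barcode"]
        b = merged.loc[col.isin(spec.classes_b), "barcode"]
    else:
        cells = merged[merged["cluster"] == spec.cluster]
        a = cells.loc[cells["tissue"] == spec.tissue_a, "barcode"]
        b = cells.loc[cells["tissue"] == spec.tissue_b, "barcode"]
    a, b = list(a), list(b)
    for name, grp in ((f"{spec.name}/A", a), (f"{spec.name}/B", b)):
        if not grp:
            raise ContrastError(f"empty group {name}")
    return a, b


def log_normalize(counts: CountMatrix, scale: float = 1e4) -> pd.DataFrame:
    """Library-size-scaled log1p expression, cells x genes (dense)."""
    mat = counts.counts.astype(float)
    totals = np.asarray(mat.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    scaled = sp.diags(scale / totals) @ mat
    dense = np.log1p(np.asarray(scaled.todense()))
    return pd.DataFrame(dense, index=counts.cells, columns=counts.genes)


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating every assignment of the
    pooled observations to the two groups (ties handled by mid-ranks)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    observed = ranks[:n1].sum()
    total = comb(len(pooled), n1)
    mean = n1 * (len(pooled) + 1) / 2.0
    obs_dev = abs(observed - mean)
    hits = 0
    for idx in combinations(range(len(pooled)), n1):
        if abs(ranks[list(idx)].sum() - mean) >= obs_dev - 1e-9:
            hits += 1
    return hits / total


def wilcoxon_de(
    expression: pd.DataFrame,
    groups: tuple[list[str], list[str]],
    total_genes: int | None = None,
    *,
    p_cutoff: float = P_CUTOFF,
    log2fc_cutoff: float = LOG2FC_CUTOFF,
    pseudocount: float = 1.0,
    method: str = "auto",
) -> pd.DataFrame:
    """Rank-sum DE over all genes between two cell groups.

    ``expression`` is a cells x genes DataFrame of normalized values
    (see :func:`log_normalize`); ``total_genes`` is the Bonferroni
    multiplier (defaults to the number of genes in ``expression``).
    ``method`` "exact" enumerates all rank assignments (small groups
    only), "asymptotic" uses the tie-corrected normal approximation,
    "auto" picks exact when both groups have at most 8 cells.
    log2fc is log2((mean_A + pc) / (mean_B + pc)): positive means higher
    in group A.
    """
    cells_a, cells_b = groups
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ContrastError("each group needs at least 3 cells")
    if method not in {"auto", "exact", "asymptotic"}:
        raise ConfigurationError(f"unknown method {method!r}")
    xa = expression.loc[cells_a].to_numpy(float)
    xb = expression.loc[cells_b].to_numpy(float)
    genes = list(expression.columns)
    total = total_genes if total_genes is not None else len(genes)

    use_exact = method == "exact" or (
        method == "auto" and max(len(cells_a), len(cells_b)) <= 8
    )

    constant = np.array(
        [np.ptp(np.concatenate([xa[:, j], xb[:, j]])) == 0 for j in range(len(genes))]
    )
    pvals = np.ones(len(genes))
    live = ~constant
    if live.any():
        if use_exact:
            for j in np.where(live)[0]:
                pvals[j] = _exact_rank_sum_p(xa[:, j], xb[:, j])
        else:
            res = stats.mannwhitneyu(
                xa[:, live], xb[:, live], axis=0, alternative="two-sided",
                method="asymptotic",
            )
            pvals[live] = res.pvalue

    mean_a, mean_b = xa.mean(axis=0), xb.mean(axis=0)
    log2fc = np.where(
        constant, 0.0, np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    )
    p_adj = np.minimum(1.0, pvals * total)
    pct_a = (xa > 0).mean(axis=0)
    pct_b = (xb > 0).mean(axis=0)
    out = pd.DataFrame(
        {
            "gene": genes,
            "p_value": pvals,
            "p_adj": p_adj,
            "log2fc": log2fc,
            "pct_in_a": pct_a,
            "pct_in_b": pct_b,
        }
    )
    out["significant"] = (out["p_value"] < p_cutoff) & (out["log2fc"].abs() >= log2fc_cutoff)
    out["abs_lfc"] = out["log2fc"].abs()
    out = out.sort_values(
        ["p_value", "abs_lfc", "gene"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns="abs_lfc").reset_index(drop=True)
    return out
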