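"""Paired blood/tissue repertoire simulator with ground truth.

Emulates the structure of a paired PBMC/plaque scTCR-seq cohort: per
patient, two matched samples whose TCR-bearing cells are a mixture of
singleton clones and expanded clones (geometric or Zipf size law), with
a configurable fraction of expanded clones shared across tissues and a
multiplicative frequency enrichment planted toward one tissue.  One
optional hyperexpanded "spike" clone (>10% of one tissue) emulates a
dominant virus-associated clone.  Matched gene-count and antibody-tag
matrices carry planted QC violations and CD4/CD8 single-positive gating
structure, plus activation/naive marker genes that separate expanded
from singleton cells, so every pipeline stage is exercised end to end.

Cells designated as QC violators (and non-T cells) carry no expanded
clone membership: the planted clonal fractions refer to the analysis
cell set that survives QC and gating, which is what the recovery tests
measure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .config import DEFAULT_TISSUES
from .errors import ConfigurationError
from .io import ADTMatrix, ChainRecord, CountMatrix

AA = "ACDEFGHIKLMNPQRSTVWY"
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
TRAV = [f"TRAV{i}" for i in (1, 2, 3, 8, 12, 13, 17, 21, 26, 29, 38)]
TRAJ = [f"TRAJ{i}" for i in (4, 9, 12, 20, 23, 31, 33, 42, 49)]
TRBV = [f"TRBV{i}" for i in (2, 4, 5, 6, 7, 9, 11, 19, 20, 28)]
TRBJ = [f"TRBJ{i}-{j}" for i in (1, 2) for j in (1, 2, 3, 5, 7)]

CD4T, CD8T = "CD4_T", "CD8_T"
DP, MYELOID = "double_positive", "myeloid"

DEFAULT_CLUSTER_PROFILES = {
    # cluster -> (weight for singleton cells, weight for expanded-clone cells)
    "C0": (3.0, 1.0),   # memory
    "C1": (2.5, 0.2),   # naive
    "C3": (0.5, 3.0),   # effector, expansion-prone
    "C5": (1.0, 0.8),   # Treg-like
    "C6": (1.0, 1.5),   # migratory
}

DEFAULT_ADT_PROFILES = {
    # true type -> protein -> (negative-binomial mean, dispersion r)
    CD4T: {"CD3": (1000, 60), "CD4": (500, 60), "CD8": (2, 10), "CD14": (1, 10)},
    CD8T: {"CD3": (1000, 60), "CD4": (2, 10), "CD8": (500, 60), "CD14": (1, 10)},
    DP: {"CD3": (1000, 60), "CD4": (500, 60), "CD8": (500, 60), "CD14": (1, 10)},
    MYELOID: {"CD3": (0.2, 10), "CD4": (8, 10), "CD8": (1, 10), "CD14": (400, 60)},
}

ACTIVATION_GENES = ["CD69", "FOS", "FOSB", "JUN", "GZMB", "GZMK", "GZMA",
                    "PRF1", "GNLY", "NKG7"]
NAIVE_GENES = ["CCR7", "SELL", "LEF1", "TCF7", "LTB", "CD27"]
FLAGGED_GENES = ("KCNQ1OT1", "UGDH-AS1", "GHET1")


@dataclass
class SimulationConfig:
    """Study-condition defaults: 3 patients, 2,000 cells per tissue,
    expanded cell fraction 23% in blood and 29% in the tissue, one
    hyperexpanded blood-dominant spike clone, CD4:CD8 about 3:1."""

    n_patients: int = 3
    cells_per_tissue: int = 2000
    expanded_cell_fraction: tuple[float, float] = (0.23, 0.29)  # (blood, tissue)
    clone_size_law: tuple = ("geometric", 0.5)
    shared_clone_fraction: float = 0.5
    enrichment_factor: float = 4.0
    enriched_tissue_probability: float = 0.7
    cluster_profiles: dict = field(default_factory=lambda: dict(DEFAULT_CLUSTER_PROFILES))
    hyperexpanded_spike: bool = True
    spike_blood_pct: float = 12.0
    spike_tissue_pct: float = 5.0
    spike_tra_cdr3: str = "CAVSDNYQLIW"
    dual_tra_rate: float = 0.10
    tra_dropout: float = 0.12
    cd4_fraction: float = 0.75
    double_positive_rate: float = 0.02
    myeloid_rate: float = 0.12
    qc_violation_rates: dict = field(
        default_factory=lambda: {"low_genes": 0.02, "high_genes": 0.01, "flagged_gene": 0.02}
    )
    adt_profiles: dict = field(default_factory=lambda: {
        t: dict(p) for t, p in DEFAULT_ADT_PROFILES.items()
    })
    n_genes: int = 6000
    seed: int | None = None
    tissues: tuple[str, str] = DEFAULT_TISSUES

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory for reproducibility")
        fracs = self._fractions()
        for f in fracs + (self.shared_clone_fraction, self.enriched_tissue_probability,
                          self.dual_tra_rate, self.tra_dropout, self.cd4_fraction,
                          self.double_positive_rate, self.myeloid_rate):
            if not (0.0 <= f <= 1.0):
                raise ConfigurationError(f"probability {f} outside [0, 1]")
        if self.enrichment_factor < 1:
            raise ConfigurationError("enrichment_factor must be >= 1")
        law, param = self.clone_size_law
        if law == "geometric":
            if not (0 < param <= 1):
                raise ConfigurationError("geometric parameter must be in (0, 1]")
        elif law == "zipf":
            if param <= 1:
                raise ConfigurationError("zipf alpha must be > 1")
        elif law == "constant":
            if param < 2 and any(f > 0 for f in fracs):
                raise ConfigurationError(
                    "clone_size_law cannot produce expanded clones (size < 2)"
                )
        else:
            raise ConfigurationError(f"unknown clone_size_law {law!r}")
        if self.qc_violation_rates.get("high_genes", 0) > 0 and self.n_genes <= 5100:
            raise ConfigurationError(
                "n_genes too small to construct a >5,000-detected-genes violation"
            )
        if self.n_patients < 1 or self.cells_per_tissue < 10:
            raise ConfigurationError("need n_patients >= 1 and cells_per_tissue >= 10")

    def _fractions(self) -> tuple[float, float]:
        f = self.expanded_cell_fraction
        if isinstance(f, (int, float)):
            return (float(f), float(f))
        return (float(f[0]), float(f[1]))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["expanded_cell_fraction"] = list(self._fractions())
        d["clone_size_law"] = list(self.clone_size_law)
        d["tissues"] = list(self.tissues)
        d["cluster_profiles"] = {k: list(v) for k, v in self.cluster_profiles.items()}
        d["adt_profiles"] = {
            t: {p: list(mv) for p, mv in prof.items()} for t, prof in self.adt_profiles.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "expanded_cell_fraction" in d and isinstance(d["expanded_cell_fraction"], list):
            d["expanded_cell_fraction"] = tuple(d["expanded_cell_fraction"])
        if "clone_size_law" in d:
            d["clone_size_law"] = tuple(d["clone_size_law"])
        if "tissues" in d:
            d["tissues"] = tuple(d["tissues"])
        if "cluster_profiles" in d:
            d["cluster_profiles"] = {k: tuple(v) for k, v in d["cluster_profiles"].items()}
        if "adt_profiles" in d:
            d["adt_profiles"] = {
                t: {p: tuple(mv) for p, mv in prof.items()}
                for t, prof in d["adt_profiles"].items()
            }
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class SimulatedDataset:
    """Everything one simulated cohort comprises, plus its ground truth."""

    chains: dict[tuple[str, str], list[ChainRecord]]  # (patient, tissue) -> records
    cell_meta: pd.DataFrame
    counts: CountMatrix
    adt: ADTMatrix
    truth_clones: pd.DataFrame
    truth_cells: pd.DataFrame
    config: SimulationConfig


def _draw_expanded_size(law: tuple, rng: np.random.Generator, cap: int) -> int:
    """One clone size >= 2, truncated at ``cap``."""
    name, param = law
    if name == "geometric":
        s = 1 + int(rng.geometric(param))
    elif name == "zipf":
        s = 1 + int(rng.zipf(param))
    else:  # constant
        s = int(param)
    return max(2, min(s, cap))


def _expanded_sizes_for_budget(law, rng, budget: int, cap: int) -> list[int]:
    """Clone sizes >= 2 summing exactly to ``budget``."""
    sizes: list[int] = []
    remaining = budget
    while remaining >= 2:
        s = min(_draw_expanded_size(law, rng, cap), remaining)
        if remaining - s == 1:
            s += 1  # absorb an unusable remainder of one cell
        sizes.append(s)
        remaining -= s
    return sizes


def sample_clone_sizes(config: SimulationConfig, rng: np.random.Generator) -> dict[str, list[int]]:
    """Marginal clone-size list per tissue for one sample pair.

    Expanded clones (size >= 2) fill the per-tissue expanded-cell budget
    exactly; every remaining TCR-bearing cell is a singleton clone.  With
    the hyperexpanded spike on, the first entry of each list is the spike
    clone (>10% of the blood tissue by construction).
    """
    config.validate()
    blood, tissue = config.tissues
    frac_b, frac_t = config._fractions()
    n = config.cells_per_tissue
    n_tcr = n - round(config.myeloid_rate * n) - round(
        sum(config.qc_violation_rates.values()) * n
    )
    out = {}
    for t, frac in ((blood, frac_b), (tissue, frac_t)):
        budget = round(frac * n_tcr)
        sizes: list[int] = []
        if config.hyperexpanded_spike:
            pct = config.spike_blood_pct if t == blood else config.spike_tissue_pct
            spike = max(2, round(pct / 100.0 * n_tcr))
            if spike > budget:
                raise ConfigurationError("spike exceeds the expanded-cell budget")
            sizes.append(spike)
            budget -= spike
        sizes.extend(_expanded_sizes_for_budget(config.clone_size_law, rng, budget,
                                                config.cells_per_tissue))
        sizes.extend([1] * (n_tcr - sum(sizes)))
        out[t] = sizes
    return out


def _stable_hash(seq: str) -> int:
    """Process-independent string hash (Python's ``hash`` is salted)."""
    h = 0
    for ch in seq:
        h = (h * 31 + ord(ch)) % 1_000_003
    return h


def _random_cdr3(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        middle = "".join(rng.choice(list(AA), size=int(rng.integers(6, 19))))
        seq = "C" + middle + "F"
        if seq not in used:
            used.add(seq)
            return seq


def _reverse_translate(aa: str) -> str:
    return "".join(_CODON.get(c, "NNN") for c in aa)


def _build_clone_plan(config: SimulationConfig, rng: np.random.Generator,
                      patient: str, is_first_patient: bool,
                      n_clean: dict[str, int]) -> list[dict]:
    """Plan every clone of one patient: per-tissue sizes, sharing,
    enriched side, subset and chain content.  ``n_clean`` is the number
    of analysis-grade TCR-bearing cells per tissue."""
    blood, tissue = config.tissues
    frac_b, frac_t = config._fractions()
    n = config.cells_per_tissue
    budgets = {blood: round(frac_b * n_clean[blood]), tissue: round(frac_t * n_clean[tissue])}

    clones: list[dict] = []
    used: set[str] = set()

    def new_clone(**kw) -> dict:
        n_tra = 0 if rng.random() < config.tra_dropout else (
            2 if rng.random() < config.dual_tra_rate else 1
        )
        clone = {
            "patient": patient,
            "tra": [_random_cdr3(rng, used) for _ in range(n_tra)],
            "trb": [_random_cdr3(rng, used)],
            "size_blood": 0, "size_tissue": 0,
            "shared": False, "enriched_tissue": "",
            "subset": CD4T if rng.random() < config.cd4_fraction else CD8T,
            "is_spike": False,
        }
        clone.update(kw)
        return clone

    if config.hyperexpanded_spike and is_first_patient:
        sb = max(2, round(config.spike_blood_pct / 100.0 * n_clean[blood]))
        st = max(2, round(config.spike_tissue_pct / 100.0 * n_clean[tissue]))
        if sb > budgets[blood] or st > budgets[tissue]:
            raise ConfigurationError("spike exceeds the expanded-cell budget")
        spike = new_clone(size_blood=sb, size_tissue=st, shared=True,
                          enriched_tissue=blood, subset=CD8T, is_spike=True)
        spike["tra"] = [config.spike_tra_cdr3]
        used.add(config.spike_tra_cdr3)
        clones.append(spike)
        budgets[blood] -= sb
        budgets[tissue] -= st

    size_key = {blood: "size_blood", tissue: "size_tissue"}
    while budgets[blood] >= 2 or budgets[tissue] >= 2:
        can_share = budgets[blood] >= 2 and budgets[tissue] >= 2
        if can_share and rng.random() < config.shared_clone_fraction:
            enriched = tissue if rng.random() < config.enriched_tissue_probability else blood
            other = blood if enriched == tissue else tissue
            s_other = min(_draw_expanded_size(config.clone_size_law, rng, n), budgets[other])
            # multiplicative frequency enrichment, stochastically rounded
            target = config.enrichment_factor * s_other
            s_enr = int(np.floor(target)) + int(rng.random() < (target % 1.0))
            s_enr = max(2, min(s_enr, budgets[enriched]))
            clone = new_clone(shared=True,
                              enriched_tissue=enriched if config.enrichment_factor > 1 else "")
            clone[size_key[other]] = s_other
            clone[size_key[enriched]] = s_enr
            budgets[other] -= s_other
            budgets[enriched] -= s_enr
        else:
            side = blood if budgets[blood] >= budgets[tissue] else tissue
            if budgets[side] < 2:
                side = tissue if side == blood else blood
            s = min(_draw_expanded_size(config.clone_size_law, rng, n), budgets[side])
            clone = new_clone()
            clone[size_key[side]] = s
            budgets[side] -= s
        for t in (blood, tissue):  # absorb unusable remainders of one cell
            if budgets[t] == 1:
                clone[size_key[t]] += 1
                budgets[t] = 0
        clone["shared"] = clone["size_blood"] > 0 and clone["size_tissue"] > 0
        clones.append(clone)

    # singletons fill the rest of each tissue's clean TCR-bearing cells
    for t in (blood, tissue):
        placed = sum(c[size_key[t]] for c in clones)
        for _ in range(n_clean[t] - placed):
            clone = new_clone()
            clone[size_key[t]] = 1
            clones.append(clone)
    return clones


def generate_paired_repertoire(
    config: SimulationConfig,
) -> tuple[dict[tuple[str, str], list[ChainRecord]], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate chains and cell metadata for every (patient, tissue).

    Returns ``(chains, cell_meta, truth_clones, truth_cells)``.  Cell
    metadata rows cover every emitted cell (including myeloid cells with
    no TCR); clone membership, cluster, true cell type and the planted
    QC-violation flag are recorded per cell in ``truth_cells``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    blood, tissue = config.tissues
    n = config.cells_per_tissue
    n_myeloid = round(config.myeloid_rate * n)

    clusters = sorted(config.cluster_profiles)
    w_single = np.array([config.cluster_profiles[c][0] for c in clusters], float)
    w_expanded = np.array([config.cluster_profiles[c][1] for c in clusters], float)
    w_single = w_single / w_single.sum()
    w_expanded = w_expanded / w_expanded.sum()

    qc_rates = config.qc_violation_rates
    qc_kinds = sorted(k for k, v in qc_rates.items() if v > 0)
    qc_p = np.array([qc_rates[k] for k in qc_kinds], float)
    if qc_p.sum() > 1:
        raise ConfigurationError("qc_violation_rates sum above 1")

    chains: dict[tuple[str, str], list[ChainRecord]] = {}
    meta_rows: list[dict] = []
    clone_rows: list[dict] = []

    for p_idx in range(config.n_patients):
        patient = f"P{p_idx + 1}"
        # planted QC violators and myeloid cells come out of the per-tissue
        # cell budget; the clonal fractions refer to the remaining clean cells
        viol_counts = {
            t: {k: int(rng.binomial(n, qc_rates[k])) for k in qc_kinds}
            for t in (blood, tissue)
        }
        n_clean = {
            t: n - n_myeloid - sum(viol_counts[t].values()) for t in (blood, tissue)
        }
        plan = _build_clone_plan(config, rng, patient, p_idx == 0, n_clean)
        for c_idx, clone in enumerate(plan):
            clone["clone_id"] = f"{patient}_cl{c_idx:05d}"
            clone_rows.append(
                {
                    "patient": patient,
                    "clone_id": clone["clone_id"],
                    "tra": ";".join(clone["tra"]) or "NA",
                    "trb": ";".join(clone["trb"]),
                    "size_blood": clone["size_blood"],
                    "size_tissue": clone["size_tissue"],
                    "shared": clone["shared"],
                    "enriched_tissue": clone["enriched_tissue"],
                    "subset": clone["subset"],
                    "is_spike": clone["is_spike"],
                }
            )
        for t in (blood, tissue):
            key = "size_blood" if t == blood else "size_tissue"
            recs: list[ChainRecord] = []
            cell_idx = 0

            def add_cell(clone: dict | None, true_type: str, violation: str) -> None:
                nonlocal cell_idx
                barcode = f"{patient}-{t}-{cell_idx:05d}"
                cell_idx += 1
                expanded = clone is not None and (clone["size_blood"] + clone["size_tissue"]) >= 2
                cluster = str(
                    rng.choice(clusters, p=w_expanded if expanded else w_single)
                ) if true_type in (CD4T, CD8T, DP) else ""
                meta_rows.append(
                    {
                        "barcode": barcode,
                        "patient": patient,
                        "tissue": t,
                        "cluster": cluster,
                        "true_type": true_type,
                        "clone_id": clone["clone_id"] if clone else "",
                        "qc_violation": violation,
                        "is_expanded_clone": bool(expanded),
                    }
                )
                if clone is None:
                    return
                for locus, seqs, vlist, jlist in (
                    ("TRA", clone["tra"], TRAV, TRAJ),
                    ("TRB", clone["trb"], TRBV, TRBJ),
                ):
                    for seq in seqs:
                        recs.append(
                            ChainRecord(
                                barcode=barcode,
                                chain_locus=locus,
                                v_gene=vlist[_stable_hash(seq) % len(vlist)],
                                j_gene=jlist[_stable_hash(seq) % len(jlist)],
                                cdr3_aa=seq,
                                cdr3_nt=_reverse_translate(seq),
                                productive=True,
                                high_confidence=True,
                                umis=int(rng.integers(1, 20)),
                            )
                        )

            # clean analysis cells carry the planned repertoire
            for clone in plan:
                true_type = DP if (not clone["is_spike"] and rng.random() < config.double_positive_rate) else clone["subset"]
                for _ in range(clone[key]):
                    add_cell(clone, true_type, "")
            # QC-violating cells: singleton TCRs, outside the planned fractions
            used_local: set[str] = set()
            for kind in qc_kinds:
                for _ in range(viol_counts[t][kind]):
                    single = {
                        "patient": patient, "clone_id": "",
                        "tra": [_random_cdr3(rng, used_local)],
                        "trb": [_random_cdr3(rng, used_local)],
                        "size_blood": 0, "size_tissue": 0, "is_spike": False,
                        "shared": False, "enriched_tissue": "",
                        "subset": CD4T if rng.random() < config.cd4_fraction else CD8T,
                    }
                    single["clone_id"] = f"{patient}_{t}_qc{cell_idx:05d}"
                    add_cell(single, single["subset"], kind)
            for _ in range(n_myeloid):
                add_cell(None, MYELOID, "")
            chains[(patient, t)] = recs

    cell_meta = pd.DataFrame(meta_rows)
    truth_cells = cell_meta.copy()
    truth_clones = pd.DataFrame(clone_rows)
    public_meta = cell_meta[["barcode", "patient", "tissue", "cluster"]].copy()
    return chains, public_meta, truth_clones, truth_cells


def generate_expression_matrices(
    config: SimulationConfig,
    truth_cells: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[CountMatrix, ADTMatrix]:
    """Gene-count and ADT matrices consistent with the planted cell flags.

    QC violators breach exactly their designated rule; expanded-clone
    cells overexpress an activation/cytotoxicity gene set and singleton
    T cells a naive/memory set, giving the DE contrasts real signal.
    True cell types receive ADT counts that reproduce CD3/CD14 T-cell
    gating and CD4/CD8 single-positive gating after CLR normalization.
    """
    named = list(FLAGGED_GENES) + ACTIVATION_GENES + NAIVE_GENES
    n_filler = config.n_genes - len(named)
    genes = named + [f"GENE{i:05d}" for i in range(n_filler)]
    gene_index = {g: i for i, g in enumerate(genes)}
    filler_ids = np.array([gene_index[g] for g in genes if g.startswith("GENE")])
    act_ids = np.array([gene_index[g] for g in ACTIVATION_GENES])
    naive_ids = np.array([gene_index[g] for g in NAIVE_GENES])
    tcr_sig_ids = np.array([gene_index[g] for g in ("CD69", "FOS", "FOSB", "JUN")])

    barcodes = list(truth_cells["barcode"])
    rows_i: list[np.ndarray] = []
    cols_i: list[np.ndarray] = []
    vals_i: list[np.ndarray] = []
    for i, cell in enumerate(truth_cells.itertuples(index=False)):
        violation = cell.qc_violation
        if violation == "low_genes":
            n_expr = int(rng.integers(40, 180))
        elif violation == "high_genes":
            n_expr = int(rng.integers(5050, min(config.n_genes - 10, 5600)))
        else:
            n_expr = int(rng.integers(600, 1500))
        pool = filler_ids
        idx = rng.choice(pool, size=min(n_expr, len(pool)), replace=False)
        counts = 1 + rng.poisson(0.4, size=idx.size)
        extra_ids: list[np.ndarray] = [idx]
        extra_vals: list[np.ndarray] = [counts]
        if cell.true_type in (CD4T, CD8T, DP):
            marker = act_ids if cell.is_expanded_clone else naive_ids
            extra_ids.append(marker)
            extra_vals.append(3 + rng.poisson(5.0, size=marker.size))
            if cell.tissue == config.tissues[1]:
                # recent-TCR-engagement signature of tissue-resident T cells
                extra_ids.append(tcr_sig_ids)
                extra_vals.append(2 + rng.poisson(4.0, size=tcr_sig_ids.size))
        idx = np.concatenate(extra_ids)
        counts = np.concatenate(extra_vals)
        if violation == "flagged_gene":
            g = gene_index[FLAGGED_GENES[int(rng.integers(len(FLAGGED_GENES)))]]
            total = int(counts.sum())
            c = max(1, int(np.ceil(0.031 * total / (1 - 0.031))))
            idx = np.concatenate([idx, [g]])
            counts = np.concatenate([counts, [c]])
        rows_i.append(np.full(idx.size, i))
        cols_i.append(idx)
        vals_i.append(counts)

    mat = sp.coo_matrix(
        (np.concatenate(vals_i), (np.concatenate(rows_i), np.concatenate(cols_i))),
        shape=(len(barcodes), len(genes)),
        dtype=np.int64,
    ).tocsr()
    count_matrix = CountMatrix(cells=barcodes, genes=genes, counts=mat)

    proteins = ["CD3", "CD4", "CD8", "CD14"]
    raw = np.zeros((len(barcodes), len(proteins)), dtype=np.int64)
    for j, prot in enumerate(proteins):
        for true_type, profile in config.adt_profiles.items():
            mask = (truth_cells["true_type"] == true_type).to_numpy()
            if not mask.any():
                continue
            mean, r = profile[prot]
            p = r / (r + mean)
            raw[mask, j] = rng.negative_binomial(r, p, size=int(mask.sum()))
    adt = ADTMatrix(cells=barcodes, proteins=proteins, raw=raw)
    return count_matrix, adt


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full simulator: repertoire, expression and ADT."""
    chains, cell_meta, truth_clones, truth_cells = generate_paired_repertoire(config)
    rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    counts, adt = generate_expression_matrices(config, truth_cells, rng)
    return SimulatedDataset(
        chains=chains, cell_meta=cell_meta, counts=counts, adt=adt,
        truth_clones=truth_clones, truth_cells=truth_cells, config=config,
    )


def _contig_frame(records: list[ChainRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "barcode": [r.barcode for r in records],
            "is_cell": "true",
            "high_confidence": [str(r.high_confidence).lower() for r in records],
            "chain": [r.chain_locus for r in records],
            "v_gene": [r.v_gene for r in records],
            "j_gene": [r.j_gene for r in records],
            "cdr3": [r.cdr3_aa for r in records],
            "cdr3_nt": [r.cdr3_nt for r in records],
            "productive": [str(r.productive).lower() for r in records],
            "umis": [r.umis for r in records],
        }
    )


def emit_dataset(dataset: SimulatedDataset, out_dir: str | Path, overwrite: bool = False) -> Path:
    """Write the simulated cohort in the pipeline's input formats.

    Layout: ``<patient>_<tissue>/filtered_contig_annotations.csv`` per
    sample, ``expression/`` (MatrixMarket genes x cells + features.tsv +
    barcodes.tsv), ``adt.csv``, ``cell_meta.csv``, the two ground-truth
    tables and the configuration used.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise ConfigurationError(f"output directory {out} is not empty (use overwrite)")
    out.mkdir(parents=True, exist_ok=True)

    for (patient, tissue), recs in sorted(dataset.chains.items()):
        sample_dir = out / f"{patient}_{tissue}"
        sample_dir.mkdir(exist_ok=True)
        _contig_frame(recs).to_csv(sample_dir / "filtered_contig_annotations.csv", index=False)

    expr_dir = out / "expression"
    expr_dir.mkdir(exist_ok=True)
    scipy.io.mmwrite(str(expr_dir / "matrix.mtx"), dataset.counts.counts.T.tocoo())
    with open(expr_dir / "features.tsv", "w") as fh:
        for g in dataset.counts.genes:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(expr_dir / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(dataset.counts.cells) + "\n")

    adt_df = pd.DataFrame(dataset.adt.raw, columns=dataset.adt.proteins)
    adt_df.insert(0, "barcode", dataset.adt.cells)
    adt_df.to_csv(out / "adt.csv", index=False)

    dataset.cell_meta.to_csv(out / "cell_meta.csv", index=False)
    dataset.truth_clones.to_csv(out / "ground_truth_clones.csv", index=False)
    dataset.truth_cells.to_csv(out / "ground_truth_cells.csv", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=True)
    return out


def read_back_dataset(out_dir: str | Path) -> SimulatedDataset:
    """Re-read an emitted cohort through the package's own readers."""
    from . import io as pio

    out = Path(out_dir)
    config = SimulationConfig.from_dict(yaml.safe_load((out / "config.yaml").read_text()))
    chains = {}
    for sample_dir in sorted(out.glob("P*_*")):
        patient, tissue = sample_dir.name.split("_", 1)
        chains[(patient, tissue)] = pio.read_contigs(
            sample_dir / "filtered_contig_annotations.csv"
        )
    counts = pio.read_count_matrix(
        out / "expression" / "matrix.mtx",
        out / "expression" / "features.tsv",
        out / "expression" / "barcodes.tsv",
    )
    adt_df = pd.read_csv(out / "adt.csv")
    adt = ADTMatrix(
        cells=list(adt_df["barcode"]),
        proteins=[c for c in adt_df.columns if c != "barcode"],
        raw=adt_df.drop(columns="barcode").to_numpy(),
    )
    cell_meta = pd.read_csv(out / "cell_meta.csv", keep_default_na=False)
    truth_clones = pd.read_csv(out / "ground_truth_clones.csv", keep_default_na=False)
    truth_cells = pd.read_csv(out / "ground_truth_cells.csv", keep_default_na=False)
    return SimulatedDataset(
        chains=chains, cell_meta=cell_meta, counts=counts, adt=adt,
        truth_clones=truth_clones, truth_cells=truth_cells, config=config,
    )
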