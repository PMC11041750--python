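"""End-to-end pipeline: simulate/read -> QC -> gate -> clonotypes ->
classify -> enrich -> quantify -> overlap -> annotate -> DE -> report.

Each stage is a function that reads its inputs from and writes its
outputs to one run directory, so stages are independently runnable (and
the CLI exposes them one by one).  Every run echoes the resolved
thresholds next to its outputs and logs cell/clone counts per stage;
outputs are deterministically ordered, so reruns on unchanged inputs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from . import clonality, gating
from .config import DEFAULT_TISSUES, ThresholdConfig
from .de import GroupSpec, define_groups, wilcoxon_de
from .errors import ConfigurationError
from .io import read_annotation_db, write_table
from .simulate import SimulationConfig, SimulatedDataset, emit_dataset, generate_dataset, read_back_dataset

log = logging.getLogger("pairedtcr")

DEFAULT_CONTRASTS = [
    {"name": "single_vs_expanded", "kind": "expansion",
     "classes_a": ["Single"], "classes_b": ["Small", "Medium", "Large"]},
    {"name": "blood_vs_tissue_enriched", "kind": "enrichment",
     "classes_a": ["PBMCEnriched"], "classes_b": ["TissueEnriched"]},
    {"name": "treg_blood_vs_tissue", "kind": "tissue_in_cluster", "cluster": "C5",
     "tissue_a": DEFAULT_TISSUES[0], "tissue_b": DEFAULT_TISSUES[1]},
]


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str = "results/run"
    data_dir: str | None = None  # read an emitted dataset; None -> simulate
    sim: SimulationConfig = field(default_factory=lambda: SimulationConfig(seed=0))
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    overlap_clusters: tuple[str, str] = ("C6", "C3")
    annotation_db: str | None = None
    contrasts: list[dict] = field(default_factory=lambda: [dict(c) for c in DEFAULT_CONTRASTS])
    scopes: tuple[str, ...] = ("all", "CD4", "CD8")
    overwrite: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        d["thresholds"] = self.thresholds.to_dict()
        d["overlap_clusters"] = list(self.overlap_clusters)
        d["scopes"] = list(self.scopes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimulationConfig.from_dict(d["sim"])
        if "thresholds" in d:
            d["thresholds"] = ThresholdConfig.from_dict(d["thresholds"])
        if "overlap_clusters" in d:
            d["overlap_clusters"] = tuple(d["overlap_clusters"])
        if "scopes" in d:
            d["scopes"] = tuple(d["scopes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def load_dataset(config: PipelineConfig) -> SimulatedDataset:
    if config.data_dir is not None:
        path = Path(config.data_dir)
        if not path.exists():
            raise ConfigurationError(f"dataset directory {path} does not exist")
        log.info("reading dataset from %s", path)
        return read_back_dataset(path)
    log.info("simulating cohort: %d patients x %d cells/tissue, seed %s",
             config.sim.n_patients, config.sim.cells_per_tissue, config.sim.seed)
    return generate_dataset(config.sim)


def stage_qc(dataset: SimulatedDataset, thresholds: ThresholdConfig, out: Path) -> list[str]:
    passing, reports = gating.qc_filter(dataset.counts, thresholds.qc)
    table = pd.DataFrame(
        {
            "barcode": [r.barcode for r in reports],
            "n_genes_detected": [r.n_genes_detected for r in reports],
            "passed": [r.passed for r in reports],
            "failure_reasons": ["; ".join(r.failure_reasons) for r in reports],
        }
    )
    for g in thresholds.qc.flagged_genes:
        table[f"pct_{g}"] = [round(r.pct_per_flagged_gene.get(g, 0.0), 6) for r in reports]
    write_table(table, out / "qc_report.csv", sort_by=["barcode"])
    log.info("qc: %d of %d cells pass", len(passing), len(reports))
    return passing


def stage_gate(dataset: SimulatedDataset, thresholds: ThresholdConfig, out: Path) -> pd.DataFrame:
    adt = gating.clr_normalize(dataset.adt, axis="per_feature")
    t_cells = set(gating.gate_t_cells(adt, thresholds.gates))
    labels = gating.gate_cd4_cd8(adt, thresholds.gates)
    table = pd.DataFrame(
        {
            "barcode": adt.cells,
            "is_t_cell": [bc in t_cells for bc in adt.cells],
            "cd4_cd8_label": [labels[bc] for bc in adt.cells],
        }
    )
    write_table(table, out / "gating.csv", sort_by=["barcode"])
    log.info("gate: %d T cells of %d cells; %d CD4 / %d CD8 single-positive",
             len(t_cells), len(adt.cells),
             int((table["cd4_cd8_label"] == gating.CD4).sum()),
             int((table["cd4_cd8_label"] == gating.CD8).sum()))
    return table


def stage_clonotypes(
    dataset: SimulatedDataset, thresholds: ThresholdConfig, out: Path
) -> pd.DataFrame:
    qc = pd.read_csv(out / "qc_report.csv")
    gate = pd.read_csv(out / "gating.csv")
    passed = set(qc.loc[qc["passed"], "barcode"])
    t_cells = set(gate.loc[gate["is_t_cell"], "barcode"])
    labels = dict(zip(gate["barcode"], gate["cd4_cd8_label"]))

    meta = dataset.cell_meta
    keep = meta["barcode"].isin(passed) & meta["barcode"].isin(t_cells)
    analysis_meta = meta.loc[keep, ["barcode", "patient", "tissue", "cluster"]].copy()
    analysis_meta["subset"] = [labels[bc] for bc in analysis_meta["barcode"]]
    analysis_barcodes = set(analysis_meta["barcode"])
    chains = [
        rec
        for recs in dataset.chains.values()
        for rec in recs
        if rec.barcode in analysis_barcodes
    ]
    frame = clonality.build_clonotypes(chains, analysis_meta, productive_only=True)
    write_table(frame, out / "repertoire.csv", sort_by=["barcode"])
    n_tcr = int((frame["clonotype"] != clonality.MISSING).sum())
    log.info("clonotypes: %d analysis cells, %d TCR-bearing, %d distinct clonotypes",
             len(frame), n_tcr, frame.loc[frame["clonotype"] != "", "clonotype"].nunique())
    return frame


def _read_repertoire(out: Path) -> pd.DataFrame:
    return pd.read_csv(out / "repertoire.csv", keep_default_na=False)


def stage_classify(thresholds: ThresholdConfig, out: Path,
                   scopes: tuple[str, ...] = ("all", "CD4", "CD8"),
                   tissues: tuple[str, str] = DEFAULT_TISSUES) -> dict[str, pd.DataFrame]:
    frame = _read_repertoire(out)
    ledgers = {}
    for scope in scopes:
        ledger = clonality.compute_abundance(
            frame, scope, thresholds=thresholds.expansion, tissues=tissues
        )
        write_table(ledger, out / f"ledger_{scope}.csv", sort_by=["patient", "clonotype"])
        ledgers[scope] = ledger
        log.info("classify[%s]: %d clones", scope, len(ledger))
    return ledgers


def stage_enrich(thresholds: ThresholdConfig, out: Path,
                 scopes: tuple[str, ...] = ("all", "CD4", "CD8")) -> dict[str, pd.DataFrame]:
    ledgers = {}
    for scope in scopes:
        ledger = pd.read_csv(out / f"ledger_{scope}.csv", keep_default_na=False)
        ledger = clonality.score_enrichment(ledger, thresholds.enrichment)
        write_table(ledger, out / f"ledger_{scope}.csv", sort_by=["patient", "clonotype"])
        ledgers[scope] = ledger
        log.info("enrich[%s]: %s", scope,
                 ledger["enrichment"].value_counts().sort_index().to_dict())
    return ledgers


def stage_overlap(clusters: tuple[str, str], out: Path) -> pd.DataFrame:
    frame = _read_repertoire(out)
    table = clonality.cluster_overlap(frame, clusters[0], clusters[1])
    write_table(table, out / "cluster_overlap.csv", sort_by=())
    log.info("overlap %s vs %s: %d shared clonotypes", clusters[0], clusters[1], len(table))
    return table


def stage_annotate(db_path: str | None, out: Path) -> pd.DataFrame:
    frame = _read_repertoire(out)
    db = read_annotation_db(db_path) if db_path else []
    hits = clonality.match_annotations(frame, db)
    write_table(hits, out / "annotation_hits.csv")
    log.info("annotate: %d hits over %d db records", len(hits), len(db))
    return hits


def _normalized_expression(dataset: SimulatedDataset, scale: float = 1e4) -> tuple[sp.csr_matrix, dict[str, int], list[str]]:
    mat = dataset.counts.counts.astype(float).tocsr()
    totals = np.asarray(mat.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    norm = sp.diags(scale / totals) @ mat
    norm.data = np.log1p(norm.data)
    index = {bc: i for i, bc in enumerate(dataset.counts.cells)}
    return norm.tocsr(), index, list(dataset.counts.genes)


def stage_de(dataset: SimulatedDataset, contrasts: list[dict], out: Path,
             chunk_genes: int = 1500) -> dict[str, pd.DataFrame]:
    frame = _read_repertoire(out)
    ledger = pd.read_csv(out / "ledger_all.csv", keep_default_na=False)
    norm, index, genes = _normalized_expression(dataset)
    results = {}
    for c in contrasts:
        spec = GroupSpec(
            name=c["name"], kind=c["kind"],
            classes_a=frozenset(c.get("classes_a", [])),
            classes_b=frozenset(c.get("classes_b", [])),
            cluster=c.get("cluster", ""),
            tissue_a=c.get("tissue_a", DEFAULT_TISSUES[0]),
            tissue_b=c.get("tissue_b", DEFAULT_TISSUES[1]),
        )
        cells_a, cells_b = define_groups(frame, ledger, spec)
        rows = [index[bc] for bc in cells_a + cells_b]
        sub = norm[rows]
        parts = []
        for start in range(0, len(genes), chunk_genes):
            cols = slice(start, min(start + chunk_genes, len(genes)))
            block = pd.DataFrame(
                np.asarray(sub[:, cols].todense()),
                index=cells_a + cells_b, columns=genes[cols],
            )
            parts.append(
                wilcoxon_de(block, (cells_a, cells_b), total_genes=len(genes),
                            method="asymptotic")
            )
        table = pd.concat(parts, ignore_index=True)
        table["abs_lfc"] = table["log2fc"].abs()
        table = table.sort_values(
            ["p_value", "abs_lfc", "gene"], ascending=[True, False, True], kind="mergesort"
        ).drop(columns="abs_lfc").reset_index(drop=True)
        write_table(table, out / f"de_{spec.name}.csv", sort_by=())
        results[spec.name] = table
        log.info("de[%s]: |A|=%d |B|=%d, %d significant genes",
                 spec.name, len(cells_a), len(cells_b), int(table["significant"].sum()))
    return results


def make_report_tables(out: Path, scopes: tuple[str, ...] = ("all", "CD4", "CD8"),
                       tissues: tuple[str, str] = DEFAULT_TISSUES) -> dict[str, pd.DataFrame]:
    """Tidy quantification tables mirroring the published bar plots."""
    frame = _read_repertoire(out)
    tables = {}
    for scope in scopes:
        ledger = pd.read_csv(out / f"ledger_{scope}.csv", keep_default_na=False)
        sub = frame if scope == "all" else frame[frame["subset"] == scope]
        if (sub["clonotype"] != clonality.MISSING).sum() == 0:
            continue
        for label in ("expansion", "enrichment"):
            pooled = clonality.quantify_by_group(sub, ledger, ["tissue"], label, tissues=tissues)
            per_patient = clonality.quantify_by_group(
                sub, ledger, ["patient", "tissue"], label, tissues=tissues
            )
            tables[f"{label}_by_tissue_{scope}"] = pooled
            tables[f"{label}_by_patient_tissue_{scope}"] = per_patient
        tables[f"enrichment_by_cluster_{scope}"] = clonality.quantify_by_group(
            sub, ledger, ["cluster", "tissue"], "enrichment", tissues=tissues
        )
    for name, table in tables.items():
        write_table(table, out / f"{name}.csv", sort_by=())
    log.info("report: wrote %d quantification tables", len(tables))
    return tables


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write the result bundle under
    ``config.out_dir``; returns that path."""
    config.thresholds.validate()
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise ConfigurationError(f"output directory {out} is not empty (use overwrite)")
    out.mkdir(parents=True, exist_ok=True)

    dataset = load_dataset(config)
    with open(out / "thresholds.yaml", "w") as fh:
        yaml.safe_dump(config.thresholds.to_dict(), fh, sort_keys=True)
    with open(out / "pipeline_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    tissues = dataset.config.tissues
    stage_qc(dataset, config.thresholds, out)
    stage_gate(dataset, config.thresholds, out)
    frame = stage_clonotypes(dataset, config.thresholds, out)
    stage_classify(config.thresholds, out, config.scopes, tissues)
    ledgers = stage_enrich(config.thresholds, out, config.scopes)
    stage_overlap(config.overlap_clusters, out)
    stage_annotate(config.annotation_db, out)
    stage_de(dataset, config.contrasts, out)
    make_report_tables(out, config.scopes, tissues)

    manifest = {
        "n_cells": len(dataset.cell_meta),
        "n_analysis_cells": int(len(frame)),
        "n_tcr_bearing": int((frame["clonotype"] != clonality.MISSING).sum()),
        "n_clonotypes": {s: int(len(l)) for s, l in ledgers.items()},
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline complete: %s", out)
    return out
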