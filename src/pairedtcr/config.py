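"""All printed classification, QC and gating constants in one configurable home.

Defaults are the study's published values where the study prints one
(expansion bins, QC bounds, CD4/CD8 ADT gates); where it does not
(CD3/CD14 gates, the quantitative enrichment rule) the defaults are this
package's documented choices — see docs/methods.md before changing them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ConfigurationError

#: tissue labels used throughout; index 0 is the blood compartment
DEFAULT_TISSUES = ("PBMC", "plaque")


@dataclass
class QCThresholds:
    """Cell-level QC: detected-gene bounds (inclusive) and per-gene
    percentage caps (strict) on doublet/apoptosis marker lncRNAs."""

    min_genes: int = 200
    max_genes: int = 5000
    flagged_genes: tuple[str, ...] = ("KCNQ1OT1", "UGDH-AS1", "GHET1")
    max_flagged_pct: float = 2.0

    def validate(self) -> None:
        if not (0 < self.min_genes <= self.max_genes):
            raise ConfigurationError("need 0 < min_genes <= max_genes")
        if not (0 < self.max_flagged_pct <= 100):
            raise ConfigurationError("max_flagged_pct must be in (0, 100]")


@dataclass
class GateThresholds:
    """ADT gates on CLR-normalized units; all inequalities strict except
    the CD14 upper bound.  cd3_min/cd14_max carry no published value and
    default to artifact choices."""

    cd4_min: float = 0.75
    cd8_min: float = 1.0
    cd3_min: float = 0.5
    cd14_max: float = 0.5

    def validate(self) -> None:
        for name in ("cd4_min", "cd8_min", "cd3_min", "cd14_max"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ConfigurationError(f"{name} must be finite")


@dataclass
class ExpansionThresholds:
    """Upper bounds (percent of the scoped TCR-bearing cells) of the
    Small / Medium / Large bins; above ``large_max_pct`` is Hyperexpanded
    and a single occurrence is always Single."""

    small_max_pct: float = 0.1
    medium_max_pct: float = 1.0
    large_max_pct: float = 10.0

    def validate(self) -> None:
        if not (0 < self.small_max_pct < self.medium_max_pct < self.large_max_pct < 100):
            raise ConfigurationError(
                "need 0 < small_max_pct < medium_max_pct < large_max_pct < 100"
            )


@dataclass
class EnrichmentParams:
    """Operational form of 'frequency higher in one tissue': at least a
    ``fold_threshold``-fold frequency excess, with absence from the other
    tissue qualifying once the clone has ``min_cells_expanded`` cells."""

    fold_threshold: float = 2.0
    min_cells_expanded: int = 2

    def validate(self) -> None:
        if self.fold_threshold < 1:
            raise ConfigurationError("fold_threshold must be >= 1")
        if self.min_cells_expanded < 1:
            raise ConfigurationError("min_cells_expanded must be >= 1")


@dataclass
class ThresholdConfig:
    """Bundle of every tunable constant, serializable alongside results."""

    qc: QCThresholds = field(default_factory=QCThresholds)
    gates: GateThresholds = field(default_factory=GateThresholds)
    expansion: ExpansionThresholds = field(default_factory=ExpansionThresholds)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)

    def validate(self) -> None:
        self.qc.validate()
        self.gates.validate()
        self.expansion.validate()
        self.enrichment.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["qc"]["flagged_genes"] = list(d["qc"]["flagged_genes"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdConfig":
        qc = d.get("qc", {})
        if "flagged_genes" in qc:
            qc = {**qc, "flagged_genes": tuple(qc["flagged_genes"])}
        cfg = cls(
            qc=QCThresholds(**qc),
            gates=GateThresholds(**d.get("gates", {})),
            expansion=ExpansionThresholds(**d.get("expansion", {})),
            enrichment=EnrichmentParams(**d.get("enrichment", {})),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ThresholdConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
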