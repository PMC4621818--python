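"""Pipeline configuration: every stage threshold with its default, YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .lysimetry import LysimetryConfig


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end pipeline.

    Defaults are the published analysis settings: -log10 P > 3 association
    threshold with >= 2 (model, year) detections, fold change >= 2 and
    FDR <= 0.01 for DEGs, < 2 cM genetic and <= 1.8 Mb physical
    co-localization windows, alpha 0.05 for score correlations and genotype
    comparisons.
    """

    seed: int = 1
    out_dir: str = "drylysim_out"

    # stage toggles
    run_lysimetry: bool = True
    run_phenotypes: bool = True
    run_association: bool = True
    run_expression: bool = True
    run_coloc: bool = True

    # synthetic-run design
    n_accessions: int = 95
    n_snps: int = 1127
    n_genes: int = 2000
    n_plants_per_genotype: int = 7
    pretreatment_days: int = 7
    drought_days: int = 10
    recovery_days: int = 0

    # phenotype / association thresholds
    correlation_alpha: float = 0.05
    correlation_method: str = "pearson"
    assoc_threshold_neg_log10_p: float = 3.0
    assoc_consistency_min: int = 2
    maf_min: float = 0.05
    missing_max: float = 0.2

    # expression thresholds
    fc_min: float = 2.0
    fdr_max: float = 0.01
    replicate_r_flag: float = 0.9

    # co-localization windows
    max_cm: float = 2.0
    max_bp: int = 1_800_000
    blast_min_len: int = 80
    blast_max_evalue: float = 1e-10

    # genotype comparison
    compare_alpha: float = 0.05

    lysimetry: LysimetryConfig = field(default_factory=LysimetryConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        d["lysimetry"]["predawn_window"] = list(d["lysimetry"]["predawn_window"])
        d["lysimetry"]["evening_window"] = list(d["lysimetry"]["evening_window"])
        d["lysimetry"]["topp_coeffs"] = list(d["lysimetry"]["topp_coeffs"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        lys = d.pop("lysimetry", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**d)
        if lys:
            lys = dict(lys)
            for key in ("predawn_window", "evening_window", "topp_coeffs"):
                if key in lys:
                    lys[key] = tuple(lys[key])
            cfg.lysimetry = LysimetryConfig(**lys)
        return cfg
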