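"""Pipeline-wide configuration.

All tunable thresholds of the analysis live in one dataclass so that every
stage (simulation, envelope, ESM calling, selection stratification) reads the
same values. Defaults follow the study conditions this package models: a
global canonical splice-site mutation rate of 13.4% among hereditary disease
alleles, a 10% background rate of exonic splicing mutations in assayed
disease alleles, a 99.9% simulation envelope, and MAF strata at 0.01% / 1%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Shared knobs for the SSM/ESM enrichment pipeline.

    Parameters
    ----------
    seed
        Master seed for all stochastic stages.
    n_reps
        Monte-Carlo replicates per entity in the sampling envelope.
    ci_level
        Coverage of the simulated envelope (0.999 = 99.9%).
    global_ssm_weight
        Fraction of disease alleles that are canonical splice-site
        mutations; the weight of the null sampling model.
    esm_background
        Background rate at which assayed exonic disease alleles disrupt
        splicing.
    prob_threshold
        Classifier probability above which a gene is called SSM-prone.
    maf_rare, maf_common
        Minor-allele-frequency cutoffs for the rare (<0.01%) and common
        (>1%) population-variant strata.
    pseudocount
        Added to every raw read count before log-ratio computation.
    fold_threshold
        Minimum allelic fold change (linear scale) for an ESM call.
    esm_fdr
        Benjamini-Hochberg FDR level for the ESM count test.
    """

    seed: int = 0
    n_reps: int = 1000
    ci_level: float = 0.999
    global_ssm_weight: float = 0.134
    esm_background: float = 0.10
    prob_threshold: float = 0.6
    maf_rare: float = 0.0001
    maf_common: float = 0.01
    pseudocount: float = 0.5
    fold_threshold: float = 1.5
    esm_fdr: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.n_reps < 100:
            raise ValueError(f"n_reps must be >= 100, got {self.n_reps}")
        for name in ("global_ssm_weight", "esm_background", "prob_threshold",
                     "maf_rare", "maf_common"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.fold_threshold < 1.0:
            raise ValueError("fold_threshold is a linear fold change >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
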