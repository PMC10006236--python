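"""Configuration objects for the simulator and the end-to-end pipeline."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InvalidConfigError


@dataclass
class SimConfig:
    """Knobs of the synthetic-data generator.

    One global integer ``seed`` drives every generator through independent
    derived streams, so tables are individually reproducible and mutually
    uncorrelated.

    Parameters
    ----------
    seed
        Master seed; equal configs with equal seeds yield byte-identical
        tables.
    n_genes
        Candidate genes, split half-and-half between the xenobiotic
        metabolism (XMG) and DNA repair (DRG) pathways.
    n_samples_per_group
        Replicates per expression group (healthy non-smokers HNS, healthy
        smokers HS, smokers with lung cancer SLC); also the number of
        samples carrying DNase signal.
    n_dhs_per_gene
        DNase I hypersensitive sites simulated within +/-100 kb of each TSS.
    n_snvs
        Total variants in the annotation table.
    n_populations
        Reference populations carrying allele-frequency columns.
    n_cases, n_controls
        Case-control cohort sizes (defaults mirror a 101/401 study design).
    effect_log_or
        Per-risk-allele log odds planted at the associated variant.
    eqtl_beta
        Planted genotype-to-expression slope for designated cis-eQTLs.
    censor_rate
        Expected fraction of censored survival records, in [0, 1].
    hazard_ratio_true
        Multiplicative hazard for risk-allele carriers (dominant collapse).
    n_planted_genes
        Genes given the reciprocal expression pattern (up in HS vs HNS,
        down in SLC vs HS).
    planted_fold_change
        Group-mean fold change of the planted pattern.
    n_planted_snvs
        Variants constructed to survive every cascade filter.
    n_shortlist_snvs
        Subset of the planted variants given promoter chromatin plus a
        lung eQTL p < 0.01, i.e. the genotyping shortlist ground truth.
    n_corr_dhs_per_gene
        DHSs per gene with a planted DNase-expression correlation.
    """

    seed: int = 0
    n_genes: int = 20
    n_samples_per_group: int = 20
    n_dhs_per_gene: int = 10
    n_snvs: int = 300
    n_populations: int = 5
    n_cases: int = 101
    n_controls: int = 401
    effect_log_or: float = math.log(2.5)
    eqtl_beta: float = -0.4
    censor_rate: float = 0.3
    hazard_ratio_true: float = 2.0
    n_planted_genes: int = 10
    planted_fold_change: float = 2.0
    n_planted_snvs: int = 22
    n_shortlist_snvs: int = 3
    n_corr_dhs_per_gene: int = 2
    expression_noise_sd: float = 0.5  # sd of log2 expression noise

    @classmethod
    def scaled(cls, seed: int = 0, n_genes: int = 20,
               n_snvs: int = 300, **kw) -> "SimConfig":
        """Config with planted counts clamped to the table sizes, for
        quick small-scale runs."""
        kw.setdefault("n_planted_genes", min(10, max(1, n_genes // 2)))
        kw.setdefault("n_planted_snvs", min(22, max(1, n_snvs // 4)))
        kw.setdefault("n_shortlist_snvs",
                      min(3, kw["n_planted_snvs"]))
        return cls(seed=seed, n_genes=n_genes, n_snvs=n_snvs, **kw)

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_samples_per_group": self.n_samples_per_group,
            "n_dhs_per_gene": self.n_dhs_per_gene,
            "n_snvs": self.n_snvs,
            "n_populations": self.n_populations,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "n_planted_genes": self.n_planted_genes,
            "n_planted_snvs": self.n_planted_snvs,
            "n_shortlist_snvs": self.n_shortlist_snvs,
        }
        for name, value in counts.items():
            if value < 0:
                raise InvalidConfigError(f"{name} must be >= 0, got {value}")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise InvalidConfigError(
                f"censor_rate must be in [0, 1], got {self.censor_rate}"
            )
        if self.hazard_ratio_true <= 0:
            raise InvalidConfigError("hazard_ratio_true must be positive")
        if self.planted_fold_change < 1:
            raise InvalidConfigError("planted_fold_change must be >= 1")
        if self.n_planted_genes > self.n_genes:
            raise InvalidConfigError("n_planted_genes exceeds n_genes")
        if self.n_shortlist_snvs > self.n_planted_snvs:
            raise InvalidConfigError("n_shortlist_snvs exceeds n_planted_snvs")
        if self.n_planted_snvs > self.n_snvs:
            raise InvalidConfigError("n_planted_snvs exceeds n_snvs")


@dataclass
class Thresholds:
    """All stage cut-offs of the prioritization cascade, with the
    defaults used throughout the analysis."""

    fold_change: float = 1.5
    expression_alpha: float = 0.05
    dhs_k: int = 10
    dhs_alpha: float = 0.05
    window_kb: int = 100
    n_perm: int = 10_000
    regulome_max_class: str = "4"
    eqtl_alpha: float = 0.05
    impact_alpha: float = 0.001
    r2_min: float = 0.8
    maf_min: float = 0.01
    shortlist_alpha: float = 0.01

    def validate(self) -> None:
        for name in ("expression_alpha", "dhs_alpha", "eqtl_alpha",
                     "impact_alpha", "shortlist_alpha"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise InvalidConfigError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 <= self.r2_min <= 1.0:
            raise InvalidConfigError("r2_min must be in [0, 1]")
        if not 0.0 <= self.maf_min < 0.5:
            raise InvalidConfigError("maf_min must be in [0, 0.5)")
        if self.fold_change < 1:
            raise InvalidConfigError("fold_change must be >= 1")
        if self.dhs_k < 0 or self.window_kb <= 0 or self.n_perm <= 0:
            raise InvalidConfigError("dhs_k, window_kb, n_perm out of range")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration: simulation inputs (or paths to
    pre-generated tables), stage thresholds, and the output directory."""

    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    out_dir: Path = Path("cisreg_out")
    input_dir: Path | None = None  # read tables instead of simulating

    def validate(self) -> None:
        self.sim.validate()
        self.thresholds.validate()
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise InvalidConfigError(f"input_dir not found: {self.input_dir}")
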