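"""Simulation and pipeline run configuration objects."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic two-species factorial experiment.

    Defaults are scaled to the study design being emulated: two sister
    species with ~14,000 / ~13,500 expressed genes, ~10,000 one-to-one
    orthologs, a 2 (population) x 2 (rearing temperature) factorial with 3
    replicates per cell, and one pooled sequencing library per population.
    """

    n_genes_per_species: int = 14000
    n_orthologs: int = 10000
    arms: dict = field(
        default_factory=lambda: {"2L": 2800, "2R": 2900, "3L": 2700, "3R": 3500, "X": 2200}
    )
    n_replicates: int = 3
    temperatures: tuple = (21, 29)
    baseline_mean_log2: float = 7.0
    baseline_sd_log2: float = 1.5
    dispersion_shape: float = 10.0  # NB shape; variance = mu + mu^2/shape
    de_fraction_per_temp: float = 0.06
    shared_de_fraction: float = 0.01
    same_direction_prob: float = 0.825
    plasticity_fraction: float = 0.15
    gei_fraction: float = 0.02
    effect_size_log2: float = 1.0
    snps_per_gene_mean: float = 3.0
    annotation_mix: dict = field(
        default_factory=lambda: {"5'UTR": 0.15, "3'UTR": 0.25, "CDS": 0.60}
    )
    fst_background_F: float = 0.05
    fst_outlier_F: float = 0.5
    outlier_fraction: float = 0.02
    outlier_in_de_enrichment: float = 3.0
    pool_coverage_mean: float = 100.0
    inversion_fraction: float = 0.3  # fraction of 3R genes inside inversion spans
    seed: int = 0

    def __post_init__(self):
        for name in (
            "de_fraction_per_temp",
            "shared_de_fraction",
            "same_direction_prob",
            "plasticity_fraction",
            "gei_fraction",
            "outlier_fraction",
            "fst_background_F",
            "fst_outlier_F",
            "inversion_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.shared_de_fraction > self.de_fraction_per_temp:
            raise ConfigError("shared_de_fraction exceeds de_fraction_per_temp")
        if abs(sum(self.annotation_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("annotation_mix must sum to 1")
        if self.dispersion_shape <= 0 or self.effect_size_log2 < 0:
            raise ConfigError("dispersion_shape must be > 0, effect size >= 0")
        if self.pool_coverage_mean <= 0:
            raise ConfigError("pool_coverage_mean must be > 0")
        if self.snps_per_gene_mean <= 0:
            raise ConfigError("snps_per_gene_mean must be > 0")
        if self.n_orthologs > self.n_genes_per_species:
            raise ConfigError("n_orthologs exceeds n_genes_per_species")
        capacity = sum(self.arms.values())
        if capacity < self.n_genes_per_species:
            raise ConfigError(
                f"arm capacities ({capacity}) below requested genes "
                f"({self.n_genes_per_species})"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["temperatures"] = list(self.temperatures)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "temperatures" in d:
            d["temperatures"] = tuple(d["temperatures"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunConfig:
    """End-to-end pipeline settings (thresholds mirror the analysis defaults)."""

    fdr: float = 0.05
    min_mean_count: float = 10.0
    tail_quantiles: tuple = (0.01, 0.005, 0.0025)
    crossover_threshold: float = 0.5
    n_perm: int = 1000
    n_boot: int = 1000
    min_coverage: int = 10
    min_allele_reads: int = 2
    min_maf: float = 0.01
    seed: int = 0
    out_dir: str = "paraclines_out"

    def __post_init__(self):
        if not 0 < self.fdr < 1:
            raise ConfigError("fdr must lie in (0, 1)")
        if any(not 0 < q < 1 for q in self.tail_quantiles):
            raise ConfigError("tail quantiles must lie in (0, 1)")
        if self.n_perm < 1 or self.n_boot < 1:
            raise ConfigError("n_perm and n_boot must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tail_quantiles"] = list(self.tail_quantiles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "tail_quantiles" in d:
            d["tail_quantiles"] = tuple(d["tail_quantiles"])
        return cls(**d)
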