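"""Core data containers shared across the pipeline.

Conventions
-----------
* Methylation matrices are CpG x sample; genotype matrices are SNP x sample.
* Genomic coordinates are 1-based inclusive (Illumina manifest / VCF
  convention); BED files are converted at the I/O boundary.
* Missing genotype dosages are ``numpy.nan`` in an otherwise {0,1,2} float
  matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass
class BetaMatrix:
    """CpG x sample matrix of methylation beta values in [0, 1].

    ``cpg_map`` carries per-CpG genomic annotation: a DataFrame indexed by
    CpG id with columns ``chrom``, ``pos`` (1-based) and ``genes`` (list of
    ``(gene_symbol, distance_bp)`` tuples for genes near the probe).
    """

    values: np.ndarray
    cpg_ids: pd.Index
    sample_ids: pd.Index
    cpg_map: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.cpg_ids = pd.Index(self.cpg_ids)
        self.sample_ids = pd.Index(self.sample_ids)
        if self.values.shape != (len(self.cpg_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cpg_ids)} CpGs x {len(self.sample_ids)} samples"
            )
        if self.cpg_ids.has_duplicates or self.sample_ids.has_duplicates:
            raise ValueError("duplicate CpG or sample ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cpg_ids, columns=self.sample_ids)


@dataclass
class ResidualMatrix:
    """CpG x sample matrix after confounder residualization (residual scale)."""

    values: np.ndarray
    cpg_ids: pd.Index
    sample_ids: pd.Index
    covariates_removed: list[str] = field(default_factory=list)
    cpg_map: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.cpg_ids = pd.Index(self.cpg_ids)
        self.sample_ids = pd.Index(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cpg_ids, columns=self.sample_ids)

    def subset_cpgs(self, ids: Sequence[str]) -> "ResidualMatrix":
        idx = self.cpg_ids.get_indexer(ids)
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise KeyError(f"unknown CpG ids: {missing[:5]}")
        cmap = self.cpg_map.loc[list(ids)] if self.cpg_map is not None else None
        return ResidualMatrix(
            self.values[idx], pd.Index(ids), self.sample_ids,
            list(self.covariates_removed), cmap,
        )


@dataclass
class GenotypeSet:
    """SNP x sample dosage matrix with a SNP map.

    ``dosages`` holds alt-allele counts {0,1,2} as floats with NaN for
    missing calls.  ``snp_map`` is indexed by SNP id with columns ``chrom``,
    ``pos``, ``ref``, ``alt``; positions are strictly increasing within a
    chromosome.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: pd.Index
    # retained by the simulator so an independent GWAS panel can be drawn
    # from the same LD process; not read by any analysis stage
    sim_params: dict | None = None

    def __post_init__(self) -> None:
        self.sample_ids = pd.Index(self.sample_ids)
        if self.dosages.shape != (len(self.snp_map), len(self.sample_ids)):
            raise ValueError("dosage shape does not match snp_map/sample_ids")
        if self.snp_map.index.has_duplicates:
            raise ValueError("duplicate SNP ids")
        for _, sub in self.snp_map.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError("positions not strictly increasing within chromosome")

    @property
    def snp_ids(self) -> pd.Index:
        return self.snp_map.index

    def subset_snps(self, mask_or_ids) -> "GenotypeSet":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            idx = self.snp_map.index.get_indexer(mask_or_ids)
        params = self.sim_params
        if params is not None and "maf" in params:
            params = {**params, "maf": np.asarray(params["maf"])[idx]}
        return GenotypeSet(self.dosages[idx], self.snp_map.iloc[idx], self.sample_ids, params)

    def subset_samples(self, keep: np.ndarray) -> "GenotypeSet":
        return GenotypeSet(
            self.dosages[:, keep], self.snp_map, self.sample_ids[keep], self.sim_params
        )


@dataclass
class ModuleAssignment:
    """Partition of CpGs into modules plus module eigengenes.

    ``labels`` maps CpG id -> integer module label; 0 is the unassigned
    ("grey") background.  ``eigengenes`` is a module x sample DataFrame whose
    rows are unit-length first principal components of the module submatrix,
    sign-aligned so the mean correlation with member CpGs is non-negative.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame
    module_sizes: pd.Series

    @property
    def module_ids(self) -> list[int]:
        return [int(m) for m in self.eigengenes.index]


@dataclass
class ModuleStats:
    """Module membership / probe significance statistics.

    mm, mm_p : CpG x module DataFrames of Pearson r and p (kME).
    ps, ps_p : per-CpG Series of point-biserial trait correlation and p.
    trait_test : module-indexed DataFrame with columns t, p (Welch).
    mmps : module-indexed DataFrame with columns r, p, degenerate.
    """

    mm: pd.DataFrame
    mm_p: pd.DataFrame
    ps: pd.Series
    ps_p: pd.Series
    trait_test: pd.DataFrame
    mmps: pd.DataFrame


@dataclass
class PreservationResult:
    """Per-module preservation statistics between a reference and test cohort.

    ``table`` is indexed by module id with columns z_density, z_connectivity,
    z_summary, median_rank, band plus the six observed statistics
    (mean_adj, prop_var_explained, mean_kme, cor_kim, cor_kme, cor_cor).
    Bands: z_summary > 10 high, 5..10 moderate, < 5 none.
    """

    table: pd.DataFrame
    n_permutations: int


@dataclass
class AssocStats:
    """Per-SNP association statistics for one trait over a set of SNPs.

    ``table`` is indexed by SNP id with columns chrom, pos, beta, se
    (optionally p, maf, n).  ``trait_type`` is 'quantitative' or
    'case_control'; it selects the colocalization prior effect scale.
    """

    table: pd.DataFrame
    trait_type: str = "quantitative"
    trait_name: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")


@dataclass
class Region:
    """1-based inclusive genomic interval around a lead SNP."""

    chrom: str
    start: int
    end: int
    lead_snp_id: str = ""
    source: str = "gwas_reported"  # gwas_reported | ld_expanded | random

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class ColocResult:
    """Colocalization posteriors for one CpG x trait x region triple."""

    cpg_id: str
    trait_name: str
    region: Region
    n_snps_shared: int
    pp: np.ndarray  # PP0..PP4
    perm_p: float | None = None

    @property
    def h34(self) -> float:
        return float(self.pp[3] + self.pp[4])

    @property
    def decision(self) -> bool:
        return self.h34 > 0.9 and self.perm_p is not None and self.perm_p < 0.05


@dataclass
class EnrichmentResult:
    """2x2 Fisher enrichment of a CpG/gene set against a target set."""

    target_name: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    p_bonferroni: float | None = None
    subset: str = "all_cpgs"
    degenerate: bool = False


@dataclass
class ModuleSpec:
    """One planted co-methylation module."""

    size: int
    loading_mean: float = 0.7
    trait_effect_d: float = 0.0


@dataclass
class MqtlSpec:
    """One planted SNP -> CpG methylation effect."""

    snp_index: int
    cpg_index: int
    r2_target: float


@dataclass
class GwasSpec:
    """Design of a simulated GWAS summary-statistics panel."""

    n_gwas: int = 2000
    causal_indices: tuple[int, ...] = ()
    h2_per_causal: float = 0.05
    shared_with_mqtl: bool = True


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort generator.

    Defaults emulate a single-cohort brain methylation study: ~120 donors,
    5,000 CpGs with five planted co-methylated modules (factor loadings
    around 0.7 on the M-value scale, unit residual noise), a binary
    psychosis-like trait at ~70% prevalence, and age / sex / Braak-stage /
    cell-proportion / plate confounding.
    """

    n_samples: int = 120
    n_cpgs: int = 5000
    module_spec: list[ModuleSpec] = field(
        default_factory=lambda: [
            ModuleSpec(150, 0.7, 0.8),
            ModuleSpec(200, 0.7, 0.0),
            ModuleSpec(250, 0.7, 0.8),
            ModuleSpec(300, 0.7, 0.0),
            ModuleSpec(400, 0.7, 0.0),
        ]
    )
    trait_prevalence: float = 0.7
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.01,        # M-value units per year
            "sex": 0.1,         # M-value shift, male vs female
            "braak": 0.05,      # per Braak stage
            "prop_neuron": 0.5, # per unit neuronal proportion
            "plate": 0.1,       # SD of per-plate offsets
        }
    )
    noise_sd: float = 1.0
    n_snps: int = 2000
    ld_block_size: int = 20
    ld_rho: float = 0.98
    maf_range: tuple[float, float] = (0.05, 0.5)
    snp_spacing: int = 5000
    cpg_spacing: int = 2000
    chrom_size: int = 500
    missing_rate: float = 0.0
    mqtl_spec: list[MqtlSpec] = field(default_factory=list)
    gwas_spec: GwasSpec = field(default_factory=GwasSpec)
    seed: int = 0

    def validate(self) -> None:
        if sum(m.size for m in self.module_spec) > self.n_cpgs:
            raise ConfigurationError("sum of module sizes exceeds n_cpgs")
        if not 0.0 <= self.trait_prevalence <= 1.0:
            raise ConfigurationError("trait_prevalence must be in [0,1]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigurationError("ld_rho must be in [0,1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0,1)")
        for spec in self.mqtl_spec:
            if not 0 <= spec.snp_index < self.n_snps:
                raise ConfigurationError(f"mQTL snp_index {spec.snp_index} out of range")
            if not 0 <= spec.cpg_index < self.n_cpgs:
                raise ConfigurationError(f"mQTL cpg_index {spec.cpg_index} out of range")
            if spec.r2_target >= 1:
                raise ConfigurationError("r2_target must be < 1")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort."""

    true_module_labels: pd.Series
    true_trait_module_ids: list[int]
    true_mqtl_pairs: list[tuple[str, str]]
    true_shared_causal_snps: list[str]
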