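"""End-to-end pipeline driver: phenotype -> preprocess -> network ->
preservation -> mQTL -> colocalization -> enrichment.

A single global seed fans out to per-stage child seeds derived by stable
hashing of stage names, so any stage can be re-run independently and
reproducibly.  Every stage writes its artifacts into the run directory and
the driver records a machine-readable manifest (config hash, seed,
package version, per-stage outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from comethnet import io as cio
from comethnet import __version__
from comethnet.coloc import coloc_permutation_p, coloc_scan, define_region
from comethnet.enrichment import gwas_region_enrichment
from comethnet.mqtl import genotype_pcs, kinship_filter, map_mqtls, mqtl_stats_for_cpg, snp_qc
from comethnet.network import (
    NetworkParams,
    compute_module_stats,
    detect_modules,
    hub_probes,
    select_candidate_modules,
)
from comethnet.phenotype import harmonize_sample_sheet, psychosis_indicator
from comethnet.preprocess import mad_filter, residualize, sample_outlier_check
from comethnet.preservation import module_preservation, replication_decision
from comethnet.types import AssocStats

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage child seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.  All thresholds default to the
    pipeline's standard values; paths must exist at run start."""

    discovery_beta: str = ""
    discovery_samples: str = ""
    validation_beta: str = ""
    validation_samples: str = ""
    cpg_map: str = ""
    genotypes_vcf: str = ""
    gwas_tsvs: list[str] = field(default_factory=list)
    out_dir: str = "run"

    covariate_columns: list[str] = field(
        default_factory=lambda: ["age", "sex", "braak", "prop_neuron", "plate"]
    )
    alpha: float = 0.05
    keep_fraction: float = 0.5
    power: float = 3.0
    max_block_size: int = 30_000
    min_module_size: int = 100
    merge_cut_height: float = 0.15
    n_perm: int = 1000
    z_high: float = 10.0
    p_mqtl: float = 1e-5
    cis_window: int = 1_000_000
    r2_min: float = 0.6
    region_max_dist: int = 250_000
    h34: float = 0.9
    perm_alpha: float = 0.05
    n_random: int = 1000
    min_snps: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def network_params(self) -> NetworkParams:
        return NetworkParams(
            power=self.power,
            max_block_size=self.max_block_size,
            min_module_size=self.min_module_size,
            merge_cut_height=self.merge_cut_height,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _check_inputs(config: PipelineConfig) -> None:
    for name in ("discovery_beta", "discovery_samples", "cpg_map"):
        path = getattr(config, name)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"missing input {name}: {path!r}")
    for name in ("validation_beta", "validation_samples", "genotypes_vcf"):
        path = getattr(config, name)
        if path and not Path(path).exists():
            raise FileNotFoundError(f"missing input {name}: {path!r}")
    for path in config.gwas_tsvs:
        if not Path(path).exists():
            raise FileNotFoundError(f"missing GWAS input: {path!r}")


def _prepare_cohort(beta_path, samples_path, cpg_map_path, config, stage):
    beta = cio.read_beta_matrix(beta_path, cpg_map_path)
    sheet = cio.read_samples(samples_path)
    if "psychosis_status" not in sheet.columns:
        sheet = harmonize_sample_sheet(sheet)
    trait = psychosis_indicator(sheet["psychosis_status"])
    trait.index = sheet.index
    keep = trait.notna()
    sheet = sheet[keep]
    trait = trait[keep].astype(int)
    sample_idx = beta.sample_ids.get_indexer(sheet.index)
    if (sample_idx < 0).any():
        raise ValueError(f"{stage}: sample sheet ids missing from beta matrix")
    from comethnet.types import BetaMatrix

    beta = BetaMatrix(
        beta.values[:, sample_idx], beta.cpg_ids, pd.Index(sheet.index), beta.cpg_map
    )
    covs = sheet[[c for c in config.covariate_columns if c in sheet.columns]]
    resid = residualize(beta, covs)
    outliers = sample_outlier_check(resid)
    if outliers:
        logger.warning("%s: flagged outlier samples (not dropped): %s", stage, outliers)
    resid = mad_filter(resid, config.keep_fraction)
    return resid, trait, sheet


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write artifacts + manifest to the run directory."""
    _check_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    params = config.network_params()

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        logger.info("stage %s done: %s", stage, info)

    # discovery cohort: preprocess + network
    resid, trait, sheet = _prepare_cohort(
        config.discovery_beta, config.discovery_samples, config.cpg_map, config,
        "discovery",
    )
    sheet.to_csv(out / "discovery_pheno.tsv", sep="\t")
    record("phenotype", n_samples=int(len(sheet)),
           n_cases=int(trait.sum()), n_controls=int((1 - trait).sum()))
    cio.write_residuals(resid, out / "discovery_residuals.tsv")
    record("preprocess", n_cpgs=int(len(resid.cpg_ids)))

    assignment = detect_modules(resid, params, seed=stage_seed(config.seed, "network"))
    stats = compute_module_stats(resid, assignment, trait.to_numpy())
    candidates = select_candidate_modules(stats, config.alpha)
    hubs = {
        m: hub_probes(stats, assignment.labels, m)
        for m in assignment.module_ids
        if int(assignment.module_sizes.get(m, 0)) >= 4
    }
    _write_module_tables(out, assignment, stats, hubs)
    record("network", n_modules=len(assignment.module_ids), candidates=candidates)

    # validation cohort: preservation + replication
    replicated = candidates
    if config.validation_beta:
        v_resid, v_trait, _ = _prepare_cohort(
            config.validation_beta, config.validation_samples, config.cpg_map,
            config, "validation",
        )
        pres = module_preservation(
            resid, assignment.labels, v_resid, n_perm=config.n_perm,
            seed=stage_seed(config.seed, "preserve"), params=params,
        )
        pres.table.to_csv(out / "preservation.tsv", sep="\t")
        shared = assignment.labels.index.intersection(v_resid.cpg_ids)
        v_labels = assignment.labels.loc[shared]
        from comethnet.network import module_eigengenes
        from comethnet.types import ModuleAssignment

        v_sub = v_resid.subset_cpgs(shared)
        v_me = module_eigengenes(v_sub, v_labels.to_numpy())
        sizes = v_labels[v_labels != 0].value_counts().sort_index()
        v_assignment = ModuleAssignment(v_labels, v_me, sizes)
        v_stats = compute_module_stats(v_sub, v_assignment, v_trait.to_numpy())
        replicated = [
            m for m in candidates
            if m in pres.table.index
            and replication_decision(pres.table.loc[m], v_stats, m, config.alpha)
        ]
        record("preserve", replicated=replicated,
               z_summary={int(m): float(pres.table.loc[m, "z_summary"])
                          for m in pres.table.index})

    # mQTL mapping on replicated-module CpGs
    mqtls = pd.DataFrame()
    coloc_rows = []
    if config.genotypes_vcf and replicated:
        geno = cio.read_vcf(config.genotypes_vcf)
        geno = snp_qc(geno)
        geno = kinship_filter(geno)
        pcs = genotype_pcs(geno)
        module_cpgs = assignment.labels.index[assignment.labels.isin(replicated)]
        module_resid = resid.subset_cpgs(resid.cpg_ids.intersection(module_cpgs))
        mqtls = map_mqtls(module_resid, geno, pcs, config.p_mqtl, config.cis_window)
        mqtls.to_csv(out / "mqtls.tsv", sep="\t", index=False)
        record("mqtl", n_cis=int((mqtls["relation"] == "cis").sum()),
               n_trans=int((mqtls["relation"] == "trans").sum()))

        # colocalization against each GWAS
        gwas_list = [cio.read_gwas_tsv(p) for p in config.gwas_tsvs]
        if gwas_list and len(mqtls):
            regions = []
            for gwas in gwas_list:
                lead = gwas.table["p"].idxmin() if "p" in gwas.table else None
                if lead is not None and lead in geno.snp_map.index:
                    regions.append(
                        define_region(lead, geno, config.r2_min, config.region_max_dist)
                    )
            cpg_stats = {}
            for cpg in mqtls["cpg"].unique():
                snps = geno.snp_map.index
                tab = mqtl_stats_for_cpg(module_resid, geno, pcs, cpg, snps)
                cpg_stats[cpg] = AssocStats(tab, "quantitative", f"meth:{cpg}")
            results = coloc_scan(cpg_stats, gwas_list, regions,
                                 config.h34, config.min_snps)
            for res in results:
                if res.h34 > config.h34:
                    gwas = next(g for g in gwas_list if g.trait_name == res.trait_name)
                    res.perm_p = coloc_permutation_p(
                        res, geno, gwas, cpg_stats,
                        n_random=config.n_random,
                        seed=stage_seed(config.seed, f"coloc:{res.cpg_id}"),
                        r2_min=config.r2_min, max_dist=config.region_max_dist,
                        min_snps=config.min_snps, h34_threshold=config.h34,
                    )
                coloc_rows.append(
                    {
                        "cpg": res.cpg_id, "trait": res.trait_name,
                        "chrom": res.region.chrom, "start": res.region.start,
                        "end": res.region.end, "lead_snp": res.region.lead_snp_id,
                        "n_snps": res.n_snps_shared,
                        **{f"pp{i}": res.pp[i] for i in range(5)},
                        "h34": res.h34, "perm_p": res.perm_p,
                        "decision": res.decision,
                    }
                )
            pd.DataFrame(coloc_rows).to_csv(out / "coloc.tsv", sep="\t", index=False)
            record("coloc", n_tested=len(coloc_rows),
                   n_colocalized=sum(r["decision"] for r in coloc_rows))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _write_module_tables(out: Path, assignment, stats, hubs: dict) -> None:
    rows = []
    hub_sets = {m: set(v) for m, v in hubs.items()}
    for cpg in assignment.labels.index:
        m = int(assignment.labels[cpg])
        rows.append(
            {
                "cpg": cpg,
                "module": m,
                "mm": stats.mm.loc[cpg, m] if m != 0 else np.nan,
                "mm_p": stats.mm_p.loc[cpg, m] if m != 0 else np.nan,
                "ps": stats.ps.loc[cpg],
                "ps_p": stats.ps_p.loc[cpg],
                "is_hub": cpg in hub_sets.get(m, ()),
            }
        )
    pd.DataFrame(rows).to_csv(out / "modules.tsv", sep="\t", index=False)
    assignment.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
    stats.trait_test.join(stats.mmps, lsuffix="_trait", rsuffix="_mmps").to_csv(
        out / "module_tests.tsv", sep="\t"
    )
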