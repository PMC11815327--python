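"""Readers and writers for the pipeline's on-disk formats.

All tabular artifacts are TSV.  Genomic coordinates are 1-based inclusive
internally (Illumina manifest / VCF convention); BED files are 0-based
half-open on disk and converted at this boundary.  Genotypes round-trip
through VCF (GT field -> dosage, './.' -> missing) or PLINK .traw.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from comethnet.types import AssocStats, BetaMatrix, GenotypeSet, Region, ResidualMatrix

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_residuals",
    "write_residuals",
    "read_cpg_map",
    "write_cpg_map",
    "read_samples",
    "write_samples",
    "read_vcf",
    "write_vcf",
    "read_traw",
    "read_gwas_tsv",
    "write_gwas_tsv",
    "read_bed",
    "write_bed",
    "write_truth",
    "read_truth",
]


def _fail(path, line_no: int, msg: str) -> None:
    raise ValueError(f"{path}:{line_no}: {msg}")


# --- methylation matrices ---------------------------------------------------


def read_matrix_tsv(path) -> pd.DataFrame:
    # round_trip parsing keeps write->read bit-exact
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_matrix_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t")


def read_beta_matrix(path, cpg_map_path=None) -> BetaMatrix:
    frame = read_matrix_tsv(path)
    vals = frame.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError(f"{path}: beta matrix contains non-finite values")
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError(f"{path}: beta values outside [0, 1]")
    cpg_map = read_cpg_map(cpg_map_path) if cpg_map_path else None
    if cpg_map is not None:
        cpg_map = cpg_map.loc[frame.index]
    return BetaMatrix(vals, frame.index, frame.columns, cpg_map)


def write_beta_matrix(beta: BetaMatrix, path, cpg_map_path=None) -> None:
    write_matrix_tsv(beta.to_frame(), path)
    if cpg_map_path and beta.cpg_map is not None:
        write_cpg_map(beta.cpg_map, cpg_map_path)


def write_residuals(mat: ResidualMatrix, path) -> None:
    write_matrix_tsv(mat.to_frame(), path)


def read_residuals(path, cpg_map_path=None) -> ResidualMatrix:
    frame = read_matrix_tsv(path)
    cpg_map = read_cpg_map(cpg_map_path) if cpg_map_path else None
    if cpg_map is not None:
        cpg_map = cpg_map.loc[frame.index]
    return ResidualMatrix(frame.to_numpy(dtype=float), frame.index, frame.columns,
                          cpg_map=cpg_map)


def read_cpg_map(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype={"chrom": str})
    genes = []
    for raw in frame.get("genes", pd.Series("", index=frame.index)).fillna(""):
        entries = []
        if raw:
            for item in str(raw).split(";"):
                gene, _, dist = item.partition(":")
                entries.append((gene, int(dist) if dist else 0))
        genes.append(entries)
    frame["genes"] = genes
    return frame


def write_cpg_map(cpg_map: pd.DataFrame, path) -> None:
    out = cpg_map.copy()
    out["genes"] = [
        ";".join(f"{g}:{d}" for g, d in entries) for entries in cpg_map["genes"]
    ]
    out.to_csv(path, sep="\t")


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t")


# --- genotypes --------------------------------------------------------------

_GT_DOSAGE = {
    "0/0": 0.0, "0|0": 0.0,
    "0/1": 1.0, "1/0": 1.0, "0|1": 1.0, "1|0": 1.0,
    "1/1": 2.0, "1|1": 2.0,
    "./.": np.nan, ".|.": np.nan, ".": np.nan,
}


def read_vcf(path) -> GenotypeSet:
    """Parse an (uncompressed) VCF's GT field into a dosage matrix."""
    sample_ids: list[str] = []
    snp_rows = []
    dosages = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    _fail(path, line_no, "VCF has no sample columns")
                sample_ids = fields[9:]
                continue
            if not sample_ids:
                _fail(path, line_no, "data line before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + len(sample_ids):
                _fail(path, line_no, f"expected {9 + len(sample_ids)} columns, got {len(fields)}")
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            fmt = fields[8].split(":")
            try:
                gt_i = fmt.index("GT")
            except ValueError:
                _fail(path, line_no, "no GT in FORMAT")
            row = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_i]
                if gt not in _GT_DOSAGE:
                    _fail(path, line_no, f"unsupported GT {gt!r}")
                row.append(_GT_DOSAGE[gt])
            try:
                pos_i = int(pos)
            except ValueError:
                _fail(path, line_no, f"non-integer POS {pos!r}")
            snp_rows.append((vid, chrom, pos_i, ref, alt))
            dosages.append(row)
    snp_map = pd.DataFrame(
        snp_rows, columns=["snp", "chrom", "pos", "ref", "alt"]
    ).set_index("snp")
    return GenotypeSet(np.array(dosages, dtype=float), snp_map, pd.Index(sample_ids))


_DOSAGE_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(geno: GenotypeSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, geno.sample_ids))
            + "\n"
        )
        for i, (sid, row) in enumerate(geno.snp_map.iterrows()):
            gts = [
                "./." if np.isnan(v) else _DOSAGE_GT[float(v)]
                for v in geno.dosages[i]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{sid}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_traw(path) -> GenotypeSet:
    """PLINK .traw transposed dosage export (CHR SNP (C)M POS COUNTED ALT + samples)."""
    frame = pd.read_csv(path, sep="\t")
    meta_cols = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]
    missing = [c for c in meta_cols if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing .traw columns {missing}")
    snp_map = pd.DataFrame(
        {
            "chrom": frame["CHR"].astype(str),
            "pos": frame["POS"].astype(int),
            "ref": frame["ALT"].astype(str),      # COUNTED is the dosage allele
            "alt": frame["COUNTED"].astype(str),
        },
        index=pd.Index(frame["SNP"], name="snp"),
    )
    dosages = frame.drop(columns=meta_cols).to_numpy(dtype=float)
    return GenotypeSet(dosages, snp_map, pd.Index(frame.columns[6:]))


# --- GWAS summary statistics ------------------------------------------------


def read_gwas_tsv(path, trait_name: str = "", trait_type: str = "quantitative") -> AssocStats:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                        float_precision="round_trip")
    required = {"snp", "chrom", "pos"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: GWAS TSV needs columns {sorted(required)}")
    if not ({"beta", "se"} <= set(frame.columns) or {"p", "maf", "n"} <= set(frame.columns)):
        raise ValueError(f"{path}: GWAS TSV needs beta+se or p+maf+n")
    return AssocStats(frame.set_index("snp"), trait_type, trait_name or Path(path).stem)


def write_gwas_tsv(stats: AssocStats, path) -> None:
    stats.table.rename_axis("snp").to_csv(path, sep="\t")


# --- regions ----------------------------------------------------------------


def read_bed(path) -> list[Region]:
    """BED (0-based half-open) -> internal 1-based inclusive regions."""
    regions = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                _fail(path, line_no, "BED line needs >= 3 fields")
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                _fail(path, line_no, "non-integer BED coordinates")
            name = fields[3] if len(fields) > 3 else ""
            regions.append(Region(fields[0], start0 + 1, end0, lead_snp_id=name))
    return regions


def write_bed(regions: list[Region], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.lead_snp_id}\n")


# --- ground truth -----------------------------------------------------------


def write_truth(truth, path) -> None:
    payload = {
        "true_module_labels": truth.true_module_labels.to_dict(),
        "true_trait_module_ids": list(truth.true_trait_module_ids),
        "true_mqtl_pairs": [list(p) for p in truth.true_mqtl_pairs],
        "true_shared_causal_snps": list(truth.true_shared_causal_snps),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path):
    from comethnet.types import GroundTruth

    payload = json.loads(Path(path).read_text())
    labels = pd.Series(payload["true_module_labels"], name="module").astype(int)
    return GroundTruth(
        labels,
        payload["true_trait_module_ids"],
        [tuple(p) for p in payload["true_mqtl_pairs"]],
        payload["true_shared_causal_snps"],
    )
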