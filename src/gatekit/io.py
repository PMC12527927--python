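"""Readers and writers for the pipeline's file formats.

Summary statistics travel as a tab-separated table with the fixed header
``SNP CHR POS EA OA GENE GENE_CHR GENE_TSS BETA SE P``.  Genotypes are
either a dosage-matrix TSV (samples x SNPs) with a sidecar SNP-metadata TSV,
or a VCF with a DS FORMAT field (read through cyvcf2; written as plain
uncompressed VCF 4.2).  Phenotypes are a TSV with IID, STATUS, SEX, COHORT
and PC columns.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import SUMMARY_COLUMNS, QtlLocus
from .exceptions import StructuralError
from .scores import GateScoreDefinition, ScoreMatrix
from .synthetic import GenotypeMatrix


def write_summary_stats(records: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in SUMMARY_COLUMNS if c not in records.columns]
    if missing:
        raise StructuralError(f"summary statistics missing columns {missing}")
    records[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "GENE_CHR": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise StructuralError(
            f"{path}: summary statistics missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# genotypes


def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path,
                     meta_path: str | Path | None = None) -> None:
    """Samples x SNPs dosage matrix plus a sidecar SNP metadata table."""
    path = Path(path)
    if meta_path is None:
        meta_path = path.with_suffix(".snps.tsv")
    df = pd.DataFrame(geno.dosages, index=geno.sample_ids,
                      columns=geno.snp_meta["id"])
    df.to_csv(path, sep="\t", index_label="IID")
    geno.snp_meta.to_csv(meta_path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path,
                    meta_path: str | Path | None = None) -> GenotypeMatrix:
    path = Path(path)
    if meta_path is None:
        meta_path = path.with_suffix(".snps.tsv")
    if not path.exists():
        raise FileNotFoundError(f"genotype file not found: {path}")
    if not Path(meta_path).exists():
        raise FileNotFoundError(f"SNP metadata file not found: {meta_path}")
    df = pd.read_csv(path, sep="\t", index_col="IID")
    meta = pd.read_csv(meta_path, sep="\t", dtype={"chrom": str})
    if list(df.columns) != list(meta["id"]):
        raise StructuralError("dosage columns do not match SNP metadata")
    return GenotypeMatrix(dosages=df.to_numpy(dtype=float), snp_meta=meta,
                          sample_ids=[str(i) for i in df.index])


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Plain-text VCF 4.2 with a DS (dosage) FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids) + "\n")
        D = geno.dosages
        for j, row in geno.snp_meta.iterrows():
            ds = "\t".join(f"{float(D[i, j]):g}"
                           for i in range(D.shape[0]))
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t"
                     f"{row['oa']}\t{row['ea']}\t.\t.\t.\tDS\t{ds}\n")


def read_vcf_dosages(path: str | Path) -> GenotypeMatrix:
    """Read a VCF with a DS FORMAT field into a dosage matrix."""
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"genotype file not found: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        rows.append(ds)
        meta.append({"id": var.ID, "chrom": str(var.CHROM), "pos": var.POS,
                     "ea": var.ALT[0], "oa": var.REF})
    dosages = np.vstack(rows).T
    meta_df = pd.DataFrame(meta)
    meta_df["af"] = dosages.mean(axis=0) / 2.0
    return GenotypeMatrix(dosages=dosages, snp_meta=meta_df,
                          sample_ids=samples)


# ---------------------------------------------------------------------------
# phenotypes, scores, definitions


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"phenotype file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    for col in ("IID", "STATUS"):
        if col not in df.columns:
            raise StructuralError(f"{path}: phenotype table lacks {col}")
    df["IID"] = df["IID"].astype(str)
    return df


def write_scores(scores: ScoreMatrix, path: str | Path) -> None:
    scores.values.to_csv(path, sep="\t", index_label="IID")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="IID")


def _locus_to_dict(locus: QtlLocus) -> dict:
    d = asdict(locus)
    d["positions"] = [int(p) for p in locus.positions]
    d["betas"] = [float(b) for b in locus.betas]
    d["adjusted_weights"] = ([float(w) for w in locus.adjusted_weights]
                             if locus.adjusted_weights is not None else None)
    return d


def write_definitions(defs: list[GateScoreDefinition],
                      path: str | Path) -> None:
    """JSON manifest: gene -> clumps -> SNP ids, positions, weights."""
    payload = [{
        "gene_id": d.gene_id, "score_type": d.score_type,
        "n_trans_loci": d.n_trans_loci,
        "loci": [_locus_to_dict(l) for l in d.loci],
    } for d in defs]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_definitions(path: str | Path) -> list[GateScoreDefinition]:
    payload = json.loads(Path(path).read_text())
    defs = []
    for d in payload:
        loci = [QtlLocus(
            gene_id=l["gene_id"], chrom=l["chrom"], start=l["start"],
            end=l["end"], snp_ids=l["snp_ids"],
            positions=np.asarray(l["positions"]),
            betas=np.asarray(l["betas"]),
            adjusted_weights=(np.asarray(l["adjusted_weights"])
                              if l["adjusted_weights"] is not None else None))
            for l in d["loci"]]
        defs.append(GateScoreDefinition(
            gene_id=d["gene_id"], score_type=d["score_type"], loci=loci,
            n_trans_loci=d["n_trans_loci"]))
    return defs


def write_instruments(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_instruments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"locus", "beta_exp", "se_exp", "beta_out", "se_out"}
    missing = needed - set(df.columns)
    if missing:
        raise StructuralError(f"{path}: instruments missing {sorted(missing)}")
    return df
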