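"""From raw QTL summary statistics to LD-adjusted trans-locus sets.

The processing chain mirrors standard polygenic-score hygiene for
trans-QTL aggregation:

1. harmonize effect alleles between the summary statistics and the
   genotype panel (sign flips for swapped alleles; strand-ambiguous A/T and
   C/G SNPs dropped);
2. classify each SNP-gene record as cis or trans (different chromosome, or
   at least ``cis_window`` bp from the TSS — default 5 Mb);
3. mask the HLA trans-hotspot (chromosome 6, 25-34 Mb, endpoints inclusive)
   out of the trans set, routing those records to a separate HLA-score set;
4. retain trans records below a p-value threshold, and gate the cis score
   on at least one cis SNP with p < 1e-6;
5. clump the surviving SNPs of each gene by single-linkage chaining within
   200 kb;
6. within each clump, convert marginal effects to joint weights with a
   ridge-regularized solve against the reference-panel LD matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .exceptions import ClassificationError, NumericalError, StructuralError
from .synthetic import GenotypeMatrix

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "GENE", "GENE_CHR",
                   "GENE_TSS", "BETA", "SE", "P"]

DEFAULT_CIS_WINDOW = 5_000_000
DEFAULT_CLUMP_WINDOW = 200_000
DEFAULT_TRANS_P = 5e-8
DEFAULT_CIS_P = 1e-6
DEFAULT_RIDGE = 0.1
HLA_REGION = ("6", 25_000_000, 34_000_000)

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class QtlLocus:
    """A clump of QTL SNPs for one gene, treated as a single locus."""

    gene_id: str
    chrom: str
    start: int
    end: int
    snp_ids: list[str]
    positions: np.ndarray
    betas: np.ndarray
    adjusted_weights: np.ndarray | None = None

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class Catalog:
    """Clumped, LD-adjusted locus sets plus a processing report."""

    trans_loci: dict[str, list[QtlLocus]]
    cis_loci: dict[str, list[QtlLocus]]
    hla_loci: dict[str, list[QtlLocus]]
    report: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------


def classify_cis_trans(records: pd.DataFrame,
                       cis_window: int = DEFAULT_CIS_WINDOW) -> pd.Series:
    """Label each record ``cis`` or ``trans``.

    Trans iff the SNP is on a different chromosome than the gene, or at
    least ``cis_window`` bp from the TSS.
    """
    if records["GENE_TSS"].isna().any() or records["GENE_CHR"].isna().any():
        raise ClassificationError(
            "records with missing GENE_CHR/GENE_TSS cannot be classified")
    diff_chrom = records["CHR"].astype(str) != records["GENE_CHR"].astype(str)
    far = (records["POS"] - records["GENE_TSS"]).abs() >= cis_window
    return pd.Series(np.where(diff_chrom | far, "trans", "cis"),
                     index=records.index)


def mask_hla(records: pd.DataFrame,
             region: tuple[str, int, int] = HLA_REGION
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (outside region, inside region).

    The region is a closed interval; records inside are excluded from GATE
    aggregation and routed to the HLA-specific score set.
    """
    chrom, start, end = region
    inside = ((records["CHR"].astype(str) == str(chrom))
              & (records["POS"] >= start) & (records["POS"] <= end))
    return records.loc[~inside], records.loc[inside]


def select_trans_qtls(records: pd.DataFrame,
                      p_threshold: float = DEFAULT_TRANS_P) -> pd.DataFrame:
    """Trans records passing the inclusion threshold."""
    return records.loc[records["P"] < p_threshold]


def cis_score_eligible(cis_records: pd.DataFrame,
                       p_threshold: float = DEFAULT_CIS_P) -> bool:
    """A cis score is defined only when >= 1 cis SNP has p below threshold."""
    return bool((cis_records["P"] < p_threshold).any())


def clump_positions(positions: np.ndarray,
                    window: int = DEFAULT_CLUMP_WINDOW) -> np.ndarray:
    """Single-linkage chaining of positions: same clump iff connected by
    steps each <= window.  Returns a clump label per input position.

    On a line, transitive chaining reduces to a sorted gap rule, which makes
    the partition deterministic and free of tie-breaking.
    """
    positions = np.asarray(positions)
    order = np.argsort(positions, kind="stable")
    labels = np.empty(len(positions), dtype=int)
    current = 0
    prev = None
    for i in order:
        if prev is not None and positions[i] - prev > window:
            current += 1
        labels[i] = current
        prev = positions[i]
    return labels


def clump_qtls(records_for_gene: pd.DataFrame,
               window: int = DEFAULT_CLUMP_WINDOW) -> list[QtlLocus]:
    """Partition one gene's records into loci by chromosome-wise chaining."""
    genes = records_for_gene["GENE"].unique()
    if len(genes) > 1:
        raise StructuralError(f"records span multiple genes: {list(genes)}")
    loci: list[QtlLocus] = []
    for chrom, sub in records_for_gene.groupby("CHR", sort=True):
        labels = clump_positions(sub["POS"].to_numpy(), window)
        for lab in np.unique(labels):
            part = sub.iloc[np.flatnonzero(labels == lab)]
            part = part.sort_values("POS", kind="stable")
            loci.append(QtlLocus(
                gene_id=str(genes[0]), chrom=str(chrom),
                start=int(part["POS"].min()), end=int(part["POS"].max()),
                snp_ids=part["SNP"].tolist(),
                positions=part["POS"].to_numpy(),
                betas=part["BETA"].to_numpy(dtype=float)))
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci


def adjust_for_ld(betas: np.ndarray, ld_matrix: np.ndarray,
                  ridge: float = DEFAULT_RIDGE) -> np.ndarray:
    """Joint weights from marginal effects: solve (R + ridge*I) w = beta.

    With ridge=0 and invertible R this equals the joint-regression
    coefficients in the reference population (for standardized or
    equal-variance genotypes).  A singular system at ridge=0 raises
    :class:`NumericalError` advising a positive ridge.
    """
    betas = np.asarray(betas, dtype=float)
    R = np.asarray(ld_matrix, dtype=float)
    if ridge < 0:
        raise NumericalError("ridge must be non-negative")
    if R.ndim != 2 or R.shape[0] != R.shape[1] or R.shape[0] != len(betas):
        raise StructuralError("LD matrix dimension does not match betas")
    if not np.allclose(R, R.T, atol=1e-8):
        raise StructuralError("LD matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise StructuralError("LD matrix must have unit diagonal")
    A = R + ridge * np.eye(len(betas))
    try:
        w = linalg.solve(A, betas, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise NumericalError(
            "LD system is singular; use a positive ridge") from exc
    if not np.all(np.isfinite(w)):
        raise NumericalError(
            "LD adjustment produced non-finite weights; use a positive ridge")
    return w


def ld_from_genotypes(geno: GenotypeMatrix, snp_ids: list[str]) -> np.ndarray:
    """Empirical dosage correlation matrix of the given SNPs."""
    d = geno.dosage_for(snp_ids)
    if d.shape[1] == 1:
        return np.ones((1, 1))
    R = np.corrcoef(d, rowvar=False)
    return np.clip(R, -1.0, 1.0)


def harmonize_alleles(records: pd.DataFrame, snp_meta: pd.DataFrame
                      ) -> tuple[pd.DataFrame, dict]:
    """Align summary-statistic effect alleles with the genotype panel.

    Records whose (EA, OA) match the panel are kept; swapped-allele records
    get their BETA sign flipped; strand-ambiguous (A/T, C/G) SNPs, allele
    mismatches and SNPs absent from the panel are dropped with counts in
    the returned report.
    """
    meta = snp_meta.set_index("id")
    report = {"input": len(records), "kept": 0, "flipped": 0,
              "ambiguous": 0, "mismatch": 0, "missing": 0}
    out = records.copy()
    keep = np.ones(len(out), dtype=bool)
    betas = out["BETA"].to_numpy(dtype=float).copy()
    for i, (_, rec) in enumerate(out.iterrows()):
        if frozenset((rec["EA"], rec["OA"])) in _AMBIGUOUS:
            report["ambiguous"] += 1
            keep[i] = False
            continue
        if rec["SNP"] not in meta.index:
            report["missing"] += 1
            keep[i] = False
            continue
        ea, oa = meta.loc[rec["SNP"], ["ea", "oa"]]
        if (rec["EA"], rec["OA"]) == (ea, oa):
            pass
        elif (rec["EA"], rec["OA"]) == (oa, ea):
            betas[i] = -betas[i]
            report["flipped"] += 1
        else:
            report["mismatch"] += 1
            keep[i] = False
    out["BETA"] = betas
    out = out.loc[keep]
    report["kept"] = len(out)
    dropped = report["ambiguous"] + report["mismatch"] + report["missing"]
    if dropped:
        logger.info("harmonize_alleles: dropped %d records "
                    "(%d ambiguous, %d mismatch, %d missing)", dropped,
                    report["ambiguous"], report["mismatch"], report["missing"])
    return out, report


# ---------------------------------------------------------------------------


def _adjusted_loci(records: pd.DataFrame, ld_geno: GenotypeMatrix,
                   clump_window: int, ridge: float
                   ) -> dict[str, list[QtlLocus]]:
    loci_by_gene: dict[str, list[QtlLocus]] = {}
    for gene, sub in records.groupby("GENE", sort=True):
        loci = clump_qtls(sub, window=clump_window)
        for locus in loci:
            R = ld_from_genotypes(ld_geno, locus.snp_ids)
            locus.adjusted_weights = adjust_for_ld(locus.betas, R, ridge)
        loci_by_gene[str(gene)] = loci
    return loci_by_gene


def build_catalog(records: pd.DataFrame, ld_geno: GenotypeMatrix,
                  cis_window: int = DEFAULT_CIS_WINDOW,
                  clump_window: int = DEFAULT_CLUMP_WINDOW,
                  trans_p: float = DEFAULT_TRANS_P,
                  cis_p: float = DEFAULT_CIS_P,
                  ridge: float = DEFAULT_RIDGE,
                  hla_region: tuple[str, int, int] | None = HLA_REGION
                  ) -> Catalog:
    """Run the full harmonize -> classify -> mask -> select -> clump ->
    LD-adjust chain and return the per-gene locus sets."""
    harmonized, report = harmonize_alleles(records, ld_geno.snp_meta)
    label = classify_cis_trans(harmonized, cis_window=cis_window)
    trans = harmonized.loc[label == "trans"]
    cis = harmonized.loc[label == "cis"]
    if hla_region is not None:
        trans, hla_trans = mask_hla(trans, region=hla_region)
    else:
        hla_trans = trans.iloc[0:0]
    trans_sel = select_trans_qtls(trans, p_threshold=trans_p)
    hla_sel = select_trans_qtls(hla_trans, p_threshold=trans_p)
    report.update({
        "n_trans": len(trans), "n_cis": len(cis),
        "n_hla_masked": len(hla_trans),
        "n_trans_selected": len(trans_sel),
        "n_hla_selected": len(hla_sel),
    })

    trans_loci = _adjusted_loci(trans_sel, ld_geno, clump_window, ridge)
    hla_loci = _adjusted_loci(hla_sel, ld_geno, clump_window, ridge)

    cis_loci: dict[str, list[QtlLocus]] = {}
    n_cis_ineligible = 0
    for gene, sub in cis.groupby("GENE", sort=True):
        if not cis_score_eligible(sub, p_threshold=cis_p):
            n_cis_ineligible += 1
            continue
        sub_sel = sub.loc[sub["P"] < cis_p]
        loci = clump_qtls(sub_sel, window=clump_window)
        for locus in loci:
            R = ld_from_genotypes(ld_geno, locus.snp_ids)
            locus.adjusted_weights = adjust_for_ld(locus.betas, R, ridge)
        cis_loci[str(gene)] = loci
    report["n_cis_ineligible_genes"] = n_cis_ineligible
    return Catalog(trans_loci=trans_loci, cis_loci=cis_loci,
                   hla_loci=hla_loci, report=report)
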