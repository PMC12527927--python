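"""Per-individual GATE, cis and HLA-specific genotype scores.

A GATE score for a gene is the weighted sum of an individual's dosages over
all of the gene's trans loci, using the LD-adjusted joint weights.  Genes
with fewer than ``min_trans_loci`` (default 5) trans clumps are excluded:
aggregating several trans-QTLs raises the signal-to-noise ratio and keeps a
single strong trans-QTL from dominating the association.  Scores are
standardized (mean 0, SD 1) on the analysis cohort so that association
effects read as per-SD log odds ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import HLA_REGION, QtlLocus
from .exceptions import StructuralError
from .synthetic import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_TRANS_LOCI = 5

SCORE_TYPES = ("eGATE", "pGATE", "cis", "hla_trans", "hla_cis")


@dataclass
class GateScoreDefinition:
    """A gene's score: its loci, their weights, and the score type."""

    gene_id: str
    score_type: str
    loci: list[QtlLocus]
    n_trans_loci: int

    def __post_init__(self) -> None:
        if self.score_type not in SCORE_TYPES:
            raise StructuralError(f"unknown score type {self.score_type!r}")

    @property
    def score_id(self) -> str:
        return f"{self.score_type}_{self.gene_id}"

    @property
    def snp_ids(self) -> list[str]:
        return [s for locus in self.loci for s in locus.snp_ids]

    @property
    def weights(self) -> np.ndarray:
        return np.concatenate([np.asarray(l.adjusted_weights, dtype=float)
                               for l in self.loci])


@dataclass
class ScoreMatrix:
    """Individuals x scores, with the standardization used and provenance."""

    values: pd.DataFrame
    standardization: pd.DataFrame      # index score_id; columns mean, sd
    provenance: dict[str, GateScoreDefinition] = field(default_factory=dict)

    @property
    def score_ids(self) -> list[str]:
        return list(self.values.columns)


def build_definitions(loci_by_gene: dict[str, list[QtlLocus]],
                      min_trans_loci: int = DEFAULT_MIN_TRANS_LOCI,
                      score_type: str = "eGATE"
                      ) -> list[GateScoreDefinition]:
    """GATE definitions for genes with at least ``min_trans_loci`` clumps."""
    defs = []
    for gene, loci in sorted(loci_by_gene.items()):
        if len(loci) < min_trans_loci:
            logger.info("gene %s removed: %d trans loci < %d", gene,
                        len(loci), min_trans_loci)
            continue
        defs.append(GateScoreDefinition(gene_id=gene, score_type=score_type,
                                        loci=loci, n_trans_loci=len(loci)))
    return defs


def build_cis_definitions(cis_loci_by_gene: dict[str, list[QtlLocus]]
                          ) -> list[GateScoreDefinition]:
    return [GateScoreDefinition(gene_id=g, score_type="cis", loci=loci,
                                n_trans_loci=len(loci))
            for g, loci in sorted(cis_loci_by_gene.items()) if loci]


def build_hla_definitions(hla_loci_by_gene: dict[str, list[QtlLocus]]
                          ) -> list[GateScoreDefinition]:
    """HLA-specific trans scores; the >=5-locus filter does not apply."""
    return [GateScoreDefinition(gene_id=g, score_type="hla_trans", loci=loci,
                                n_trans_loci=len(loci))
            for g, loci in sorted(hla_loci_by_gene.items()) if loci]


def compute_scores(geno: GenotypeMatrix,
                   definitions: list[GateScoreDefinition],
                   standardize: bool = True) -> ScoreMatrix:
    """Weighted dosage sums for every definition, optionally standardized.

    SNPs missing from the genotype panel are skipped with a log entry; a
    definition whose SNPs are all missing is dropped with a warning.
    Missing dosage values are mean-imputed by the genotype container.
    """
    present = set(geno.snp_meta["id"])
    cols, means, sds, prov = {}, {}, {}, {}
    for d in definitions:
        snp_ids = d.snp_ids
        weights = d.weights
        mask = np.array([s in present for s in snp_ids])
        if not mask.any():
            logger.warning("definition %s dropped: no SNPs in genotypes",
                           d.score_id)
            continue
        if not mask.all():
            logger.info("definition %s: %d/%d SNPs missing from genotypes",
                        d.score_id, int((~mask).sum()), len(snp_ids))
        kept = [s for s, m in zip(snp_ids, mask) if m]
        raw = geno.dosage_for(kept) @ weights[mask]
        mu, sd = float(raw.mean()), float(raw.std())
        if standardize:
            if sd == 0:
                logger.warning("score %s has zero variance; left unscaled",
                               d.score_id)
                vals = raw - mu
                sd_used = 1.0
            else:
                vals = (raw - mu) / sd
                sd_used = sd
            cols[d.score_id] = vals
            means[d.score_id], sds[d.score_id] = mu, sd_used
        else:
            cols[d.score_id] = raw
            means[d.score_id], sds[d.score_id] = 0.0, 1.0
        prov[d.score_id] = d
    values = pd.DataFrame(cols, index=geno.sample_ids)
    standardization = pd.DataFrame(
        {"mean": pd.Series(means), "sd": pd.Series(sds)})
    return ScoreMatrix(values=values, standardization=standardization,
                       provenance=prov)


def hla_scores(geno: GenotypeMatrix,
               definitions: list[GateScoreDefinition],
               region: tuple[str, int, int] = HLA_REGION) -> ScoreMatrix:
    """Scores restricted to the HLA region; kept separate from GATE output.

    Every member SNP must lie inside the region mask.
    """
    chrom, start, end = region
    for d in definitions:
        for locus in d.loci:
            if (str(locus.chrom) != str(chrom) or locus.start < start
                    or locus.end > end):
                raise StructuralError(
                    f"locus {locus.gene_id}:{locus.chrom}:{locus.start} of "
                    f"{d.score_id} lies outside the HLA region")
    return compute_scores(geno, definitions)
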