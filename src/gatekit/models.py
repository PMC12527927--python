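"""Model/results objects tying the analysis stages together.

:class:`GateModel` is constructed from QTL summary statistics, genotype
dosages and a phenotype table (``from_synthetic`` builds all three from the
generator); ``fit()`` runs catalog building, score computation, association,
clustering and core-gene calling and returns a :class:`GateResults` with the
estimates, a ``summary()`` table, and hooks for information and Mendelian
randomization follow-ups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from . import catalog as cat
from . import mr as mr_mod
from .association import (DEFAULT_CORE_P, DEFAULT_CORR_THRESHOLD,
                          call_core_genes, calls_to_frame,
                          cluster_scores, fit_all_associations,
                          fit_score_association, score_correlation_matrix)
from .exceptions import GatekitError
from .information import InformationEstimate, gene_information
from .scores import (DEFAULT_MIN_TRANS_LOCI, build_cis_definitions,
                     build_definitions, build_hla_definitions,
                     compute_scores, hla_scores)
from .synthetic import (ArchitectureConfig, GenotypeMatrix, StudyData,
                        simulate_study)


@dataclass
class GateConfig:
    """Thresholds of the analysis, defaults as used throughout."""

    cis_window: int = cat.DEFAULT_CIS_WINDOW
    clump_window: int = cat.DEFAULT_CLUMP_WINDOW
    trans_p: float = cat.DEFAULT_TRANS_P
    cis_p: float = cat.DEFAULT_CIS_P
    ridge: float = cat.DEFAULT_RIDGE
    hla_region: tuple[str, int, int] | None = cat.HLA_REGION
    min_trans_loci: int = DEFAULT_MIN_TRANS_LOCI
    core_p: float = DEFAULT_CORE_P
    corr_threshold: float = DEFAULT_CORR_THRESHOLD
    score_type: str = "eGATE"
    covariate_set: str = "discovery"


class GateModel:
    """Aggregated trans-effect analysis of one case-control dataset."""

    def __init__(self, summary_stats: pd.DataFrame,
                 genotypes: GenotypeMatrix,
                 phenotypes: pd.DataFrame,
                 ld_genotypes: GenotypeMatrix | None = None,
                 config: GateConfig | None = None,
                 study: StudyData | None = None):
        self.summary_stats = summary_stats
        self.genotypes = genotypes
        self.phenotypes = phenotypes
        self.ld_genotypes = ld_genotypes if ld_genotypes is not None \
            else genotypes
        self.config = config or GateConfig()
        self.study = study     # retained for synthetic truth-based follow-ups

    @classmethod
    def from_synthetic(cls, arch: ArchitectureConfig | None = None,
                       n_cases: int = 5267, n_controls: int = 4909,
                       n_ref: int = 10000, seed: int | None = None,
                       config: GateConfig | None = None) -> "GateModel":
        """Simulate a study (discovery-sized by default) and wrap it."""
        arch = arch or ArchitectureConfig()
        study = simulate_study(arch, n_cases=n_cases, n_controls=n_controls,
                               n_ref=n_ref, seed=seed)
        return cls(study.summary_stats, study.cc_genotypes, study.phenotypes,
                   ld_genotypes=study.ref_genotypes, config=config,
                   study=study)

    def fit(self) -> "GateResults":
        c = self.config
        catalog = cat.build_catalog(
            self.summary_stats, self.ld_genotypes, cis_window=c.cis_window,
            clump_window=c.clump_window, trans_p=c.trans_p, cis_p=c.cis_p,
            ridge=c.ridge, hla_region=c.hla_region)
        gate_defs = build_definitions(catalog.trans_loci,
                                      min_trans_loci=c.min_trans_loci,
                                      score_type=c.score_type)
        cis_defs = build_cis_definitions(catalog.cis_loci)
        hla_defs = build_hla_definitions(catalog.hla_loci)
        gate_scores = compute_scores(self.genotypes, gate_defs)
        cis_scores_ = compute_scores(self.genotypes, cis_defs)
        hla_scores_ = (hla_scores(self.genotypes, hla_defs, region=c.hla_region)
                       if c.hla_region and hla_defs
                       else compute_scores(self.genotypes, hla_defs))

        associations = fit_all_associations(gate_scores, self.phenotypes,
                                            covariate_set=c.covariate_set)
        cis_assoc = (fit_all_associations(cis_scores_, self.phenotypes,
                                          covariate_set=c.covariate_set)
                     if cis_scores_.score_ids else pd.DataFrame())
        hla_assoc = (fit_all_associations(hla_scores_, self.phenotypes,
                                          covariate_set=c.covariate_set)
                     if hla_scores_.score_ids else pd.DataFrame())

        controls = self.phenotypes.loc[self.phenotypes["STATUS"] == 0,
                                       "IID"].astype(str).tolist()
        if len(gate_scores.score_ids) >= 2:
            corr = score_correlation_matrix(gate_scores.values, controls)
            clusters = cluster_scores(corr, threshold=c.corr_threshold)
        elif len(gate_scores.score_ids) == 1:
            corr = pd.DataFrame([[1.0]], index=gate_scores.score_ids,
                                columns=gate_scores.score_ids)
            clusters = {gate_scores.score_ids[0]: 1}
        else:
            corr, clusters = pd.DataFrame(), {}
        calls = (call_core_genes(associations, clusters, p_threshold=c.core_p)
                 if clusters else [])
        return GateResults(model=self, catalog=catalog,
                           gate_scores=gate_scores, cis_scores=cis_scores_,
                           hla_score_matrix=hla_scores_,
                           associations=associations, cis_assoc=cis_assoc,
                           hla_assoc=hla_assoc, correlations=corr,
                           clusters=clusters, calls=calls_to_frame(calls)
                           if calls else pd.DataFrame())


@dataclass
class GateResults:
    """Fitted GATE analysis: associations, clusters and core-gene calls."""

    model: GateModel
    catalog: cat.Catalog
    gate_scores: "object"
    cis_scores: "object"
    hla_score_matrix: "object"
    associations: pd.DataFrame
    cis_assoc: pd.DataFrame
    hla_assoc: pd.DataFrame
    correlations: pd.DataFrame
    clusters: dict[str, int]
    calls: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def putative_core_genes(self) -> list[str]:
        if self.calls.empty:
            return []
        return sorted(self.calls.loc[self.calls["status"] == "putative_core",
                                     "gene_id"].unique())

    def report_table(self) -> pd.DataFrame:
        """Per-gene table mirroring the main results layout: gene, score
        type, TSS, locus count, per-SD log OR and p, cis log OR and p."""
        rows = []
        cis_by_gene = ({r["gene_id"]: r for _, r in self.cis_assoc.iterrows()}
                       if not self.cis_assoc.empty else {})
        gm = (self.model.study.truth.gene_meta().set_index("gene_id")
              if self.model.study is not None else None)
        for _, r in self.associations.iterrows():
            gene = r.get("gene_id", r["score_id"])
            cis = cis_by_gene.get(gene)
            row = {
                "gene": gene, "score_type": r.get("score_type", ""),
                "chr": gm.loc[gene, "chrom"] if gm is not None
                and gene in gm.index else "",
                "tss_mb": (round(gm.loc[gene, "tss"] / 1e6, 2)
                           if gm is not None and gene in gm.index else ""),
                "n_trans_loci": r.get("n_trans_loci", ""),
                "log_or": r["log_or"], "p": r["p"],
                "cis_log_or": cis["log_or"] if cis is not None else np.nan,
                "cis_p": cis["p"] if cis is not None else np.nan,
                "status": "",
            }
            if not self.calls.empty:
                m = self.calls.loc[self.calls["score_id"] == r["score_id"]]
                if not m.empty:
                    row["status"] = m["status"].iloc[0]
            rows.append(row)
        df = pd.DataFrame(rows)
        return df.sort_values("p").reset_index(drop=True)

    def summary(self) -> SimpleTable:
        df = self.report_table()
        data = [[str(v) if not isinstance(v, float)
                 else f"{v:.3g}" for v in row] for row in df.to_numpy()]
        return SimpleTable(data, headers=list(df.columns),
                           title="Aggregated trans-effect score associations")

    def gene_information(self, gene_id: str, expression: pd.DataFrame,
                         h2_trans: float) -> InformationEstimate:
        """Diluted information for one gene, using measured expression."""
        sid = f"{self.model.config.score_type}_{gene_id}"
        if sid not in self.gate_scores.values.columns:
            raise GatekitError(f"no GATE score for gene {gene_id}")
        row = self.associations.loc[self.associations["score_id"] == sid]
        beta = float(row["log_or"].iloc[0])
        common = [i for i in self.gate_scores.values.index
                  if i in expression.index]
        return gene_information(
            beta, self.gate_scores.values.loc[common, sid].to_numpy(),
            expression.loc[common, gene_id].to_numpy(), h2_trans)

    def mr_instruments(self, gene_id: str) -> list[mr_mod.Instrument]:
        """Per-locus instruments: lead-SNP exposure effect from the
        reference summary statistics, outcome effect from a per-SNP logistic
        fit on the case-control cohort."""
        sid = f"{self.model.config.score_type}_{gene_id}"
        definition = self.gate_scores.provenance.get(sid)
        if definition is None:
            raise GatekitError(f"no GATE definition for gene {gene_id}")
        ss = self.model.summary_stats
        pheno = self.model.phenotypes.set_index("IID")
        geno = self.model.genotypes
        pheno = pheno.loc[[str(i) for i in geno.sample_ids]]
        cov_cols = [c for c in ("SEX", "COHORT", "PC1", "PC2", "PC3")
                    if c in pheno.columns]
        instruments = []
        for locus in definition.loci:
            sub = ss[(ss["GENE"] == gene_id) & (ss["SNP"].isin(locus.snp_ids))]
            lead = sub.loc[sub["P"].idxmin()]
            dos = geno.dosage_for([lead["SNP"]])[:, 0]
            sd = dos.std()
            if sd == 0:
                continue
            res = fit_score_association(
                (dos - dos.mean()) / sd, pheno["STATUS"],
                pheno[cov_cols] if cov_cols else None,
                score_id=str(lead["SNP"]))
            # per-SD scaling on both sides keeps the ratio interpretable
            instruments.append(mr_mod.Instrument(
                locus_id=f"{locus.chrom}:{locus.start}",
                beta_exposure=float(lead["BETA"]) * sd,
                se_exposure=float(lead["SE"]) * sd,
                beta_outcome=res.log_or, se_outcome=res.se))
        return instruments

    def mendelian_randomization(self, gene_id: str, seed: int = 0,
                                **kwargs) -> mr_mod.MrResult:
        return mr_mod.fit_pleiotropy_marginalized(
            self.mr_instruments(gene_id), seed=seed, **kwargs)

    def plot_score_correlations(self, ax=None):
        """Heatmap of score correlations (computed over controls)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.correlations.to_numpy(), vmin=-1, vmax=1,
                       cmap="RdBu_r")
        ax.set_xticks(range(len(self.correlations)),
                      self.correlations.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(len(self.correlations)),
                      self.correlations.index, fontsize=7)
        ax.figure.colorbar(im, ax=ax, label="r (controls)")
        return ax


class TransMR:
    """Two-sample MR of a gene product on disease from trans-QTL instruments."""

    def __init__(self, instruments: list[mr_mod.Instrument]):
        if not instruments:
            raise GatekitError("no instruments supplied")
        self.instruments = instruments

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TransMR":
        return cls(mr_mod.instruments_from_frame(df))

    def fit(self, seed: int = 0, **kwargs) -> mr_mod.MrResult:
        return mr_mod.fit_pleiotropy_marginalized(self.instruments,
                                                  seed=seed, **kwargs)

    def wald_ratios(self) -> np.ndarray:
        return mr_mod.wald_ratios(self.instruments)
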