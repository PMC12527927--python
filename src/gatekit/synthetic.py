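"""Synthetic cohorts with an omnigenic trans-regulatory architecture.

This module generates everything the aggregated trans-effect (GATE) analysis
consumes: LD-blocked genotype dosages, gene expression with configurable cis
and trans heritability, a binary disease driven by the trans-regulated
component of a few "core" genes, and a reference cohort of marginal QTL
summary statistics.  A trans-hotspot mimicking the HLA region (a block on
chromosome 6, 25-34 Mb, with trans effects on many genes and a direct effect
on disease) can be switched on to exercise the hotspot mask downstream.

The generative model, briefly:

* Haplotypes are Gaussian copulas: a latent AR(1) chain within each LD block,
  thresholded at the MAF quantile.  The latent adjacent correlation is
  calibrated (via Owen's T) so that the *dosage-scale* adjacent correlation
  equals ``block_rho``; blocks are mutually independent.  All SNPs in a block
  share one MAF so that high target correlations remain attainable.
* Expression of gene g is ``sqrt(h2_trans)*T + sqrt(h2_cis)*C + noise`` where
  T (C) is the standardized trans (cis) genetic value, so realized variance
  fractions match the configuration.
* Disease is logistic in the standardized trans genetic values of core genes
  (plus an optional direct hotspot effect): the intercept is the log-odds of
  ``prevalence``, i.e. the disease probability at mean liability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit, owens_t

from .exceptions import ConfigurationError, SimulationError, StructuralError

logger = logging.getLogger(__name__)

#: Unambiguous effect/other allele pairs (no A/T or C/G strand flips).
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

_CHROMS = [str(c) for c in range(1, 23)]

HLA_LIKE_REGION = ("6", 25_000_000, 34_000_000)


@dataclass
class ArchitectureConfig:
    """Parameters of the synthetic omnigenic architecture.

    The defaults describe the study conditions the package is exercised
    under: five core genes each hit by eight peripheral trans loci, trans
    heritability of expression 0.4 and cis heritability 0.1, a per-SD
    core-gene log odds ratio of 0.3 on disease, and an active HLA-like
    hotspot at chromosome 6, 25-34 Mb.
    """

    n_snps: int = 300
    n_blocks: int = 100
    block_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_core_genes: int = 5
    n_peripheral_loci_per_gene: int = 8
    trans_effect_sd: float = 0.15
    h2_trans: float = 0.4
    h2_cis: float = 0.1
    core_log_or: float = 0.3
    prevalence: float = 0.1
    hla_like_region: tuple[str, int, int] | None = HLA_LIKE_REGION
    seed: int = 0
    # --- knobs beyond the core architecture ---
    n_null_genes: int = 5          # genes with QTLs but no disease effect
    n_shared_genes: int = 0        # ISG-like cluster sharing one locus set
    shared_beta_jitter: float = 0.25   # relative per-locus beta jitter in cluster
    n_individuals: int = 1000      # default cohort size for simulate_genotypes
    hotspot_n_snps: int = 5
    hotspot_trans_share: float = 0.15   # hotspot share of trans genetic variance
    hotspot_disease_log_or: float = 0.5
    covariate_confounding: float = 0.0  # effect of PC1 on liability
    n_pcs: int = 10

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.05 <= lo <= hi <= 0.5):
            raise ConfigurationError(
                f"maf_range must lie within [0.05, 0.5], got {self.maf_range}")
        if not (0.0 <= self.block_rho < 1.0):
            raise ConfigurationError(
                f"block_rho must be in [0, 1), got {self.block_rho}")
        if not (0.0 <= self.h2_trans < 1.0 and 0.0 <= self.h2_cis < 1.0):
            raise ConfigurationError("h2_trans and h2_cis must be in [0, 1)")
        if self.h2_trans + self.h2_cis >= 1.0:
            raise ConfigurationError(
                f"h2_trans + h2_cis must be < 1, got "
                f"{self.h2_trans + self.h2_cis}")
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigurationError("prevalence must be in (0, 1)")
        if not (0.0 <= self.hotspot_trans_share < 1.0):
            raise ConfigurationError("hotspot_trans_share must be in [0, 1)")
        for name in ("n_snps", "n_blocks", "n_core_genes",
                     "n_peripheral_loci_per_gene", "n_individuals"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_blocks > self.n_snps:
            raise ConfigurationError("n_blocks cannot exceed n_snps")

    @property
    def n_genes(self) -> int:
        return self.n_shared_genes + self.n_core_genes + self.n_null_genes

    @property
    def hotspot_active(self) -> bool:
        return self.hla_like_region is not None and self.hotspot_n_snps > 0


@dataclass
class GenotypeMatrix:
    """Dosage matrix plus per-SNP metadata.

    ``dosages`` holds effect-allele counts in [0, 2] (individuals x SNPs);
    ``snp_meta`` carries id, chrom, pos, ea, oa and the empirical effect
    allele frequency ``af``.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.dosages.shape[1] != len(self.snp_meta):
            raise StructuralError(
                f"dosage columns ({self.dosages.shape[1]}) != snp_meta rows "
                f"({len(self.snp_meta)})")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise StructuralError("dosage rows != number of sample ids")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def column_index(self, snp_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_meta["id"])}
        return np.array([lookup[s] for s in snp_ids], dtype=int)

    def dosage_for(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Float dosages for the requested SNPs, mean-imputing missing values."""
        cols = self.dosage_float(self.column_index(snp_ids))
        return cols

    def dosage_float(self, idx: np.ndarray) -> np.ndarray:
        d = np.asarray(self.dosages[:, idx], dtype=float)
        if np.isnan(d).any():
            means = np.nanmean(d, axis=0)
            nan_r, nan_c = np.nonzero(np.isnan(d))
            d[nan_r, nan_c] = means[nan_c]
        return d

    def subset(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        rows = np.array([pos[s] for s in sample_ids], dtype=int)
        return GenotypeMatrix(self.dosages[rows], self.snp_meta.copy(),
                              list(sample_ids))


@dataclass
class GeneSpec:
    """Ground-truth architecture of one gene."""

    gene_id: str
    chrom: str
    tss: int
    cis_index: int
    cis_beta: float
    trans_indices: np.ndarray
    trans_betas: np.ndarray
    hotspot_betas: np.ndarray      # one per hotspot SNP; empty if no hotspot
    h2_trans: float
    h2_cis: float
    log_or: float
    is_core: bool
    cluster: str | None = None     # shared-locus cluster label, if any


@dataclass
class TrueArchitecture:
    """Ground truth: SNP panel, per-gene causal effects, disease effects."""

    config: ArchitectureConfig
    snp_meta: pd.DataFrame          # id chrom pos ea oa maf block
    block_sizes: np.ndarray
    block_latent_rho: np.ndarray
    block_maf: np.ndarray
    genes: list[GeneSpec]
    hotspot_indices: np.ndarray
    hotspot_disease_weights: np.ndarray

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def gene(self, gene_id: str) -> GeneSpec:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def gene_meta(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": self.gene_ids,
            "chrom": [g.chrom for g in self.genes],
            "tss": [g.tss for g in self.genes],
        })


# ---------------------------------------------------------------------------
# copula calibration


def _binary_corr(p: float, latent_rho: float) -> float:
    """Pearson correlation of two threshold-Bernoulli(p) variables whose
    latents are standard bivariate normal with correlation ``latent_rho``.

    Uses the Owen's-T identity for equal thresholds h:
    Phi2(h, h; rho) = Phi(h) - 2*T(h, sqrt((1-rho)/(1+rho))).
    """
    if latent_rho <= 0.0:
        return 0.0
    h = stats.norm.ppf(p)
    a = math.sqrt((1.0 - latent_rho) / (1.0 + latent_rho))
    p11 = stats.norm.cdf(h) - 2.0 * float(owens_t(h, a))
    return (p11 - p * p) / (p * (1.0 - p))


def _latent_rho_for(p: float, target: float) -> float:
    """Latent AR(1) step correlation giving dosage-scale correlation ``target``."""
    if target <= 0.0:
        return 0.0
    hi = 0.999999
    if _binary_corr(p, hi) < target:   # pragma: no cover - not reachable
        return hi
    return float(brentq(lambda r: _binary_corr(p, r) - target, 0.0, hi,
                        xtol=1e-8))


# ---------------------------------------------------------------------------
# architecture sampling


def _panel_layout(config: ArchitectureConfig, rng: np.random.Generator):
    """Block sizes, chromosomes, positions and MAFs of the SNP panel."""
    base = config.n_snps // config.n_blocks
    sizes = np.full(config.n_blocks, base, dtype=int)
    sizes[: config.n_snps - base * config.n_blocks] += 1
    chroms, positions, block_of = [], [], []
    next_pos = {c: 1_000_000 for c in _CHROMS}
    next_pos["6"] = 40_000_000   # keep regular chr6 blocks clear of the hotspot
    for b, m in enumerate(sizes):
        chrom = _CHROMS[b % len(_CHROMS)]
        start = next_pos[chrom]
        for k in range(m):
            chroms.append(chrom)
            positions.append(start + k * 20_000)
            block_of.append(b)
        next_pos[chrom] = start + m * 20_000 + 1_000_000
    block_maf = rng.uniform(*config.maf_range, size=config.n_blocks)
    # hotspot block appended last, inside the HLA-like region
    if config.hotspot_active:
        chrom, lo, hi = config.hla_like_region
        start = (lo + hi) // 2
        b = config.n_blocks
        for k in range(config.hotspot_n_snps):
            chroms.append(chrom)
            positions.append(start + k * 20_000)
            block_of.append(b)
        sizes = np.append(sizes, config.hotspot_n_snps)
        block_maf = np.append(block_maf, rng.uniform(*config.maf_range))
    n_total = len(chroms)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_total)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    meta = pd.DataFrame({
        "id": [f"rs{i + 1}" for i in range(n_total)],
        "chrom": chroms,
        "pos": positions,
        "ea": ea,
        "oa": oa,
        "maf": block_maf[np.asarray(block_of)],
        "block": block_of,
    })
    return sizes, block_maf, meta


def sample_architecture(config: ArchitectureConfig,
                        rng: np.random.Generator | None = None
                        ) -> TrueArchitecture:
    """Draw the SNP panel and the gene-level causal architecture.

    Core genes receive ``n_peripheral_loci_per_gene`` disjoint trans LD
    blocks (always on a different chromosome than the gene) plus one cis
    block near the TSS.  If ``n_shared_genes >= 2`` the first genes form an
    ISG-like cluster sharing a single locus set (betas jittered per gene);
    only the first member carries the disease effect, so the cluster is
    jointly associated but individually unresolvable — as in real data.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sizes, block_maf, meta = _panel_layout(config, rng)
    latent = np.array([_latent_rho_for(m, config.block_rho)
                       for m in block_maf])

    n_regular_blocks = config.n_blocks
    hotspot_block = n_regular_blocks if config.hotspot_active else None
    hot_idx = (meta.index[meta["block"] == hotspot_block].to_numpy()
               if hotspot_block is not None else np.array([], dtype=int))

    n_clusters = 1 if config.n_shared_genes >= 2 else 0
    n_locus_sets = n_clusters + config.n_core_genes + config.n_null_genes
    need = n_locus_sets * config.n_peripheral_loci_per_gene + config.n_genes
    if need > n_regular_blocks:
        raise ConfigurationError(
            f"architecture needs {need} LD blocks but only "
            f"{n_regular_blocks} are configured; increase n_blocks")

    free = list(rng.permutation(n_regular_blocks))
    block_snps = {b: meta.index[meta["block"] == b].to_numpy()
                  for b in range(len(sizes))}

    def block_chrom(b: int) -> str:
        return meta.loc[block_snps[b][0], "chrom"]

    def take_block(avoid_chroms: frozenset = frozenset()) -> int:
        for i in range(len(free) - 1, -1, -1):
            if block_chrom(free[i]) not in avoid_chroms:
                return free.pop(i)
        raise ConfigurationError(
            "not enough LD blocks outside the excluded chromosomes; "
            "increase n_blocks")

    def draw_betas(k: int, sd: float) -> np.ndarray:
        mags = rng.uniform(0.5, 1.5, size=k) * sd
        signs = rng.choice([-1.0, 1.0], size=k)
        return mags * signs

    genes: list[GeneSpec] = []

    # one latent "HLA antigen" axis carries both the hotspot's direct disease
    # effect and its trans effects on genes, so HLA scores and disease share
    # a common genetic direction (as for a real trans-hotspot)
    hot_axis = (rng.normal(1.0, 0.25, size=len(hot_idx))
                if len(hot_idx) else np.array([]))
    # small internal calibration cohort, used only to scale the hotspot
    # loading of each gene to `hotspot_trans_share` of its trans variance
    calib = _simulate_dosages(sizes, latent, block_maf, 2000,
                              np.random.default_rng(rng.integers(2 ** 31)))
    var_axis = float(np.var(calib[:, hot_idx] @ hot_axis)) if len(hot_idx) \
        else 0.0

    def add_gene(gene_id, cis_block, trans_idx, trans_betas, log_or, is_core,
                 cluster):
        cis_snps = block_snps[cis_block]
        cis_index = int(rng.choice(cis_snps))
        chrom = meta.loc[cis_index, "chrom"]
        tss = int(meta.loc[cis_snps[0], "pos"]) + 10_000
        # positive loading: the hotspot pushes its target genes in the same
        # direction it pushes disease, as for an immune trans-hotspot
        if len(hot_idx) and var_axis > 0 and config.hotspot_trans_share > 0:
            share = config.hotspot_trans_share * rng.uniform(0.8, 1.2)
            var_per = float(np.var(calib[:, trans_idx]
                                   @ np.asarray(trans_betas, dtype=float)))
            gamma = math.sqrt(share / (1.0 - share) * var_per / var_axis)
            hot_betas = gamma * hot_axis
        else:
            hot_betas = np.array([])
        genes.append(GeneSpec(
            gene_id=gene_id, chrom=chrom, tss=tss, cis_index=cis_index,
            cis_beta=1.0, trans_indices=np.asarray(trans_idx, dtype=int),
            trans_betas=np.asarray(trans_betas, dtype=float),
            hotspot_betas=hot_betas, h2_trans=config.h2_trans,
            h2_cis=config.h2_cis, log_or=log_or, is_core=is_core,
            cluster=cluster))

    def pick_trans(avoid_chroms: frozenset) -> np.ndarray:
        blocks = [take_block(avoid_chroms)
                  for _ in range(config.n_peripheral_loci_per_gene)]
        return np.array([int(rng.choice(block_snps[b])) for b in blocks])

    gid = 0
    # shared-locus (ISG-like) cluster: loci drawn once, cis blocks kept off
    # the shared chromosomes so the loci stay trans for every member gene
    if n_clusters:
        shared_idx = pick_trans(frozenset())
        shared_chroms = frozenset(meta.loc[i, "chrom"] for i in shared_idx)
        shared_betas = draw_betas(len(shared_idx), config.trans_effect_sd)
        for k in range(config.n_shared_genes):
            jitter = rng.normal(
                0.0, config.shared_beta_jitter * config.trans_effect_sd,
                size=len(shared_idx))
            add_gene(f"GENE{gid:03d}", take_block(shared_chroms), shared_idx,
                     shared_betas + jitter,
                     log_or=config.core_log_or if k == 0 else 0.0,
                     is_core=(k == 0), cluster="ISG")
            gid += 1
    for _ in range(config.n_core_genes + config.n_null_genes):
        is_core = gid - config.n_shared_genes < config.n_core_genes
        cis_block = take_block()
        idx = pick_trans(frozenset([block_chrom(cis_block)]))
        add_gene(f"GENE{gid:03d}", cis_block, idx,
                 draw_betas(len(idx), config.trans_effect_sd),
                 log_or=config.core_log_or if is_core else 0.0,
                 is_core=is_core, cluster=None)
        gid += 1

    hot_weights = hot_axis
    return TrueArchitecture(
        config=config, snp_meta=meta, block_sizes=sizes,
        block_latent_rho=latent, block_maf=block_maf, genes=genes,
        hotspot_indices=hot_idx, hotspot_disease_weights=hot_weights)


# ---------------------------------------------------------------------------
# genotype simulation


def _simulate_dosages(block_sizes: np.ndarray, block_latent: np.ndarray,
                      block_maf: np.ndarray, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Copula-haplotype dosages: 2 thresholded latent AR(1) chains per person."""
    n_hap = 2 * n
    cols = []
    for b, m in enumerate(block_sizes):
        rho_z = block_latent[b]
        h = stats.norm.ppf(block_maf[b])
        z = np.empty((n_hap, m))
        z[:, 0] = rng.standard_normal(n_hap)
        if m > 1:
            eps = rng.standard_normal((n_hap, m - 1))
            c = math.sqrt(1.0 - rho_z * rho_z)
            for k in range(1, m):
                z[:, k] = rho_z * z[:, k - 1] + c * eps[:, k - 1]
        alleles = (z < h).astype(np.int8)
        cols.append(alleles[0::2] + alleles[1::2])
    return np.concatenate(cols, axis=1)


def simulate_genotypes(config: ArchitectureConfig,
                       truth: TrueArchitecture | None = None,
                       n: int | None = None,
                       rng: np.random.Generator | None = None,
                       id_prefix: str = "S") -> GenotypeMatrix:
    """Simulate dosages for ``n`` individuals on the architecture's SNP panel.

    Two haplotypes per individual; each haplotype is a thresholded latent
    AR(1) Gaussian within every block (blocks independent).  With a fixed
    rng state the output is bit-identical across calls.
    """
    if truth is None:
        truth = sample_architecture(config)
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = config.n_individuals if n is None else n
    dosages = _simulate_dosages(truth.block_sizes, truth.block_latent_rho,
                                truth.block_maf, n, rng)
    meta = truth.snp_meta.copy()
    meta["af"] = dosages.mean(axis=0) / 2.0
    ids = [f"{id_prefix}{i + 1:06d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, snp_meta=meta, sample_ids=ids)


# ---------------------------------------------------------------------------
# expression


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def trans_genetic_values(geno: GenotypeMatrix, truth: TrueArchitecture,
                         standardize: bool = True) -> pd.DataFrame:
    """Per-gene trans genetic value (peripheral loci plus hotspot effects)."""
    out = {}
    for g in truth.genes:
        d = geno.dosage_float(g.trans_indices)
        t = d @ g.trans_betas if d.size else np.zeros(geno.n_individuals)
        if len(truth.hotspot_indices) and len(g.hotspot_betas):
            t = t + geno.dosage_float(truth.hotspot_indices) @ g.hotspot_betas
        out[g.gene_id] = _standardize(t) if standardize else t
    return pd.DataFrame(out, index=geno.sample_ids)


def simulate_expression(geno: GenotypeMatrix, truth: TrueArchitecture,
                        rng: np.random.Generator | None = None
                        ) -> pd.DataFrame:
    """Expression = sqrt(h2_trans)*T + sqrt(h2_cis)*C + noise, unit variance.

    Components are standardized within the cohort, so realized variance
    fractions match the configured heritabilities up to sampling error.
    """
    if geno.snp_meta.shape[0] != truth.snp_meta.shape[0]:
        raise StructuralError("genotypes do not match the architecture panel")
    rng = np.random.default_rng(truth.config.seed + 2) if rng is None else rng
    t_std = trans_genetic_values(geno, truth)
    out = {}
    for g in truth.genes:
        c_std = _standardize(geno.dosage_float(np.array([g.cis_index]))[:, 0]
                             * g.cis_beta)
        noise_sd = math.sqrt(max(0.0, 1.0 - g.h2_trans - g.h2_cis))
        x = (math.sqrt(g.h2_trans) * t_std[g.gene_id].to_numpy()
             + math.sqrt(g.h2_cis) * c_std
             + noise_sd * rng.standard_normal(geno.n_individuals))
        out[g.gene_id] = x
    return pd.DataFrame(out, index=geno.sample_ids)


# ---------------------------------------------------------------------------
# disease


def liability(geno: GenotypeMatrix, truth: TrueArchitecture,
              pc1: np.ndarray | None = None) -> np.ndarray:
    """Log-odds of disease per individual under the true model."""
    cfg = truth.config
    eta = np.full(geno.n_individuals,
                  math.log(cfg.prevalence / (1.0 - cfg.prevalence)))
    t_std = trans_genetic_values(geno, truth)
    for g in truth.genes:
        if g.log_or != 0.0:
            eta = eta + g.log_or * t_std[g.gene_id].to_numpy()
    if cfg.hotspot_active and cfg.hotspot_disease_log_or != 0.0:
        burden = geno.dosage_float(truth.hotspot_indices) \
            @ truth.hotspot_disease_weights
        eta = eta + cfg.hotspot_disease_log_or * _standardize(burden)
    if pc1 is not None and cfg.covariate_confounding != 0.0:
        eta = eta + cfg.covariate_confounding * pc1
    return eta


def simulate_case_control(geno: GenotypeMatrix,
                          expression: pd.DataFrame | None,
                          truth: TrueArchitecture,
                          n_cases: int, n_controls: int,
                          rng: np.random.Generator | None = None
                          ) -> pd.DataFrame:
    """Sample disease status on a genotype pool and select an exact design.

    Returns a phenotype/covariate table (IID, STATUS, SEX, COHORT, PC1..PCk)
    with exactly ``n_cases`` cases and ``n_controls`` controls drawn from the
    pool.  Raises :class:`SimulationError` with guidance when the pool cannot
    supply the requested counts.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    n = geno.n_individuals
    pcs = rng.standard_normal((n, cfg.n_pcs))
    eta = liability(geno, truth, pc1=pcs[:, 0])
    status = (rng.random(n) < expit(eta)).astype(int)
    case_idx = np.flatnonzero(status == 1)
    ctrl_idx = np.flatnonzero(status == 0)
    if len(case_idx) < n_cases or len(ctrl_idx) < n_controls:
        raise SimulationError(
            f"pool of {n} yielded {len(case_idx)} cases / {len(ctrl_idx)} "
            f"controls but {n_cases}/{n_controls} were requested; enlarge the "
            f"pool or adjust prevalence ({cfg.prevalence}) / effect sizes")
    keep = np.concatenate([rng.choice(case_idx, n_cases, replace=False),
                           rng.choice(ctrl_idx, n_controls, replace=False)])
    keep = rng.permutation(keep)
    ids = [geno.sample_ids[i] for i in keep]
    pheno = pd.DataFrame({
        "IID": ids,
        "STATUS": status[keep],
        "SEX": rng.integers(1, 3, size=len(keep)),
        "COHORT": rng.choice(["BIO", "SLG", "PRE"], size=len(keep)),
    })
    for k in range(cfg.n_pcs):
        pheno[f"PC{k + 1}"] = pcs[keep, k]
    return pheno


# ---------------------------------------------------------------------------
# reference summary statistics


def reference_summary_stats(geno_ref: GenotypeMatrix,
                            expression_ref: pd.DataFrame,
                            truth: TrueArchitecture) -> pd.DataFrame:
    """Marginal SNP -> gene summary statistics on a reference cohort.

    Simple-regression effect, SE and p of each SNP on each standardized
    expression column, in the summary-statistic table dialect
    (SNP CHR POS EA OA GENE GENE_CHR GENE_TSS BETA SE P).  The reference
    cohort must be disjoint from the case-control cohort and free of
    duplicated individuals.  Monomorphic SNPs are skipped with a log entry.
    """
    if len(set(geno_ref.sample_ids)) != len(geno_ref.sample_ids):
        raise StructuralError("duplicated individual ids in reference cohort")
    if list(expression_ref.index) != list(geno_ref.sample_ids):
        raise StructuralError("expression rows do not match genotype samples")
    n = geno_ref.n_individuals
    if n < 4:
        raise StructuralError("reference cohort too small for regression")
    X = geno_ref.dosage_float(np.arange(geno_ref.n_snps))
    X = X - X.mean(axis=0)
    sxx = (X ** 2).sum(axis=0)
    poly = sxx > 1e-12
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("reference_summary_stats: skipped %d monomorphic SNPs",
                    n_mono)
    Y = expression_ref.to_numpy(dtype=float)
    Y = (Y - Y.mean(axis=0)) / Y.std(axis=0)
    syy = (Y ** 2).sum(axis=0)
    B = (X[:, poly].T @ Y) / sxx[poly, None]          # snps x genes
    sse = syy[None, :] - B ** 2 * sxx[poly, None]
    se = np.sqrt(np.maximum(sse, 0.0) / ((n - 2) * sxx[poly, None]))
    tstat = np.divide(B, se, out=np.zeros_like(B), where=se > 0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    meta = geno_ref.snp_meta.loc[poly].reset_index(drop=True)
    gmeta = truth.gene_meta().set_index("gene_id")
    frames = []
    for j, gene in enumerate(expression_ref.columns):
        frames.append(pd.DataFrame({
            "SNP": meta["id"], "CHR": meta["chrom"], "POS": meta["pos"],
            "EA": meta["ea"], "OA": meta["oa"], "GENE": gene,
            "GENE_CHR": gmeta.loc[gene, "chrom"],
            "GENE_TSS": gmeta.loc[gene, "tss"],
            "BETA": B[:, j], "SE": se[:, j], "P": pvals[:, j],
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# whole-study convenience


@dataclass
class StudyData:
    """A complete synthetic study: reference cohort, summary statistics and
    a case-control cohort with expression for dilution estimation."""

    truth: TrueArchitecture
    ref_genotypes: GenotypeMatrix
    ref_expression: pd.DataFrame
    summary_stats: pd.DataFrame
    cc_genotypes: GenotypeMatrix
    cc_expression: pd.DataFrame
    phenotypes: pd.DataFrame


def simulate_study(config: ArchitectureConfig, n_cases: int, n_controls: int,
                   n_ref: int, seed: int | None = None) -> StudyData:
    """Generate reference and case-control cohorts sharing one SNP panel.

    The pool for rejection sampling of the case-control design is sized from
    the configured prevalence with a 40% safety margin.  Reference and target
    individuals are disjoint by construction (distinct id prefixes and rng
    streams).
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    r_arch, r_ref, r_refx, r_pool, r_cc, r_ccx = [
        np.random.default_rng(s) for s in ss.spawn(6)]
    truth = sample_architecture(config, rng=r_arch)
    ref = simulate_genotypes(config, truth, n=n_ref, rng=r_ref,
                             id_prefix="REF")
    ref_expr = simulate_expression(ref, truth, rng=r_refx)
    sumstats = reference_summary_stats(ref, ref_expr, truth)
    p = config.prevalence
    n_pool = int(1.4 * max(n_cases / p, n_controls / (1.0 - p))) + 500
    pool = simulate_genotypes(config, truth, n=n_pool, rng=r_pool,
                              id_prefix="CC")
    pheno = simulate_case_control(pool, None, truth, n_cases, n_controls,
                                  rng=r_cc)
    cc = pool.subset(pheno["IID"].tolist())
    cc_expr = simulate_expression(cc, truth, rng=r_ccx)
    return StudyData(truth=truth, ref_genotypes=ref, ref_expression=ref_expr,
                     summary_stats=sumstats, cc_genotypes=cc,
                     cc_expression=cc_expr, phenotypes=pheno)
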