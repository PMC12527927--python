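"""Score-disease association, score clustering, and core-gene calls.

Each standardized score is tested against case-control status with a
maximum-likelihood logistic regression adjusting for sex, cohort and
genetic principal components; the reported coefficient is the per-SD log
odds ratio with a Wald standard error and p-value.  Scores of detected
genes are then correlated over controls, clustered (average linkage on
1 - |r|), and genes are called putative core genes only when significant
*and* not part of a multi-gene correlation cluster — correlated scores
share trans-QTLs, so the mediating gene cannot be distinguished.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import StructuralError
from .scores import ScoreMatrix

logger = logging.getLogger(__name__)

DEFAULT_CORE_P = 1e-6
DEFAULT_CORR_THRESHOLD = 0.25

#: covariate sets used in discovery (sex, cohort, 10 PCs) and replication
#: (sex, 20 PCs, no cohort) designs
COVARIATE_SETS = {
    "discovery": ("SEX", "COHORT") + tuple(f"PC{i}" for i in range(1, 11)),
    "replication": ("SEX",) + tuple(f"PC{i}" for i in range(1, 21)),
}


@dataclass
class AssociationResult:
    """Per-SD log odds ratio of one score on disease."""

    score_id: str
    log_or: float
    se: float
    p: float
    n_cases: int
    n_controls: int
    covariate_set: str
    converged: bool = True
    separated: bool = False


@dataclass
class CoreGeneCall:
    gene_id: str
    score_id: str
    status: str               # putative_core | cluster_member | not_significant
    cluster_id: int
    min_cluster_p: float


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code categoricals, drop degenerate columns, add a constant."""
    parts = []
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(d)
        else:
            parts.append(s.astype(float).to_frame())
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(
        index=covariates.index)
    degenerate = [c for c in X.columns if X[c].nunique() <= 1]
    if degenerate:
        logger.info("dropping degenerate covariates: %s", degenerate)
        X = X.drop(columns=degenerate)
    X.insert(0, "const", 1.0)
    return X


def fit_score_association(score: np.ndarray | pd.Series,
                          status: np.ndarray | pd.Series,
                          covariates: pd.DataFrame | None = None,
                          score_id: str = "score",
                          covariate_set: str = "discovery"
                          ) -> AssociationResult:
    """Logistic regression of disease on one standardized score.

    Perfect separation is flagged with an infinite-estimate sentinel rather
    than raised.
    """
    y = np.asarray(status, dtype=float)
    s = np.asarray(score, dtype=float)
    if covariates is not None:
        X = _design_matrix(covariates.reset_index(drop=True))
    else:
        X = pd.DataFrame({"const": np.ones(len(y))})
    X = X.copy()
    X.insert(1, "_score", s)
    n_cases = int(y.sum())
    n_controls = int(len(y) - n_cases)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X.to_numpy(dtype=float)).fit(disp=0,
                                                           maxiter=200)
        beta = float(res.params[1])
        se = float(res.bse[1])
        pval = float(res.pvalues[1])
        converged = bool(res.mle_retvals["converged"])
        separated = (not np.isfinite(se) or abs(beta) > 20
                     or (not converged and se > 100))
        if separated:
            beta = np.inf if beta > 0 else -np.inf
            se, pval = np.inf, np.nan
        return AssociationResult(score_id=score_id, log_or=beta, se=se,
                                 p=pval, n_cases=n_cases,
                                 n_controls=n_controls,
                                 covariate_set=covariate_set,
                                 converged=converged, separated=separated)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        logger.warning("perfect separation for %s", score_id)
        return AssociationResult(score_id=score_id, log_or=np.inf, se=np.inf,
                                 p=np.nan, n_cases=n_cases,
                                 n_controls=n_controls,
                                 covariate_set=covariate_set,
                                 converged=False, separated=True)


def fit_all_associations(scores: ScoreMatrix, phenotypes: pd.DataFrame,
                         covariate_set: str = "discovery",
                         covariate_cols: tuple[str, ...] | None = None
                         ) -> pd.DataFrame:
    """Association results for every score column, as a tidy table."""
    if covariate_cols is None:
        covariate_cols = COVARIATE_SETS[covariate_set]
    pheno = phenotypes.set_index("IID").loc[scores.values.index]
    cols = [c for c in covariate_cols if c in pheno.columns]
    missing = set(covariate_cols) - set(cols)
    if missing:
        logger.info("covariates absent from phenotype table: %s",
                    sorted(missing))
    rows = []
    for sid in scores.score_ids:
        r = fit_score_association(scores.values[sid], pheno["STATUS"],
                                  pheno[cols], score_id=sid,
                                  covariate_set=covariate_set)
        d = r.__dict__.copy()
        prov = scores.provenance.get(sid)
        if prov is not None:
            d["gene_id"] = prov.gene_id
            d["score_type"] = prov.score_type
            d["n_trans_loci"] = prov.n_trans_loci
        rows.append(d)
    return pd.DataFrame(rows)


def score_correlation_matrix(scores: pd.DataFrame,
                             control_ids: list[str] | np.ndarray
                             ) -> pd.DataFrame:
    """Pearson correlations between scores, computed over controls only."""
    sub = scores.loc[control_ids]
    if sub.shape[0] < 3:
        raise StructuralError("need at least 3 control individuals")
    if sub.shape[1] < 2:
        raise StructuralError("need at least 2 scores")
    sds = sub.std(ddof=0)
    zero_var = sds[sds == 0].index.tolist()
    if zero_var:
        logger.warning("excluding zero-variance scores: %s", zero_var)
        sub = sub.drop(columns=zero_var)
    R = np.corrcoef(sub.to_numpy(dtype=float), rowvar=False)
    return pd.DataFrame(R, index=sub.columns, columns=sub.columns)


def cluster_scores(corr: pd.DataFrame,
                   threshold: float = DEFAULT_CORR_THRESHOLD
                   ) -> dict[str, int]:
    """Average-linkage hierarchical clustering on distance 1 - |r|.

    The tree is cut at distance 1 - threshold, so clusters group scores
    whose absolute correlations reach the threshold.  Deterministic given
    the input matrix.
    """
    ids = list(corr.index)
    if len(ids) == 1:
        return {ids[0]: 1}
    D = 1.0 - np.abs(corr.to_numpy(dtype=float))
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=1.0 - threshold, criterion="distance")
    return {sid: int(lab) for sid, lab in zip(ids, labels)}


def call_core_genes(results: pd.DataFrame, clusters: dict[str, int],
                    p_threshold: float = DEFAULT_CORE_P
                    ) -> list[CoreGeneCall]:
    """Apply the core-gene rule to association results.

    Significant score in a singleton cluster -> ``putative_core``;
    significant in a multi-gene cluster -> ``cluster_member``; otherwise
    ``not_significant``.
    """
    missing = set(results["score_id"]) - set(clusters)
    if missing:
        raise StructuralError(
            f"scores without cluster assignment: {sorted(missing)}")
    sizes: dict[int, set[str]] = {}
    for sid, lab in clusters.items():
        row = results.loc[results["score_id"] == sid]
        gene = (row["gene_id"].iloc[0] if "gene_id" in results.columns
                and not row.empty else sid)
        sizes.setdefault(lab, set()).add(str(gene))
    calls = []
    for _, row in results.iterrows():
        sid = row["score_id"]
        gene = str(row.get("gene_id", sid))
        lab = clusters[sid]
        members = results.loc[
            results["score_id"].map(clusters.__getitem__) == lab]
        min_p = float(np.nanmin(members["p"].to_numpy(dtype=float)))
        sig = np.isfinite(row["p"]) and row["p"] < p_threshold
        if not sig:
            status = "not_significant"
        elif len(sizes[lab]) > 1:
            status = "cluster_member"
        else:
            status = "putative_core"
        calls.append(CoreGeneCall(gene_id=gene, score_id=sid, status=status,
                                  cluster_id=lab, min_cluster_p=min_p))
    return calls


def calls_to_frame(calls: list[CoreGeneCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])
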