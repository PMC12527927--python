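"""Mendelian randomization with pleiotropy marginalized out.

Each trans-QTL locus is an instrument: its effect on the gene product
(exposure) and its log odds ratio on disease (outcome).  The causal slope
theta is estimated under

    beta_outcome_j ~ Normal(theta * beta_exposure_j + alpha_j, se_outcome_j^2)

where alpha_j is an unobserved direct (pleiotropic) effect of instrument j
on disease, given a regularized-horseshoe prior: most instruments are
assumed clean, a few may have large direct effects.  Conditionally on the
horseshoe scales the alphas are Gaussian and are integrated out
analytically, leaving a marginal likelihood over (theta, tau, lambda_1..J)
that is sampled with an affine-invariant ensemble MCMC (emcee).  The
reported "support p-analog" is the two-sided posterior tail probability
2*min(P(theta>0), P(theta<0)) — an analog of a p-value, not a frequentist
one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import emcee
import numpy as np

from .exceptions import GatekitError, StructuralError

logger = logging.getLogger(__name__)

DEFAULT_GLOBAL_SCALE = 0.05   # prior scale of pleiotropy on the log-OR scale
DEFAULT_SLAB_SCALE = 1.0
DEFAULT_N_WALKERS = 32
DEFAULT_N_STEPS = 750
DEFAULT_N_BURN = 250
_THETA_PRIOR_SD = 10.0


@dataclass
class Instrument:
    """One trans-QTL locus used as an instrumental variable."""

    locus_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float

    def __post_init__(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise StructuralError(
                f"instrument {self.locus_id}: standard errors must be > 0")


@dataclass
class MrResult:
    """Posterior summary of the causal slope."""

    theta_mean: float
    theta_sd: float
    interval: tuple[float, float]        # central 95% credible interval
    wald: "np.ndarray"                   # structured per-instrument ratios
    p_analog: float
    diagnostics: dict = field(default_factory=dict)
    valid: bool = True
    theta_draws: np.ndarray | None = None


def wald_ratios(instruments: list[Instrument]) -> np.ndarray:
    """Per-instrument Wald ratio and first-order delta-method SE.

    ratio = beta_outcome / beta_exposure;
    se^2 = se_out^2/b_exp^2 + b_out^2 se_exp^2/b_exp^4.
    Instruments with zero exposure effect are excluded with a warning.
    """
    rows = []
    for ins in instruments:
        if ins.beta_exposure == 0:
            logger.warning("instrument %s excluded: zero exposure effect",
                           ins.locus_id)
            continue
        ratio = ins.beta_outcome / ins.beta_exposure
        var = (ins.se_outcome ** 2 / ins.beta_exposure ** 2
               + ins.beta_outcome ** 2 * ins.se_exposure ** 2
               / ins.beta_exposure ** 4)
        rows.append((ins.locus_id, ratio, math.sqrt(var)))
    return np.array(rows, dtype=[("locus_id", "U64"), ("ratio", float),
                                 ("se", float)])


def ivw_slope(instruments: list[Instrument]) -> float:
    """Inverse-variance-weighted slope through the origin (no pleiotropy)."""
    b = np.array([i.beta_exposure for i in instruments])
    y = np.array([i.beta_outcome for i in instruments])
    w = np.array([1.0 / i.se_outcome ** 2 for i in instruments])
    return float((w * b * y).sum() / (w * b * b).sum())


def naive_slope(instruments: list[Instrument]) -> float:
    """Unweighted regression-through-origin slope (no pleiotropy handling)."""
    b = np.array([i.beta_exposure for i in instruments])
    y = np.array([i.beta_outcome for i in instruments])
    return float((b * y).sum() / (b * b).sum())


def _log_posterior_factory(b: np.ndarray, y: np.ndarray, s2: np.ndarray,
                           se_exp2: np.ndarray, global_scale: float,
                           slab_scale: float, inflate_exposure: bool):
    """Vectorized log posterior over walkers.

    Parameters per walker: [theta, log tau, log lambda_1..J].
    alpha_j | tau, lambda ~ N(0, tau^2 * lam_tilde_j^2) is marginalized:
    y_j ~ N(theta b_j, s_j^2 + tau^2 lam_tilde_j^2), with the regularized
    horseshoe lam_tilde_j^2 = c^2 lam_j^2 / (c^2 + tau^2 lam_j^2).
    """
    c2 = slab_scale ** 2

    def log_prob(params: np.ndarray) -> np.ndarray:
        params = np.atleast_2d(params)
        theta = params[:, 0]
        log_tau = params[:, 1]
        log_lam = params[:, 2:]
        tau2 = np.exp(2.0 * log_tau)
        lam2 = np.exp(2.0 * log_lam)
        lam_t2 = c2 * lam2 / (c2 + tau2[:, None] * lam2)
        var = s2[None, :] + tau2[:, None] * lam_t2
        if inflate_exposure:
            var = var + theta[:, None] ** 2 * se_exp2[None, :]
        resid = y[None, :] - theta[:, None] * b[None, :]
        loglik = -0.5 * (resid ** 2 / var + np.log(2.0 * math.pi * var)
                         ).sum(axis=1)
        # priors: theta ~ N(0, 10^2); tau ~ half-Cauchy(global_scale);
        # lambda_j ~ half-Cauchy(1); log-Jacobians for the log transforms
        lp = -0.5 * theta ** 2 / _THETA_PRIOR_SD ** 2
        tau = np.exp(log_tau)
        lp += (-np.log1p((tau / global_scale) ** 2) + log_tau)
        lam = np.exp(log_lam)
        lp += (-np.log1p(lam ** 2) + log_lam).sum(axis=1)
        out = loglik + lp
        out[~np.isfinite(out)] = -np.inf
        return out

    return log_prob


def fit_pleiotropy_marginalized(instruments: list[Instrument],
                                global_scale: float = DEFAULT_GLOBAL_SCALE,
                                slab_scale: float = DEFAULT_SLAB_SCALE,
                                seed: int = 0,
                                n_walkers: int = DEFAULT_N_WALKERS,
                                n_steps: int = DEFAULT_N_STEPS,
                                n_burn: int = DEFAULT_N_BURN,
                                exposure_error: str = "plugin",
                                keep_draws: bool = False) -> MrResult:
    """Posterior over the causal slope, marginalizing pleiotropic effects.

    ``exposure_error`` is "plugin" (exposure betas treated as fixed, the
    two-sample MR default) or "inflate" (outcome variance inflated by
    theta^2 * se_exposure^2).  At least 3 instruments are recommended; a
    single instrument degenerates to its Wald ratio.  The result is flagged
    invalid when sampler diagnostics (effective sample size, acceptance
    fraction) fall outside thresholds.
    """
    usable = [i for i in instruments if i.beta_exposure != 0]
    if not usable:
        raise GatekitError("no usable instruments (all zero exposure effects)")
    if len(usable) < 3:
        logger.warning("only %d instrument(s); >= 3 recommended", len(usable))
    if exposure_error not in ("plugin", "inflate"):
        raise GatekitError("exposure_error must be 'plugin' or 'inflate'")
    b = np.array([i.beta_exposure for i in usable])
    y = np.array([i.beta_outcome for i in usable])
    s2 = np.array([i.se_outcome ** 2 for i in usable])
    se_exp2 = np.array([i.se_exposure ** 2 for i in usable])
    J = len(usable)
    ndim = J + 2
    n_walkers = max(n_walkers, 2 * ndim + 2)

    log_prob = _log_posterior_factory(b, y, s2, se_exp2, global_scale,
                                      slab_scale, exposure_error == "inflate")
    rng = np.random.default_rng(seed)
    theta0 = ivw_slope(usable)
    p0 = np.column_stack([
        theta0 + 0.1 * rng.standard_normal(n_walkers),
        math.log(global_scale) + 0.3 * rng.standard_normal(n_walkers),
        0.3 * rng.standard_normal((n_walkers, J)),
    ])
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob, vectorize=True)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_burn + n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn)          # steps x walkers x dim
    theta_draws = chain[:, :, 0].reshape(-1)

    acc = float(sampler.acceptance_fraction.mean())
    try:
        tau_int = float(emcee.autocorr.integrated_time(
            chain[:, :, 0], quiet=True)[0])
    except Exception:                                   # pragma: no cover
        tau_int = float("nan")
    ess = (len(theta_draws) / tau_int if np.isfinite(tau_int) and tau_int > 0
           else float("nan"))
    valid = bool(np.isfinite(ess) and ess >= 100 and 0.05 < acc < 0.95)
    if not valid:
        logger.warning("MR sampler diagnostics out of range "
                       "(ess=%.0f, acceptance=%.2f); result flagged invalid",
                       ess, acc)

    mean = float(theta_draws.mean())
    sd = float(theta_draws.std())
    lo, hi = np.percentile(theta_draws, [2.5, 97.5])
    pos = float((theta_draws > 0).mean())
    p_analog = max(2.0 * min(pos, 1.0 - pos), 2.0 / len(theta_draws))
    return MrResult(
        theta_mean=mean, theta_sd=sd, interval=(float(lo), float(hi)),
        wald=wald_ratios(usable), p_analog=p_analog,
        diagnostics={"ess": ess, "acceptance_fraction": acc,
                     "autocorr_time": tau_int, "n_divergent": 0,
                     "n_instruments": J,
                     "n_draws": int(len(theta_draws))},
        valid=valid,
        theta_draws=theta_draws if keep_draws else None)


def instruments_from_frame(df) -> list[Instrument]:
    """Build instruments from a table with columns
    locus, beta_exp, se_exp, beta_out, se_out."""
    return [Instrument(str(r["locus"]), float(r["beta_exp"]),
                       float(r["se_exp"]), float(r["beta_out"]),
                       float(r["se_out"])) for _, r in df.iterrows()]
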