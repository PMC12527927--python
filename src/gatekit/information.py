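"""Genetic contributions to disease on the information-for-discrimination
scale.

For a rare disease with additive genetic effects on the logistic scale, the
total genetic information for discriminating cases from non-cases equals the
logarithm of the sibling recurrence risk ratio: ``log2(lambda_s)`` bits
(4 bits for lambda_s = 16).  A single standardized predictor with log odds
ratio beta contributes ``beta^2 / 2`` nats, i.e. ``beta^2 / (2 ln 2)`` bits.

A genotype score is an imperfect predictor of the trans-regulated component
of expression, so its observed information understates the gene's underlying
contribution.  The dilution factor ``r^2 / h2_trans`` — the proportion of
the trans-heritable expression variance the score captures, with r the
score-expression correlation — divides the observed information:

    I = beta^2 / (2 log 2) / (r^2 / h2_trans)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import GatekitError, InconsistencyError

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

#: below this r^2 a dilution estimate is flagged unstable
DILUTION_R2_FLOOR = 1e-3


@dataclass
class InformationEstimate:
    """Diluted-information estimate for one gene (all symbols per-SD)."""

    beta: float
    r2: float
    h2_trans: float
    info_bits: float
    dilution: float


@dataclass
class TotalInformation:
    lambda_s: float
    total_bits: float


def total_information(lambda_s: float) -> float:
    """Total genetic information for discrimination, in bits: log2(lambda_s)."""
    if lambda_s < 1.0:
        raise GatekitError(
            f"recurrence risk ratio must be >= 1, got {lambda_s}")
    return math.log2(lambda_s)


def predictor_information(beta: float) -> float:
    """Information of one standardized predictor: beta^2 / (2 ln 2) bits."""
    if not np.isfinite(beta):
        raise GatekitError("beta must be finite")
    return beta * beta / (2.0 * LN2)


def diluted_information(beta: float, r2: float,
                        h2_trans: float) -> InformationEstimate:
    """Correct the observed information for score imperfection.

    Requires 0 < r2 <= h2_trans < 1; the corrected estimate is the observed
    information divided by the dilution factor r2/h2_trans, hence always at
    least the uncorrected value.
    """
    if not (0.0 < h2_trans < 1.0):
        raise GatekitError(f"h2_trans must be in (0, 1), got {h2_trans}")
    if r2 <= 0.0:
        raise GatekitError("r2 must be positive; the dilution correction is "
                           "undefined for a score unrelated to expression")
    if r2 > h2_trans:
        raise InconsistencyError(
            f"r2 ({r2}) exceeds h2_trans ({h2_trans}): dilution would exceed "
            "1; check the inputs")
    dilution = r2 / h2_trans
    info = predictor_information(beta) / dilution
    return InformationEstimate(beta=beta, r2=r2, h2_trans=h2_trans,
                               info_bits=info, dilution=dilution)


def fraction_of_total(info_bits: float, total_bits: float) -> float:
    """Percentage of the total genetic effect: 100 * info / total."""
    if total_bits <= 0:
        raise GatekitError("total_bits must be positive")
    return 100.0 * info_bits / total_bits


def estimate_dilution(score: np.ndarray, expression: np.ndarray,
                      h2_trans: float) -> tuple[float, float, bool]:
    """Estimate r^2 and the dilution factor from paired observations.

    Returns ``(r2, dilution, stable)``.  ``h2_trans`` comes from ground
    truth in synthetic runs or from external expression studies on real
    data.  A dilution exceeding 1 through sampling noise is clipped with a
    warning; an r^2 below :data:`DILUTION_R2_FLOOR` is flagged unstable.
    """
    s = np.asarray(score, dtype=float)
    x = np.asarray(expression, dtype=float)
    if s.shape != x.shape:
        raise GatekitError("score and expression must be paired")
    if len(s) < 3:
        raise GatekitError("need at least 3 paired observations")
    if not (0.0 < h2_trans <= 1.0):
        raise GatekitError(f"h2_trans must be in (0, 1], got {h2_trans}")
    r = np.corrcoef(s, x)[0, 1]
    r2 = float(r * r)
    dilution = r2 / h2_trans
    if dilution > 1.0:
        logger.warning("estimated dilution %.3f > 1 (sampling noise); "
                       "clipping to 1", dilution)
        dilution = 1.0
    stable = r2 >= DILUTION_R2_FLOOR
    if not stable:
        logger.warning("r^2 = %.2e below stability floor %.0e; dilution "
                       "estimate unreliable", r2, DILUTION_R2_FLOOR)
    return r2, dilution, stable


def gene_information(beta: float, score: np.ndarray, expression: np.ndarray,
                     h2_trans: float) -> InformationEstimate:
    """Convenience: estimate dilution from data, then correct the information."""
    r2, _, stable = estimate_dilution(score, expression, h2_trans)
    if not stable:
        raise GatekitError("dilution estimate unstable (r^2 below floor)")
    return diluted_information(beta, min(r2, h2_trans), h2_trans)


def pathway_information(beta_combined: float, r2_combined: float,
                        h2_trans_combined: float,
                        lambda_s: float) -> tuple[InformationEstimate, float]:
    """Information of a pathway-level combined score and its share of total.

    The combined score should be the mean of the standardized member scores;
    summing per-gene corrected estimates over correlated genes would
    double-count shared trans-effects.
    """
    est = diluted_information(beta_combined, r2_combined, h2_trans_combined)
    pct = fraction_of_total(est.info_bits, total_information(lambda_s))
    return est, pct
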