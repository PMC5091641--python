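"""Score calibration: P-values from a decoy score distribution and a
logistic map from the ranking score to prob[SS].

Random local-alignment scores of unrelated profiles follow an extreme-value
(Gumbel) law; its location/scale are fit by method of moments on decoy
scores.  The shared-structure probability prob[SS] is a logistic function of
the (negated) ranking score, fit on a labeled benchmark of true and false
hits.  Absolute prob[SS] values are therefore calibrated to this package's
own synthetic benchmark, not to any external tool's.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .align import AlignmentHit, ScoringParams, score_aass

EULER_GAMMA = 0.5772156649015329
PVAL_FLOOR = 1e-300


@dataclass
class CalibrationModel:
    gumbel_mu: float
    gumbel_beta: float
    library_size: int
    logistic_a: float
    logistic_b: float

    def __post_init__(self) -> None:
        if self.gumbel_beta <= 0:
            raise ValueError("gumbel_beta must be > 0")
        if self.logistic_b <= 0:
            raise ValueError(
                "logistic_b must be > 0 (prob must rise as score_aass falls)"
            )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            return cls(**json.load(fh))

    def with_library_size(self, n: int) -> "CalibrationModel":
        return CalibrationModel(
            self.gumbel_mu, self.gumbel_beta, n, self.logistic_a, self.logistic_b
        )


def fit_gumbel(scores) -> tuple[float, float]:
    """Method-of-moments Gumbel fit: beta = sd*sqrt(6)/pi, mu = mean - g*beta."""
    s = np.asarray(scores, dtype=float)
    beta = float(s.std(ddof=1) * math.sqrt(6.0) / math.pi)
    mu = float(s.mean() - EULER_GAMMA * beta)
    return mu, beta


def raw_score_aass(
    score: float,
    score_ss: float,
    mu: float,
    beta: float,
    params: ScoringParams,
) -> float:
    """Ranking score of a raw hit under a Gumbel null (no logistic needed)."""
    p = gumbel_pval(score, mu, beta)
    return score_aass(
        math.log(p), min(p, 1.0 - 1e-16), score, score_ss,
        lamda=params.lamda, ss_cap_enabled=params.ss_cap_enabled,
    )


def gumbel_pval(score: float, mu: float, beta: float) -> float:
    """P(random score >= score) under Gumbel(mu, beta), floored at 1e-300."""
    z = (score - mu) / beta
    p = -math.expm1(-math.exp(-z)) if z > -30 else 1.0
    return min(max(p, PVAL_FLOOR), 1.0)


def fit_calibration(
    decoy_scores,
    labeled: list[tuple[float, bool]],
    library_size: int,
) -> CalibrationModel:
    """Fit the Gumbel null on decoy scores (method of moments) and the
    prob[SS] logistic on a labeled (score_aass, is_true) set.

    beta = sd * sqrt(6) / pi, mu = mean - gamma * beta.  The logistic is a
    penalized fit of is_true on -score_aass, which stays finite even when
    the classes are perfectly separated.
    """
    scores = np.asarray(decoy_scores, dtype=float)
    if scores.size < 100:
        raise ValueError(f"need >= 100 decoy scores, got {scores.size}")
    mu, beta = fit_gumbel(scores)

    y = np.array([bool(t) for _, t in labeled])
    if y.all() or not y.any():
        raise ValueError("labeled set must contain both classes")
    x = np.array([-a for a, _ in labeled], dtype=float)
    a, b = _platt_fit(x, y)
    if b <= 0:
        raise ValueError("logistic fit has non-positive slope")
    return CalibrationModel(mu, beta, int(library_size), a, b)


def _platt_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Platt scaling: logistic fit with smoothed targets.

    Targets (n+ + 1)/(n+ + 2) and 1/(n- + 2) keep the maximum-likelihood
    slope finite even when the classes are perfectly separated.
    """
    xs = x.std()
    if xs == 0:
        raise ValueError("degenerate labeled set: constant score_aass")
    xm = x.mean()
    z = (x - xm) / xs
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    t = np.where(y, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(w):
        a0, b0 = w
        eta = a0 + b0 * z
        # -sum(t*log(p) + (1-t)*log(1-p)) in a numerically stable form
        val = np.sum(np.logaddexp(0.0, eta) - t * eta)
        grad_common = expit(eta) - t
        return val, np.array([grad_common.sum(), (grad_common * z).sum()])

    res = minimize(nll, x0=np.array([0.0, 1.0]), jac=True, method="L-BFGS-B")
    a0, b0 = res.x
    return float(a0 - b0 * xm / xs), float(b0 / xs)


def calibrate_hit(
    h: AlignmentHit,
    model: CalibrationModel,
    params: ScoringParams | None = None,
) -> AlignmentHit:
    """Fill pval, evalue, score_aass and prob[SS] on a hit (in place).

    pval is the Gumbel survival of the DP score; evalue = library_size *
    pval; prob[SS] = 100 * sigmoid(a + b * (-score_aass)), strictly
    decreasing in score_aass.
    """
    params = params or ScoringParams()
    p = gumbel_pval(h.score, model.gumbel_mu, model.gumbel_beta)
    h.pval = p
    h.logPval = math.log(p)
    h.evalue = model.library_size * p
    # guard the second score_aass branch against pval rounding to 1.0
    p_for_aass = min(p, 1.0 - 1e-16)
    h.score_aass = score_aass(
        h.logPval, p_for_aass, h.score, h.score_ss,
        lamda=params.lamda, ss_cap_enabled=params.ss_cap_enabled,
    )
    h.prob_ss = float(
        100.0 * expit(model.logistic_a + model.logistic_b * (-h.score_aass))
    )
    return h
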