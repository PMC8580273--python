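"""Range statistic and the three-ROPE omnibus test of life-course models.

The range phi = max(w) - min(w) of a simplex weight vector summarizes the
three classic life-course hypotheses in one dimension: phi = 0 when every
measurement occasion matters equally (accumulation), phi = 1 when a single
occasion carries the whole effect (critical period), and phi in between for
any other pattern (sensitive periods).  Two thresholds 0 < a < b < 1 carve
[0, 1] into regions of practical equivalence (ROPEs): accumulation = [0, a],
sensitive = (a, b), critical = [b, 1].  The posterior probability of each
model is the fraction of MCMC weight draws whose phi lands in its interval;
the three probabilities are exhaustive and sum to one.  A decision is
*conclusive* when one model's probability exceeds the decision threshold
(default 0.9); Bayes factors against the prior ROPE probabilities provide a
relative measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .exceptions import (
    EmptyOrthantError,
    InvalidInputError,
    UndefinedBayesFactorError,
)
from .rankings import DrawMatrix, _as_values

__all__ = [
    "RopeConfig",
    "RopeResult",
    "SignCoherence",
    "MODEL_LABELS",
    "range_statistic",
    "classify_phi",
    "rope_test",
    "prior_rope_probabilities",
    "bayes_factor",
    "sign_coherence_probability",
]

MODEL_LABELS = ("accumulation", "sensitive", "critical")

#: Negative components within this of zero are treated as rounding noise.
_NEG_CLIP = -1e-12
#: Row sums must be within this of 1 to count as simplex points.
_SIMPLEX_TOL = 1e-8


@dataclass(frozen=True)
class RopeConfig:
    """Thresholds of the composite test.

    a, b : interval bounds for phi; accumulation = [0, a], sensitive =
        (a, b), critical = [b, 1].  Defaults (0.15, 0.85).
    decision_threshold : posterior probability required for a conclusive
        call (default 0.9).
    bf_threshold : Bayes factor regarded as decisive (default 3.2).
    """

    a: float = 0.15
    b: float = 0.85
    decision_threshold: float = 0.9
    bf_threshold: float = 3.2

    def __post_init__(self) -> None:
        if not (0.0 < self.a < self.b < 1.0):
            raise InvalidInputError("need 0 < a < b < 1")
        if not (0.0 < self.decision_threshold < 1.0):
            raise InvalidInputError("decision_threshold must be in (0, 1)")
        if self.bf_threshold <= 0:
            raise InvalidInputError("bf_threshold must be positive")


@dataclass(frozen=True)
class RopeResult:
    """Posterior ROPE probabilities and the conclusive/inconclusive call."""

    p_accumulation: float
    p_sensitive: float
    p_critical: float
    decision: str  # accumulation | sensitive | critical | inconclusive
    phi_mean: float
    phi_quantiles: dict
    config: RopeConfig
    bayes_factors: dict | None = None
    log_bayes_factors: dict | None = None

    @property
    def probabilities(self) -> dict:
        return {
            "accumulation": self.p_accumulation,
            "sensitive": self.p_sensitive,
            "critical": self.p_critical,
        }

    @property
    def conclusive(self) -> bool:
        return self.decision != "inconclusive"

    def to_dict(self) -> dict:
        return {
            "p_accumulation": self.p_accumulation,
            "p_sensitive": self.p_sensitive,
            "p_critical": self.p_critical,
            "decision": self.decision,
            "phi_mean": self.phi_mean,
            "phi_quantiles": self.phi_quantiles,
            "a": self.config.a,
            "b": self.config.b,
            "decision_threshold": self.config.decision_threshold,
            "bayes_factors": self.bayes_factors,
            "log_bayes_factors": self.log_bayes_factors,
        }


class SignCoherence(NamedTuple):
    """Posterior mass on sign-coherent coefficient vectors."""

    coherent: float
    positive: float
    negative: float


def range_statistic(w) -> float | np.ndarray:
    """max(w) - min(w), row-wise for a 2-D input.

    Lies in [0, 1] for simplex input: 0 at the accumulation point, 1 at a
    critical vertex.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim not in (1, 2) or w.shape[-1] < 2:
        raise InvalidInputError("w must be a vector or matrix with >= 2 columns")
    if not np.all(np.isfinite(w)):
        raise InvalidInputError("w must be finite")
    phi = w.max(axis=-1) - w.min(axis=-1)
    return float(phi) if w.ndim == 1 else phi


def classify_phi(phi: float, cfg: RopeConfig | None = None) -> str:
    """Assign one range value to its ROPE (boundaries go to the closed
    outer intervals — a measure-zero choice for continuous posteriors)."""
    cfg = cfg or RopeConfig()
    if not (0.0 <= phi <= 1.0):
        raise InvalidInputError("phi must lie in [0, 1]; classify simplex draws only")
    if phi <= cfg.a:
        return "accumulation"
    if phi >= cfg.b:
        return "critical"
    return "sensitive"


def _validate_simplex(values: np.ndarray) -> np.ndarray:
    if values.min() < _NEG_CLIP:
        raise InvalidInputError("weight draws must be non-negative")
    values = np.clip(values, 0.0, None)
    sums = values.sum(axis=1)
    if np.abs(sums - 1.0).max() > _SIMPLEX_TOL:
        raise InvalidInputError("weight draws must lie on the simplex (rows sum to 1)")
    return values


def rope_test(
    weight_draws,
    cfg: RopeConfig | None = None,
    prior_probabilities: dict | None = None,
) -> RopeResult:
    """Posterior probability of the three life-course models.

    Each draw's phi falls in exactly one ROPE, so the probabilities are
    exhaustive.  If prior ROPE probabilities are supplied (see
    :func:`prior_rope_probabilities`), per-model Bayes factors of the form
    [p(M|y)/p(M)] / [p(not M|y)/p(not M)] are reported alongside.
    """
    cfg = cfg or RopeConfig()
    values = _validate_simplex(_as_values(weight_draws))
    phi = range_statistic(values)
    n_acc = int((phi <= cfg.a).sum())
    n_crit = int((phi >= cfg.b).sum())
    S = phi.size
    p = {
        "accumulation": n_acc / S,
        "critical": n_crit / S,
    }
    p["sensitive"] = 1.0 - p["accumulation"] - p["critical"]
    decision = "inconclusive"
    for m in MODEL_LABELS:
        if p[m] > cfg.decision_threshold:
            decision = m
            break
    bfs = logbfs = None
    if prior_probabilities is not None:
        bfs, logbfs = {}, {}
        for m in MODEL_LABELS:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bf = bayes_factor(p[m], prior_probabilities[m])
            bfs[m] = bf
            logbfs[m] = float(np.log(bf)) if bf > 0 else -np.inf
    qs = np.quantile(phi, [0.025, 0.5, 0.975])
    return RopeResult(
        p_accumulation=p["accumulation"],
        p_sensitive=p["sensitive"],
        p_critical=p["critical"],
        decision=decision,
        phi_mean=float(phi.mean()),
        phi_quantiles={"2.5%": float(qs[0]), "50%": float(qs[1]), "97.5%": float(qs[2])},
        config=cfg,
        bayes_factors=bfs,
        log_bayes_factors=logbfs,
    )


def prior_rope_probabilities(
    T: int,
    cfg: RopeConfig | None = None,
    alpha: float = 1.0,
    prior_draw_count: int = 20000,
    seed: int = 0,
) -> dict:
    """Monte-Carlo ROPE probabilities under the Dirichlet(alpha * 1) prior.

    For T = 2 with alpha = 1 the range phi = |2 w1 - 1| is uniform on
    [0, 1], so the exact answer is (a, b - a, 1 - b).
    """
    cfg = cfg or RopeConfig()
    if T < 2:
        raise InvalidInputError("T must be >= 2")
    if alpha <= 0:
        raise InvalidInputError("alpha must be positive")
    if prior_draw_count < 1000:
        raise InvalidInputError("need at least 1000 prior draws")
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.full(T, alpha), size=prior_draw_count)
    phi = range_statistic(w)
    p_acc = float((phi <= cfg.a).mean())
    p_crit = float((phi >= cfg.b).mean())
    return {
        "accumulation": p_acc,
        "sensitive": 1.0 - p_acc - p_crit,
        "critical": p_crit,
    }


def bayes_factor(posterior_p: float, prior_p: float) -> float:
    """[posterior_p / prior_p] / [(1 - posterior_p) / (1 - prior_p)].

    The posterior-to-prior odds ratio of a model against its complement.
    """
    if not (0.0 < prior_p < 1.0):
        raise UndefinedBayesFactorError(
            "Bayes factor undefined when the prior probability is 0 or 1"
        )
    if not (0.0 <= posterior_p <= 1.0):
        raise InvalidInputError("posterior_p must lie in [0, 1]")
    if posterior_p == 1.0:
        warnings.warn("posterior probability 1: Bayes factor is +inf", RuntimeWarning)
        return float("inf")
    if posterior_p == 0.0:
        warnings.warn("posterior probability 0: Bayes factor is 0", RuntimeWarning)
        return 0.0
    return (posterior_p / prior_p) / ((1.0 - posterior_p) / (1.0 - prior_p))


def sign_coherence_probability(coef_draws) -> SignCoherence:
    """Fraction of unrestricted coefficient draws that are sign-coherent.

    A row is sign-coherent when all components are strictly positive or all
    strictly negative (rows containing zeros count as neither).  The
    all-positive and all-negative fractions are reported separately: they
    are the posterior probabilities of the two orthants whose union carries
    the common-sign assumption of the simplex parameterization.
    """
    values = _as_values(coef_draws)
    pos = float((values > 0).all(axis=1).mean())
    neg = float((values < 0).all(axis=1).mean())
    return SignCoherence(coherent=pos + neg, positive=pos, negative=neg)
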