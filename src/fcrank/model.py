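"""Bayesian inference for the reparameterized life-course regression.

The model writes the linear coefficients of T repeated exposures as
theta = delta * w, where w lives on the T-part simplex and captures the
*relative* importance of each measurement occasion while the scalar delta
is the total lifetime effect:

    y_i = alpha + delta * sum_j x_ij w_j + c_i' gamma + eps_i,
    eps_i ~ N(0, sigma)

(intercept alpha and covariates c optional).  Priors: w ~ Dirichlet(alpha_w
* 1) — uniform on the simplex by default, delta ~ Cauchy(0, 2.5), sigma ~
lognormal(1, 1), covariate coefficients Cauchy(0, 2.5), intercept
Cauchy(0, 10).  The simplex constraint is enforced by an additive
log-ratio parameterization (softmax of T-1 free logits with the matching
Jacobian), never by clipping.

Sampling uses the package's vectorized adaptive random-walk Metropolis on
the unconstrained parameters; the Gaussian likelihood is evaluated through
the sufficient statistics (A'A, A'y, y'y), so one posterior evaluation
costs O(T^2) regardless of the sample size.  Split-Rhat and bulk effective
sample size are computed per reported parameter with arviz and the fit
fails loudly when any Rhat exceeds the configured threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._sampler import run_rwm
from .exceptions import ConvergenceError, InvalidInputError, EmptyOrthantError
from .rankings import DrawMatrix, _as_values

__all__ = [
    "PriorConfig",
    "McmcConfig",
    "LifecourseDataset",
    "PosteriorDraws",
    "DeltaInterval",
    "fit",
    "delta_interval",
    "sign_then_simplex",
]

_LOG_PI = float(np.log(np.pi))


@dataclass(frozen=True)
class PriorConfig:
    """Prior hyperparameters.

    dirichlet_alpha : concentration of the symmetric Dirichlet on w;
        1 is uniform on the simplex, > 1 biases toward accumulation,
        < 1 toward a critical period.
    delta_cauchy_scale : scale of the Cauchy(0, .) prior on the lifetime
        effect (weakly informative default 2.5).
    sigma_lognormal : (location, scale) of log sigma (default (1, 1)).
    gamma_cauchy_scale : scale for covariate coefficients (default 2.5).
    intercept_cauchy_scale : scale for the intercept (default 10).
    """

    dirichlet_alpha: float = 1.0
    delta_cauchy_scale: float = 2.5
    sigma_lognormal: tuple[float, float] = (1.0, 1.0)
    gamma_cauchy_scale: float = 2.5
    intercept_cauchy_scale: float = 10.0

    def __post_init__(self) -> None:
        if min(
            self.dirichlet_alpha,
            self.delta_cauchy_scale,
            self.sigma_lognormal[1],
            self.gamma_cauchy_scale,
            self.intercept_cauchy_scale,
        ) <= 0:
            raise InvalidInputError("all prior scales must be positive")


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    ``draws_per_chain`` retained draws per chain are produced by thinning
    ``draws_per_chain * thin`` post-warmup iterations.  Defaults are
    desk-scale (4 chains x 1000 retained draws); ``full_settings`` gives a
    5 x 10000 configuration for final analyses.
    """

    chains: int = 4
    draws_per_chain: int = 1000
    warmup: int = 5000
    thin: int = 24
    seed: int = 0
    rhat_threshold: float = 1.01

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise InvalidInputError("need >= 2 chains for split-Rhat diagnostics")
        if self.chains * self.draws_per_chain < 1000:
            raise InvalidInputError("need >= 1000 total post-warmup draws")
        if self.thin < 1 or self.warmup < 0:
            raise InvalidInputError("thin >= 1 and warmup >= 0 required")

    @classmethod
    def full_settings(cls, seed: int = 0) -> "McmcConfig":
        return cls(chains=5, draws_per_chain=10000, warmup=10000, thin=24, seed=seed)


@dataclass(frozen=True)
class LifecourseDataset:
    """Outcome, n x T exposure matrix and optional covariates, no missing
    values (missing-data handling is upstream of this package)."""

    outcome: np.ndarray
    exposures: np.ndarray
    covariates: np.ndarray | None = None
    occasion_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.outcome, dtype=float)
        X = np.asarray(self.exposures, dtype=float)
        if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.size:
            raise InvalidInputError("outcome must be length-n, exposures n x T")
        if X.shape[1] < 2:
            raise InvalidInputError("need at least two measurement occasions")
        if y.size <= X.shape[1]:
            raise InvalidInputError("need more observations than occasions (n > T)")
        if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
            raise InvalidInputError("data must be finite with no missing values")
        if np.any(X.std(axis=0) == 0):
            raise InvalidInputError("constant exposure column")
        C = self.covariates
        if C is not None:
            C = np.asarray(C, dtype=float)
            if C.ndim != 2 or C.shape[0] != y.size:
                raise InvalidInputError("covariates must be n x K")
            if not np.all(np.isfinite(C)):
                raise InvalidInputError("covariates must be finite")
            if np.linalg.matrix_rank(np.column_stack([np.ones(y.size), C])) < C.shape[1] + 1:
                raise InvalidInputError("rank-deficient covariates")
        object.__setattr__(self, "outcome", y)
        object.__setattr__(self, "exposures", X)
        object.__setattr__(self, "covariates", C)
        if self.occasion_names is not None:
            names = tuple(self.occasion_names)
            if len(names) != X.shape[1]:
                raise InvalidInputError("occasion_names length must equal T")
            object.__setattr__(self, "occasion_names", names)

    @property
    def n(self) -> int:
        return self.outcome.size

    @property
    def T(self) -> int:
        return self.exposures.shape[1]

    @property
    def K(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]


@dataclass(frozen=True)
class PosteriorDraws:
    """Pooled posterior draws plus per-parameter convergence diagnostics."""

    weight_draws: DrawMatrix
    delta_draws: np.ndarray
    sigma_draws: np.ndarray
    intercept_draws: np.ndarray | None
    gamma_draws: np.ndarray | None
    diagnostics: dict  # name -> {"rhat": float, "ess": float}
    accept_rate: float

    @property
    def draw_count(self) -> int:
        return self.delta_draws.size

    @property
    def max_rhat(self) -> float:
        return max(d["rhat"] for d in self.diagnostics.values())


@dataclass(frozen=True)
class DeltaInterval:
    """Central credible interval for the lifetime effect delta."""

    mean: float
    low: float
    high: float
    level: float

    @property
    def excludes_zero(self) -> bool:
        return self.low > 0.0 or self.high < 0.0

    def __str__(self) -> str:
        return f"{self.mean:.2f} ({self.low:.2f}, {self.high:.2f})"


def _softmax_aug(Z: np.ndarray) -> np.ndarray:
    """Rows of logits (T-1) -> simplex rows (T) with last logit fixed at 0."""
    full = np.concatenate([Z, np.zeros((Z.shape[0], 1))], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


def _cauchy_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    return -np.log(scale) - _LOG_PI - np.log1p((x / scale) ** 2)


def _initial_point(data: LifecourseDataset, include_intercept: bool) -> np.ndarray:
    """Least-squares start: w from normalized exposure coefficients, delta
    from their sum, log sigma from the residual scale."""
    X, y = data.exposures, data.outcome
    cols = [X]
    if include_intercept:
        cols.append(np.ones((data.n, 1)))
    if data.covariates is not None:
        cols.append(data.covariates)
    A = np.column_stack(cols) if len(cols) > 1 else X
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    theta = coef[: data.T]
    s = theta.sum()
    if abs(s) < 1e-6:
        w0 = np.full(data.T, 1.0 / data.T)
        d0 = 0.0
    else:
        w0 = np.clip(theta / s, 1e-3, None)
        w0 /= w0.sum()
        d0 = float(s)
    resid = y - A @ coef
    parts = [np.log(w0[:-1] / w0[-1]), [d0, np.log(resid.std() + 1e-9)]]
    if include_intercept or data.covariates is not None:
        parts.append(coef[data.T :])
    return np.concatenate([np.asarray(p, dtype=float).ravel() for p in parts])


def fit(
    data: LifecourseDataset,
    priors: PriorConfig | None = None,
    mcmc: McmcConfig | None = None,
    include_intercept: bool | None = None,
    standardize: bool = False,
) -> PosteriorDraws:
    """Draw from the posterior of (w, delta, sigma[, alpha, gamma]).

    ``include_intercept`` defaults to True whenever covariates are present
    (an observational analysis) and False otherwise (the simulation-study
    model has no intercept).  ``standardize`` z-scores the exposure
    columns first — off by default, since simulated exposures are already
    standardized.  Raises :class:`ConvergenceError` when any parameter's
    split-Rhat exceeds ``mcmc.rhat_threshold``.
    """
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig()
    if include_intercept is None:
        include_intercept = data.covariates is not None
    if data.covariates is not None and not include_intercept:
        raise InvalidInputError("covariate adjustment requires an intercept")
    if standardize:
        X = data.exposures
        data = LifecourseDataset(
            outcome=data.outcome,
            exposures=(X - X.mean(axis=0)) / X.std(axis=0),
            covariates=data.covariates,
            occasion_names=data.occasion_names,
        )

    T, K, n = data.T, data.K, data.n
    n_extra = (1 if include_intercept else 0) + K
    ndim = (T - 1) + 2 + n_extra

    cols = [data.exposures]
    if include_intercept:
        cols.append(np.ones((n, 1)))
    if data.covariates is not None:
        cols.append(data.covariates)
    A = np.column_stack(cols) if len(cols) > 1 else data.exposures
    AtA = A.T @ A
    Aty = A.T @ data.outcome
    yty = float(data.outcome @ data.outcome)

    alpha_w = priors.dirichlet_alpha
    d_scale = priors.delta_cauchy_scale
    s_loc, s_scale = priors.sigma_lognormal
    i_scale = priors.intercept_cauchy_scale
    g_scale = priors.gamma_cauchy_scale

    def log_posterior(P: np.ndarray) -> np.ndarray:
        Z = P[:, : T - 1]
        delta = P[:, T - 1]
        logsig = P[:, T]
        w = _softmax_aug(Z)
        u = delta[:, None] * w  # coefficients on the exposures
        if n_extra:
            u = np.concatenate([u, P[:, T + 1 :]], axis=1)
        quad = np.einsum("ct,tu,cu->c", u, AtA, u)
        sse = yty - 2.0 * (u @ Aty) + quad
        ll = -n * logsig - 0.5 * sse * np.exp(-2.0 * logsig)
        # Dirichlet(alpha_w) density plus the ALR Jacobian prod(w_i)
        lp = alpha_w * np.log(w + 1e-300).sum(axis=1)
        lp += _cauchy_logpdf(delta, d_scale)
        lp += -0.5 * ((logsig - s_loc) / s_scale) ** 2
        j = T + 1
        if include_intercept:
            lp += _cauchy_logpdf(P[:, j], i_scale)
            j += 1
        if K:
            lp += _cauchy_logpdf(P[:, j:], g_scale).sum(axis=1)
        return ll + lp

    rng = np.random.default_rng([int(mcmc.seed) % 2**31, 0x5EED])
    run = run_rwm(
        log_posterior,
        _initial_point(data, include_intercept),
        chains=mcmc.chains,
        warmup=mcmc.warmup,
        iterations=mcmc.draws_per_chain * mcmc.thin,
        thin=mcmc.thin,
        rng=rng,
    )
    draws = run.draws  # (chains, keep, ndim)
    C, S_per, _ = draws.shape
    w = _softmax_aug(draws[..., : T - 1].reshape(-1, T - 1)).reshape(C, S_per, T)
    delta = draws[..., T - 1]
    sigma = np.exp(draws[..., T])

    names = data.occasion_names or tuple(f"w{j + 1}" for j in range(T))
    tracked = {names[j]: w[..., j] for j in range(T)}
    tracked["delta"] = delta
    tracked["sigma"] = sigma
    j = T + 1
    if include_intercept:
        tracked["intercept"] = draws[..., j]
        j += 1
    for k in range(K):
        tracked[f"gamma{k + 1}"] = draws[..., j + k]

    diagnostics = _diagnose(tracked)
    offending = {
        name: d["rhat"]
        for name, d in diagnostics.items()
        if d["rhat"] > mcmc.rhat_threshold
    }
    result = PosteriorDraws(
        weight_draws=DrawMatrix(w.reshape(-1, T)),
        delta_draws=delta.ravel(),
        sigma_draws=sigma.ravel(),
        intercept_draws=tracked["intercept"].ravel() if include_intercept else None,
        gamma_draws=(
            np.column_stack([tracked[f"gamma{k + 1}"].ravel() for k in range(K)])
            if K
            else None
        ),
        diagnostics=diagnostics,
        accept_rate=run.accept_rate,
    )
    if offending:
        raise ConvergenceError(
            "MCMC did not converge; split-Rhat above "
            f"{mcmc.rhat_threshold}: {offending}",
            offending=offending,
        )
    return result


def _diagnose(tracked: dict) -> dict:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset({k: v for k, v in tracked.items()})
        rhat = az.rhat(ds)
        ess = az.ess(ds)
    return {
        k: {"rhat": float(rhat[k].values), "ess": float(ess[k].values)}
        for k in tracked
    }


def delta_interval(draws, level: float = 0.95) -> DeltaInterval:
    """Equal-tailed credible interval for delta; the gate before any model
    comparison is whether it excludes zero."""
    if not (0.0 < level < 1.0):
        raise InvalidInputError("level must be in (0, 1)")
    if isinstance(draws, PosteriorDraws):
        d = draws.delta_draws
    else:
        d = np.asarray(draws, dtype=float).ravel()
    tail = (1.0 - level) / 2.0
    low, high = np.quantile(d, [tail, 1.0 - tail])
    return DeltaInterval(mean=float(d.mean()), low=float(low), high=float(high), level=level)


def sign_then_simplex(coef_draws, orthant: str = "both") -> np.ndarray:
    """Map sign-coherent coefficient draws back to the simplex.

    Keeps the rows lying in the requested orthant ("positive", "negative"
    or "both") and divides each by its component sum; a negative-orthant
    row has a negative sum, so the image is on the simplex either way.
    """
    values = _as_values(coef_draws)
    if orthant not in ("positive", "negative", "both"):
        raise InvalidInputError("orthant must be 'positive', 'negative' or 'both'")
    pos = (values > 0).all(axis=1)
    neg = (values < 0).all(axis=1)
    keep = {"positive": pos, "negative": neg, "both": pos | neg}[orthant]
    if not keep.any():
        raise EmptyOrthantError(f"no draws in the {orthant} orthant")
    sub = values[keep]
    return sub / sub.sum(axis=1, keepdims=True)
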