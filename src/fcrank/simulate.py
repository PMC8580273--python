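"""Synthetic life-course cohorts and the operating-characteristics study.

Cohorts follow the generating model

    y_i = delta* . sum_j x_ij w*_j + eps_i,     eps_i ~ N(0, 1)

with T repeated Gaussian exposures of unit variance and AR(1) correlation
0.7 between adjacent occasions (0.49 between next-nearest, i.e. lag-k
correlation 0.7^k — the unique stationary structure matching the stated
three-occasion pattern).  Four ground-truth weight families define the
study grid:

    accumulation        w* = (1/T, ..., 1/T)
    linear_sensitive    w*  prop. to (1, 2, ..., T)
    nonlinear_sensitive w* = (0.75, 0.2, 0.05, 0, ..., 0)
    critical            w* = (0, ..., 0, 1)

The full study crosses the four families with T in {3, 5, 7}, n in
{700, 1500, 3000} and delta* in {0, 1, 2}: 108 cells, 72 of them non-null.
Each cell runs the three-stage decision — (1) does the 95% interval for
delta exclude zero, (2) if so, the ROPE test on the range of w, (3) if the
sensitive model is chosen, the finest credible rank scored by q = r/r* and
checked for consistency with the true ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConvergenceError, InvalidInputError
from .model import (
    DeltaInterval,
    LifecourseDataset,
    McmcConfig,
    PosteriorDraws,
    PriorConfig,
    delta_interval,
    fit,
)
from .rankings import (
    FcrResult,
    PartialRanking,
    finest_credible_rank,
    full_rank_label,
    is_consistent,
    q_metric,
)
from .rope import RopeConfig, RopeResult, prior_rope_probabilities, rope_test

__all__ = [
    "FAMILIES",
    "GroundTruth",
    "CellResult",
    "StudyResult",
    "make_exposures",
    "make_outcome",
    "simulate_dataset",
    "run_cell",
    "default_grid",
    "run_study",
]

FAMILIES = ("accumulation", "linear_sensitive", "nonlinear_sensitive", "critical")

_ALIASES = {
    "accumulation": "accumulation",
    "linear": "linear_sensitive",
    "linear_sensitive": "linear_sensitive",
    "nonlinear": "nonlinear_sensitive",
    "nonlinear_sensitive": "nonlinear_sensitive",
    "critical": "critical",
}

#: family -> the conclusive ROPE decision it should produce
FAMILY_TO_MODEL = {
    "accumulation": "accumulation",
    "linear_sensitive": "sensitive",
    "nonlinear_sensitive": "sensitive",
    "critical": "critical",
}

#: alternative (a, b) thresholds re-tested for decision stability
SENSITIVITY_THRESHOLDS = ((0.1, 0.9), (0.2, 0.8))

_EXPOSURE_RHO = 0.7


@dataclass(frozen=True)
class GroundTruth:
    """One simulation regime: family label, true weights and effect size."""

    family: str
    w_star: np.ndarray
    delta_star: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "w_star", np.asarray(self.w_star, dtype=float))
        if self.family not in FAMILIES:
            raise InvalidInputError(f"unknown family {self.family!r}")

    @classmethod
    def make(cls, family: str, T: int, delta_star: float) -> "GroundTruth":
        family = _ALIASES.get(family)
        if family is None:
            raise InvalidInputError(f"unknown family; choose one of {sorted(_ALIASES)}")
        if T < 2:
            raise InvalidInputError("T must be >= 2")
        if family == "accumulation":
            w = np.full(T, 1.0 / T)
        elif family == "linear_sensitive":
            t = np.arange(1, T + 1, dtype=float)
            w = t / t.sum()
        elif family == "nonlinear_sensitive":
            if T < 3:
                raise InvalidInputError("nonlinear_sensitive needs T >= 3")
            w = np.concatenate([[0.75, 0.2, 0.05], np.zeros(T - 3)])
        else:  # critical
            w = np.zeros(T)
            w[-1] = 1.0
        return cls(family=family, w_star=w, delta_star=float(delta_star))

    @property
    def T(self) -> int:
        return self.w_star.size

    @property
    def true_ranking(self) -> PartialRanking:
        """Tie-merged full ranking of w* (e.g. nonlinear T=5 -> '4,5|3|2|1')."""
        return full_rank_label(self.w_star)

    @property
    def r_star(self) -> int:
        return self.true_ranking.r

    @property
    def true_model(self) -> str:
        return FAMILY_TO_MODEL[self.family]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def make_exposures(n: int, T: int, seed=0) -> np.ndarray:
    """n i.i.d. rows from N(0, Sigma) with Sigma_jk = 0.7^|j-k| (unit
    variances; 0.7 adjacent, 0.49 next-nearest correlations)."""
    if n < 2 or T < 2:
        raise InvalidInputError("need n >= 2 and T >= 2")
    lags = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
    cov = _EXPOSURE_RHO ** lags
    L = np.linalg.cholesky(cov)
    return _rng(seed).standard_normal((n, T)) @ L.T


def make_outcome(exposures: np.ndarray, truth: GroundTruth, seed=0) -> np.ndarray:
    """y = delta* X w* + N(0, 1) noise."""
    X = np.asarray(exposures, dtype=float)
    if X.ndim != 2 or X.shape[1] != truth.T:
        raise InvalidInputError("exposures must be n x T with T matching the truth")
    return truth.delta_star * (X @ truth.w_star) + _rng(seed).standard_normal(X.shape[0])


def simulate_dataset(truth: GroundTruth, n: int, seed=0) -> LifecourseDataset:
    """One synthetic cohort under the given regime."""
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_x, s_y = root.spawn(2)
    X = make_exposures(n, truth.T, np.random.default_rng(s_x))
    y = make_outcome(X, truth, np.random.default_rng(s_y))
    return LifecourseDataset(outcome=y, exposures=X)


@lru_cache(maxsize=64)
def _cached_prior_probs(T: int, a: float, b: float, alpha: float) -> dict:
    return prior_rope_probabilities(
        T, RopeConfig(a=a, b=b), alpha=alpha, prior_draw_count=50000, seed=20210510
    )


@dataclass
class CellResult:
    """Everything recorded for one simulation cell."""

    family: str
    T: int
    n: int
    delta_star: float
    seed: int
    delta: DeltaInterval | None = None
    gate_passed: bool | None = None
    rope: RopeResult | None = None
    decision: str | None = None  # accumulation|sensitive|critical|inconclusive
    fcr: FcrResult | None = None
    q: float | None = None
    consistent: bool | None = None
    alt_decisions: dict | None = None
    max_rhat: float | None = None
    error: str | None = None

    @property
    def cell_id(self) -> str:
        d = f"{self.delta_star:g}"
        return f"{self.family}_T{self.T}_n{self.n}_d{d}"

    @property
    def conclusive_correct(self) -> bool:
        return self.decision == FAMILY_TO_MODEL[self.family]

    def to_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "family": self.family,
            "T": self.T,
            "n": self.n,
            "delta_star": self.delta_star,
            "seed": self.seed,
            "delta": None
            if self.delta is None
            else {
                "mean": self.delta.mean,
                "low": self.delta.low,
                "high": self.delta.high,
                "level": self.delta.level,
            },
            "gate_passed": self.gate_passed,
            "rope": None if self.rope is None else self.rope.to_dict(),
            "decision": self.decision,
            "fcr": None if self.fcr is None else self.fcr.to_dict(),
            "q": self.q,
            "consistent": self.consistent,
            "alt_decisions": self.alt_decisions,
            "max_rhat": self.max_rhat,
            "error": self.error,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellResult":
        delta = None
        if d.get("delta") is not None:
            delta = DeltaInterval(
                mean=d["delta"]["mean"],
                low=d["delta"]["low"],
                high=d["delta"]["high"],
                level=d["delta"]["level"],
            )
        rope = None
        if d.get("rope") is not None:
            r = d["rope"]
            rope = RopeResult(
                p_accumulation=r["p_accumulation"],
                p_sensitive=r["p_sensitive"],
                p_critical=r["p_critical"],
                decision=r["decision"],
                phi_mean=r["phi_mean"],
                phi_quantiles=r["phi_quantiles"],
                config=RopeConfig(
                    a=r["a"], b=r["b"], decision_threshold=r["decision_threshold"]
                ),
                bayes_factors=r.get("bayes_factors"),
                log_bayes_factors=r.get("log_bayes_factors"),
            )
        fcr = None if d.get("fcr") is None else FcrResult.from_dict(d["fcr"])
        return cls(
            family=d["family"],
            T=d["T"],
            n=d["n"],
            delta_star=d["delta_star"],
            seed=d["seed"],
            delta=delta,
            gate_passed=d.get("gate_passed"),
            rope=rope,
            decision=d.get("decision"),
            fcr=fcr,
            q=d.get("q"),
            consistent=d.get("consistent"),
            alt_decisions=d.get("alt_decisions"),
            max_rhat=d.get("max_rhat"),
            error=d.get("error"),
        )


def run_cell(
    truth: GroundTruth,
    n: int,
    priors: PriorConfig | None = None,
    mcmc: McmcConfig | None = None,
    rope_cfg: RopeConfig | None = None,
    beta: float = 0.9,
    seed: int = 0,
    sensitivity: bool = True,
    compute_bf: bool = True,
) -> CellResult:
    """Three-stage decision on one simulated cohort.

    Non-convergence triggers one retry with doubled warmup and thinning;
    a second failure is recorded on the cell (``error``), not raised.
    """
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig()
    rope_cfg = rope_cfg or RopeConfig()
    out = CellResult(
        family=truth.family, T=truth.T, n=n, delta_star=truth.delta_star, seed=int(seed)
    )
    root = np.random.SeedSequence(int(seed))
    data_seed, fit_seed = root.spawn(2)
    data = simulate_dataset(truth, n, seed=data_seed)
    fit_seed_int = int(fit_seed.generate_state(1)[0] % 2**31)

    draws: PosteriorDraws | None = None
    try:
        draws = fit(data, priors, replace(mcmc, seed=fit_seed_int))
    except ConvergenceError:
        retry = replace(
            mcmc,
            seed=(fit_seed_int + 1) % 2**31,
            warmup=mcmc.warmup * 2,
            thin=mcmc.thin * 2,
        )
        try:
            draws = fit(data, priors, retry)
        except ConvergenceError as exc:
            out.error = f"non-convergence after retry: {exc}"
            out.max_rhat = max(exc.offending.values()) if exc.offending else None
            return out
    out.max_rhat = draws.max_rhat

    out.delta = delta_interval(draws, level=0.95)
    out.gate_passed = out.delta.excludes_zero
    if not out.gate_passed:
        return out

    prior_probs = (
        _cached_prior_probs(truth.T, rope_cfg.a, rope_cfg.b, priors.dirichlet_alpha)
        if compute_bf
        else None
    )
    out.rope = rope_test(draws.weight_draws, rope_cfg, prior_probabilities=prior_probs)
    out.decision = out.rope.decision

    if sensitivity:
        out.alt_decisions = {}
        for a_alt, b_alt in SENSITIVITY_THRESHOLDS:
            alt = rope_test(
                draws.weight_draws,
                RopeConfig(a=a_alt, b=b_alt, decision_threshold=rope_cfg.decision_threshold),
            )
            out.alt_decisions[f"a={a_alt},b={b_alt}"] = alt.decision

    if out.decision == "sensitive":
        out.fcr = finest_credible_rank(draws.weight_draws, beta=beta)
        if truth.r_star >= 1:
            out.q = q_metric(out.fcr.fcr, truth.true_ranking)
        out.consistent = is_consistent(out.fcr.fcr, truth.w_star)
    return out


def default_grid(
    Ts: Sequence[int] = (3, 5, 7),
    ns: Sequence[int] = (700, 1500, 3000),
    deltas: Sequence[float] = (0.0, 1.0, 2.0),
    families: Sequence[str] = FAMILIES,
) -> list[tuple[str, int, int, float]]:
    """(family, T, n, delta*) tuples; the default crossing has 108 cells,
    72 of them with delta* != 0."""
    return [
        (f, T, n, d) for f in families for T in Ts for n in ns for d in deltas
    ]


@dataclass
class StudyResult:
    """Aggregate view of a grid of cells."""

    cells: list[CellResult]
    master_seed: int

    # -- accounting over the non-null cells ---------------------------------

    @property
    def nonnull_cells(self) -> list[CellResult]:
        return [c for c in self.cells if c.delta_star != 0]

    @property
    def null_cells(self) -> list[CellResult]:
        return [c for c in self.cells if c.delta_star == 0]

    def confusion(self) -> pd.DataFrame:
        """True family x inferred model counts over non-null cells; 'u'
        collects inconclusive decisions, failed gates and failed fits."""
        short = {"accumulation": "a", "sensitive": "s", "critical": "c"}
        table = pd.DataFrame(
            0, index=list(FAMILIES), columns=["a", "s", "c", "u"], dtype=int
        )
        for c in self.nonnull_cells:
            col = short.get(c.decision, "u")
            table.loc[c.family, col] += 1
        return table

    @property
    def conclusive_correct_count(self) -> int:
        return sum(c.conclusive_correct for c in self.nonnull_cells)

    @property
    def inconclusive_count(self) -> int:
        return sum(not c.conclusive_correct and not _misclassified(c) for c in self.nonnull_cells)

    @property
    def misclassified_count(self) -> int:
        return sum(_misclassified(c) for c in self.nonnull_cells)

    def q_by_n(self) -> pd.Series:
        """Mean q per sample size over sensitive-truth cells that reached
        the ranking stage (decision == sensitive)."""
        rows = [
            (c.n, c.q)
            for c in self.nonnull_cells
            if c.decision == "sensitive" and c.q is not None
        ]
        if not rows:
            return pd.Series(dtype=float, name="q")
        df = pd.DataFrame(rows, columns=["n", "q"])
        return df.groupby("n")["q"].mean().rename("q")

    @property
    def consistency_violations(self) -> int:
        return sum(c.consistent is False for c in self.cells)

    @property
    def sensitivity_changes(self) -> int:
        """Cells whose conclusive decision flips to a *different conclusive
        model* under the alternative (a, b) thresholds."""
        changes = 0
        for c in self.cells:
            if c.decision in (None, "inconclusive") or not c.alt_decisions:
                continue
            for alt in c.alt_decisions.values():
                if alt != "inconclusive" and alt != c.decision:
                    changes += 1
                    break
        return changes

    def delta_gate_coverage(self) -> tuple[int, int]:
        """(cells whose 95% interval contains 0, total) over null cells."""
        null = [c for c in self.null_cells if c.delta is not None]
        covered = sum(not c.delta.excludes_zero for c in null)
        return covered, len(null)

    def summary(self) -> str:
        lines = [
            f"cells: {len(self.cells)} ({len(self.nonnull_cells)} non-null)",
            f"conclusive and correct: {self.conclusive_correct_count}/{len(self.nonnull_cells)}",
            f"inconclusive: {self.inconclusive_count}",
            f"misclassified: {self.misclassified_count}",
            f"consistency violations: {self.consistency_violations}",
        ]
        q = self.q_by_n()
        for n, val in q.items():
            lines.append(f"mean q at n={n}: {val:.3f}")
        cov, tot = self.delta_gate_coverage()
        if tot:
            lines.append(f"delta 95% interval covers 0 in {cov}/{tot} null cells")
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        (out / "cells").mkdir(parents=True, exist_ok=True)
        for c in self.cells:
            (out / "cells" / f"{c.cell_id}.json").write_text(
                json.dumps(c.to_dict(), indent=1)
            )
        self.confusion().to_csv(out / "confusion.csv")
        self.q_by_n().to_csv(out / "q_table.csv")
        (out / "summary.txt").write_text(self.summary() + "\n")


def _misclassified(c: CellResult) -> bool:
    return c.decision in ("accumulation", "sensitive", "critical") and not c.conclusive_correct


def run_study(
    grid: Iterable[tuple[str, int, int, float]] | None = None,
    priors: PriorConfig | None = None,
    mcmc: McmcConfig | None = None,
    rope_cfg: RopeConfig | None = None,
    beta: float = 0.9,
    master_seed: int = 0,
    out_dir=None,
    progress: bool = False,
) -> StudyResult:
    """Run every cell of the grid with deterministic per-cell seeds.

    With ``out_dir`` set, finished cells are written as they complete and
    an interrupted run resumes from the existing cell files.
    """
    grid = list(grid) if grid is not None else default_grid()
    seeds = np.random.SeedSequence(int(master_seed)).generate_state(len(grid)) % 2**31
    cells: list[CellResult] = []
    cell_dir = None
    if out_dir is not None:
        cell_dir = Path(out_dir) / "cells"
        cell_dir.mkdir(parents=True, exist_ok=True)
    for (family, T, n, d), cell_seed in zip(grid, seeds):
        truth = GroundTruth.make(family, T, d)
        probe = CellResult(family=truth.family, T=T, n=n, delta_star=float(d), seed=int(cell_seed))
        if cell_dir is not None and (cell_dir / f"{probe.cell_id}.json").exists():
            cells.append(
                CellResult.from_dict(
                    json.loads((cell_dir / f"{probe.cell_id}.json").read_text())
                )
            )
            continue
        cell = run_cell(
            truth,
            n,
            priors=priors,
            mcmc=mcmc,
            rope_cfg=rope_cfg,
            beta=beta,
            seed=int(cell_seed),
        )
        cells.append(cell)
        if cell_dir is not None:
            (cell_dir / f"{cell.cell_id}.json").write_text(
                json.dumps(cell.to_dict(), indent=1)
            )
        if progress:
            print(
                f"[{len(cells)}/{len(grid)}] {cell.cell_id}: "
                f"decision={cell.decision} gate={cell.gate_passed}",
                flush=True,
            )
    result = StudyResult(cells=cells, master_seed=int(master_seed))
    if out_dir is not None:
        result.save(out_dir)
    return result
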