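"""Partial rankings of measurement occasions and the finest credible rank.

A *partial ranking* orders measurement occasions 1..T by the magnitude of
their weights, block-wise: ``"3|1|2"`` says occasion 3 has the smallest
weight and occasion 2 the largest, while ``"1,3|2"`` says only that
occasion 2 dominates both others, leaving 1 vs 3 undetermined.  Blocks are
separated by ``"|"`` (a *distinction*); occasions inside a block are
incomparable.  The leftmost block is always the least important.

Given posterior draws of a weight (or coefficient) vector, the posterior
probability of a ranking is estimated by the fraction of draws satisfying
its inequalities.  The *finest credible rank* (FCR) at level beta is found
by starting from the maximum a posteriori full ranking and greedily merging
adjacent blocks — each merge picks the coarsening with the highest
posterior probability — stopping at the first ranking whose probability
reaches beta.  The result is the most informative ordering statement that
can be made with beta credibility.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import InvalidInputError, UndefinedMetricError

__all__ = [
    "PartialRanking",
    "DrawMatrix",
    "FcrResult",
    "full_rank_label",
    "satisfies",
    "ranking_probability",
    "coarsenings",
    "finest_credible_rank",
    "q_metric",
    "is_consistent",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PartialRanking:
    """Ordered blocks of 1-based occasion indices, least important first.

    ``blocks`` must partition {1..T}.  The canonical string form joins
    blocks with "|" and sorts indices inside a block ascending, so
    "3,1|2" canonicalizes to "1,3|2".
    """

    blocks: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        canon = tuple(tuple(sorted(int(i) for i in b)) for b in self.blocks)
        object.__setattr__(self, "blocks", canon)
        if not canon or any(len(b) == 0 for b in canon):
            raise InvalidInputError("blocks must be non-empty")
        flat = sorted(i for b in canon for i in b)
        if flat != list(range(1, len(flat) + 1)):
            raise InvalidInputError(
                f"blocks must partition 1..T, got {self.to_string()!r}"
            )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_string(cls, s: str) -> "PartialRanking":
        """Parse e.g. ``"1,3|2"``; within-block order is irrelevant."""
        try:
            blocks = tuple(
                tuple(int(tok) for tok in part.split(","))
                for part in s.strip().split("|")
            )
        except ValueError as exc:
            raise InvalidInputError(f"cannot parse ranking string {s!r}") from exc
        return cls(blocks)

    @classmethod
    def vacuous(cls, T: int) -> "PartialRanking":
        """The single-block ranking that asserts nothing."""
        return cls((tuple(range(1, T + 1)),))

    # -- structure ----------------------------------------------------------

    @property
    def T(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def r(self) -> int:
        """Number of distinctions ('|' separators)."""
        return len(self.blocks) - 1

    @property
    def is_vacuous(self) -> bool:
        return len(self.blocks) == 1

    @property
    def is_full(self) -> bool:
        return all(len(b) == 1 for b in self.blocks)

    def to_string(self) -> str:
        return "|".join(",".join(str(i) for i in b) for b in self.blocks)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


@dataclass(frozen=True)
class DrawMatrix:
    """S x T matrix of posterior draws of a weight or coefficient vector.

    Rows need not lie on the simplex: the FCR applies to unrestricted
    coefficient vectors as well.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise InvalidInputError("draws must be a 2-D array (S x T)")
        if v.shape[0] < 1 or v.shape[1] < 2:
            raise InvalidInputError("draws need S >= 1 rows and T >= 2 columns")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("draws must be finite")
        object.__setattr__(self, "values", v)

    @property
    def draw_count(self) -> int:
        return self.values.shape[0]

    @property
    def occasion_count(self) -> int:
        return self.values.shape[1]


def _as_values(draws) -> np.ndarray:
    if isinstance(draws, DrawMatrix):
        return draws.values
    return DrawMatrix(np.asarray(draws, dtype=float)).values


@dataclass(frozen=True)
class FcrResult:
    """Greedy coarsening chain from the MAP full ranking to the vacuous one.

    ``fcr`` is the first chain element whose posterior probability reaches
    ``beta``; the result is *conclusive* unless that element is vacuous.
    """

    chain: tuple[PartialRanking, ...]
    probabilities: tuple[float, ...]
    beta: float
    fcr: PartialRanking
    conclusive: bool

    @property
    def fcr_probability(self) -> float:
        return self.probabilities[self.chain.index(self.fcr)]

    def to_dict(self) -> dict:
        return {
            "chain": [
                {"ranking": p.to_string(), "probability": float(pr)}
                for p, pr in zip(self.chain, self.probabilities)
            ],
            "beta": self.beta,
            "fcr": self.fcr.to_string(),
            "conclusive": self.conclusive,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FcrResult":
        chain = tuple(PartialRanking.from_string(e["ranking"]) for e in d["chain"])
        probs = tuple(float(e["probability"]) for e in d["chain"])
        return cls(
            chain=chain,
            probabilities=probs,
            beta=float(d["beta"]),
            fcr=PartialRanking.from_string(d["fcr"]),
            conclusive=bool(d["conclusive"]),
        )

    def format_report(self) -> str:
        """Nested sub-model table: one row per granularity, e.g.

        ``3|4|2|1|5\t0.197`` ... ending with the vacuous ranking at 1.000.
        """
        lines = ["Ranking\tProbability"]
        for p, pr in zip(self.chain, self.probabilities):
            lines.append(f"{p.to_string()}\t{pr:.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def full_rank_label(w: Sequence[float]) -> PartialRanking:
    """Label a point with its full ranking, least important occasion first.

    (0.2, 0.7, 0.1) -> "3|1|2".  Exact ties are merged into one block, so
    the result may be partial for vectors with repeated values (e.g. the
    zero-padded ground truths of the simulation study).
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise InvalidInputError("w must be a 1-D vector of length >= 2")
    if not np.all(np.isfinite(w)):
        raise InvalidInputError("w must be finite")
    order = np.argsort(w, kind="stable")
    blocks: list[list[int]] = [[int(order[0]) + 1]]
    for prev, cur in zip(order[:-1], order[1:]):
        if w[cur] == w[prev]:
            blocks[-1].append(int(cur) + 1)
        else:
            blocks.append([int(cur) + 1])
    return PartialRanking(tuple(tuple(b) for b in blocks))


def _satisfies_rows(values: np.ndarray, p: PartialRanking) -> np.ndarray:
    """Boolean mask of rows satisfying all of p's block inequalities."""
    ok = np.ones(values.shape[0], dtype=bool)
    for lo, hi in zip(p.blocks[:-1], p.blocks[1:]):
        lo_idx = [i - 1 for i in lo]
        hi_idx = [i - 1 for i in hi]
        ok &= values[:, lo_idx].max(axis=1) < values[:, hi_idx].min(axis=1)
    return ok


def satisfies(w: Sequence[float], p: PartialRanking) -> bool:
    """True iff every occasion in an earlier block has a strictly smaller
    value than every occasion in any later block (cross-block ties fail)."""
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or w.size != p.T:
        raise InvalidInputError(f"w must have length {p.T}, got shape {w.shape}")
    return bool(_satisfies_rows(w[None, :], p)[0])


def ranking_probability(draws, p: PartialRanking) -> float:
    """Fraction of draws satisfying the ranking (1.0 for the vacuous one)."""
    values = _as_values(draws)
    if values.shape[1] != p.T:
        raise InvalidInputError(
            f"draws have {values.shape[1]} occasions but ranking has {p.T}"
        )
    if p.is_vacuous:
        return 1.0
    return float(_satisfies_rows(values, p).mean())


def coarsenings(p: PartialRanking) -> list[PartialRanking]:
    """All rankings obtained by merging exactly one adjacent block pair.

    Returned in merge-position order (leftmost merge first); empty for the
    vacuous ranking.
    """
    out = []
    for k in range(p.n_blocks - 1):
        merged = p.blocks[:k] + (p.blocks[k] + p.blocks[k + 1],) + p.blocks[k + 2 :]
        out.append(PartialRanking(merged))
    return out


def _map_full_label(values: np.ndarray) -> PartialRanking:
    """Most frequent full-ranking label among draws.

    Ties within a draw are merged by :func:`full_rank_label`; ties between
    equally frequent labels break by canonical-string lexicographic order.
    """
    S, T = values.shape
    sorted_vals = np.sort(values, axis=1)
    has_tie = (np.diff(sorted_vals, axis=1) == 0).any(axis=1)
    counts: Counter[str] = Counter()
    if not has_tie.all():
        order = np.argsort(values[~has_tie], axis=1, kind="stable") + 1
        labels, freq = np.unique(order, axis=0, return_counts=True)
        for lab, f in zip(labels, freq):
            counts["|".join(str(i) for i in lab)] += int(f)
    for row in values[has_tie]:
        counts[full_rank_label(row).to_string()] += 1
    best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    return PartialRanking.from_string(best)


def finest_credible_rank(draws, beta: float = 0.9) -> FcrResult:
    """Greedy coarsening chain and the beta-level finest credible rank.

    The chain starts at the maximum a posteriori full ranking among the
    draws' labels and at each step keeps the most probable coarsening
    (ties merge the adjacent pair with the smallest leading index).  The
    FCR is the first chain element with probability >= beta; the result is
    inconclusive iff that element is the vacuous ranking.
    """
    values = _as_values(draws)
    if not 0.0 < beta < 1.0:
        raise InvalidInputError("beta must lie strictly between 0 and 1")
    current = _map_full_label(values)
    chain = [current]
    probs = [ranking_probability(values, current)]
    while not current.is_vacuous:
        cands = coarsenings(current)
        cand_probs = [ranking_probability(values, c) for c in cands]
        best = max(cand_probs)
        # tie-break: smallest leading index of the merged pair
        tied = [c for c, pr in zip(cands, cand_probs) if pr == best]
        current = min(
            tied,
            key=lambda c: min(
                min(b) for b in c.blocks if b not in current.blocks
            ),
        )
        chain.append(current)
        probs.append(best)
    fcr = next(p for p, pr in zip(chain, probs) if pr >= beta)
    return FcrResult(
        chain=tuple(chain),
        probabilities=tuple(float(p) for p in probs),
        beta=float(beta),
        fcr=fcr,
        conclusive=not fcr.is_vacuous,
    )


def q_metric(fcr: PartialRanking, truth: PartialRanking) -> float:
    """Fraction q = r/r* of the truth's distinctions retained by the FCR.

    Undefined when the truth makes no distinctions (r* = 0, the
    accumulation ground truth).
    """
    if truth.r == 0:
        raise UndefinedMetricError("q is undefined when the true ranking has r* = 0")
    return fcr.r / truth.r


def is_consistent(fcr: PartialRanking, truth_w: Sequence[float]) -> bool:
    """True iff the FCR never asserts w_i < w_j when in truth w_i >= w_j.

    Separating components that are exactly tied in the truth counts as
    inconsistent (the assertion of a strict order is unwarranted).
    """
    w = np.asarray(truth_w, dtype=float)
    if w.ndim != 1 or w.size != fcr.T:
        raise InvalidInputError(f"truth_w must have length {fcr.T}")
    for a in range(fcr.n_blocks):
        for b in range(a + 1, fcr.n_blocks):
            lo = [i - 1 for i in fcr.blocks[a]]
            hi = [i - 1 for i in fcr.blocks[b]]
            if w[lo].max() >= w[hi].min():
                return False
    return True
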