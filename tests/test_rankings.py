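"""Partial-ranking algebra, posterior ranking probabilities and the FCR."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fcrank as fc
from fcrank.exceptions import InvalidInputError, UndefinedMetricError
from fcrank.rankings import _map_full_label

R = fc.PartialRanking.from_string


# ---------------------------------------------------------------------------
# PartialRanking structure
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "raw, canonical",
    [("3,1|2", "1,3|2"), ("1,3|2", "1,3|2"), ("2|3,1", "2|1,3"), ("1,2,3", "1,2,3")],
)
def test_canonical_string_sorts_within_blocks(raw, canonical):
    assert R(raw).to_string() == canonical


@pytest.mark.parametrize("bad", ["1|1|2", "1|3", "0|1", "|", "1,a|2"])
def test_non_partitions_rejected(bad):
    with pytest.raises(InvalidInputError):
        R(bad)


def test_distinction_count_and_flags():
    assert R("1|2|3").r == 2 and R("1|2|3").is_full
    assert R("1,2,3").r == 0 and R("1,2,3").is_vacuous
    assert fc.PartialRanking.vacuous(4) == R("1,2,3,4")


# ---------------------------------------------------------------------------
# full_rank_label / satisfies
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "w, label",
    [
        ((0.2, 0.7, 0.1), "3|1|2"),
        ((0.1, 0.2, 0.7), "1|2|3"),
        ((0, 0, 1), "1,2|3"),  # tie-merge for padded ground truths
        ((0.75, 0.2, 0.05, 0, 0), "4,5|3|2|1"),
    ],
)
def test_full_rank_label(w, label):
    assert fc.full_rank_label(w).to_string() == label


def test_full_rank_label_rejects_non_finite():
    with pytest.raises(InvalidInputError):
        fc.full_rank_label([0.1, np.nan, 0.2])


@pytest.mark.parametrize(
    "w, p, expected",
    [
        ((0.1, 0.05, 0.85), "1,2|3", True),
        ((0.5, 0.1, 0.4), "1,2|3", False),
        ((0.2, 0.7, 0.1), "3|1|2", True),
        ((0.5, 0.5, 0.7), "1|2|3", False),  # cross-block tie fails strictly
    ],
)
def test_satisfies(w, p, expected):
    assert fc.satisfies(w, R(p)) is expected


def test_satisfies_length_mismatch():
    with pytest.raises(InvalidInputError):
        fc.satisfies([0.5, 0.5], R("1|2|3"))


# ---------------------------------------------------------------------------
# ranking_probability
# ---------------------------------------------------------------------------


def test_ranking_probability_counts_satisfying_rows():
    rows = np.array(
        [[0.1, 0.2, 0.7], [0.2, 0.1, 0.7], [0.5, 0.1, 0.4], [0.25, 0.05, 0.7]]
    )
    assert fc.ranking_probability(rows, R("1,2|3")) == 0.75
    assert fc.ranking_probability(rows, R("1,2,3")) == 1.0


def test_single_point_posterior_has_unit_probability():
    rows = np.tile([0.2, 0.7, 0.1], (50, 1))
    assert fc.ranking_probability(rows, R("3|1|2")) == 1.0


def _brute_force_probability(values, p):
    """Sum of empirical full-ranking frequencies over all T! labels
    consistent with the partial ranking (counted in integers so the result
    is bit-identical to a direct frequency)."""
    S, T = values.shape
    count = 0
    for perm in itertools.permutations(range(1, T + 1)):
        full = fc.PartialRanking(tuple((i,) for i in perm))
        if _full_consistent_with(full, p):
            count += round(fc.ranking_probability(values, full) * S)
    return count / S


def _full_consistent_with(full, partial):
    """A full ranking refines a partial ranking iff each partial block is a
    contiguous run of the full ranking's singletons in order."""
    order = [b[0] for b in full.blocks]
    pos = 0
    for block in partial.blocks:
        chunk = set(order[pos : pos + len(block)])
        if chunk != set(block):
            return False
        pos += len(block)
    return True


def _random_partial(rng, T):
    cuts = sorted(rng.choice(range(1, T), size=rng.integers(0, T), replace=False))
    perm = list(rng.permutation(T) + 1)
    blocks, prev = [], 0
    for c in [*cuts, T]:
        blocks.append(tuple(perm[prev:c]))
        prev = c
    return fc.PartialRanking(tuple(blocks))


@pytest.mark.parametrize("T", [3, 4, 5])
def test_oracle_equivalence_with_full_ranking_enumeration(T):
    """ranking_probability must equal the brute-force sum of empirical
    frequencies of all consistent full rankings."""
    rng = np.random.default_rng(T)
    for _ in range(20):
        values = rng.dirichlet(np.ones(T), size=200)
        p = _random_partial(rng, T)
        assert fc.ranking_probability(values, p) == pytest.approx(
            _brute_force_probability(values, p), abs=1e-12
        )


def test_full_ranking_frequencies_partition_unity():
    rng = np.random.default_rng(0)
    values = rng.dirichlet(np.ones(4), size=300)
    total = sum(
        fc.ranking_probability(values, fc.PartialRanking(tuple((i,) for i in perm)))
        for perm in itertools.permutations(range(1, 5))
    )
    assert total == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# coarsenings
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "p, expected",
    [
        ("3|1|2", {"1,3|2", "3|1,2"}),
        ("1,2|3,4|5", {"1,2,3,4|5", "1,2|3,4,5"}),
        ("1,2,3", set()),
    ],
)
def test_coarsenings(p, expected):
    assert {c.to_string() for c in fc.coarsenings(R(p))} == expected


def test_coarsening_probability_monotone():
    rng = np.random.default_rng(5)
    values = rng.dirichlet(np.ones(5), size=400)
    for _ in range(25):
        p = _random_partial(rng, 5)
        base = fc.ranking_probability(values, p)
        for c in fc.coarsenings(p):
            assert fc.ranking_probability(values, c) >= base


# ---------------------------------------------------------------------------
# finest_credible_rank
# ---------------------------------------------------------------------------


def test_fcr_degenerate_posterior():
    draws = np.tile([0.1, 0.2, 0.7], (1000, 1))
    res = fc.finest_credible_rank(draws, beta=0.9)
    assert res.fcr.to_string() == "1|2|3"
    assert res.fcr_probability == 1.0
    assert res.conclusive


def test_fcr_two_atom_posterior():
    draws = np.vstack(
        [np.tile([0.1, 0.2, 0.7], (600, 1)), np.tile([0.2, 0.1, 0.7], (400, 1))]
    )
    res = fc.finest_credible_rank(draws, beta=0.9)
    assert [p.to_string() for p in res.chain] == ["1|2|3", "1,2|3", "1,2,3"]
    assert res.probabilities == (0.6, 1.0, 1.0)
    assert res.fcr.to_string() == "1,2|3"


def test_fcr_chain_shape_and_monotonicity():
    rng = np.random.default_rng(9)
    for _ in range(30):
        T = int(rng.integers(3, 7))
        values = rng.dirichlet(np.ones(T), size=300)
        res = fc.finest_credible_rank(values, beta=0.9)
        assert len(res.chain) == T  # tie-free continuous draws
        assert res.chain[0].is_full and res.chain[-1].is_vacuous
        assert all(
            b >= a for a, b in zip(res.probabilities[:-1], res.probabilities[1:])
        )
        assert res.probabilities[-1] == 1.0
        # each element coarsens its predecessor by one merge
        for prev, nxt in zip(res.chain[:-1], res.chain[1:]):
            assert nxt in fc.coarsenings(prev)
        assert res.conclusive == (not res.fcr.is_vacuous)


def test_fcr_rejects_empty_or_bad_beta():
    with pytest.raises(InvalidInputError):
        fc.finest_credible_rank(np.empty((0, 3)))
    with pytest.raises(InvalidInputError):
        fc.finest_credible_rank(np.ones((5, 3)) / 3, beta=1.0)


def test_map_label_tie_break_is_lexicographic():
    draws = np.vstack(
        [np.tile([0.1, 0.2, 0.7], (50, 1)), np.tile([0.7, 0.2, 0.1], (50, 1))]
    )
    assert _map_full_label(draws).to_string() == "1|2|3"  # before "3|2|1"


# ---------------------------------------------------------------------------
# q metric and consistency
# ---------------------------------------------------------------------------


def test_q_metric_values():
    assert fc.q_metric(R("1,2|3,4|5,6|7"), R("1|2|3|4|5|6|7")) == 0.5
    assert fc.q_metric(R("1|2|3"), R("1|2|3")) == 1.0
    assert fc.q_metric(R("1,2,3"), R("1|2|3")) == 0.0


def test_q_metric_undefined_for_vacuous_truth():
    with pytest.raises(UndefinedMetricError):
        fc.q_metric(R("1|2|3"), R("1,2,3"))


@pytest.mark.parametrize(
    "fcr, truth_w, expected",
    [
        ("2|1,3", (0.2, 0.3, 0.5), False),  # asserts w2<w1 but truth w1<w2
        ("1,2,3", (0.9, 0.05, 0.05), True),  # vacuous asserts nothing
        ("1,2|3", (0.1, 0.2, 0.7), True),
        ("1|2|3", (0.0, 0.0, 1.0), False),  # splits truly tied components
    ],
)
def test_is_consistent(fcr, truth_w, expected):
    assert fc.is_consistent(R(fcr), truth_w) is expected


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------


@given(
    st.lists(
        st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=2, max_size=7
    )
)
@settings(max_examples=100, deadline=None)
def test_label_of_point_is_always_satisfied_by_it(w):
    """Any point satisfies its own tie-merged label, and the label's block
    count matches the number of distinct values."""
    label = fc.full_rank_label(w)
    assert label.n_blocks == len(set(w))
    assert fc.satisfies(w, label) or label.n_blocks < len(w)  # ties fail strictness
    if len(set(w)) == len(w):
        assert fc.satisfies(w, label)


@given(st.integers(min_value=2, max_value=7), st.integers(min_value=0, max_value=2**32 - 1))
@settings(max_examples=50, deadline=None)
def test_fcr_result_roundtrips_through_json(T, seed):
    rng = np.random.default_rng(seed)
    values = rng.dirichlet(np.ones(T), size=100)
    res = fc.finest_credible_rank(values, beta=0.9)
    assert fc.FcrResult.from_dict(res.to_dict()) == res
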