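"""Range statistic, ROPE probabilities, Bayes factors, sign coherence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fcrank as fc
from fcrank.exceptions import InvalidInputError, UndefinedBayesFactorError


# ---------------------------------------------------------------------------
# range statistic and classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "w, phi",
    [((1 / 3, 1 / 3, 1 / 3), 0.0), ((0, 0, 1), 1.0), ((0.2, 0.7, 0.1), 0.6)],
)
def test_range_statistic(w, phi):
    assert fc.range_statistic(w) == pytest.approx(phi)


def test_range_statistic_rowwise_and_validation():
    rows = np.array([[0.1, 0.9], [0.5, 0.5]])
    assert fc.range_statistic(rows) == pytest.approx([0.8, 0.0])
    with pytest.raises(InvalidInputError):
        fc.range_statistic([0.5, np.inf])


@pytest.mark.parametrize(
    "phi, label",
    [
        (0.10, "accumulation"),
        (0.90, "critical"),
        (0.50, "sensitive"),
        (0.15, "accumulation"),  # boundaries go to the closed outer intervals
        (0.85, "critical"),
    ],
)
def test_classify_phi(phi, label):
    assert fc.classify_phi(phi, fc.RopeConfig()) == label


def test_classify_phi_rejects_out_of_range():
    with pytest.raises(InvalidInputError):
        fc.classify_phi(1.2, fc.RopeConfig())


def test_rope_config_validation():
    with pytest.raises(InvalidInputError):
        fc.RopeConfig(a=0.9, b=0.1)


# ---------------------------------------------------------------------------
# rope_test
# ---------------------------------------------------------------------------


def _simplex_rows_with_phi(phis):
    """Three-part simplex rows (m, m, m + phi) with prescribed range phi."""
    rows = [[(1 - phi) / 3, (1 - phi) / 3, (1 - phi) / 3 + phi] for phi in phis]
    return np.array(rows)


def test_rope_test_counts_equally_represented_phis():
    rows = _simplex_rows_with_phi([0.1, 0.5, 0.9] * 10)
    res = fc.rope_test(rows, fc.RopeConfig())
    assert res.p_accumulation == pytest.approx(1 / 3)
    assert res.p_sensitive == pytest.approx(1 / 3)
    assert res.p_critical == pytest.approx(1 / 3)
    assert res.decision == "inconclusive"


def test_rope_test_degenerate_accumulation():
    rows = np.tile([1 / 3, 1 / 3, 1 / 3], (100, 1))
    res = fc.rope_test(rows)
    assert (res.p_accumulation, res.p_sensitive, res.p_critical) == (1.0, 0.0, 0.0)
    assert res.decision == "accumulation"


def test_rope_decision_sensitive_above_threshold():
    """A posterior like the observational example's (0.0004, 0.9973, 0.0023)
    split must yield a sensitive decision."""
    phis = [0.1] * 4 + [0.5] * 9973 + [0.9] * 23
    res = fc.rope_test(_simplex_rows_with_phi(phis))
    assert res.decision == "sensitive"
    assert res.p_sensitive == pytest.approx(0.9973)


def test_rope_test_rejects_off_simplex_rows():
    with pytest.raises(InvalidInputError):
        fc.rope_test(np.array([[0.5, 0.6, 0.2]]))
    with pytest.raises(InvalidInputError):
        fc.rope_test(np.array([[-0.2, 0.6, 0.6]]))


@given(st.integers(min_value=0, max_value=2**32 - 1), st.integers(min_value=2, max_value=7))
@settings(max_examples=50, deadline=None)
def test_rope_probabilities_exhaustive(seed, T):
    rng = np.random.default_rng(seed)
    rows = rng.dirichlet(np.ones(T), size=200)
    res = fc.rope_test(rows)
    assert res.p_accumulation + res.p_sensitive + res.p_critical == pytest.approx(
        1.0, abs=1e-12
    )
    assert min(res.p_accumulation, res.p_sensitive, res.p_critical) >= 0.0


# ---------------------------------------------------------------------------
# prior ROPE probabilities
# ---------------------------------------------------------------------------


def test_prior_rope_closed_form_two_occasions():
    """For T=2 under Dirichlet(1,1), phi = |2 w1 - 1| is uniform on [0,1],
    so the prior ROPE probabilities are (a, b-a, 1-b)."""
    p = fc.prior_rope_probabilities(2, fc.RopeConfig(), prior_draw_count=200000, seed=3)
    assert p["accumulation"] == pytest.approx(0.15, abs=0.01)
    assert p["sensitive"] == pytest.approx(0.70, abs=0.01)
    assert p["critical"] == pytest.approx(0.15, abs=0.01)


def test_prior_concentrates_on_accumulation_for_large_alpha():
    p = fc.prior_rope_probabilities(3, fc.RopeConfig(), alpha=500.0,
                                    prior_draw_count=5000, seed=0)
    assert p["accumulation"] > 0.99


def test_prior_probabilities_sum_to_one():
    p = fc.prior_rope_probabilities(5, fc.RopeConfig(), prior_draw_count=2000, seed=1)
    assert sum(p.values()) == pytest.approx(1.0)


def test_degenerate_thresholds_make_sensitive_certain():
    """With (a, b) -> (0, 1) the simplex interior is all 'sensitive': a
    uniform prior gives the sensitive model probability ~1."""
    cfg = fc.RopeConfig(a=1e-9, b=1 - 1e-9)
    p = fc.prior_rope_probabilities(3, cfg, prior_draw_count=5000, seed=2)
    assert p["sensitive"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Bayes factor
# ---------------------------------------------------------------------------


def test_bayes_factor_values():
    assert fc.bayes_factor(0.5, 0.5) == 1.0
    assert fc.bayes_factor(0.9, 0.5) == pytest.approx(9.0)


def test_bayes_factor_boundaries():
    with pytest.raises(UndefinedBayesFactorError):
        fc.bayes_factor(0.5, 1.0)
    with pytest.warns(RuntimeWarning):
        assert fc.bayes_factor(1.0, 0.5) == np.inf
    with pytest.warns(RuntimeWarning):
        assert fc.bayes_factor(0.0, 0.5) == 0.0


def test_rope_test_reports_bayes_factors_with_priors():
    rows = np.tile([1 / 3, 1 / 3, 1 / 3], (100, 1))
    priors = {"accumulation": 0.2, "sensitive": 0.6, "critical": 0.2}
    res = fc.rope_test(rows, prior_probabilities=priors)
    assert res.bayes_factors["accumulation"] == np.inf
    assert res.bayes_factors["sensitive"] == 0.0
    assert res.log_bayes_factors["critical"] == -np.inf


# ---------------------------------------------------------------------------
# sign coherence
# ---------------------------------------------------------------------------


def test_sign_coherence_all_positive():
    rows = np.tile([1.0, 2.0, 3.0], (10, 1))
    sc = fc.sign_coherence_probability(rows)
    assert sc == (1.0, 1.0, 0.0)


def test_sign_coherence_mixed_rows():
    rows = np.vstack([np.tile([1.0, 1.0], (5, 1)), np.tile([-1.0, 1.0], (5, 1))])
    sc = fc.sign_coherence_probability(rows)
    assert sc.coherent == 0.5 and sc.positive == 0.5 and sc.negative == 0.0


def test_sign_coherence_zero_counts_as_neither():
    rows = np.array([[0.0, 1.0], [-1.0, -2.0]])
    sc = fc.sign_coherence_probability(rows)
    assert sc.coherent == 0.5 and sc.negative == 0.5
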