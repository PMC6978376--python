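import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from riskaudit import (
    ClassSummaries,
    RiskModel,
    ScoreDistributions,
    estimate_score_pdfs,
    fit_class_summaries,
    posterior_given_score,
    relative_likelihood,
    sample_class_features,
    unit_schema,
)
from riskaudit.generative import BIN_EDGES, N_BINS


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_registry_scale_prevalences(schema_2d):
    """Event fractions match the printed registry rates: 7.15% and 0.511%."""
    rng = np.random.default_rng(0)
    for n, n_pos, expected, digits in ((43063, 3078, 7.15, 2), (16618, 85, 0.511, 3)):
        y = np.zeros(n, dtype=int)
        y[:n_pos] = 1
        X = rng.random((n, 2))
        s = fit_class_summaries(pd.DataFrame(X, columns=["x1", "x2"]), y, schema_2d)
        assert round(100 * s.prevalence, digits) == expected


def test_hand_computed_mean_and_covariance(schema_2d):
    """Class {(0,0),(2,2)} on identity ranges: mean (1,1), cov [[2,2],[2,2]]."""
    X = np.array([[0.0, 0.0], [2.0, 2.0], [0.1, 0.9], [0.5, 0.4]])
    y = np.array([1, 1, 0, 0])
    ridge = 1e-6
    s = fit_class_summaries(X, y, schema_2d, ridge=ridge)
    np.testing.assert_allclose(s.mean_pos, [1.0, 1.0])
    np.testing.assert_allclose(
        s.cov_pos - ridge * np.eye(2), [[2.0, 2.0], [2.0, 2.0]], atol=1e-12
    )


def test_identical_rows_give_ridge_covariance(schema_2d):
    X = np.array([[0.3, 0.3]] * 5 + [[0.1, 0.9], [0.5, 0.4]])
    y = np.array([1] * 5 + [0, 0])
    s = fit_class_summaries(X, y, schema_2d, ridge=1e-4)
    np.testing.assert_allclose(s.cov_pos, 1e-4 * np.eye(2), atol=1e-15)


def test_fit_error_cases(schema_2d, small_table):
    X, y = small_table
    with pytest.raises(ValueError, match="degenerate labels"):
        fit_class_summaries(X, np.ones_like(y), schema_2d)
    with pytest.raises(ValueError, match="invalid feature value"):
        bad = X.copy()
        bad.iloc[0, 0] = np.inf
        fit_class_summaries(bad, y, schema_2d)
    with pytest.raises(ValueError, match="singular"):
        # one feature duplicated -> rank-deficient covariance
        dup = X.copy()
        dup["x2"] = dup["x1"]
        fit_class_summaries(dup, y, schema_2d, ridge=0.0)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def make_mixed_summaries():
    schema = unit_schema(1, 1)
    # binary latent mean 0.3 with the Bernoulli-moment variance
    return ClassSummaries(
        schema=schema,
        mean_pos=np.array([0.5, 0.3]),
        mean_neg=np.array([0.4, 0.2]),
        cov_pos=np.diag([0.01, 0.3 * 0.7]),
        cov_neg=np.diag([0.01, 0.2 * 0.8]),
        prevalence=0.3,
        n_pos=100,
        n_neg=100,
    )


def test_sampling_is_deterministic_under_seed():
    s = make_mixed_summaries()
    a = sample_class_features(s, "positive", 5, seed=11)
    b = sample_class_features(s, "positive", 5, seed=11)
    pd.testing.assert_frame_equal(a, b)


def test_binary_threshold_frequency_matches_gaussian_tail_mass():
    """Latent mean 0.3, sd sqrt(0.21): P(draw > 0.5) ≈ 0.331."""
    s = make_mixed_summaries()
    X = sample_class_features(s, "positive", 100_000, seed=3)
    analytic = stats.norm.sf(0.5, 0.3, np.sqrt(0.21))
    assert abs(X["b1"].mean() - analytic) < 0.02
    assert set(np.unique(X["b1"])) <= {0.0, 1.0}


def test_continuous_sample_mean_near_fitted_mean():
    s = make_mixed_summaries()
    X = sample_class_features(s, "positive", 100_000, seed=4)
    se = 0.1 / np.sqrt(100_000)
    assert abs(X["x1"].mean() - 0.5) < 3 * se
    assert X["x1"].min() >= 0.0 and X["x1"].max() <= 1.0


def test_sampling_error_cases():
    s = make_mixed_summaries()
    with pytest.raises(ValueError, match="unknown class"):
        sample_class_features(s, "middle", 5, seed=0)
    bad = make_mixed_summaries()
    bad.cov_pos = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
    with pytest.raises(ValueError, match="positive definite"):
        sample_class_features(bad, "positive", 5, seed=0)


# ---------------------------------------------------------------------------
# score PDFs
# ---------------------------------------------------------------------------


def test_histogram_matches_analytic_normal_bin_masses(one_dim_summaries):
    """1-D identity model: bin masses equal normal CDF differences (TV < 0.01)."""
    model = RiskModel(score_fn=lambda X: X[:, 0], label="identity")
    dist = estimate_score_pdfs(one_dim_summaries, model, batch=1_000_000, seed=0)
    for mass, mu in ((dist.mass_pos, 0.7), (dist.mass_neg, 0.3)):
        cdf = stats.norm.cdf(BIN_EDGES, mu, 0.1)
        analytic = np.diff(cdf)
        # clipping sends the tail mass outside [0,1] into the terminal bins
        analytic[0] += cdf[0]
        analytic[-1] += 1.0 - cdf[-1]
        tv = 0.5 * np.abs(mass - analytic).sum()
        assert tv < 0.01
        assert abs(mass.sum() - 1.0) < 1e-9


def test_identical_class_summaries_give_unit_beta(one_dim_summaries):
    sym = ClassSummaries(
        schema=one_dim_summaries.schema,
        mean_pos=np.array([0.5]),
        mean_neg=np.array([0.5]),
        cov_pos=np.array([[0.01]]),
        cov_neg=np.array([[0.01]]),
        prevalence=0.5,
        n_pos=10,
        n_neg=10,
    )
    model = RiskModel(score_fn=lambda X: X[:, 0], label="identity")
    dist = estimate_score_pdfs(sym, model, batch=200_000, seed=1)
    occupied = (dist.mass_pos > 5e-4) & (dist.mass_neg > 5e-4)
    beta = dist.mass_pos[occupied] / dist.mass_neg[occupied]
    assert np.all((beta > 0.8) & (beta < 1.25))


def test_batch_too_small_rejected(one_dim_summaries):
    model = RiskModel(score_fn=lambda X: X[:, 0])
    with pytest.raises(ValueError, match="batch too small"):
        estimate_score_pdfs(one_dim_summaries, model, batch=500)


def test_unconverged_result_is_flagged_and_logged(one_dim_summaries, caplog):
    model = RiskModel(score_fn=lambda X: X[:, 0])
    with caplog.at_level(logging.WARNING, logger="riskaudit.generative"):
        dist = estimate_score_pdfs(
            one_dim_summaries, model, batch=2000, seed=0,
            alpha_ks=0.999999, max_iter=2,
        )
    assert dist.converged is False
    assert any("did not converge" in r.message for r in caplog.records)


def test_score_one_maps_into_last_bin():
    assert ScoreDistributions.bin_index(1.0) == N_BINS - 1
    assert ScoreDistributions.bin_index(0.0) == 0
    assert ScoreDistributions.bin_index(0.9995) == N_BINS - 1


# ---------------------------------------------------------------------------
# relative likelihood and posterior
# ---------------------------------------------------------------------------


def manual_dist():
    mass_pos = np.full(N_BINS, 1.0)
    mass_neg = np.full(N_BINS, 1.0)
    mass_pos[500] = 4.0  # bin [0.5, 0.501)
    mass_neg[500] = 2.0
    return ScoreDistributions(
        mass_pos=mass_pos / mass_pos.sum(),
        mass_neg=mass_neg / mass_neg.sum(),
        n_samples_pos=1000,
        n_samples_neg=1000,
        converged=True,
    )


def test_relative_likelihood_is_the_bin_mass_ratio():
    dist = manual_dist()
    expected = (4.0 / 1003.0) / (2.0 / 1001.0)
    assert relative_likelihood(dist, 0.5005) == pytest.approx(expected)
    with pytest.raises(ValueError, match="outside"):
        relative_likelihood(dist, 1.2)


def test_unconverged_distributions_can_be_rejected():
    dist = manual_dist()
    dist.converged = False
    with pytest.raises(ValueError, match="converge"):
        relative_likelihood(dist, 0.5, allow_unconverged=False)


@pytest.mark.parametrize(
    "beta,pi,expected",
    [
        (1.0, 0.0715, 0.0715),
        (3.0, 0.25, 0.5),
        (0.0, 0.3, 0.0),
        (1e14, 0.3, 1.0),
    ],
)
def test_posterior_worked_examples(beta, pi, expected):
    assert posterior_given_score(beta, pi) == pytest.approx(expected, abs=1e-9)


@given(
    beta=st.floats(0.001, 1000.0),
    pi=st.floats(0.001, 0.999),
)
@settings(deadline=None, max_examples=200)
def test_posterior_normalization_and_range(beta, pi):
    """P(y=1|ŷ) + P(y=0|ŷ) = 1 with the negative posterior at (1/β, 1−π)."""
    p1 = posterior_given_score(beta, pi)
    p0 = posterior_given_score(1.0 / beta, 1.0 - pi)
    assert 0.0 <= p1 <= 1.0
    assert p1 + p0 == pytest.approx(1.0, abs=1e-9)


@given(
    pi=st.floats(0.01, 0.99),
    b1=st.floats(0.01, 100.0),
    b2=st.floats(0.01, 100.0),
)
@settings(deadline=None, max_examples=200)
def test_posterior_strictly_monotone_in_beta(pi, b1, b2):
    if np.isclose(b1, b2, rtol=1e-9):
        return
    lo, hi = sorted((b1, b2))
    assert posterior_given_score(lo, pi) < posterior_given_score(hi, pi)
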