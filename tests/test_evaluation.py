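import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from riskaudit import (
    auc,
    brier_score,
    calibration_curve,
    compare_subgroups,
    hosmer_lemeshow,
    normalized_brier,
    stratified_bootstrap,
    subgroup_split,
)
from riskaudit.evaluation import _paired_ttest


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "y,p,expected",
    [([0, 1], [0.0, 1.0], 0.0), ([0, 1], [0.5, 0.5], 0.25), ([1], [0.0], 1.0)],
)
def test_brier_examples(y, p, expected):
    assert brier_score(y, p) == pytest.approx(expected)


def test_normalized_brier_examples():
    y = [0, 0, 1, 1]
    assert normalized_brier(y, [0.5, 0.5, 0.5, 0.5]) == pytest.approx(1.0)
    assert normalized_brier(y, [0.0, 0.0, 1.0, 1.0]) == pytest.approx(0.0)
    # B = 0.01, B_null = 0.25 -> ratio 0.04
    assert normalized_brier(y, [0.1, 0.1, 0.9, 0.9]) == pytest.approx(0.04)
    with pytest.raises(ValueError, match="null model degenerate"):
        normalized_brier([1, 1], [0.5, 0.5])


def test_auc_examples():
    assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
    assert auc([0, 0, 1, 1], [0.3, 0.3, 0.3, 0.3]) == 0.5
    # enumerated: pairs (0.1,0.35)+, (0.1,0.8)+, (0.4,0.35)-, (0.4,0.8)+ -> 3/4
    assert auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)
    with pytest.raises(ValueError, match="both classes"):
        auc([1, 1], [0.2, 0.8])


@given(
    y=st.lists(st.integers(0, 1), min_size=4, max_size=30),
    scale=st.floats(0.1, 5.0),
    shift=st.floats(-2.0, 2.0),
)
@settings(deadline=None, max_examples=100)
def test_auc_invariant_under_increasing_transform(y, scale, shift):
    if len(set(y)) < 2:
        return
    rng = np.random.default_rng(0)
    p = rng.random(len(y))
    # logistic of an affine map is strictly increasing
    q = 1.0 / (1.0 + np.exp(-(scale * p + shift)))
    assert auc(y, p) == pytest.approx(auc(y, q), abs=1e-12)


# ---------------------------------------------------------------------------
# calibration and Hosmer–Lemeshow
# ---------------------------------------------------------------------------


def test_calibration_hand_binned_example():
    table = calibration_curve([0, 1], [0.07, 0.12])
    np.testing.assert_allclose(table.bin_centers, [0.05, 0.15])
    np.testing.assert_allclose(table.mean_prediction, [0.07, 0.12])
    np.testing.assert_allclose(table.observed_fraction, [0.0, 1.0])
    assert table.bin_counts.tolist() == [1, 1]


def test_calibration_empty_and_pooling():
    assert len(calibration_curve([], []).bin_centers) == 0
    rng = np.random.default_rng(5)
    p = rng.uniform(0.0, 1.0, 5000)
    y = (rng.random(5000) < p).astype(int)
    table = calibration_curve(y, p)
    # pooled observed fractions reproduce the overall event rate
    pooled = np.average(table.observed_fraction, weights=table.bin_counts)
    assert pooled == pytest.approx(y.mean(), abs=1e-12)
    # calibrated cohort: per-bin deviation within 3 binomial SEs
    se = np.sqrt(table.mean_prediction * (1 - table.mean_prediction) / table.bin_counts)
    assert np.all(
        np.abs(table.observed_fraction - table.mean_prediction) < 3 * se + 1e-9
    )


def test_hosmer_lemeshow_zero_statistic_on_exact_fit():
    # five groups of 10, constant prediction per group, observed = expected
    y, p = [], []
    for rate in (0.1, 0.2, 0.3, 0.4, 0.5):
        n_pos = int(round(10 * rate))
        y += [1] * n_pos + [0] * (10 - n_pos)
        p += [rate] * 10
    stat, pval = hosmer_lemeshow(y, p, n_groups=5)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert pval == pytest.approx(1.0)


def test_hosmer_lemeshow_pvalues_uniform_for_fitted_model():
    """Classic setting: logistic model fitted on the same data, df = g − 2."""
    from sklearn.linear_model import LogisticRegression

    rng = np.random.default_rng(7)
    pvals = []
    for _ in range(200):
        x = rng.standard_normal(1000)
        p_true = 1.0 / (1.0 + np.exp(-(-1.0 + 1.2 * x)))
        y = (rng.random(1000) < p_true).astype(int)
        lr = LogisticRegression(C=1e6).fit(x[:, None], y)
        pvals.append(hosmer_lemeshow(y, lr.predict_proba(x[:, None])[:, 1])[1])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_hosmer_lemeshow_detects_gross_miscalibration():
    rng = np.random.default_rng(8)
    rejections = 0
    for _ in range(40):
        p = rng.uniform(0.05, 0.6, 5000)
        y = (rng.random(5000) < p).astype(int)
        shifted = np.clip(p + 0.3, 0.0, 1.0)
        rejections += hosmer_lemeshow(y, shifted)[1] < 0.05
    assert rejections / 40 > 0.95


# ---------------------------------------------------------------------------
# bootstrap plan and subgroup split
# ---------------------------------------------------------------------------


def test_stratified_replicates_resample_classes_separately():
    y = np.array([1] * 7 + [0] * 93)
    plan = stratified_bootstrap(y, n_boot=10, fraction=0.2, seed=1)
    for idx in plan.replicate_indices:
        assert idx.size == 20
        assert y[idx].sum() == 1  # round(0.2*7)=1 positive draw
    # determinism
    plan2 = stratified_bootstrap(y, n_boot=10, fraction=0.2, seed=1)
    for a, b in zip(plan.replicate_indices, plan2.replicate_indices):
        np.testing.assert_array_equal(a, b)


def test_unstratified_full_fraction_is_classic_bootstrap():
    y = np.array([0, 1] * 25)
    plan = stratified_bootstrap(y, n_boot=3, fraction=1.0, stratified=False, seed=0)
    assert all(idx.size == 50 for idx in plan.replicate_indices)


def test_vanishing_stratum_is_an_error():
    y = np.array([1] + [0] * 99)
    with pytest.raises(ValueError, match="stratum vanishes"):
        stratified_bootstrap(y, fraction=0.2)


def test_subgroup_split_examples_and_ties():
    np.testing.assert_array_equal(
        subgroup_split([0.1, 0.2, 0.3, 0.4], 50.0), [False, False, True, True]
    )
    rng = np.random.default_rng(9)
    u = rng.permutation(1000) / 1000.0
    assert subgroup_split(u, 1.0).sum() == 10  # exactly the 10 largest
    # ties at the threshold are all included
    tied = np.array([0.0, 1.0, 1.0, 1.0, 0.5, 0.2, 0.1, 0.3])
    mask = subgroup_split(tied, 25.0)
    assert mask[tied == 1.0].all()
    with pytest.raises(ValueError, match="degenerate split"):
        subgroup_split([0.5, 0.5, 0.5], 50.0)


# ---------------------------------------------------------------------------
# subgroup comparison
# ---------------------------------------------------------------------------


def test_paired_ttest_degenerate_cases():
    v = np.array([0.4, 0.5, 0.6])
    assert _paired_ttest(v, v.copy()) == 1.0  # identical vectors
    a, b = v, v + 0.2
    # swapping arms negates the mean difference but keeps the p-value
    assert _paired_ttest(a, b) == _paired_ttest(b, a)


def test_compare_subgroups_flags_overestimating_tail():
    """Miscalibrated high scores: flagged arm worse in ≥95/100 replicates."""
    rng = np.random.default_rng(12)
    n = 8000
    true_p = rng.uniform(0.01, 0.6, n)
    y = (rng.random(n) < true_p).astype(int)
    y_hat = np.where(true_p > 0.3, np.clip(3 * true_p, 0, 1), true_p)
    # unreliability surrogate: distance between reported and true risk
    u = np.abs(y_hat - true_p)
    plan = stratified_bootstrap(y, n_boot=100, fraction=0.2, seed=3)
    comp = compare_subgroups(y_hat, y, u, plan, top_percent=10.0)
    worse = np.sum(comp.brier_sub > comp.brier_comp)
    assert worse >= 95
    assert comp.p_brier < 1e-10


def test_rare_outcome_three_bootstrap_configuration_runs(caplog):
    """The very-low-event-rate protocol variant (3 replicates) completes."""
    import logging

    rng = np.random.default_rng(14)
    n = 4000
    p = rng.uniform(0.05, 0.5, n)
    y = (rng.random(n) < p).astype(int)
    u = rng.random(n)
    plan = stratified_bootstrap(y, n_boot=3, fraction=0.2, seed=5)
    with caplog.at_level(logging.WARNING, logger="riskaudit.evaluation"):
        comp = compare_subgroups(p, y, u, plan, top_percent=50.0)
    assert comp.n_boot == 3
    assert np.isfinite(comp.brier_sub).all()
    assert any("fragile" in r.message for r in caplog.records)


def test_compare_subgroups_single_class_arm_error():
    rng = np.random.default_rng(13)
    n = 200
    y = np.zeros(n, dtype=int)
    y[:40] = 1
    y_hat = rng.uniform(0.1, 0.9, n)
    u = np.zeros(n)
    u[:2] = 1.0  # subgroup = two positive patients -> always single-class
    plan = stratified_bootstrap(y, n_boot=20, fraction=0.5, seed=4)
    with pytest.raises(ValueError, match="missing"):
        compare_subgroups(y_hat, y, u, plan, top_percent=1.0)
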