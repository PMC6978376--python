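"""Statistical evaluation protocol for audited subgroups.

Implements the subgroup evaluation used to validate the unreliability
score: accuracy via the Brier score normalized by a null model that
predicts the subgroup event rate for everyone, discrimination via the AUC
(Mann–Whitney concordance), calibration via fixed-center binned curves and
the Hosmer–Lemeshow test, uncertainty via a stratified 20%-of-pool
bootstrap, and paired two-sided t-tests between a flagged subgroup and its
complement across bootstrap replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

#: standard 10-bin calibration centers 0.05, 0.15, ..., 0.95
DEFAULT_BIN_CENTERS = np.arange(0.05, 1.0, 0.1)
#: 3-bin variant for very-low-prevalence models whose scores top out near 0.03
LOW_RATE_BIN_CENTERS = np.array([0.005, 0.015, 0.025])


def _check_pair(outcomes, predictions) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(outcomes, dtype=float).reshape(-1)
    p = np.asarray(predictions, dtype=float).reshape(-1)
    if y.shape != p.shape:
        raise ValueError("outcomes and predictions differ in length")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("outcomes must be binary 0/1")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("predictions must lie in [0, 1]")
    return y, p


def brier_score(outcomes, predictions) -> float:
    """Mean squared error between outcomes and predicted probabilities."""
    y, p = _check_pair(outcomes, predictions)
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.mean((y - p) ** 2))


def normalized_brier(outcomes, predictions) -> float:
    """Brier score scaled by the null model predicting the event rate.

    B_null is the Brier score of the constant prediction ȳ (the event rate
    of the evaluated subgroup), so the ratio is comparable across subgroups
    with different prevalences.  Values above 1 mean the model does worse
    than knowing only the subgroup event rate.
    """
    y, p = _check_pair(outcomes, predictions)
    ybar = y.mean() if y.size else np.nan
    if y.size == 0 or ybar in (0.0, 1.0):
        raise ValueError("null model degenerate: subgroup needs both classes")
    b_null = float(np.mean((y - ybar) ** 2))
    return float(np.mean((y - p) ** 2)) / b_null


def auc(outcomes, predictions) -> float:
    """Mann–Whitney concordance probability (ties count 1/2)."""
    y, p = _check_pair(outcomes, predictions)
    if y.size == 0 or y.min() == y.max():
        raise ValueError("AUC undefined: both classes must be present")
    return float(roc_auc_score(y, p))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationTable:
    """Per-bin mean prediction vs observed event fraction.

    Only occupied bins are stored; an absent bin is absent, not zero.
    """

    bin_centers: np.ndarray
    mean_prediction: np.ndarray
    observed_fraction: np.ndarray
    bin_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "mean_prediction": self.mean_prediction,
                "observed_fraction": self.observed_fraction,
                "count": self.bin_counts,
            }
        )


def calibration_curve(
    outcomes,
    predictions,
    bin_centers: np.ndarray | Sequence[float] = DEFAULT_BIN_CENTERS,
) -> CalibrationTable:
    """Bin predictions into fixed equal-width bins; report event rate per bin.

    Predictions falling outside the binning range are assigned to the
    nearest terminal bin (logged).
    """
    y, p = _check_pair(outcomes, predictions)
    centers = np.asarray(bin_centers, dtype=float)
    if centers.size < 2 or np.any(np.diff(centers) <= 0):
        raise ValueError("bin centers must be increasing with at least 2 bins")
    widths = np.diff(centers)
    if not np.allclose(widths, widths[0]):
        raise ValueError("bin centers must be equally spaced")
    half = widths[0] / 2.0
    edges = np.concatenate([[centers[0] - half], centers + half])
    if y.size == 0:
        empty = np.array([])
        return CalibrationTable(empty, empty, empty, np.array([], dtype=int))
    n_outside = int(np.sum((p < edges[0]) | (p > edges[-1])))
    if n_outside:
        logger.info(
            "%d predictions outside the calibration range; assigned to terminal bins",
            n_outside,
        )
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, centers.size - 1)
    occupied, mean_p, frac, counts = [], [], [], []
    for k in range(centers.size):
        in_bin = idx == k
        if not in_bin.any():
            continue
        occupied.append(centers[k])
        mean_p.append(p[in_bin].mean())
        frac.append(y[in_bin].mean())
        counts.append(int(in_bin.sum()))
    return CalibrationTable(
        np.array(occupied), np.array(mean_p), np.array(frac), np.array(counts)
    )


def hosmer_lemeshow(
    outcomes,
    predictions,
    n_groups: int = 10,
) -> tuple[float, float]:
    """Hosmer–Lemeshow goodness-of-fit test on decile-of-risk groups.

    Rows are sorted by predicted score and split into ``n_groups`` equal
    groups; the statistic sums (O−E)²/(E(1−E/n)) over groups where O and E
    are observed and expected event counts.  Groups whose expected count is
    zero are merged into their neighbor (logged).  The p-value uses a
    chi-square reference with ``n_groups − 2`` degrees of freedom.
    """
    y, p = _check_pair(outcomes, predictions)
    if n_groups < 2:
        raise ValueError("n_groups must be at least 2")
    if y.size == 0 or y.min() == y.max():
        raise ValueError("both classes must be present")
    order = np.argsort(p, kind="stable")
    groups = [g for g in np.array_split(order, n_groups) if g.size]
    obs = [y[g].sum() for g in groups]
    exp = [p[g].sum() for g in groups]
    sizes = [g.size for g in groups]
    merged_obs, merged_exp, merged_n = [], [], []
    for o, e, n in zip(obs, exp, sizes):
        if merged_exp and (e == 0.0 or merged_exp[-1] == 0.0):
            logger.info("merging Hosmer-Lemeshow group with zero expected events")
            merged_obs[-1] += o
            merged_exp[-1] += e
            merged_n[-1] += n
        else:
            merged_obs.append(o)
            merged_exp.append(e)
            merged_n.append(n)
    stat = 0.0
    for o, e, n in zip(merged_obs, merged_exp, merged_n):
        denom = e * (1.0 - e / n)
        if denom <= 0:
            continue  # saturated group (all predictions 0 or 1, matching outcomes)
        stat += (o - e) ** 2 / denom
    df = max(len(merged_obs) - 2, 1)
    return float(stat), float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapPlan:
    """Precomputed with-replacement resampling indices into a test pool."""

    n_boot: int
    fraction: float
    stratified: bool
    seed: int
    replicate_indices: list[np.ndarray] = field(default_factory=list)


def stratified_bootstrap(
    outcomes,
    n_boot: int = 100,
    fraction: float = 0.2,
    stratified: bool = True,
    seed: int = 0,
) -> BootstrapPlan:
    """Build a bootstrap plan over a pool of outcomes.

    Each replicate samples ``round(fraction·N)`` rows with replacement; in
    stratified mode positives and negatives are resampled separately with
    sizes ``round(fraction·n_pos)`` and ``round(fraction·n_neg)``, keeping
    every replicate's event count near the pool's.
    """
    y = np.asarray(outcomes, dtype=float).reshape(-1)
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    rng = np.random.default_rng(seed)
    replicates: list[np.ndarray] = []
    if stratified:
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        n_pos = int(round(fraction * pos_idx.size))
        n_neg = int(round(fraction * neg_idx.size))
        if n_pos == 0 or n_neg == 0:
            raise ValueError(
                "stratum vanishes: round(fraction * class size) is zero"
            )
        for _ in range(n_boot):
            take_pos = rng.choice(pos_idx, size=n_pos, replace=True)
            take_neg = rng.choice(neg_idx, size=n_neg, replace=True)
            replicates.append(np.concatenate([take_pos, take_neg]))
    else:
        size = int(round(fraction * y.size))
        if size == 0:
            raise ValueError("replicate size is zero")
        for _ in range(n_boot):
            replicates.append(rng.integers(0, y.size, size=size))
    return BootstrapPlan(n_boot, fraction, stratified, int(seed), replicates)


def subgroup_split(u_values, top_percent: float) -> np.ndarray:
    """Flag the top ``top_percent`` percent of unreliability values.

    The threshold is the (100 − top_percent)th percentile of the *full*
    pool, computed once; ties at the threshold are included in the flagged
    subgroup.
    """
    u = np.asarray(u_values, dtype=float).reshape(-1)
    if not 0.0 < top_percent < 100.0:
        raise ValueError("top_percent must lie strictly between 0 and 100")
    if u.size == 0 or u.min() == u.max():
        raise ValueError("degenerate split: all unreliability values equal")
    threshold = np.percentile(u, 100.0 - top_percent)
    return u >= threshold


# ---------------------------------------------------------------------------
# subgroup comparison
# ---------------------------------------------------------------------------


def _paired_ttest(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired t-test p-value; 1.0 when all differences vanish."""
    ok = np.isfinite(a) & np.isfinite(b)
    d = a[ok] - b[ok]
    if d.size < 2 or np.allclose(d, 0.0):
        return 1.0
    if np.std(d, ddof=1) <= 1e-12 * max(1.0, float(np.abs(d).max())):
        return 0.0  # constant nonzero difference
    return float(stats.ttest_rel(a[ok], b[ok]).pvalue)


@dataclass
class SubgroupComparison:
    """Bootstrap comparison of a flagged subgroup against its complement."""

    rule: str
    mask: np.ndarray
    n_boot: int
    brier_sub: np.ndarray
    brier_comp: np.ndarray
    auc_sub: np.ndarray
    auc_comp: np.ndarray
    p_brier: float
    p_auc: float
    calibration_sub: CalibrationTable
    calibration_comp: CalibrationTable

    @staticmethod
    def _summ(v: np.ndarray) -> tuple[float, float]:
        ok = np.isfinite(v)
        n = int(ok.sum())
        if n == 0:
            return float("nan"), float("nan")
        sem = float(np.std(v[ok], ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        return float(np.mean(v[ok])), sem

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, vec in (
            ("normalized_brier_subgroup", self.brier_sub),
            ("normalized_brier_complement", self.brier_comp),
            ("auc_subgroup", self.auc_sub),
            ("auc_complement", self.auc_comp),
        ):
            mean, sem = self._summ(vec)
            rows.append({"metric": name, "mean": mean, "sem": sem})
        df = pd.DataFrame(rows)
        df.attrs["p_brier"] = self.p_brier
        df.attrs["p_auc"] = self.p_auc
        return df


def compare_subgroups(
    y_hat,
    outcomes,
    u_values,
    plan: BootstrapPlan,
    top_percent: float = 1.0,
    bin_centers: np.ndarray | Sequence[float] = DEFAULT_BIN_CENTERS,
    mask: np.ndarray | None = None,
) -> SubgroupComparison:
    """Evaluate a flagged subgroup vs its complement across bootstraps.

    The subgroup is the top ``top_percent`` of ``u_values`` (threshold fixed
    on the pool, applied within replicates) unless an explicit ``mask`` is
    given.  Per replicate the normalized Brier score and AUC are computed
    for both arms; a replicate arm with a single outcome class records the
    metric as missing (logged).  If more than half of the replicates are
    missing a metric, an error is raised.  Paired two-sided t-tests compare
    the arms across replicates; calibration tables are pooled over the full
    test pool per arm.
    """
    y, p = _check_pair(outcomes, y_hat)
    u = np.asarray(u_values, dtype=float).reshape(-1)
    if u.shape != y.shape:
        raise ValueError("u_values must match the cohort length")
    if mask is None:
        mask = subgroup_split(u, top_percent)
        rule = f"top {top_percent:g}% of U"
    else:
        mask = np.asarray(mask, dtype=bool).reshape(-1)
        rule = "explicit mask"
    nb = plan.n_boot
    if nb < 10:
        logger.warning("paired t-tests across %d bootstrap replicates are fragile", nb)
    bs, bc, as_, ac = (np.full(nb, np.nan) for _ in range(4))
    n_missing = 0
    for r, idx in enumerate(plan.replicate_indices):
        if idx.max() >= y.size:
            raise ValueError("bootstrap plan indexes beyond the cohort")
        m = mask[idx]
        for arm, store_b, store_a in ((m, bs, as_), (~m, bc, ac)):
            ya, pa = y[idx][arm], p[idx][arm]
            if ya.size == 0 or ya.min() == ya.max():
                n_missing += 1
                logger.info("replicate %d: single-class arm, metrics missing", r)
                continue
            store_b[r] = normalized_brier(ya, pa)
            store_a[r] = auc(ya, pa)
    for vec, name in ((bs, "subgroup"), (bc, "complement")):
        if np.sum(~np.isfinite(vec)) > nb / 2:
            raise ValueError(f"more than half of replicates missing for {name} arm")
    return SubgroupComparison(
        rule=rule,
        mask=mask,
        n_boot=nb,
        brier_sub=bs,
        brier_comp=bc,
        auc_sub=as_,
        auc_comp=ac,
        p_brier=_paired_ttest(bs, bc),
        p_auc=_paired_ttest(as_, ac),
        calibration_sub=calibration_curve(y[mask], p[mask], bin_centers),
        calibration_comp=calibration_curve(y[~mask], p[~mask], bin_centers),
    )
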