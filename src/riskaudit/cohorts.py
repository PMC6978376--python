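"""Seeded synthetic registries and risk models for exercising the audit.

Real acute-coronary-syndrome registries of the kind the method targets are
access-restricted, so everything here generates cohorts with the same
statistical structure: two-class multivariate-Gaussian feature vectors with
mixed continuous/binary features, outcome prevalences from balanced down to
~0.5%, and risk models (logistic, nomogram-style point lookups) that can be
given a localized miscalibration such as an overestimating high-risk tail.

Binary features are parameterized by *latent* Gaussian class means with
Bernoulli-moment variances; draws are thresholded at 0.5, so the realized
0/1 frequency is the Gaussian upper-tail mass at the threshold (a latent
mean of 0.3 yields a frequency near 0.33).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import logging

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .generative import RiskModel, draw_mvn_mixed
from .schema import BINARY, CONTINUOUS, FeatureSchema, unit_schema

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cohort specification and generation
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Everything needed to regenerate a synthetic cohort bit-exactly."""

    n: int
    prevalence: float
    schema: FeatureSchema
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    cov_pos: np.ndarray
    cov_neg: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.schema.n_features
        self.mean_pos = np.asarray(self.mean_pos, dtype=float).reshape(p)
        self.mean_neg = np.asarray(self.mean_neg, dtype=float).reshape(p)
        self.cov_pos = np.asarray(self.cov_pos, dtype=float).reshape(p, p)
        self.cov_neg = np.asarray(self.cov_neg, dtype=float).reshape(p, p)
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie strictly between 0 and 1")
        if self.n < 1:
            raise ValueError("cohort size must be positive")

    def to_dict(self) -> dict:
        return {
            "n": int(self.n),
            "prevalence": self.prevalence,
            "schema": self.schema.to_dict(),
            "mean_pos": self.mean_pos.tolist(),
            "mean_neg": self.mean_neg.tolist(),
            "cov_pos": self.cov_pos.tolist(),
            "cov_neg": self.cov_neg.tolist(),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        return cls(
            n=int(d["n"]),
            prevalence=float(d["prevalence"]),
            schema=FeatureSchema.from_dict(d["schema"]),
            mean_pos=np.asarray(d["mean_pos"], dtype=float),
            mean_neg=np.asarray(d["mean_neg"], dtype=float),
            cov_pos=np.asarray(d["cov_pos"], dtype=float),
            cov_neg=np.asarray(d["cov_neg"], dtype=float),
            seed=int(d.get("seed", 0)),
        )


@dataclass
class SyntheticCohort:
    features: pd.DataFrame
    labels: np.ndarray
    spec: CohortSpec


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort: Bernoulli(π) labels, then class-conditional features.

    Label-first generation keeps prevalence an explicit knob.  Identical
    specs produce identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    labels = (rng.random(spec.n) < spec.prevalence).astype(int)
    mask = spec.schema.binary_mask
    X = np.empty((spec.n, spec.schema.n_features))
    pos = labels == 1
    if pos.any():
        X[pos] = draw_mvn_mixed(rng, spec.mean_pos, spec.cov_pos, mask, int(pos.sum()))
    if (~pos).any():
        X[~pos] = draw_mvn_mixed(
            rng, spec.mean_neg, spec.cov_neg, mask, int((~pos).sum())
        )
    return SyntheticCohort(spec.schema.to_frame(X), labels, spec)


def _structured_cov(sds: np.ndarray, corr: float, scale: float = 1.0) -> np.ndarray:
    p = sds.shape[0]
    R = np.full((p, p), corr)
    np.fill_diagonal(R, 1.0)
    return scale * (R * np.outer(sds, sds))


def grace_like_spec(
    n: int = 40_000,
    prevalence: float = 0.0715,
    seed: int = 2020,
    separation: float = 1.0,
) -> CohortSpec:
    """Registry-like cohort: 8 continuous + 3 binary features, ~7% mortality.

    Default class separation was picked once so that the Bayes-optimal
    discrimination sits near AUC 0.81, the level reported for widely used
    acute-coronary-syndrome mortality scores.  ``separation`` scales the
    class mean shift (0 → no signal).
    """
    schema = unit_schema(8, 3)
    mean_neg_c = np.array([0.40, 0.45, 0.38, 0.50, 0.42, 0.35, 0.48, 0.44])
    shift_c = separation * np.array(
        [0.094, 0.075, 0.063, -0.050, 0.069, 0.088, 0.038, 0.056]
    )
    sds_c = np.array([0.13, 0.15, 0.12, 0.16, 0.14, 0.12, 0.15, 0.13])
    # binary features: latent means; variance uses the Bernoulli moment
    lat_neg_b = np.array([0.30, 0.22, 0.12])
    lat_pos_b = lat_neg_b + separation * np.array([0.113, 0.100, 0.100])
    mean_neg = np.concatenate([mean_neg_c, lat_neg_b])
    mean_pos = np.concatenate([mean_neg_c + shift_c, lat_pos_b])
    sds_neg = np.concatenate([sds_c, np.sqrt(lat_neg_b * (1 - lat_neg_b))])
    sds_pos = np.concatenate([sds_c, np.sqrt(lat_pos_b * (1 - lat_pos_b))])
    return CohortSpec(
        n=n,
        prevalence=prevalence,
        schema=schema,
        mean_pos=mean_pos,
        mean_neg=mean_neg,
        cov_pos=_structured_cov(sds_pos, 0.15, scale=1.1),
        cov_neg=_structured_cov(sds_neg, 0.15),
        seed=seed,
    )


def stroke_like_spec(
    n: int = 16_618,
    prevalence: float = 0.00511,
    seed: int = 2020,
) -> CohortSpec:
    """Very-low-prevalence cohort (~0.5% events) for the rare-outcome regime."""
    base = grace_like_spec(n=n, prevalence=prevalence, seed=seed, separation=0.8)
    return base


# ---------------------------------------------------------------------------
# risk-model constructors
# ---------------------------------------------------------------------------


def make_logistic_model(
    weights: Sequence[float],
    intercept: float,
    label: str = "logistic model",
) -> RiskModel:
    """score(x) = logistic(intercept + w·x) on normalized features."""
    w = np.asarray(weights, dtype=float)

    def score(X: np.ndarray) -> np.ndarray:
        if X.shape[1] != w.shape[0]:
            raise ValueError("weight length does not match the feature count")
        z = intercept + X @ w
        return 1.0 / (1.0 + np.exp(-z))

    return RiskModel(score_fn=score, label=label)


def make_nomogram_model(
    point_tables: Sequence[tuple[Sequence[float], Sequence[float]]],
    lookup: tuple[Sequence[float], Sequence[float]],
    label: str = "nomogram model",
) -> RiskModel:
    """Nomogram-style model: per-feature point tables plus a probability lookup.

    Each point table is ``(value_knots, point_knots)``, interpolated
    piecewise-linearly per feature; the lookup maps the total point score to
    a probability through a monotone piecewise-linear table.  Totals outside
    the lookup range are clamped to the terminal knots (logged).
    """
    tables = [
        (np.asarray(v, dtype=float), np.asarray(p, dtype=float))
        for v, p in point_tables
    ]
    totals_knots = np.asarray(lookup[0], dtype=float)
    prob_knots = np.asarray(lookup[1], dtype=float)
    if np.any(np.diff(totals_knots) <= 0):
        raise ValueError("lookup point knots must be strictly increasing")
    if np.any(np.diff(prob_knots) < 0):
        raise ValueError("lookup probabilities must be monotone nondecreasing")
    if prob_knots.min() < 0 or prob_knots.max() > 1:
        raise ValueError("lookup probabilities must lie in [0, 1]")

    def score(X: np.ndarray) -> np.ndarray:
        if X.shape[1] != len(tables):
            raise ValueError("point table count does not match the feature count")
        total = np.zeros(X.shape[0])
        for j, (vk, pk) in enumerate(tables):
            total += np.interp(X[:, j], vk, pk)
        outside = int(np.sum((total < totals_knots[0]) | (total > totals_knots[-1])))
        if outside:
            logger.info(
                "%d point totals outside the lookup range; clamped to terminal knots",
                outside,
            )
        return np.interp(total, totals_knots, prob_knots)

    return RiskModel(score_fn=score, label=label)


def perturb_model(
    model: RiskModel,
    region: tuple[float, float],
    multiplier: float,
) -> RiskModel:
    """Localized miscalibration injector.

    Where the base score falls inside ``region`` the score becomes
    ``clip(multiplier * score, 0, 1)``; elsewhere it is unchanged.  A
    multiplier above 1 creates an overestimating tail, the failure mode the
    unreliability audit is designed to flag.
    """
    lo, hi = region
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("region must be a subinterval of [0, 1]")

    def score(X: np.ndarray) -> np.ndarray:
        base = model(X)
        inside = (base >= lo) & (base <= hi)
        return np.where(inside, np.clip(multiplier * base, 0.0, 1.0), base)

    return RiskModel(
        score_fn=score,
        label=f"{model.label} (x{multiplier:g} on [{lo:g}, {hi:g}])",
    )


def fit_nomogram_model(
    features: pd.DataFrame | np.ndarray,
    labels,
    schema: FeatureSchema,
    n_lookup_knots: int = 25,
    label: str = "fitted nomogram",
) -> RiskModel:
    """Develop a nomogram-style risk model from a training cohort.

    Per-feature points are linear with diagonal-LDA-style weights
    (mean difference over pooled variance, scaled to a 0–100 point range);
    the total-points-to-probability lookup is a univariate logistic
    regression of the outcome on the point total, tabulated at evenly
    spaced knots.  This mimics how published point-score nomograms are
    built, without reproducing any real score's coefficients.
    """
    X = schema.normalize(features)
    y = np.asarray(labels).astype(int).reshape(-1)
    if y.min() == y.max():
        raise ValueError("both classes required to fit a nomogram")
    mu1, mu0 = X[y == 1].mean(axis=0), X[y == 0].mean(axis=0)
    var = X.var(axis=0, ddof=1) + 1e-9
    w = (mu1 - mu0) / var
    w = 100.0 * w / np.max(np.abs(w))
    tables = [(np.array([0.0, 1.0]), np.array([0.0, wj])) for wj in w]
    totals = X @ w
    lr = LogisticRegression(C=1e6, solver="lbfgs")
    lr.fit(totals[:, None], y)
    knots = np.linspace(totals.min(), totals.max(), n_lookup_knots)
    probs = lr.predict_proba(knots[:, None])[:, 1]
    probs = np.maximum.accumulate(np.clip(probs, 0.0, 1.0))  # enforce monotone lookup
    return make_nomogram_model(tables, (knots, probs), label=label)
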