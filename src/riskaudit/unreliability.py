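"""Unreliability scores and expected-unreliability curves.

Two variants of the score are provided.  The score-space form, used for all
cohort audits, is

    U = | P^G(y=1 | ŷ) − ŷ |,

the absolute disagreement between the model's prediction ŷ and the
generative Bayes posterior given that prediction.  The feature-space form
υ = |P^G(y=1|x) − ŷ| evaluates the class densities at the patient's own
feature vector instead of pushing them through the score histogram; it is
dearer and is exposed per patient on request.

U = 0 is necessary but not sufficient for the risk model to agree with the
generative posterior in feature space: a large U flags a prediction that
cannot be reconciled with the training-data summaries, while a small U is
not a certificate of correctness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .generative import (
    ClassSummaries,
    RiskModel,
    ScoreDistributions,
    mixed_log_density,
    posterior_given_score,
    relative_likelihood,
)


def unreliability_score(
    posterior: np.ndarray | float,
    y_hat: np.ndarray | float,
) -> np.ndarray | float:
    """U = |posterior − ŷ|, both arguments probabilities in [0, 1]."""
    p = np.asarray(posterior, dtype=float)
    y = np.asarray(y_hat, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or np.any(y < 0) or np.any(y > 1):
        raise ValueError("posterior and y_hat must lie in [0, 1]")
    u = np.abs(p - y)
    return float(u) if (np.isscalar(posterior) and np.isscalar(y_hat)) else u


def pointwise_unreliability(
    summaries: ClassSummaries,
    x: np.ndarray | Sequence[float],
    y_hat: float,
) -> float:
    """Feature-space unreliability υ(x) = |P^G(y=1|x) − ŷ|.

    Class densities are evaluated at ``x`` (normalized units, schema order)
    with binary coordinates handled through the thresholded-Gaussian mass;
    the posterior is π·d1 / (π·d1 + (1−π)·d0).
    """
    if not 0.0 <= y_hat <= 1.0:
        raise ValueError("y_hat must lie in [0, 1]")
    x = np.asarray(x, dtype=float).reshape(1, -1)
    if x.shape[1] != summaries.schema.n_features:
        raise ValueError("x does not conform to the schema")
    mask = summaries.schema.binary_mask
    l1 = mixed_log_density(x, summaries.mean_pos, summaries.cov_pos, mask)[0]
    l0 = mixed_log_density(x, summaries.mean_neg, summaries.cov_neg, mask)[0]
    if l1 < -600 and l0 < -600:
        raise ValueError("point outside model support: zero density in both classes")
    pi = summaries.prevalence
    posterior = 1.0 / (1.0 + np.exp(np.log((1 - pi) / pi) + l0 - l1))
    return float(abs(posterior - y_hat))


def score_cohort(
    summaries: ClassSummaries,
    model: RiskModel,
    dist: ScoreDistributions,
    features: pd.DataFrame | np.ndarray,
    with_pointwise: bool = False,
    prevalence: float | None = None,
) -> pd.DataFrame:
    """Audit every row of a feature table.

    Returns a DataFrame (row order preserved) with columns ``y_hat``,
    ``beta``, ``posterior`` and ``U``; ``upsilon`` is added when
    ``with_pointwise`` is set.  ``prevalence`` defaults to the training
    prevalence stored in the summaries.
    """
    X = summaries.schema.normalize(features)
    pi = summaries.prevalence if prevalence is None else float(prevalence)
    index = features.index if isinstance(features, pd.DataFrame) else None
    if X.shape[0] == 0:
        cols = ["y_hat", "beta", "posterior", "U"] + (
            ["upsilon"] if with_pointwise else []
        )
        return pd.DataFrame(columns=cols, dtype=float)
    y_hat = model(X)
    beta = relative_likelihood(dist, y_hat)
    posterior = posterior_given_score(beta, pi)
    out = pd.DataFrame(
        {
            "y_hat": y_hat,
            "beta": np.asarray(beta, dtype=float),
            "posterior": np.asarray(posterior, dtype=float),
            "U": np.abs(np.asarray(posterior) - y_hat),
        },
        index=index,
    )
    if with_pointwise:
        mask = summaries.schema.binary_mask
        l1 = mixed_log_density(X, summaries.mean_pos, summaries.cov_pos, mask)
        l0 = mixed_log_density(X, summaries.mean_neg, summaries.cov_neg, mask)
        post_x = 1.0 / (1.0 + np.exp(np.log((1 - pi) / pi) + l0 - l1))
        out["upsilon"] = np.abs(post_x - y_hat)
    return out


# ---------------------------------------------------------------------------
# expected-unreliability curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BetaLaw:
    """Distribution placed on the relative likelihood β for averaging.

    ``kind="uniform"`` is uniform on (0, upper]; ``kind="point"`` is a point
    mass (the degenerate law, useful for sanity checks).
    """

    kind: str = "uniform"
    upper: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "point"):
            raise ValueError(f"unknown beta law {self.kind!r}")
        if self.upper <= 0:
            raise ValueError("beta law upper bound must be positive")


@dataclass
class ExpectedUnreliabilityCurve:
    """E[U | ŷ] over a score grid, for a prevalence and a β law."""

    prevalence: float
    y_hat_grid: np.ndarray
    expected_U: np.ndarray
    beta_law: BetaLaw
    n_nodes: int


def expected_unreliability_curve(
    prevalence: float,
    y_hat_grid: np.ndarray | Sequence[float],
    beta_law: BetaLaw = BetaLaw(),
    n_nodes: int = 100_000,
) -> ExpectedUnreliabilityCurve:
    """Average unreliability as a function of the model prediction.

    For each grid score ŷ computes E_β[ |β·π/(β·π + 1 − π) − ŷ| ] under the
    β law by deterministic trapezoid quadrature (no seed dependence).  Under
    class imbalance the curve rises with ŷ: rare-outcome cohorts make
    high-risk predictions the ones most likely to be unreliable.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    grid = np.asarray(y_hat_grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > 1):
        raise ValueError("y_hat grid must lie within [0, 1]")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("y_hat grid must be strictly increasing")
    pi = float(prevalence)
    if beta_law.kind == "point":
        post = posterior_given_score(beta_law.upper, pi)
        expected = np.abs(post - grid)
        return ExpectedUnreliabilityCurve(pi, grid, expected, beta_law, 1)
    nodes = np.linspace(0.0, beta_law.upper, n_nodes)
    post = nodes * pi / (nodes * pi + (1.0 - pi))
    integrand = np.abs(post[None, :] - grid[:, None])
    expected = np.trapezoid(integrand, nodes, axis=1) / beta_law.upper
    return ExpectedUnreliabilityCurve(pi, grid, expected, beta_law, n_nodes)
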