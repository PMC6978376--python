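"""Class-conditional generative reference for auditing a risk model.

The audit compares a clinical risk model f(x) against an alternate risk
estimate derived *only* from summary statistics of the model's training
data.  Per outcome class a multivariate normal is fit to the (normalized)
feature vectors; pushing a large number of generative draws through the risk
model yields histogram estimates of the score-conditional likelihoods
P(ŷ | y=1) and P(ŷ | y=0).  Their ratio β = P(ŷ|y=1)/P(ŷ|y=0), combined
with the outcome prevalence π through Bayes' rule,

    P(y=1 | ŷ) = β·π / (β·π + 1 − π),

is the alternate prediction that the unreliability score compares with ŷ.

Binary features are modeled as thresholded latent Gaussians: the MVN is fit
to the raw 0/1 values, and generative draws are cut at 0.5.  Continuous
draws are clipped to the unit box, the risk model's domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .schema import FeatureSchema

logger = logging.getLogger(__name__)

#: histogram resolution for the score-conditional likelihoods
BIN_WIDTH = 0.001
N_BINS = 1000
BIN_EDGES = np.linspace(0.0, 1.0, N_BINS + 1)

POSITIVE = "positive"
NEGATIVE = "negative"


# ---------------------------------------------------------------------------
# risk-model contract
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskModel:
    """A deterministic map from normalized feature vectors to scores in [0, 1].

    ``score_fn`` receives an ``(n, p)`` array in schema order / normalized
    units and must return ``n`` scores.  Outputs are validated to [0, 1];
    the same input must always produce the same output.
    """

    score_fn: Callable[[np.ndarray], np.ndarray]
    label: str = "risk model"

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        y = np.asarray(self.score_fn(X), dtype=float).reshape(-1)
        if y.shape[0] != X.shape[0]:
            raise ValueError(f"{self.label}: score_fn returned wrong length")
        if not np.all(np.isfinite(y)):
            raise ValueError(f"{self.label}: non-finite score")
        if y.min() < -1e-12 or y.max() > 1 + 1e-12:
            raise ValueError(f"{self.label}: score outside [0, 1]")
        return np.clip(y, 0.0, 1.0)


# ---------------------------------------------------------------------------
# class summaries
# ---------------------------------------------------------------------------


@dataclass
class ClassSummaries:
    """Per-class MVN parameters plus prevalence — all the method needs.

    This is the "summary statistics" artifact that replaces raw training
    data: mean vector and covariance matrix per class (normalized feature
    units, ridge already added to the covariance diagonals), outcome
    prevalence π, and class counts.
    """

    schema: FeatureSchema
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    cov_pos: np.ndarray
    cov_neg: np.ndarray
    prevalence: float
    n_pos: int
    n_neg: int
    ridge: float = 0.0

    def __post_init__(self) -> None:
        p = self.schema.n_features
        self.mean_pos = np.asarray(self.mean_pos, dtype=float).reshape(p)
        self.mean_neg = np.asarray(self.mean_neg, dtype=float).reshape(p)
        self.cov_pos = np.asarray(self.cov_pos, dtype=float).reshape(p, p)
        self.cov_neg = np.asarray(self.cov_neg, dtype=float).reshape(p, p)
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie strictly between 0 and 1")
        for cov, tag in ((self.cov_pos, "positive"), (self.cov_neg, "negative")):
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"{tag}-class covariance is not symmetric")

    def mean_cov(self, which_class: str) -> tuple[np.ndarray, np.ndarray]:
        if which_class == POSITIVE:
            return self.mean_pos, self.cov_pos
        if which_class == NEGATIVE:
            return self.mean_neg, self.cov_neg
        raise ValueError(f"unknown class tag {which_class!r}")

    def to_dict(self) -> dict:
        return {
            "schema": self.schema.to_dict(),
            "mean_pos": self.mean_pos.tolist(),
            "mean_neg": self.mean_neg.tolist(),
            "cov_pos": self.cov_pos.tolist(),
            "cov_neg": self.cov_neg.tolist(),
            "prevalence": self.prevalence,
            "n_pos": int(self.n_pos),
            "n_neg": int(self.n_neg),
            "ridge": self.ridge,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassSummaries":
        return cls(
            schema=FeatureSchema.from_dict(d["schema"]),
            mean_pos=np.asarray(d["mean_pos"], dtype=float),
            mean_neg=np.asarray(d["mean_neg"], dtype=float),
            cov_pos=np.asarray(d["cov_pos"], dtype=float),
            cov_neg=np.asarray(d["cov_neg"], dtype=float),
            prevalence=float(d["prevalence"]),
            n_pos=int(d["n_pos"]),
            n_neg=int(d["n_neg"]),
            ridge=float(d.get("ridge", 0.0)),
        )


def fit_class_summaries(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    schema: FeatureSchema,
    ridge: float = 1e-6,
) -> ClassSummaries:
    """Fit per-class sample means and covariances on normalized features.

    Covariances use the unbiased (n−1) estimator; ``ridge * I`` is added to
    each covariance so the MVN stays samplable when a class is small or a
    feature is (near-)degenerate.  Prevalence is the positive fraction of
    the supplied rows.
    """
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    X = schema.normalize(features)
    y = np.asarray(labels).astype(int).reshape(-1)
    if y.shape[0] != X.shape[0]:
        raise ValueError("features and labels disagree in length")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be binary 0/1")
    n_pos = int(y.sum())
    n_neg = int(y.shape[0] - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate labels: both classes must be present")
    if n_pos < 2 or n_neg < 2:
        raise ValueError("each class needs at least 2 rows for covariance estimation")

    out: dict[str, np.ndarray] = {}
    for tag, Xc in ((POSITIVE, X[y == 1]), (NEGATIVE, X[y == 0])):
        mean = Xc.mean(axis=0)
        cov = np.cov(Xc, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov) + ridge * np.eye(schema.n_features)
        if ridge == 0.0:
            try:
                linalg.cholesky(cov, lower=True)
            except linalg.LinAlgError as exc:
                raise ValueError(
                    f"{tag}-class covariance is singular; pass a positive ridge"
                ) from exc
        out[tag] = (mean, cov)  # type: ignore[assignment]

    return ClassSummaries(
        schema=schema,
        mean_pos=out[POSITIVE][0],
        mean_neg=out[NEGATIVE][0],
        cov_pos=out[POSITIVE][1],
        cov_neg=out[NEGATIVE][1],
        prevalence=n_pos / y.shape[0],
        n_pos=n_pos,
        n_neg=n_neg,
        ridge=ridge,
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def draw_mvn_mixed(
    rng: np.random.Generator,
    mean: np.ndarray,
    cov: np.ndarray,
    binary_mask: np.ndarray,
    n: int,
) -> np.ndarray:
    """Draw ``n`` mixed-feature vectors from one class MVN.

    Latent Gaussian draws are thresholded at 0.5 on binary coordinates and
    clipped to [0, 1] on continuous ones, so the output lives in the risk
    model's domain.
    """
    try:
        L = linalg.cholesky(np.asarray(cov, dtype=float), lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("covariance is not positive definite") from exc
    Z = rng.standard_normal((n, mean.shape[0]))
    X = mean + Z @ L.T
    mask = np.asarray(binary_mask, dtype=bool)
    if mask.any():
        X[:, mask] = (X[:, mask] > 0.5).astype(float)
    cont = ~mask
    if cont.any():
        X[:, cont] = np.clip(X[:, cont], 0.0, 1.0)
    return X


def sample_class_features(
    summaries: ClassSummaries,
    which_class: str,
    n: int,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Sample a patient×feature table from one fitted class distribution."""
    if n < 1:
        raise ValueError("n must be at least 1")
    mean, cov = summaries.mean_cov(which_class)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = draw_mvn_mixed(rng, mean, cov, summaries.schema.binary_mask, n)
    return summaries.schema.to_frame(X)


# ---------------------------------------------------------------------------
# score-conditional likelihoods
# ---------------------------------------------------------------------------


@dataclass
class ScoreDistributions:
    """Histogram estimates of P(ŷ|y=1) and P(ŷ|y=0) over [0, 1].

    Bins are half-open ``[k·0.001, (k+1)·0.001)`` with the final bin closed,
    so a score of exactly 1.0 falls in the last bin.  ``mass_*`` are the
    pseudocount-smoothed, renormalized per-bin probability masses.
    """

    mass_pos: np.ndarray
    mass_neg: np.ndarray
    n_samples_pos: int
    n_samples_neg: int
    converged: bool
    ks_pvalues: dict[str, list[float]] = field(default_factory=dict)
    pseudocount: float = 1.0
    bin_edges: np.ndarray = field(default_factory=lambda: BIN_EDGES.copy())

    def __post_init__(self) -> None:
        self.mass_pos = np.asarray(self.mass_pos, dtype=float)
        self.mass_neg = np.asarray(self.mass_neg, dtype=float)
        for m in (self.mass_pos, self.mass_neg):
            if m.shape != (N_BINS,):
                raise ValueError(f"expected {N_BINS} bins")
            if m.min() < 0 or abs(m.sum() - 1.0) > 1e-9:
                raise ValueError("bin masses must be nonnegative and sum to 1")

    @staticmethod
    def bin_index(y_hat: np.ndarray | float) -> np.ndarray:
        y = np.asarray(y_hat, dtype=float)
        if np.any(y < 0) or np.any(y > 1):
            raise ValueError("score outside [0, 1]")
        return np.minimum((y / BIN_WIDTH).astype(int), N_BINS - 1)

    def to_dict(self) -> dict:
        return {
            "bin_width": BIN_WIDTH,
            "mass_pos": self.mass_pos.tolist(),
            "mass_neg": self.mass_neg.tolist(),
            "n_samples_pos": int(self.n_samples_pos),
            "n_samples_neg": int(self.n_samples_neg),
            "converged": bool(self.converged),
            "ks_pvalues": self.ks_pvalues,
            "pseudocount": self.pseudocount,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreDistributions":
        return cls(
            mass_pos=np.asarray(d["mass_pos"], dtype=float),
            mass_neg=np.asarray(d["mass_neg"], dtype=float),
            n_samples_pos=int(d["n_samples_pos"]),
            n_samples_neg=int(d["n_samples_neg"]),
            converged=bool(d["converged"]),
            ks_pvalues={k: list(v) for k, v in d.get("ks_pvalues", {}).items()},
            pseudocount=float(d.get("pseudocount", 1.0)),
        )


def estimate_score_pdfs(
    summaries: ClassSummaries,
    model: RiskModel,
    batch: int = 1_000_000,
    seed: int | np.random.Generator = 0,
    alpha_ks: float = 0.05,
    max_iter: int = 20,
    pseudocount: float = 1.0,
) -> ScoreDistributions:
    """Monte-Carlo estimate of the score-conditional likelihoods per class.

    Per class: draw ``batch`` generative feature vectors, score them, and
    histogram the scores at bin width 0.001.  Then repeatedly draw another
    batch and compare the previous score sample against the combined sample
    with a two-sample Kolmogorov–Smirnov test; a class has converged once
    the test fails to reject at ``alpha_ks``.  If ``max_iter`` rounds are
    exhausted first the result is returned with ``converged=False`` and a
    warning is logged — never silently.

    A uniform ``pseudocount`` of virtual samples is added to every bin
    before normalizing so that the likelihood ratio stays finite on empty
    bins.
    """
    if batch < 1000:
        raise ValueError("batch too small for 1000 bins (need batch >= 1000)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = summaries.schema.binary_mask

    scores: dict[str, np.ndarray] = {}
    done: dict[str, bool] = {}
    pvals: dict[str, list[float]] = {POSITIVE: [], NEGATIVE: []}
    for tag in (POSITIVE, NEGATIVE):
        mean, cov = summaries.mean_cov(tag)
        scores[tag] = model(draw_mvn_mixed(rng, mean, cov, mask, batch))
        done[tag] = False

    for _ in range(max_iter):
        if all(done.values()):
            break
        for tag in (POSITIVE, NEGATIVE):
            if done[tag]:
                continue
            mean, cov = summaries.mean_cov(tag)
            new = model(draw_mvn_mixed(rng, mean, cov, mask, batch))
            combined = np.concatenate([scores[tag], new])
            p = float(stats.ks_2samp(scores[tag], combined).pvalue)
            pvals[tag].append(p)
            scores[tag] = combined
            done[tag] = p >= alpha_ks
    converged = all(done.values())
    if not converged:
        logger.warning(
            "score PDF estimation did not converge after %d iterations "
            "(K-S p-values pos=%s neg=%s); returning converged=False",
            max_iter,
            pvals[POSITIVE][-3:],
            pvals[NEGATIVE][-3:],
        )

    masses = {}
    for tag in (POSITIVE, NEGATIVE):
        counts, _ = np.histogram(scores[tag], bins=BIN_EDGES)
        smoothed = counts.astype(float) + pseudocount
        masses[tag] = smoothed / smoothed.sum()

    return ScoreDistributions(
        mass_pos=masses[POSITIVE],
        mass_neg=masses[NEGATIVE],
        n_samples_pos=scores[POSITIVE].shape[0],
        n_samples_neg=scores[NEGATIVE].shape[0],
        converged=converged,
        ks_pvalues=pvals,
        pseudocount=pseudocount,
    )


def relative_likelihood(
    dist: ScoreDistributions,
    y_hat: np.ndarray | float,
    allow_unconverged: bool = True,
) -> np.ndarray | float:
    """β(ŷ) = P(ŷ|y=1) / P(ŷ|y=0) from the smoothed histogram masses."""
    if not dist.converged and not allow_unconverged:
        raise ValueError("score distributions did not converge")
    idx = dist.bin_index(y_hat)
    beta = dist.mass_pos[idx] / dist.mass_neg[idx]
    return float(beta) if np.isscalar(y_hat) else beta


def posterior_given_score(
    beta: np.ndarray | float,
    prevalence: float,
) -> np.ndarray | float:
    """Bayes posterior P(y=1|ŷ) = β·π / (β·π + 1 − π).

    Monotone increasing in β at fixed π; equals π at β = 1.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    b = np.asarray(beta, dtype=float)
    if np.any(b < 0):
        raise ValueError("beta must be nonnegative")
    post = b * prevalence / (b * prevalence + (1.0 - prevalence))
    return float(post) if np.isscalar(beta) else post


# ---------------------------------------------------------------------------
# mixed continuous/binary density (for the feature-space unreliability)
# ---------------------------------------------------------------------------


def mixed_log_density(
    X: np.ndarray,
    mean: np.ndarray,
    cov: np.ndarray,
    binary_mask: np.ndarray,
) -> np.ndarray:
    """Log density of mixed vectors under a thresholded-Gaussian class model.

    Coordinates are processed in schema order via the conditional-Gaussian
    chain rule.  Continuous coordinates contribute the conditional normal
    density; binary coordinates contribute the conditional probability that
    the latent Gaussian falls on the observed side of the 0.5 threshold
    (conditioning on the 0/1 value itself for subsequent coordinates — an
    approximation that keeps the factorization Gaussian).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    mask = np.asarray(binary_mask, dtype=bool)
    n, p = X.shape
    logd = np.zeros(n)
    for j in range(p):
        if j == 0:
            mu_j = np.full(n, mean[0])
            var_j = cov[0, 0]
        else:
            a = linalg.solve(cov[:j, :j], cov[:j, j], assume_a="pos")
            mu_j = mean[j] + (X[:, :j] - mean[:j]) @ a
            var_j = cov[j, j] - cov[:j, j] @ a
        sd = np.sqrt(max(var_j, 1e-12))
        if mask[j]:
            p_one = stats.norm.sf(0.5, loc=mu_j, scale=sd)
            prob = np.where(X[:, j] > 0.5, p_one, 1.0 - p_one)
            logd += np.log(np.clip(prob, 1e-300, None))
        else:
            logd += stats.norm.logpdf(X[:, j], loc=mu_j, scale=sd)
    return logd


def make_generative_posterior_model(
    schema: FeatureSchema,
    mean_pos: np.ndarray,
    cov_pos: np.ndarray,
    mean_neg: np.ndarray,
    cov_neg: np.ndarray,
    prevalence: float,
    label: str = "generative Bayes posterior",
) -> RiskModel:
    """Risk model equal to the generative posterior P(y=1|x).

    Useful as the self-consistency oracle: auditing this model against the
    same generative law should produce unreliability scores near zero.
    """
    mask = schema.binary_mask
    pi = float(prevalence)

    def score(X: np.ndarray) -> np.ndarray:
        l1 = mixed_log_density(X, mean_pos, cov_pos, mask)
        l0 = mixed_log_density(X, mean_neg, cov_neg, mask)
        # posterior = 1 / (1 + (1-pi)/pi * d0/d1), computed in log space
        return 1.0 / (1.0 + np.exp(np.log((1 - pi) / pi) + l0 - l1))

    return RiskModel(score_fn=score, label=label)


def bayes_model_from_summaries(summaries: ClassSummaries) -> RiskModel:
    """Posterior model built from fitted class summaries."""
    return make_generative_posterior_model(
        summaries.schema,
        summaries.mean_pos,
        summaries.cov_pos,
        summaries.mean_neg,
        summaries.cov_neg,
        summaries.prevalence,
        label="fitted generative posterior",
    )
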