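"""End-to-end synthetic audit studies.

These routines wire the modules into the complete protocols used to
validate the method on synthetic registries: a 1-D Gaussian construction
with a closed-form Bayes oracle, the self-consistency (agreement) check,
and repeated full audits of a miscalibrated or well-specified risk model on
an imbalanced cohort with bootstrap subgroup evaluation.  All randomness
flows from a single seed per call; seeds for sub-steps are spawned from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import evaluation
from .cohorts import (
    CohortSpec,
    fit_nomogram_model,
    generate_cohort,
    grace_like_spec,
    perturb_model,
)
from .generative import (
    BIN_EDGES,
    ClassSummaries,
    RiskModel,
    estimate_score_pdfs,
    fit_class_summaries,
    make_generative_posterior_model,
    posterior_given_score,
    relative_likelihood,
)
from .schema import unit_schema
from .unreliability import score_cohort


def _spawn(seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# 1-D Gaussian construction with closed-form oracle
# ---------------------------------------------------------------------------


def one_dim_construction(
    mu_pos: float = 0.7,
    mu_neg: float = 0.3,
    sd: float = 0.1,
    prevalence: float = 0.5,
) -> tuple[ClassSummaries, RiskModel]:
    """Single continuous feature, interior class normals, identity model.

    The risk model returns the feature itself, so the score-conditional
    likelihoods are the class densities and the pipeline posterior can be
    checked against πφ₁(ŷ)/(πφ₁(ŷ)+(1−π)φ₀(ŷ)) in closed form.
    """
    schema = unit_schema(1)
    summaries = ClassSummaries(
        schema=schema,
        mean_pos=np.array([mu_pos]),
        mean_neg=np.array([mu_neg]),
        cov_pos=np.array([[sd**2]]),
        cov_neg=np.array([[sd**2]]),
        prevalence=prevalence,
        n_pos=1000,
        n_neg=1000,
    )
    identity = RiskModel(score_fn=lambda X: X[:, 0], label="identity")
    return summaries, identity


def closed_form_posterior(
    y_hat: np.ndarray,
    mu_pos: float,
    mu_neg: float,
    sd: float,
    prevalence: float,
) -> np.ndarray:
    """Exact Bayes posterior for the 1-D normal construction.

    Evaluated per histogram bin via normal CDF differences — the analytic
    limit of the histogram-ratio estimator, free of discretization bias.
    """
    idx = np.minimum((np.asarray(y_hat, dtype=float) / 0.001).astype(int), 999)
    lo, hi = BIN_EDGES[idx], BIN_EDGES[idx + 1]
    m1 = stats.norm.cdf(hi, mu_pos, sd) - stats.norm.cdf(lo, mu_pos, sd)
    m0 = stats.norm.cdf(hi, mu_neg, sd) - stats.norm.cdf(lo, mu_neg, sd)
    return prevalence * m1 / (prevalence * m1 + (1 - prevalence) * m0)


def oracle_equivalence_error(
    batch: int = 1_000_000,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> float:
    """Max |Monte-Carlo posterior − closed-form posterior| on the score grid.

    Uses the 1-D construction; the grid defaults to the standard
    calibration-bin centers 0.05, 0.15, ..., 0.95, where the predictive
    mixture carries the cohort's mass.
    """
    summaries, model = one_dim_construction()
    dist = estimate_score_pdfs(summaries, model, batch=batch, seed=seed)
    if grid is None:
        grid = np.arange(0.05, 1.0, 0.1)
    beta = relative_likelihood(dist, grid)
    mc = posterior_given_score(beta, summaries.prevalence)
    exact = closed_form_posterior(grid, 0.7, 0.3, 0.1, summaries.prevalence)
    return float(np.max(np.abs(mc - exact)))


def agreement_mean_unreliability(
    batch: int = 1_000_000,
    n_cohort: int = 20_000,
    prevalence: float = 0.0715,
    seed: int = 0,
) -> float:
    """Mean cohort U when the risk model *is* the generative Bayes posterior.

    With the audited model equal to P^G(y=1|x), every prediction should be
    reconcilable with the generative reference, so mean U shrinks toward
    zero as the Monte-Carlo batch grows.
    """
    s_pdf, s_cohort = _spawn(seed, 2)
    summaries, _ = one_dim_construction(prevalence=prevalence)
    bayes = make_generative_posterior_model(
        summaries.schema,
        summaries.mean_pos,
        summaries.cov_pos,
        summaries.mean_neg,
        summaries.cov_neg,
        prevalence,
    )
    dist = estimate_score_pdfs(summaries, bayes, batch=batch, seed=s_pdf)
    spec = CohortSpec(
        n=n_cohort,
        prevalence=prevalence,
        schema=summaries.schema,
        mean_pos=summaries.mean_pos,
        mean_neg=summaries.mean_neg,
        cov_pos=summaries.cov_pos,
        cov_neg=summaries.cov_neg,
        seed=s_cohort,
    )
    cohort = generate_cohort(spec)
    scored = score_cohort(summaries, bayes, dist, cohort.features)
    return float(scored["U"].mean())


# ---------------------------------------------------------------------------
# full audit of one synthetic registry
# ---------------------------------------------------------------------------


@dataclass
class AuditOutcome:
    """Subgroup-vs-complement metrics from one end-to-end audit.

    ``brier_*``/``auc_*`` are means across bootstrap replicates (the
    protocol's error-bar machinery); ``pool_brier_*`` are single point
    estimates on the full test pool.  The pool-level figures are the ones
    to use for bias-sensitive contrasts: a bootstrap subgroup arm holds
    only fraction·subgroup patients, and the normalized-Brier ratio is
    biased upward on such small arms, which would masquerade as
    degradation in a null comparison.
    """

    brier_sub: float
    brier_comp: float
    auc_sub: float
    auc_comp: float
    pool_brier_sub: float
    pool_brier_comp: float
    p_brier: float
    p_auc: float
    converged: bool

    @property
    def brier_gap(self) -> float:
        return self.brier_sub - self.brier_comp

    @property
    def pool_brier_gap(self) -> float:
        return self.pool_brier_sub - self.pool_brier_comp

    @property
    def detects_degradation(self) -> bool:
        """Higher subgroup error and lower subgroup discrimination."""
        return self.brier_sub > self.brier_comp and self.auc_sub < self.auc_comp


def run_audit(
    seed: int,
    model_kind: str = "perturbed-nomogram",
    n: int = 40_000,
    prevalence: float = 0.0715,
    batch: int = 100_000,
    region: tuple[float, float] = (0.2, 1.0),
    multiplier: float = 3.0,
    top_percent: float = 1.0,
    n_boot: int = 100,
    train_fraction: float = 1.0 / 3.0,
) -> AuditOutcome:
    """One complete audit on a fresh registry-like cohort.

    A cohort of size ``n`` is generated and split into a development part
    (used to fit the class summaries and, for the nomogram, the risk model)
    and a test pool.  ``model_kind`` selects the audited model:

    - ``"perturbed-nomogram"``: a nomogram developed on the training part,
      then given a localized overestimating tail (``multiplier`` on
      ``region``) — the failure mode the audit should flag;
    - ``"bayes"``: the generative posterior under the true cohort
      parameters, unperturbed — the null case where no subgroup should
      stand out.

    The top ``top_percent`` of U is compared with its complement over a
    stratified 20% bootstrap with ``n_boot`` replicates.
    """
    s_cohort, s_pdf, s_boot = _spawn(seed, 3)
    spec = grace_like_spec(n=n, prevalence=prevalence, seed=s_cohort)
    cohort = generate_cohort(spec)
    n_train = int(round(train_fraction * n))
    X_train = cohort.features.iloc[:n_train]
    y_train = cohort.labels[:n_train]
    X_test = cohort.features.iloc[n_train:].reset_index(drop=True)
    y_test = cohort.labels[n_train:]

    summaries = fit_class_summaries(X_train, y_train, spec.schema)
    if model_kind == "perturbed-nomogram":
        base = fit_nomogram_model(X_train, y_train, spec.schema)
        model = perturb_model(base, region, multiplier)
    elif model_kind == "nomogram":
        model = fit_nomogram_model(X_train, y_train, spec.schema)
    elif model_kind == "bayes":
        model = make_generative_posterior_model(
            spec.schema, spec.mean_pos, spec.cov_pos, spec.mean_neg, spec.cov_neg,
            prevalence,
        )
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")

    dist = estimate_score_pdfs(summaries, model, batch=batch, seed=s_pdf)
    scored = score_cohort(summaries, model, dist, X_test)
    plan = evaluation.stratified_bootstrap(y_test, n_boot=n_boot, seed=s_boot)
    comp = evaluation.compare_subgroups(
        scored["y_hat"].to_numpy(), y_test, scored["U"].to_numpy(), plan,
        top_percent=top_percent,
    )
    y_hat = scored["y_hat"].to_numpy()
    mask = comp.mask
    return AuditOutcome(
        brier_sub=float(np.nanmean(comp.brier_sub)),
        brier_comp=float(np.nanmean(comp.brier_comp)),
        auc_sub=float(np.nanmean(comp.auc_sub)),
        auc_comp=float(np.nanmean(comp.auc_comp)),
        pool_brier_sub=evaluation.normalized_brier(y_test[mask], y_hat[mask]),
        pool_brier_comp=evaluation.normalized_brier(y_test[~mask], y_hat[~mask]),
        p_brier=comp.p_brier,
        p_auc=comp.p_auc,
        converged=dist.converged,
    )


def repeated_audits(
    n_reps: int,
    seed: int,
    model_kind: str = "perturbed-nomogram",
    **kwargs,
) -> list[AuditOutcome]:
    """Run ``n_reps`` independent end-to-end audits with spawned seeds."""
    return [
        run_audit(s, model_kind=model_kind, **kwargs)
        for s in _spawn(seed, n_reps)
    ]
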