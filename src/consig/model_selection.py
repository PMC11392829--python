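"""Survival-learner registry, LOOCV and cross-cohort model selection.

A learner is a two-stage composition: an optional screening stage that
narrows the candidate genes (e.g. the univariate prognostic screen) and a
fitting stage that returns a Cox model (full fit, ridge, lasso, or stepwise
selection).  Combinations are benchmarked by Harrell's C-index on held-out
validation cohorts — each learner is fitted once on the full training
cohort and applied unchanged to every validation cohort — and by
leave-one-out cross-validation on the training cohort, where the n pooled
out-of-fold linear predictors are scored together (single left-out samples
admit no within-fold pairs).

The natively implemented fitting stages are CoxPH, ridge Cox, lasso Cox
(IRLS with cyclic coordinate descent, lambda chosen by inner 5-fold CV) and
forward/backward stepwise Cox.  The registry accepts externally supplied
learners with the same call signature, so richer ensembles can be plugged
in without changing the evaluation machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .io_model import SurvivalDataset, ValidationError
from .survival_risk import (
    CoxModel,
    concordance_index,
    fit_cox,
    stepcox_backward,
    stepcox_forward,
    univariate_screen,
)

log = logging.getLogger(__name__)

__all__ = [
    "LearnerSpec",
    "SelectionReport",
    "fit_lasso_cox",
    "default_registry",
    "loocv_linear_predictor",
    "evaluate_combinations",
    "compare_models",
]

ScreenFn = Callable[[SurvivalDataset, list[str]], list[str]]
FitFn = Callable[[SurvivalDataset, list[str]], CoxModel]


@dataclass(frozen=True)
class LearnerSpec:
    """A named screen->fit composition; ``screen`` may be None."""

    name: str
    fit: FitFn
    screen: ScreenFn | None = None

    def run(self, ds: SurvivalDataset, candidates: list[str]) -> CoxModel:
        genes = self.screen(ds, candidates) if self.screen else list(candidates)
        if not genes:
            raise ValidationError(f"{self.name}: screening left no genes")
        return self.fit(ds, genes)


@dataclass
class SelectionReport:
    """Per-learner training LOOCV and per-cohort validation C-indexes."""

    table: pd.DataFrame  # index: learner, columns: loocv, <cohorts...>, mean_validation, n_genes
    winner: str


# ---------------------------------------------------------------------------
# Native fitting stages
# ---------------------------------------------------------------------------


def _fit_full(ds: SurvivalDataset, genes: list[str]) -> CoxModel:
    X = ds.covariate_matrix(genes)
    return fit_cox(X, ds.time, ds.event, genes=genes)


def _fit_ridge(lam: float) -> FitFn:
    def fit(ds: SurvivalDataset, genes: list[str]) -> CoxModel:
        X = ds.covariate_matrix(genes)
        return fit_cox(X, ds.time, ds.event, ridge_lambda=lam, genes=genes)

    return fit


def _soft(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


def _lasso_path_fit(X, time, event, lam, beta0, max_cycles=50, tol=1e-5):
    """One lasso-Cox solve by iteratively reweighted coordinate descent."""
    from .survival_risk import _loglik_grad_hess, _sorted_arrays  # internal reuse

    Xs, ts, es = _sorted_arrays(X, time, event)
    beta = beta0.copy()
    p = X.shape[1]
    for _ in range(max_cycles):
        _, grad, info = _loglik_grad_hess(beta, Xs, ts, es)
        h = np.clip(np.diag(info), 1e-8, None)
        delta = 0.0
        for j in range(p):
            old = beta[j]
            beta[j] = _soft(h[j] * old + grad[j], lam) / h[j]
            if beta[j] != old:
                # keep the gradient coordinate-consistent within the cycle
                _, grad, info = _loglik_grad_hess(beta, Xs, ts, es)
                h = np.clip(np.diag(info), 1e-8, None)
            delta = max(delta, abs(beta[j] - old))
        if delta < tol:
            break
    return beta


def fit_lasso_cox(
    ds: SurvivalDataset,
    genes: list[str],
    n_lambdas: int = 20,
    n_folds: int = 5,
    seed: int = 0,
) -> CoxModel:
    """Lasso-penalized Cox fit with lambda chosen by inner cross-validation.

    The lambda grid is log-spaced from the smallest value zeroing every
    coefficient down to 1% of it; folds are a fixed seeded split and each
    lambda is scored by the pooled held-out C-index.  The selected support is
    refitted unpenalized so reported coefficients and p-values are standard.
    """
    X = ds.covariate_matrix(genes)
    time, event = ds.time, ds.event
    from .survival_risk import _loglik_grad_hess, _sorted_arrays

    Xs, ts, es = _sorted_arrays(X, time, event)
    _, grad0, _ = _loglik_grad_hess(np.zeros(X.shape[1]), Xs, ts, es)
    lam_max = np.abs(grad0).max()
    lambdas = np.geomspace(lam_max, 0.01 * lam_max, n_lambdas)

    rng = np.random.default_rng(seed)
    folds = rng.permuted(np.arange(len(time)) % n_folds)
    cv_score = np.zeros(n_lambdas)
    for f in range(n_folds):
        tr, te = folds != f, folds == f
        beta = np.zeros(X.shape[1])
        for i, lam in enumerate(lambdas):
            beta = _lasso_path_fit(X[tr], time[tr], event[tr], lam, beta)
            scores = X[te] @ beta
            if event[te].sum() and np.ptp(scores) > 0:
                cv_score[i] += concordance_index(scores, time[te], event[te]).cindex
            else:
                cv_score[i] += 0.5
    best_lam = lambdas[int(np.argmax(cv_score))]
    beta = _lasso_path_fit(X, time, event, best_lam, np.zeros(X.shape[1]))
    support = [g for g, b in zip(genes, beta) if b != 0.0]
    if not support:
        from .survival_risk import null_loglik

        ll0 = null_loglik(time, event)
        return CoxModel(genes=[], beta=np.zeros(0), se=np.zeros(0),
                        wald_p=np.zeros(0), loglik=ll0, aic=-2 * ll0)
    return _fit_full(ds, support)


def default_registry(alpha: float = 0.05, ridge_lambda: float = 1.0) -> list[LearnerSpec]:
    """The shipped learner registry: native fits with and without screening."""

    def screen(ds: SurvivalDataset, candidates: list[str]) -> list[str]:
        return [g for g, _, _ in univariate_screen(ds, candidates, alpha=alpha)]

    return [
        LearnerSpec("CoxPH", _fit_full),
        LearnerSpec(f"RidgeCox(lambda={ridge_lambda:g})", _fit_ridge(ridge_lambda)),
        LearnerSpec("StepCox[forward]", lambda ds, g: stepcox_forward(ds, g)),
        LearnerSpec("StepCox[backward]", lambda ds, g: stepcox_backward(ds, g)),
        LearnerSpec("UniScreen + CoxPH", _fit_full, screen),
        LearnerSpec("UniScreen + StepCox[forward]",
                    lambda ds, g: stepcox_forward(ds, g), screen),
        LearnerSpec("LassoCox", lambda ds, g: fit_lasso_cox(ds, g)),
    ]


# ---------------------------------------------------------------------------
# LOOCV and combination evaluation
# ---------------------------------------------------------------------------


def _subset(ds: SurvivalDataset, mask: np.ndarray) -> SurvivalDataset:
    return SurvivalDataset(
        expression=ds.expression.iloc[:, mask],
        time=ds.time[mask],
        event=ds.event[mask],
        cohort_id=ds.cohort_id,
    )


def loocv_linear_predictor(
    spec: LearnerSpec, ds: SurvivalDataset, candidates: list[str]
) -> np.ndarray:
    """Pooled leave-one-out linear predictors.

    Sample i's score comes from a model fitted without sample i; fold
    failures yield NaN and more than 20% of them abort the evaluation.
    """
    n = ds.n_samples
    if n < 10:
        raise ValidationError("LOOCV needs at least 10 samples")
    scores = np.full(n, np.nan)
    failures = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            model = spec.run(_subset(ds, mask), candidates)
        except (ValidationError, np.linalg.LinAlgError) as exc:
            failures += 1
            log.warning("LOOCV fold %d failed for %s: %s", i, spec.name, exc)
            continue
        if model.n_covariates == 0:
            scores[i] = 0.0
        else:
            x = ds.expression.loc[model.genes].iloc[:, i].to_numpy(dtype=float)
            scores[i] = float(x @ model.beta)
    if failures > 0.2 * n:
        raise ValidationError(f"{failures}/{n} LOOCV folds failed for {spec.name}")
    return scores


def _validation_cindex(model: CoxModel, cohort: SurvivalDataset) -> float:
    if model.n_covariates == 0:
        return 0.5
    X = cohort.covariate_matrix(model.genes)
    scores = X @ model.beta
    if np.ptp(scores) == 0:
        return 0.5
    return concordance_index(scores, cohort.time, cohort.event).cindex


def evaluate_combinations(
    registry: list[LearnerSpec],
    train: SurvivalDataset,
    validations: list[SurvivalDataset],
    candidates: list[str],
    run_loocv: bool = True,
) -> SelectionReport:
    """Fit every learner on the training cohort and rank by mean validation
    C-index (descending); ties break by fewer genes, then name."""
    if not registry or not validations:
        raise ValidationError("registry and validations must be non-empty")
    rows = {}
    for spec in registry:
        model = spec.run(train, candidates)
        row: dict[str, float] = {"n_genes": model.n_covariates}
        if run_loocv:
            oof = loocv_linear_predictor(spec, train, candidates)
            ok = ~np.isnan(oof)
            if np.ptp(oof[ok]) == 0:
                row["loocv"] = 0.5
            else:
                row["loocv"] = concordance_index(
                    oof[ok], train.time[ok], train.event[ok]
                ).cindex
        for cohort in validations:
            row[cohort.cohort_id] = _validation_cindex(model, cohort)
        row["mean_validation"] = float(
            np.mean([row[c.cohort_id] for c in validations])
        )
        rows[spec.name] = row
    table = pd.DataFrame(rows).T
    ranked = table.sort_values(
        by=["mean_validation", "n_genes"], ascending=[False, True], kind="stable"
    )
    # deterministic final tie-break on name
    top = ranked[
        (ranked["mean_validation"] == ranked["mean_validation"].iloc[0])
        & (ranked["n_genes"] == ranked["n_genes"].iloc[0])
    ]
    winner = sorted(top.index)[0]
    return SelectionReport(table=ranked, winner=winner)


def compare_models(
    models: list[tuple[str, list[str], np.ndarray]],
    cohorts: list[SurvivalDataset],
) -> pd.DataFrame:
    """C-index table for externally supplied fixed-coefficient signatures.

    Genes missing from a cohort contribute zero to the linear predictor
    (logged); a model with more than half its genes missing in a cohort gets
    NA for that cell.
    """
    out = {}
    for name, genes, beta in models:
        beta = np.asarray(beta, dtype=float)
        if len(genes) != len(beta):
            raise ValidationError(f"model {name}: gene/coefficient length mismatch")
        row = {}
        for cohort in cohorts:
            present = [g for g in genes if g in cohort.expression.index]
            if len(present) < 0.5 * len(genes):
                log.warning(
                    "model %s: %d/%d genes missing in %s -> NA",
                    name, len(genes) - len(present), len(genes), cohort.cohort_id,
                )
                row[cohort.cohort_id] = np.nan
                continue
            if len(present) < len(genes):
                log.info(
                    "model %s: %d genes missing in %s treated as zero",
                    name, len(genes) - len(present), cohort.cohort_id,
                )
            b = np.array([beta[genes.index(g)] for g in present])
            scores = cohort.covariate_matrix(present) @ b
            if np.ptp(scores) == 0:
                row[cohort.cohort_id] = 0.5
            else:
                row[cohort.cohort_id] = concordance_index(
                    scores, cohort.time, cohort.event
                ).cindex
        out[name] = row
    return pd.DataFrame(out).T
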