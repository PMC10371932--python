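"""Recalibration and update of an externally derived logistic risk model.

Three nested corrections of a published model on a new cohort, all fitted by
maximum likelihood through one shared routine so the deviance nesting
``refit <= slope <= in-the-large <= external`` holds numerically:

* calibration-in-the-large — ``logit(p') = alpha + logit(p)``: a new
  intercept with the original linear predictor as a fixed offset, correcting
  average risk only;
* logistic recalibration (calibration slope) — ``logit(p'') = alpha +
  beta * logit(p)``: intercept plus a multiplier that compresses or expands
  the risk spread;
* model update (refit) — the same covariates, all coefficients re-estimated
  on the new cohort, reported with Wald standard errors, p-values and odds
  ratios.

``run_validation_ladder`` chains external validation and the three fits into
ordered validation reports with likelihood-ratio tests between rungs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .errors import ConvergenceError, ModelSpecError, ValidationInputError
from .metrics import (
    BootstrapSettings,
    TestResult,
    ValidationReport,
    likelihood_ratio_test,
    residual_deviance,
    validation_report,
)
from .model import (
    ModelSpec,
    Predictions,
    _TRANSFORMS,
    compute_logit,
    jaccess_model,
    score_cohort,
)

_Z95 = 1.96  # normal quantile used for the printed 95% Wald intervals

DEFAULT_COVARIATES = ("diabetes", "age", "sss", "lvef")
DEFAULT_TRANSFORMS = {"sss": "sss_category"}


@dataclass(frozen=True)
class CoefficientEstimate:
    """One fitted coefficient with Wald inference on the odds-ratio scale.

    ``odds_ratio = exp(estimate)`` and ``or_ci = exp(estimate +/- 1.96 SE)``
    are derived in the constructor and always consistent with the estimate.
    """

    name: str
    estimate: float
    se: float
    p_value: float = field(init=False)
    odds_ratio: float = field(init=False)
    or_low: float = field(init=False)
    or_high: float = field(init=False)

    def __post_init__(self):
        if self.se < 0:
            raise ValidationInputError("standard error must be >= 0")
        z = self.estimate / self.se if self.se > 0 else np.inf * np.sign(self.estimate)
        object.__setattr__(self, "p_value", float(2 * stats.norm.sf(abs(z))))
        with np.errstate(over="ignore"):  # an unidentified term may have inf OR bound
            object.__setattr__(self, "odds_ratio", float(np.exp(self.estimate)))
            object.__setattr__(self, "or_low", float(np.exp(self.estimate - _Z95 * self.se)))
            object.__setattr__(self, "or_high", float(np.exp(self.estimate + _Z95 * self.se)))


@dataclass
class MLEFit:
    """Raw output of the shared binomial maximum-likelihood routine."""

    params: np.ndarray
    se: np.ndarray
    deviance: float
    df_resid: int
    iterations: int
    converged: bool
    fitted: np.ndarray
    names: list[str]


@dataclass
class RecalibrationResult:
    """A fitted recalibration or update, with enough to re-score a cohort."""

    mode: str  # in_the_large | slope | refit
    alpha: float
    beta: float
    deviance: float
    df: int
    converged: bool
    iterations: int
    model: ModelSpec | None = None
    coefficients: list[CoefficientEstimate] | None = None

    def apply(self, logit: np.ndarray) -> np.ndarray:
        """Recalibrated linear predictor alpha + beta * logit."""
        return self.alpha + self.beta * np.asarray(logit, dtype=float)


# -- shared maximizer ------------------------------------------------------


def fit_logistic_mle(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray | None = None,
    names: Sequence[str] | None = None,
    maxiter: int = 100,
) -> MLEFit:
    """Binomial GLM by IRLS with an optional fixed per-row offset.

    The single likelihood maximizer behind all three fits. Standard errors
    come from the inverse observed information. Non-convergence, rank
    deficiency and (quasi-)separation raise, never warn silently.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    n, k = X.shape
    if n <= k:
        raise ValidationInputError(f"need more observations ({n}) than parameters ({k})")
    if np.linalg.matrix_rank(X) < k:
        # point at a culprit: a column linearly dependent on the preceding ones
        for j in range(1, k + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j:
                raise ValidationInputError(
                    f"design matrix is rank deficient at column {names[j - 1]!r}"
                )
    if y.sum() == 0 or y.sum() == n:
        raise ConvergenceError("outcome has a single class; the MLE does not exist")

    glm = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset)
    try:
        with np.errstate(all="ignore"):
            res = glm.fit(maxiter=maxiter, tol=1e-12)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not res.converged:
        raise ConvergenceError(f"IRLS did not converge in {maxiter} iterations")
    mu = np.asarray(res.fittedvalues)
    score = X.T @ (y - mu)
    tol = 1e-6 * max(1.0, float(np.abs(X).max()))
    if np.abs(score).max() > tol:
        raise ConvergenceError(
            f"score equations unsatisfied (max |score| = {np.abs(score).max():.3g})"
        )
    return MLEFit(
        params=np.asarray(res.params, dtype=float),
        se=np.asarray(res.bse, dtype=float),
        deviance=float(res.deviance),
        df_resid=n - k,
        iterations=len(res.fit_history["deviance"]) - 1,
        converged=True,
        fitted=mu,
        names=names,
    )


# -- the three fits --------------------------------------------------------


def fit_calibration_in_the_large(predictions: Predictions) -> RecalibrationResult:
    """New intercept only; the original logit enters as a fixed offset.

    The intercept's score equation forces the mean recalibrated probability
    to equal the observed event rate.
    """
    n = len(predictions)
    fit = fit_logistic_mle(
        np.ones((n, 1)),
        predictions.mace,
        offset=predictions.logit,
        names=["alpha"],
    )
    return RecalibrationResult(
        mode="in_the_large",
        alpha=float(fit.params[0]),
        beta=1.0,
        deviance=fit.deviance,
        df=n - 1,
        converged=fit.converged,
        iterations=fit.iterations,
    )


def fit_logistic_recalibration(predictions: Predictions) -> RecalibrationResult:
    """Calibration slope: outcome regressed on the original linear predictor."""
    if np.ptp(predictions.logit) == 0:
        raise ValidationInputError("logits are constant; the slope is unidentified")
    n = len(predictions)
    X = np.column_stack([np.ones(n), predictions.logit])
    fit = fit_logistic_mle(X, predictions.mace, names=["alpha", "beta"])
    return RecalibrationResult(
        mode="slope",
        alpha=float(fit.params[0]),
        beta=float(fit.params[1]),
        deviance=fit.deviance,
        df=n - 2,
        converged=fit.converged,
        iterations=fit.iterations,
    )


def build_design(
    cohort: CohortTable,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    transforms: dict[str, str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Intercept-first design matrix with per-covariate transforms applied."""
    transforms = DEFAULT_TRANSFORMS if transforms is None else transforms
    cols = [np.ones(cohort.n)]
    for name in covariates:
        if name not in cohort.frame.columns:
            raise ModelSpecError(f"covariate {name!r} not found in cohort columns")
        tag = transforms.get(name, "identity")
        cols.append(_TRANSFORMS[tag](cohort.frame[name].to_numpy()))
    return np.column_stack(cols), ["intercept", *covariates]


def refit_model(
    cohort: CohortTable,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    transforms: dict[str, str] | None = None,
) -> RecalibrationResult:
    """Full model update: re-estimate every coefficient on this cohort.

    Extra named covariates present in the cohort can simply be appended to
    ``covariates`` (extended update); they flow through the same fit.
    """
    transforms = DEFAULT_TRANSFORMS if transforms is None else transforms
    X, names = build_design(cohort, covariates, transforms)
    fit = fit_logistic_mle(X, cohort.frame["mace"].to_numpy(), names=names)
    estimates = [
        CoefficientEstimate(name, float(b), float(s))
        for name, b, s in zip(fit.names, fit.params, fit.se)
    ]
    spec = ModelSpec(
        intercept=float(fit.params[0]),
        coefficients={n: float(b) for n, b in zip(names[1:], fit.params[1:])},
        transforms={k: v for k, v in transforms.items() if k in covariates},
        scale="fraction",
    )
    return RecalibrationResult(
        mode="refit",
        alpha=float(fit.params[0]),
        beta=float("nan"),
        deviance=fit.deviance,
        df=fit.df_resid,
        converged=fit.converged,
        iterations=fit.iterations,
        model=spec,
        coefficients=estimates,
    )


def recalibrated_model(base: ModelSpec, result: RecalibrationResult) -> ModelSpec:
    """Fold alpha/beta into the base model so the recalibrated model re-scores.

    ``alpha + beta * (b0 + sum b_j x_j)`` is itself a linear predictor with
    intercept ``alpha + beta*b0`` and coefficients ``beta*b_j``.
    """
    if result.mode == "refit":
        assert result.model is not None
        return result.model
    return ModelSpec(
        intercept=result.alpha + result.beta * base.intercept,
        coefficients={k: result.beta * v for k, v in base.coefficients.items()},
        transforms=dict(base.transforms),
        scale=base.scale,
    )


# -- the ladder ------------------------------------------------------------

LADDER_ORDER = ("external", "in_the_large", "slope", "refit")


@dataclass
class LadderResult:
    """External validation plus the three nested corrections, in order."""

    reports: dict[str, ValidationReport]
    fits: dict[str, RecalibrationResult]
    lrts: dict[str, TestResult]
    base_model: ModelSpec

    def deviances(self) -> dict[str, float]:
        return {k: r.deviance for k, r in self.reports.items()}


def run_validation_ladder(
    cohort: CohortTable,
    model: ModelSpec | None = None,
    *,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    transforms: dict[str, str] | None = None,
    settings: BootstrapSettings | None = None,
    span: float = 0.75,
    groups: int = 10,
) -> LadderResult:
    """Score, validate, recalibrate (both forms) and refit on one cohort.

    Deviance degrees of freedom follow the external-validation convention:
    n for the fixed external model, then n-1, n-2 and n-1-#covariates down
    the ladder. LRTs compare each correction against the external model,
    plus the slope-vs-refit comparison.
    """
    model = model or jaccess_model()
    settings = settings or BootstrapSettings()
    pred_ext = score_cohort(cohort, model)
    k = len(covariates)

    fit_itl = fit_calibration_in_the_large(pred_ext)
    fit_slope = fit_logistic_recalibration(pred_ext)
    fit_refit = refit_model(cohort, covariates, transforms)

    y = cohort.frame["mace"].to_numpy()
    preds = {
        "external": pred_ext,
        "in_the_large": Predictions.from_logits(fit_itl.apply(pred_ext.logit), y),
        "slope": Predictions.from_logits(fit_slope.apply(pred_ext.logit), y),
        "refit": score_cohort(cohort, fit_refit.model),
    }
    n_params = {"external": 0, "in_the_large": 1, "slope": 2, "refit": 1 + k}

    dev_ext, _ = residual_deviance(pred_ext)
    lrts = {
        "in_the_large_vs_external": likelihood_ratio_test(dev_ext, fit_itl.deviance, 1),
        "slope_vs_external": likelihood_ratio_test(dev_ext, fit_slope.deviance, 2),
        "refit_vs_external": likelihood_ratio_test(dev_ext, fit_refit.deviance, 1 + k),
        "refit_vs_slope": likelihood_ratio_test(
            fit_slope.deviance, fit_refit.deviance, k - 1
        ),
    }
    per_rung_lrt = {
        "external": None,
        "in_the_large": lrts["in_the_large_vs_external"],
        "slope": lrts["slope_vs_external"],
        "refit": lrts["refit_vs_external"],
    }

    reports = {}
    for i, mode in enumerate(LADDER_ORDER):
        reports[mode] = validation_report(
            preds[mode],
            label=f"{cohort.label}:{mode}",
            n_params=n_params[mode],
            settings=BootstrapSettings(
                resamples=settings.resamples,
                seed=settings.seed + i,
                max_retries=settings.max_retries,
            ),
            span=span,
            groups=groups,
            lrt_vs_external=per_rung_lrt[mode],
        )
    fits = {"in_the_large": fit_itl, "slope": fit_slope, "refit": fit_refit}
    return LadderResult(reports=reports, fits=fits, lrts=lrts, base_model=model)


def table3_frame(result: RecalibrationResult) -> pd.DataFrame:
    """Coefficient table of a refit: estimate, SE, Wald p, odds ratio with CI."""
    if result.coefficients is None:
        raise ValidationInputError("not a refit result")
    rows = []
    for ce in result.coefficients:
        rows.append(
            {
                "term": ce.name,
                "estimate": ce.estimate,
                "se": ce.se,
                "p_value": ce.p_value,
                "odds_ratio": np.nan if ce.name == "intercept" else ce.odds_ratio,
                "or_low": np.nan if ce.name == "intercept" else ce.or_low,
                "or_high": np.nan if ce.name == "intercept" else ce.or_high,
            }
        )
    return pd.DataFrame(rows)
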