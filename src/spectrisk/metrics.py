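"""Performance and calibration statistics for externally validated risk models.

Everything a model-validation report needs from a vector of predicted
probabilities paired with binary outcomes: marginal event rate, concordance
(C-statistic), Brier score, residual deviance, likelihood-ratio tests,
Hosmer-Lemeshow goodness of fit on risk deciles, decile calibration with a
least-squares line and R-squared, loess calibration curves with the d_max /
d_mean discrepancy summaries, percentile-bootstrap confidence intervals, and
two-group descriptive comparisons (Student t / chi-square).

Conventions that printed values depend on:

* Quantile bins are formed on the sorted order of predicted probabilities,
  left-closed / right-open, with tied predictions kept together in the lower
  bin, so bin sizes may be unequal.
* The Hosmer-Lemeshow statistic uses variance-corrected expected counts,
  ``(O-E)^2 / (E (1 - E/n_bin))`` summed over bins, with ``df = bins - 2``.
* Concordance gives tied pairs half credit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .errors import DegenerateStatisticError, ValidationInputError
from .model import Predictions


# -- result containers -----------------------------------------------------


@dataclass(frozen=True)
class TestResult:
    """A chi-square-style test: statistic, degrees of freedom, two-sided p."""

    statistic: float
    df: int
    p_value: float

    def __post_init__(self):
        if self.df < 1:
            raise ValidationInputError("test needs df >= 1")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationInputError("p-value outside [0, 1]")


@dataclass(frozen=True)
class DecileCalibration:
    """Mean predicted vs observed event proportion per risk bin, with an OLS line."""

    pred_mean: np.ndarray
    obs_rate: np.ndarray
    count: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    p_value: float


@dataclass(frozen=True)
class CalibrationCurve:
    """Loess-calibrated observed probability against predicted probability.

    ``d_max`` and ``d_mean`` are the maximum and mean absolute difference
    between each patient's predicted probability and its loess-smoothed
    observed counterpart; ``span`` records the smoothing fraction used.
    """

    grid_pred: np.ndarray
    grid_loess: np.ndarray
    d_max: float
    d_mean: float
    span: float
    d_max_ci: tuple[float, float] | None = None
    d_mean_ci: tuple[float, float] | None = None


@dataclass(frozen=True)
class BootstrapSettings:
    """Patient-level resampling plan for confidence intervals."""

    resamples: int = 1000
    seed: int = 0
    interval: str = "percentile"
    max_retries: int = 100

    def __post_init__(self):
        if self.resamples < 0:
            raise ValidationInputError("resamples must be >= 0")
        if self.interval != "percentile":
            raise ValidationInputError("only the percentile interval is implemented")


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    low: float
    high: float


@dataclass
class ValidationReport:
    """All per-model statistics of a validation run (one ladder rung)."""

    label: str
    n: int
    events: int
    marginal_p: float
    deviance: float
    df: int
    c_statistic: float
    brier: float
    hosmer_lemeshow: TestResult
    deciles: DecileCalibration
    curve: CalibrationCurve
    c_ci: tuple[float, float] | None = None
    brier_ci: tuple[float, float] | None = None
    lrt_vs_external: TestResult | None = None
    extra: dict = field(default_factory=dict)


# -- elementary statistics -------------------------------------------------


def marginal_probability(predictions: Predictions) -> float:
    """Cohort-wide event proportion, events / n."""
    return float(np.mean(predictions.mace))


def c_statistic(predictions: Predictions) -> float:
    """Concordance: P(event patient ranks above non-event patient), ties 0.5.

    Computed with midranks (Mann-Whitney form), identical to the explicit
    double loop over all event/non-event pairs.
    """
    y = predictions.mace
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise DegenerateStatisticError(
            "concordance needs at least one event and one non-event"
        )
    ranks = stats.rankdata(predictions.p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def brier_score(predictions: Predictions) -> float:
    """Mean squared difference between predicted probability and outcome."""
    return float(np.mean((predictions.p - predictions.mace) ** 2))


def residual_deviance(predictions: Predictions, n_params: int = 0) -> tuple[float, int]:
    """Binomial residual deviance and its degrees of freedom.

    ``-2 * sum[y log p + (1-y) log(1-p)]`` with ``df = n - n_params``, where
    ``n_params`` counts parameters estimated on this cohort: 0 for a fixed
    external model, 1 for calibration-in-the-large, 2 for the calibration
    slope, 1 + #covariates for a full refit.
    """
    p, y = predictions.p, predictions.mace
    # Predictions already guarantees p strictly inside (0, 1)
    dev = -2.0 * float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    return dev, len(p) - n_params


def likelihood_ratio_test(
    dev_restricted: float, dev_full: float, df_diff: int
) -> TestResult:
    """LRT between nested fits from their residual deviances."""
    if df_diff < 1:
        raise ValidationInputError("LRT needs df >= 1")
    statistic = dev_restricted - dev_full
    if statistic < -1e-8:
        raise ValidationInputError(
            "restricted deviance below full deviance: models are not nested"
        )
    statistic = max(statistic, 0.0)
    return TestResult(statistic, df_diff, float(stats.chi2.sf(statistic, df_diff)))


# -- risk-sorted binning ---------------------------------------------------


def _quantile_bin_edges(p_sorted: np.ndarray, groups: int) -> list[int]:
    """Split positions for ``groups`` quantile bins over sorted predictions.

    Tied predictions never straddle a boundary: the whole tied run stays in
    the lower bin. Returns strictly increasing edge positions ending at n;
    empty bins collapse, so fewer than ``groups`` bins may come back.
    """
    n = len(p_sorted)
    edges: list[int] = []
    prev = 0
    for i in range(1, groups + 1):
        b = int(round(n * i / groups))
        while 0 < b < n and p_sorted[b] == p_sorted[b - 1]:
            b += 1
        if b > prev:
            edges.append(b)
            prev = b
    if edges[-1] != n:  # pragma: no cover - guaranteed by construction
        edges[-1] = n
    return edges


def _binned(predictions: Predictions, groups: int):
    order = np.argsort(predictions.p, kind="mergesort")
    ps = predictions.p[order]
    ys = predictions.mace[order]
    edges = _quantile_bin_edges(ps, groups)
    start = 0
    bins = []
    for stop in edges:
        bins.append((ps[start:stop], ys[start:stop]))
        start = stop
    return bins


def hosmer_lemeshow(predictions: Predictions, groups: int = 10) -> TestResult:
    """Hosmer-Lemeshow goodness of fit on risk-sorted quantile bins.

    Statistic: sum over bins of (O - E)^2 / (E (1 - E/n_bin)); df = bins - 2.
    """
    if groups < 2:
        raise ValidationInputError("Hosmer-Lemeshow needs at least 2 groups")
    if len(predictions) < groups:
        raise ValidationInputError("need n >= groups")
    if len(np.unique(predictions.p)) < 2:
        raise ValidationInputError("need at least 2 distinct predicted values")
    bins = _binned(predictions, groups)
    if len(bins) < 3:
        raise ValidationInputError(
            "ties collapsed the bins below 3; use fewer groups"
        )
    chi2 = 0.0
    for pb, yb in bins:
        nb = len(pb)
        e = float(pb.sum())
        o = float(yb.sum())
        denom = e * (1.0 - e / nb)
        if denom <= 0:
            raise ValidationInputError(
                "zero expected count in a bin; use fewer groups"
            )
        chi2 += (o - e) ** 2 / denom
    df = len(bins) - 2
    return TestResult(chi2, df, float(stats.chi2.sf(chi2, df)))


def decile_calibration(predictions: Predictions, groups: int = 10) -> DecileCalibration:
    """Observed vs predicted event proportion per risk decile with an OLS fit.

    The line is ordinary least squares through the (mean predicted, observed)
    bin points; R-squared and its F-test p-value quantify linearity.
    """
    if len(predictions) < groups:
        raise ValidationInputError("need n >= number of bins")
    if len(np.unique(predictions.p)) < groups:
        warnings.warn(
            "fewer distinct predictions than bins; tied bins were collapsed",
            stacklevel=2,
        )
    bins = _binned(predictions, groups)
    pred_mean = np.array([pb.mean() for pb, _ in bins])
    obs_rate = np.array([yb.mean() for _, yb in bins])
    count = np.array([len(pb) for pb, _ in bins])
    if len(bins) < 3:
        raise ValidationInputError("need at least 3 bins for a calibration line")
    fit = stats.linregress(pred_mean, obs_rate)
    return DecileCalibration(
        pred_mean=pred_mean,
        obs_rate=obs_rate,
        count=count,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
    )


def loess_calibration(predictions: Predictions, span: float = 0.75) -> CalibrationCurve:
    """Loess-smoothed observed probability vs predicted, with d_max / d_mean.

    Degree-1 locally weighted regression (tricube kernel, no robustness
    iterations) of the binary outcome on the predicted probability; the
    smoothed curve is clipped to [0, 1].
    """
    if not 0 < span <= 1:
        raise ValidationInputError("span must lie in (0, 1]")
    if len(predictions) < 30:
        raise ValidationInputError("loess calibration needs n >= 30")
    from statsmodels.nonparametric.smoothers_lowess import lowess

    p = predictions.p
    y = predictions.mace.astype(float)
    delta = 0.01 * (p.max() - p.min())
    fitted = lowess(y, p, frac=span, it=0, delta=delta, return_sorted=False)
    fitted = np.clip(fitted, 0.0, 1.0)
    d = np.abs(p - fitted)
    order = np.argsort(p, kind="mergesort")
    return CalibrationCurve(
        grid_pred=p[order],
        grid_loess=fitted[order],
        d_max=float(d.max()),
        d_mean=float(d.mean()),
        span=span,
    )


# -- bootstrap -------------------------------------------------------------


def bootstrap_ci(
    evaluator: Callable[[Predictions], float],
    predictions: Predictions,
    settings: BootstrapSettings,
) -> BootstrapCI:
    """Percentile bootstrap CI for a scalar statistic of the predictions.

    Patients are resampled with replacement; a resample on which the
    statistic is undefined (``DegenerateStatisticError``) is redrawn, up to
    ``settings.max_retries`` attempts per resample. Fully reproducible under
    a fixed seed.
    """
    point, low, high = _bootstrap(lambda pr: np.atleast_1d(evaluator(pr)), predictions, settings)
    return BootstrapCI(float(point[0]), float(low[0]), float(high[0]))


def _bootstrap(evaluator, predictions, settings):
    """Vector-statistic percentile bootstrap shared by report assembly."""
    rng = np.random.default_rng(settings.seed)
    n = len(predictions)
    point = np.asarray(evaluator(predictions), dtype=float)
    if settings.resamples == 0:
        return point, np.full_like(point, np.nan), np.full_like(point, np.nan)
    draws = np.empty((settings.resamples, len(point)))
    for r in range(settings.resamples):
        for _ in range(settings.max_retries):
            idx = rng.integers(0, n, n)
            try:
                draws[r] = evaluator(predictions.take(idx))
                break
            except DegenerateStatisticError:
                continue
        else:
            raise DegenerateStatisticError(
                f"statistic undefined on {settings.max_retries} consecutive resamples"
            )
    low = np.percentile(draws, 2.5, axis=0)
    high = np.percentile(draws, 97.5, axis=0)
    return point, low, high


# -- descriptive group comparison -----------------------------------------


def _is_indicator(x: np.ndarray) -> bool:
    return bool(np.all(np.isin(x, [0, 1])))


def compare_groups(
    group_a: CohortTable,
    group_b: CohortTable,
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-variable two-group comparison: Student t or chi-square, as appropriate.

    Indicator variables (values in {0, 1}) get a 2x2 chi-square test without
    continuity correction; continuous variables get a two-sample Student t
    test (pooled variance). Returns one row per variable with group summaries
    (mean +/- SD, or n (%)) and a two-sided p-value.
    """
    if variables is None:
        variables = [
            c for c in group_a.frame.columns if c != "mace" and c in group_b.frame.columns
        ]
    rows = []
    for var in variables:
        a = group_a.frame[var].to_numpy(dtype=float)
        b = group_b.frame[var].to_numpy(dtype=float)
        if _is_indicator(a) and _is_indicator(b):
            table = np.array(
                [[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]]
            )
            if np.any(table.sum(axis=0) == 0):
                stat, p, df = 0.0, 1.0, 1
            else:
                stat, p, df, _ = stats.chi2_contingency(table, correction=False)
            rows.append(
                {
                    "variable": var,
                    "kind": "indicator",
                    "group_a": f"{int(a.sum())} ({100 * a.mean():.0f}%)",
                    "group_b": f"{int(b.sum())} ({100 * b.mean():.0f}%)",
                    "statistic": float(stat),
                    "df": int(df),
                    "p_value": float(p),
                }
            )
        else:
            if np.var(a) == 0 and np.var(b) == 0:
                raise ValidationInputError(
                    f"variable {var!r} has zero variance in both groups"
                )
            stat, p = stats.ttest_ind(a, b, equal_var=True)
            rows.append(
                {
                    "variable": var,
                    "kind": "continuous",
                    "group_a": f"{a.mean():.1f} ± {a.std(ddof=1):.1f}",
                    "group_b": f"{b.mean():.1f} ± {b.std(ddof=1):.1f}",
                    "statistic": float(stat),
                    "df": int(len(a) + len(b) - 2),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)


# -- report assembly -------------------------------------------------------


def validation_report(
    predictions: Predictions,
    *,
    label: str,
    n_params: int = 0,
    settings: BootstrapSettings | None = None,
    span: float = 0.75,
    groups: int = 10,
    lrt_vs_external: TestResult | None = None,
) -> ValidationReport:
    """Assemble every per-model statistic, with joint bootstrap CIs.

    One bootstrap pass evaluates (C, Brier, d_max, d_mean) on each resample,
    so all four intervals come from the same resampling stream.
    """
    settings = settings or BootstrapSettings()
    dev, df = residual_deviance(predictions, n_params)
    curve = loess_calibration(predictions, span)

    def _joint(pr: Predictions) -> np.ndarray:
        cv = loess_calibration(pr, span)
        return np.array([c_statistic(pr), brier_score(pr), cv.d_max, cv.d_mean])

    point, low, high = _bootstrap(_joint, predictions, settings)
    have_ci = settings.resamples > 0
    curve = CalibrationCurve(
        grid_pred=curve.grid_pred,
        grid_loess=curve.grid_loess,
        d_max=curve.d_max,
        d_mean=curve.d_mean,
        span=span,
        d_max_ci=(float(low[2]), float(high[2])) if have_ci else None,
        d_mean_ci=(float(low[3]), float(high[3])) if have_ci else None,
    )
    return ValidationReport(
        label=label,
        n=len(predictions),
        events=int(predictions.mace.sum()),
        marginal_p=marginal_probability(predictions),
        deviance=dev,
        df=df,
        c_statistic=float(point[0]),
        brier=float(point[1]),
        hosmer_lemeshow=hosmer_lemeshow(predictions, groups),
        deciles=decile_calibration(predictions, groups),
        curve=curve,
        c_ci=(float(low[0]), float(high[0])) if have_ci else None,
        brier_ci=(float(low[1]), float(high[1])) if have_ci else None,
        lrt_vs_external=lrt_vs_external,
    )
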