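"""Machine- and human-readable outputs for validation runs.

JSON reports are serialized from (and validated against) the pydantic models
below, which act as the shipped schema. Plot data — decile points with error
bars, the loess band, and the predicted-probability histogram — is always
exported as CSV so a run stays useful on headless systems; rendering is the
caller's business. Every output embeds the package version, the seed, and a
hash of the run configuration, and serialization is canonical (sorted keys,
fixed float reprs), so identical configurations produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .metrics import ValidationReport
from .recalibrate import LadderResult, RecalibrationResult, table3_frame


def config_hash(config: dict) -> str:
    """Short stable digest of a run configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


# -- schema ----------------------------------------------------------------


class TestResultDoc(BaseModel):
    statistic: float
    df: int = Field(ge=1)
    p_value: float = Field(ge=0.0, le=1.0)


class DecileDoc(BaseModel):
    pred_mean: list[float]
    obs_rate: list[float]
    count: list[int]
    slope: float
    intercept: float
    r_squared: float = Field(ge=0.0, le=1.0)
    p_value: float


class CurveDoc(BaseModel):
    d_max: float = Field(ge=0.0)
    d_mean: float = Field(ge=0.0)
    span: float
    d_max_ci: Optional[tuple[float, float]] = None
    d_mean_ci: Optional[tuple[float, float]] = None


class ReportDoc(BaseModel):
    """One model's validation statistics (a Table-2-style column)."""

    label: str
    n: int
    events: int
    marginal_probability: float
    deviance: float
    df: int
    c_statistic: float
    c_ci: Optional[tuple[float, float]] = None
    brier: float
    brier_ci: Optional[tuple[float, float]] = None
    hosmer_lemeshow: TestResultDoc
    deciles: DecileDoc
    curve: CurveDoc
    lrt_vs_external: Optional[TestResultDoc] = None


class FitDoc(BaseModel):
    mode: str
    alpha: float
    beta: Optional[float] = None
    deviance: float
    df: int
    iterations: int


class ProvenanceDoc(BaseModel):
    package: str = "spectrisk"
    version: str = __version__
    seed: int
    config_hash: str


class ReportDocument(BaseModel):
    """Top-level JSON document for a validation or ladder run."""

    provenance: ProvenanceDoc
    reports: dict[str, ReportDoc]
    fits: dict[str, FitDoc] = {}
    lrts: dict[str, TestResultDoc] = {}


# -- converters ------------------------------------------------------------


def _test_doc(t) -> TestResultDoc | None:
    if t is None:
        return None
    return TestResultDoc(statistic=t.statistic, df=t.df, p_value=t.p_value)


def report_doc(report: ValidationReport) -> ReportDoc:
    d = report.deciles
    c = report.curve
    return ReportDoc(
        label=report.label,
        n=report.n,
        events=report.events,
        marginal_probability=report.marginal_p,
        deviance=report.deviance,
        df=report.df,
        c_statistic=report.c_statistic,
        c_ci=report.c_ci,
        brier=report.brier,
        brier_ci=report.brier_ci,
        hosmer_lemeshow=_test_doc(report.hosmer_lemeshow),
        deciles=DecileDoc(
            pred_mean=[float(x) for x in d.pred_mean],
            obs_rate=[float(x) for x in d.obs_rate],
            count=[int(x) for x in d.count],
            slope=d.slope,
            intercept=d.intercept,
            r_squared=d.r_squared,
            p_value=d.p_value,
        ),
        curve=CurveDoc(
            d_max=c.d_max, d_mean=c.d_mean, span=c.span,
            d_max_ci=c.d_max_ci, d_mean_ci=c.d_mean_ci,
        ),
        lrt_vs_external=_test_doc(report.lrt_vs_external),
    )


def fit_doc(fit: RecalibrationResult) -> FitDoc:
    beta = None if fit.mode == "refit" else fit.beta
    return FitDoc(
        mode=fit.mode, alpha=fit.alpha, beta=beta,
        deviance=fit.deviance, df=fit.df, iterations=fit.iterations,
    )


def document_from_ladder(ladder: LadderResult, seed: int, config: dict) -> ReportDocument:
    return ReportDocument(
        provenance=ProvenanceDoc(seed=seed, config_hash=config_hash(config)),
        reports={k: report_doc(r) for k, r in ladder.reports.items()},
        fits={k: fit_doc(f) for k, f in ladder.fits.items()},
        lrts={k: _test_doc(t) for k, t in ladder.lrts.items()},
    )


def document_from_report(report: ValidationReport, seed: int, config: dict) -> ReportDocument:
    return ReportDocument(
        provenance=ProvenanceDoc(seed=seed, config_hash=config_hash(config)),
        reports={"external": report_doc(report)},
    )


# -- writers ---------------------------------------------------------------


def write_json(doc: ReportDocument, path: str | Path) -> None:
    """Canonical JSON: sorted keys, newline-terminated — byte-stable."""
    payload = json.dumps(doc.model_dump(), sort_keys=True, indent=2)
    Path(path).write_text(payload + "\n")


def validate_report_json(path: str | Path) -> ReportDocument:
    """Parse and schema-validate a report file; raises on any violation."""
    return ReportDocument.model_validate_json(Path(path).read_text())


def _provenance_comment(doc: ReportDocument) -> str:
    p = doc.provenance
    return f"# {p.package} {p.version} seed={p.seed} config={p.config_hash}\n"


def write_decile_csv(doc: ReportDocument, path: str | Path) -> None:
    """Decile calibration points, one block per model, with binomial error bars."""
    rows = []
    for model, rep in doc.reports.items():
        d = rep.deciles
        for pm, ob, ct in zip(d.pred_mean, d.obs_rate, d.count):
            se = float(np.sqrt(max(ob * (1 - ob), 0.0) / ct)) if ct > 0 else np.nan
            rows.append(
                {"model": model, "pred_mean": pm, "obs_rate": ob, "count": ct, "obs_se": se}
            )
    frame = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(_provenance_comment(doc))
        frame.to_csv(fh, index=False, float_format="%.6g")


def write_loess_csv(ladder: LadderResult, doc: ReportDocument, path: str | Path) -> None:
    """Loess calibration curves (predicted grid vs smoothed observed)."""
    rows = []
    for model, rep in ladder.reports.items():
        c = rep.curve
        for gp, gl in zip(c.grid_pred, c.grid_loess):
            rows.append({"model": model, "pred": float(gp), "loess_obs": float(gl)})
    frame = pd.DataFrame(rows).drop_duplicates()
    with open(path, "w") as fh:
        fh.write(_provenance_comment(doc))
        frame.to_csv(fh, index=False, float_format="%.6g")


def write_histogram_csv(ladder: LadderResult, doc: ReportDocument, path: str | Path, bins: int = 20) -> None:
    """Predicted-probability histogram per model (figure lower panel data)."""
    rows = []
    for model, rep in ladder.reports.items():
        p = np.asarray(rep.curve.grid_pred)
        counts, edges = np.histogram(p, bins=bins, range=(0.0, 1.0))
        for c, lo, hi in zip(counts, edges[:-1], edges[1:]):
            rows.append({"model": model, "bin_low": lo, "bin_high": hi, "count": int(c)})
    frame = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(_provenance_comment(doc))
        frame.to_csv(fh, index=False, float_format="%.6g")


def table2_text(doc: ReportDocument) -> str:
    """Human-readable summary mirroring a per-model statistics table."""
    order = [k for k in ("external", "in_the_large", "slope", "refit") if k in doc.reports]
    order += [k for k in doc.reports if k not in order]
    lines = [_provenance_comment(doc).rstrip("\n")]

    def row(label, fmt, get):
        cells = [fmt.format(*np.atleast_1d(get(doc.reports[k]))) for k in order]
        lines.append(f"{label:<28}" + "".join(f"{c:>26}" for c in cells))

    lines.append(f"{'':<28}" + "".join(f"{k:>26}" for k in order))
    row("n", "{:d}", lambda r: r.n)
    row("events", "{:d}", lambda r: r.events)
    row("marginal probability", "{:.3f}", lambda r: r.marginal_probability)
    row("degrees of freedom", "{:d}", lambda r: r.df)
    row("residual deviance", "{:.1f}", lambda r: r.deviance)
    row("d_max", "{:.3f}", lambda r: r.curve.d_max)
    row("d_mean", "{:.3f}", lambda r: r.curve.d_mean)
    row(
        "Hosmer-Lemeshow chi2 (P)",
        "{:.1f} (P={:.3g})",
        lambda r: (r.hosmer_lemeshow.statistic, r.hosmer_lemeshow.p_value),
    )
    row("fit on deciles R2", "{:.3f}", lambda r: r.deciles.r_squared)
    row("C-statistic", "{:.3f}", lambda r: r.c_statistic)
    row("Brier score", "{:.3f}", lambda r: r.brier)

    def ci_row(label, get):
        cells = []
        for k in order:
            ci = get(doc.reports[k])
            cells.append("-" if ci is None else f"({ci[0]:.3f}, {ci[1]:.3f})")
        lines.append(f"{label:<28}" + "".join(f"{c:>26}" for c in cells))

    ci_row("  C 95% CI", lambda r: r.c_ci)
    ci_row("  Brier 95% CI", lambda r: r.brier_ci)
    if doc.lrts:
        lines.append("")
        lines.append("Likelihood-ratio tests:")
        for k, t in doc.lrts.items():
            lines.append(f"  {k:<28} chi2={t.statistic:.2f} df={t.df} P={t.p_value:.3g}")
    return "\n".join(lines) + "\n"
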