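"""Logistic risk model representation and cohort scoring.

A :class:`ModelSpec` is an intercept plus named coefficients with per-covariate
transforms. The packaged default is the published J-ACCESS three-year MACE
model for stress SPECT myocardial perfusion imaging::

    logit = -4.8125 + 0.8858*diabetes + 0.0558*age
            + 0.1941*SSS_category - 0.0475*LVEF
    p     = 1 / (1 + exp(-logit))

where ``SSS_category`` grades the summed stress score as normal (0-3),
mildly (4-8), moderately (9-13) or severely (>= 14) abnormal, coded 0-3.
The coefficient multiplies the category index, not the raw score.

Probabilities are carried internally on the fraction scale; percent is a
presentation scale only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .cohort import CohortTable, PatientRecord
from .errors import ModelSpecError, ValidationInputError

#: SSS category boundaries: scores 0-3 -> 0, 4-8 -> 1, 9-13 -> 2, >= 14 -> 3
_SSS_EDGES = np.array([4, 9, 14])

TRANSFORM_TAGS = ("identity", "sss_category")
SCALE_TAGS = ("fraction", "percent")


def categorize_sss(sss):
    """Grade a summed stress score into severity categories 0-3.

    Normal (0-3) -> 0, mildly (4-8) -> 1, moderately (9-13) -> 2,
    severely (>= 14) abnormal -> 3. Accepts scalars or arrays.
    """
    arr = np.asarray(sss)
    if np.any(arr < 0):
        raise ValidationInputError("summed stress score must be >= 0")
    cat = np.digitize(arr, _SSS_EDGES)
    if np.isscalar(sss) or arr.ndim == 0:
        return int(cat)
    return cat.astype(np.int64)


_TRANSFORMS = {
    "identity": lambda x: np.asarray(x, dtype=float),
    "sss_category": lambda x: np.asarray(categorize_sss(x), dtype=float),
}


@dataclass(frozen=True)
class ModelSpec:
    """Intercept + named coefficients + covariate transforms for a logistic model."""

    intercept: float
    coefficients: dict[str, float]
    transforms: dict[str, str] = field(default_factory=dict)
    scale: str = "fraction"

    def __post_init__(self):
        if not self.coefficients:
            raise ModelSpecError("model needs at least one coefficient")
        for name, tag in self.transforms.items():
            if name not in self.coefficients:
                raise ModelSpecError(
                    f"transform declared for {name!r}, which has no coefficient"
                )
            if tag not in TRANSFORM_TAGS:
                raise ModelSpecError(f"unknown transform {tag!r} for {name!r}")
        if self.scale not in SCALE_TAGS:
            raise ModelSpecError(f"unknown probability scale {self.scale!r}")

    def transform_for(self, name: str) -> str:
        return self.transforms.get(name, "identity")

    # -- serialization (JSON) ---------------------------------------------

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "transforms": dict(self.transforms),
            "scale": self.scale,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        try:
            return cls(
                intercept=float(d["intercept"]),
                coefficients={k: float(v) for k, v in d["coefficients"].items()},
                transforms=dict(d.get("transforms", {})),
                scale=d.get("scale", "fraction"),
            )
        except (KeyError, TypeError) as exc:
            raise ModelSpecError(f"malformed model specification: {exc}") from exc

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def jaccess_model() -> ModelSpec:
    """The packaged J-ACCESS three-year MACE model."""
    text = resources.files("spectrisk.data").joinpath("jaccess_model.json").read_text()
    return ModelSpec.from_dict(json.loads(text))


# -- scoring ---------------------------------------------------------------


def _covariate_column(data, name: str):
    """Resolve a covariate by name from a DataFrame, PatientRecord or mapping."""
    if isinstance(data, pd.DataFrame):
        if name in data.columns:
            return data[name].to_numpy()
        raise ModelSpecError(f"covariate {name!r} not found in cohort columns")
    if isinstance(data, PatientRecord):
        if hasattr(data, name):
            return getattr(data, name)
        if name in data.extras:
            return data.extras[name]
        raise ModelSpecError(f"covariate {name!r} not found on patient record")
    try:
        return data[name]
    except (KeyError, TypeError) as exc:
        raise ModelSpecError(f"covariate {name!r} not found") from exc


def compute_logit(data, model: ModelSpec):
    """Linear predictor of ``model`` for one record (scalar) or a DataFrame (array)."""
    total = model.intercept
    for name, coef in model.coefficients.items():
        x = _covariate_column(data, name)
        total = total + coef * _TRANSFORMS[model.transform_for(name)](x)
    return total


def logit_to_probability(logit, scale: str = "fraction"):
    """Inverse logit; multiplied by 100 when ``scale`` is ``'percent'``."""
    if scale not in SCALE_TAGS:
        raise ModelSpecError(f"unknown probability scale {scale!r}")
    from scipy.special import expit

    p = expit(np.asarray(logit, dtype=float))
    if scale == "percent":
        p = p * 100.0
    if np.ndim(logit) == 0:
        return float(p)
    return p


def probability_to_logit(p):
    """Analytic inverse of :func:`logit_to_probability` on the fraction scale."""
    from scipy.special import logit as _logit

    out = _logit(np.asarray(p, dtype=float))
    return float(out) if np.ndim(p) == 0 else out


class RiskPrediction(NamedTuple):
    """Per-patient linear predictor, probability (fraction scale) and outcome."""

    logit: float
    p: float
    mace: int


@dataclass(frozen=True)
class Predictions:
    """Ordered per-patient predictions paired with observed outcomes.

    ``p`` is always on the fraction scale with ``p = expit(logit)`` exactly
    by construction.
    """

    logit: np.ndarray
    p: np.ndarray
    mace: np.ndarray

    def __post_init__(self):
        logit = np.asarray(self.logit, dtype=float)
        p = np.asarray(self.p, dtype=float)
        y = np.asarray(self.mace)
        if not (len(logit) == len(p) == len(y)):
            raise ValidationInputError("logit, p and mace must have equal length")
        if len(p) == 0:
            raise ValidationInputError("predictions are empty")
        if np.any((p <= 0) | (p >= 1)):
            raise ValidationInputError("probabilities must lie strictly in (0, 1)")
        if not np.all(np.isin(y, [0, 1])):
            raise ValidationInputError("outcomes must be 0/1")
        object.__setattr__(self, "logit", logit)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "mace", np.asarray(y, dtype=np.int64))

    @classmethod
    def from_logits(cls, logit, mace) -> "Predictions":
        logit = np.asarray(logit, dtype=float)
        return cls(logit=logit, p=logit_to_probability(logit), mace=mace)

    def __len__(self) -> int:
        return len(self.p)

    def __getitem__(self, i: int) -> RiskPrediction:
        return RiskPrediction(float(self.logit[i]), float(self.p[i]), int(self.mace[i]))

    def __iter__(self) -> Iterable[RiskPrediction]:
        return (self[i] for i in range(len(self)))

    def take(self, idx) -> "Predictions":
        """Row subset / resample (used by the bootstrap)."""
        idx = np.asarray(idx)
        return Predictions(self.logit[idx], self.p[idx], self.mace[idx])


def score_cohort(cohort: CohortTable, model: ModelSpec) -> Predictions:
    """Score every patient, preserving row order."""
    logit = compute_logit(cohort.frame, model)
    return Predictions.from_logits(logit, cohort.frame["mace"].to_numpy())
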