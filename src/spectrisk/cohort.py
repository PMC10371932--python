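"""Patient-level cohort container and CSV I/O.

A cohort is one row per patient with the covariates used by the three-year
MACE risk model: ``age`` (years, >= 20 by the inclusion rule), ``diabetes``
(0/1), ``sss`` (summed stress score, integer >= 0), ``lvef`` (left-ventricular
ejection fraction in %, 0-100) and the binary ``mace`` outcome. An optional
``year`` column records the calendar year of the imaging study; any further
numeric columns are carried along as named extra covariates so that extended
model updates (risk factors beyond the core four) run through the same code
path.

Input files are comma-separated with a header row. Column names are matched
case-insensitively. Missing values are rejected outright — the modelling
pipeline performs no imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import CohortError

CORE_COLUMNS = ("age", "diabetes", "sss", "lvef", "mace")
OPTIONAL_COLUMNS = ("year",)


@dataclass
class PatientRecord:
    """One patient: model covariates, outcome, and optional extras."""

    age: float
    diabetes: int
    sss: int
    lvef: float
    mace: int
    year: int | None = None
    extras: dict[str, float] = field(default_factory=dict)


def _check_binary(series: pd.Series, name: str) -> None:
    bad = ~series.isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortError(f"column {name!r} must be 0/1; offending row {row}")


class CohortTable:
    """Validated, ordered collection of patient records backed by a DataFrame.

    Construction validates every invariant once; downstream statistics can
    then assume a clean table. Row order is preserved everywhere.
    """

    def __init__(self, frame: pd.DataFrame, label: str = "cohort"):
        if not isinstance(frame, pd.DataFrame):
            raise CohortError("expected a pandas DataFrame")
        frame = frame.copy()
        frame.columns = [str(c).strip().lower() for c in frame.columns]
        missing = [c for c in CORE_COLUMNS if c not in frame.columns]
        if missing:
            raise CohortError(f"missing required column(s): {', '.join(missing)}")
        if len(frame) == 0:
            raise CohortError("cohort is empty")

        for col in frame.columns:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            na = coerced.isna()
            if na.any():
                row = int(np.flatnonzero(na.to_numpy())[0])
                raise CohortError(
                    f"column {col!r} has a missing or non-numeric value at row {row}; "
                    "no imputation is performed"
                )
            frame[col] = coerced

        self._validate_invariants(frame)
        frame = frame.reset_index(drop=True)
        frame["diabetes"] = frame["diabetes"].astype(np.int64)
        frame["sss"] = frame["sss"].astype(np.int64)
        frame["mace"] = frame["mace"].astype(np.int64)
        if "year" in frame.columns:
            frame["year"] = frame["year"].astype(np.int64)
        self._frame = frame
        self.label = label

    @staticmethod
    def _validate_invariants(frame: pd.DataFrame) -> None:
        age = frame["age"]
        if (age < 20).any():
            row = int(np.flatnonzero((age < 20).to_numpy())[0])
            raise CohortError(f"age must be >= 20 years (inclusion rule); row {row}")
        sss = frame["sss"]
        if (sss < 0).any() or not np.allclose(sss, np.round(sss)):
            raise CohortError("sss must be a non-negative integer score")
        lvef = frame["lvef"]
        if ((lvef < 0) | (lvef > 100)).any():
            row = int(np.flatnonzero(((lvef < 0) | (lvef > 100)).to_numpy())[0])
            raise CohortError(f"lvef must lie in [0, 100] percent; row {row}")
        _check_binary(frame["mace"], "mace")
        _check_binary(frame["diabetes"], "diabetes")

    # -- accessors ---------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def n(self) -> int:
        return len(self._frame)

    def __len__(self) -> int:
        return self.n

    @property
    def extra_columns(self) -> list[str]:
        known = set(CORE_COLUMNS) | set(OPTIONAL_COLUMNS)
        return [c for c in self._frame.columns if c not in known]

    def records(self) -> Iterator[PatientRecord]:
        extras_cols = self.extra_columns
        has_year = "year" in self._frame.columns
        for row in self._frame.itertuples(index=False):
            d = row._asdict()
            yield PatientRecord(
                age=float(d["age"]),
                diabetes=int(d["diabetes"]),
                sss=int(d["sss"]),
                lvef=float(d["lvef"]),
                mace=int(d["mace"]),
                year=int(d["year"]) if has_year else None,
                extras={c: float(d[c]) for c in extras_cols},
            )

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def read_csv(cls, path: str | Path, label: str | None = None) -> "CohortTable":
        path = Path(path)
        frame = pd.read_csv(path, skipinitialspace=True, comment="#")
        return cls(frame, label=label or path.stem)

    def to_csv(self, path: str | Path) -> None:
        self._frame.to_csv(path, index=False, float_format="%.6g")

    # -- subgrouping -------------------------------------------------------

    def filter_years(self, first: int, last: int, label: str | None = None) -> "CohortTable":
        """Subcohort with ``first <= year <= last`` (temporal subgroup analysis)."""
        if "year" not in self._frame.columns:
            raise CohortError("cohort has no 'year' column; cannot split by period")
        sub = self._frame[(self._frame["year"] >= first) & (self._frame["year"] <= last)]
        if len(sub) == 0:
            raise CohortError(f"no patients with year in [{first}, {last}]")
        return CohortTable(sub, label=label or f"{self.label}:{first}-{last}")

    def split_by_year(self, cut: int) -> tuple["CohortTable", "CohortTable"]:
        """Split into (year <= cut, year > cut) subcohorts."""
        if "year" not in self._frame.columns:
            raise CohortError("cohort has no 'year' column; cannot split by period")
        lo = self._frame[self._frame["year"] <= cut]
        hi = self._frame[self._frame["year"] > cut]
        if len(lo) == 0 or len(hi) == 0:
            raise CohortError(f"year split at {cut} leaves an empty group")
        return (
            CohortTable(lo, label=f"{self.label}:<= {cut}"),
            CohortTable(hi, label=f"{self.label}:> {cut}"),
        )
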