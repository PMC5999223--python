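"""Slide-level and case-level data model with delimited-text I/O.

Two flat tables drive the whole analysis, mirroring the "one database with
values per slide, one with summation values per case" layout used during the
original data gathering:

* the **slide table** — one row per stained section with ``case_id``,
  ``region``, ``slide_id``, ``staining`` and one column per registered
  histomorphological variable (missing cells allowed);
* the **clinical table** — one row per case with demographics and the
  clinical endpoints used in the explorative models.

Reading is strict about schema (missing required columns are fatal) but
tolerant about rows: unparseable or out-of-range cells reject the offending
row and are collected as :class:`RowError` diagnostics instead of aborting
the load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variables import DEFAULT_REGIONS, STAININGS, VARIABLES_BY_NAME, VariableSpec

log = logging.getLogger(__name__)

REQUIRED_SLIDE_COLUMNS = ("case_id", "region", "slide_id", "staining")

CLINICAL_COLUMNS = (
    "case_id",
    "age",
    "sex",
    "bmi",
    "qmg_baseline",
    "qmg_drop_m12_36",
    "mms_m12_36",
    "mg_duration_months",
    "prednisone_pre_g",
    "prednisone_post_g",
)

#: Binary clinical endpoints (values restricted to {0, 1}).
BINARY_ENDPOINTS = ("qmg_drop_m12_36", "mms_m12_36")


class SchemaError(ValueError):
    """Fatal structural problem in an input table (missing column, duplicate key)."""


@dataclass(frozen=True)
class RowError:
    """Diagnostic for one rejected input row."""

    row: int  # 0-based data row index in the source file
    column: str | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f"row {self.row}" + (f", column {self.column}" if self.column else "")
        return f"{where}: {self.message}"


@dataclass(frozen=True)
class SlideRecord:
    """One slide's measurements: identity, stain and variable -> value map."""

    case_id: str
    region: str
    slide_id: str
    staining: str
    values: Mapping[str, float | str]


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-case covariates and endpoints.

    Prednisone loads are areas under the dose-time curve, in grams: before
    surgery (``prednisone_pre_g``) and over months 0-12 after surgery
    (``prednisone_post_g``).  ``qmg_drop_m12_36`` (3-point QMG drop) and
    ``mms_m12_36`` (minimal manifestation status between months 12 and 36)
    are binary.
    """

    case_id: str
    age: float
    sex: str
    bmi: float
    qmg_baseline: float
    qmg_drop_m12_36: int
    mms_m12_36: int
    mg_duration_months: float
    prednisone_pre_g: float
    prednisone_post_g: float

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"{self.case_id}: sex must be 'female' or 'male'")
        for name in BINARY_ENDPOINTS:
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{self.case_id}: {name} must be 0 or 1")
        if self.prednisone_pre_g < 0 or self.prednisone_post_g < 0:
            raise ValueError(f"{self.case_id}: prednisone loads must be nonnegative")


class CaseTable:
    """Slide-level measurements grouped by case.

    Wraps a tidy per-slide DataFrame (rows sorted by ``case_id`` then
    ``slide_id`` for determinism) together with the variable schema and any
    row-level diagnostics collected while reading.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        specs: Mapping[str, VariableSpec] | None = None,
        row_errors: Sequence[RowError] = (),
    ) -> None:
        for col in REQUIRED_SLIDE_COLUMNS:
            if col not in frame.columns:
                raise SchemaError(f"slide table lacks required column {col!r}")
        dupes = frame["slide_id"][frame["slide_id"].duplicated()]
        if len(dupes):
            raise SchemaError(f"duplicate slide_id values: {sorted(set(dupes))[:5]}")
        bad_stain = set(frame["staining"]) - set(STAININGS)
        if bad_stain:
            raise SchemaError(f"unknown stainings {sorted(bad_stain)}; allowed: {STAININGS}")
        self._df = (
            frame.sort_values(["case_id", "slide_id"], kind="mergesort").reset_index(drop=True)
        )
        self.specs: dict[str, VariableSpec] = dict(specs or VARIABLES_BY_NAME)
        self.row_errors: list[RowError] = list(row_errors)

    # -- introspection -------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        """The underlying per-slide DataFrame (copy)."""
        return self._df.copy()

    @property
    def case_ids(self) -> list[str]:
        return sorted(self._df["case_id"].unique())

    @property
    def n_cases(self) -> int:
        return self._df["case_id"].nunique()

    @property
    def variables(self) -> list[str]:
        return [c for c in self._df.columns if c in self.specs]

    def n_slides(self, case_id: str) -> int:
        return int((self._df["case_id"] == case_id).sum())

    def slides(self, case_id: str) -> list[SlideRecord]:
        sub = self._df[self._df["case_id"] == case_id]
        if sub.empty:
            raise KeyError(f"unknown case_id {case_id!r}")
        out = []
        for _, row in sub.iterrows():
            vals = {v: row[v] for v in self.variables if not _is_missing(row[v])}
            out.append(
                SlideRecord(row["case_id"], row["region"], row["slide_id"], row["staining"], vals)
            )
        return out

    def values(
        self, case_id: str, variable: str, staining: str | None = None
    ) -> np.ndarray:
        """Non-missing values of ``variable`` for one case, ordered by slide_id."""
        spec = self._spec(variable)
        if not spec.is_numeric:
            raise ValueError(f"{variable} is nominal; no numeric values")
        sub = self._df[self._df["case_id"] == case_id]
        if staining is not None:
            sub = sub[sub["staining"] == staining]
        if variable not in sub.columns:
            return np.array([], dtype=float)
        vals = pd.to_numeric(sub[variable], errors="coerce")
        return vals.dropna().to_numpy(dtype=float)

    def m_points(self, case_id: str, variable: str, staining: str | None = None) -> int:
        """Number of measurement points: slides with a non-missing value."""
        return len(self.values(case_id, variable, staining))

    def _spec(self, variable: str) -> VariableSpec:
        try:
            return self.specs[variable]
        except KeyError:
            raise KeyError(f"unknown variable {variable!r}") from None

    # -- I/O -----------------------------------------------------------
    def write_csv(self, path: str | Path, sep: str = ",") -> None:
        self._df.to_csv(path, sep=sep, index=False)


def _is_missing(value: object) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value))


def read_slide_table(
    path: str | Path,
    variable_specs: Mapping[str, VariableSpec] | None = None,
    sep: str = ",",
    regions: Iterable[str] | None = DEFAULT_REGIONS,
) -> CaseTable:
    """Read a delimited slide table into a :class:`CaseTable`.

    Rows with unparseable numerics, out-of-range values, unknown stainings
    or (when ``regions`` is given) unknown region codes are rejected and
    reported through ``CaseTable.row_errors``; missing cells are preserved
    as missing.  A missing required column raises :class:`SchemaError`.
    """
    specs = dict(variable_specs or VARIABLES_BY_NAME)
    df = pd.read_csv(
        path, sep=sep, dtype={c: str for c in REQUIRED_SLIDE_COLUMNS}
    )
    for col in REQUIRED_SLIDE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"slide table {path}: missing required column {col!r}")

    value_cols = [c for c in df.columns if c in specs]
    extra = [c for c in df.columns if c not in specs and c not in REQUIRED_SLIDE_COLUMNS]
    if extra:
        log.warning("slide table %s: ignoring unregistered columns %s", path, extra)

    errors: list[RowError] = []
    bad = np.zeros(len(df), dtype=bool)

    for i, stain in enumerate(df["staining"]):
        if stain not in STAININGS:
            errors.append(RowError(i, "staining", f"unknown staining {stain!r}"))
            bad[i] = True
    if regions is not None:
        vocab = set(regions)
        for i, reg in enumerate(df["region"]):
            if reg not in vocab:
                errors.append(RowError(i, "region", f"unknown region {reg!r}"))
                bad[i] = True
    dup = df["slide_id"].duplicated()
    for i in np.flatnonzero(dup.to_numpy()):
        errors.append(RowError(int(i), "slide_id", f"duplicate slide_id {df['slide_id'][i]!r}"))
        bad[i] = True

    for col in value_cols:
        spec = specs[col]
        if not spec.is_numeric:
            continue  # nominal: stored verbatim, never parsed
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        unparseable = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        for i in np.flatnonzero(unparseable.to_numpy()):
            errors.append(RowError(int(i), col, f"unparseable value {raw[i]!r}"))
            bad[i] = True
        out_of_range = num.notna() & ((num < spec.range_min) | (num > spec.range_max))
        for i in np.flatnonzero(out_of_range.to_numpy()):
            errors.append(
                RowError(
                    int(i),
                    col,
                    f"value {num[i]:g} outside range [{spec.range_min:g}, {spec.range_max:g}]",
                )
            )
            bad[i] = True
        df[col] = num

    if bad.any():
        log.warning("slide table %s: rejected %d row(s); see row_errors", path, int(bad.sum()))
    return CaseTable(df[~bad], specs, errors)


def read_clinical_table(path: str | Path, sep: str = ",") -> list[ClinicalRecord]:
    """Read the per-case clinical table; one record per case.

    Duplicate ``case_id`` and non-binary values in binary endpoints are
    fatal (:class:`SchemaError` / :class:`ValueError`).
    """
    df = pd.read_csv(path, sep=sep, dtype={"case_id": str, "sex": str})
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"clinical table {path}: missing required column {col!r}")
    dupes = df["case_id"][df["case_id"].duplicated()]
    if len(dupes):
        raise SchemaError(f"clinical table {path}: duplicate case_id {sorted(set(dupes))}")
    records = []
    for _, row in df.iterrows():
        records.append(
            ClinicalRecord(
                case_id=row["case_id"],
                age=float(row["age"]),
                sex=str(row["sex"]),
                bmi=float(row["bmi"]),
                qmg_baseline=float(row["qmg_baseline"]),
                qmg_drop_m12_36=_as_binary(row["qmg_drop_m12_36"], "qmg_drop_m12_36", row["case_id"]),
                mms_m12_36=_as_binary(row["mms_m12_36"], "mms_m12_36", row["case_id"]),
                mg_duration_months=float(row["mg_duration_months"]),
                prednisone_pre_g=float(row["prednisone_pre_g"]),
                prednisone_post_g=float(row["prednisone_post_g"]),
            )
        )
    return records


def _as_binary(value: object, name: str, case_id: str) -> int:
    v = float(value)  # type: ignore[arg-type]
    if v not in (0.0, 1.0):
        raise ValueError(f"{case_id}: endpoint {name} must be 0 or 1, got {value!r}")
    return int(v)


def clinical_to_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Tidy per-case DataFrame with the canonical clinical columns."""
    return pd.DataFrame([r.__dict__ for r in records], columns=list(CLINICAL_COLUMNS))


def write_clinical_table(records: Sequence[ClinicalRecord], path: str | Path, sep: str = ",") -> None:
    clinical_to_frame(records).to_csv(path, sep=sep, index=False)


def summarize_per_case(
    case_table: CaseTable, variable: str, staining: str | None = None
) -> pd.DataFrame:
    """Per-case location summaries (mean, median, mode, min-max range).

    Computed over non-missing slide values only.  Cases with no value carry
    NaN summaries but are retained.  Nominal variables are unsupported.

    Returns a DataFrame indexed by case_id with columns
    ``n, mean, median, mode, min, max``.
    """
    spec = case_table._spec(variable)
    if spec.scale == "nominal":
        raise ValueError(f"{variable} is nominal; summaries need an ordinal/interval variable")
    rows = {}
    for cid in case_table.case_ids:
        vals = case_table.values(cid, variable, staining)
        if len(vals) == 0:
            rows[cid] = dict(n=0, mean=np.nan, median=np.nan, mode=np.nan, min=np.nan, max=np.nan)
        else:
            ser = pd.Series(vals)
            rows[cid] = dict(
                n=len(vals),
                mean=float(ser.mean()),
                median=float(ser.median()),
                mode=float(ser.mode().min()),  # smallest modal value on ties
                min=float(ser.min()),
                max=float(ser.max()),
            )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "case_id"
    return out
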