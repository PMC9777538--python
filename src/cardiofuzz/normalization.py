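"""Min-max scaling of clinical variables and the patient/cohort containers.

All model mathematics runs on the unit interval; this module owns the
mapping between physical units and that scale, including the projection of
laboratory reference limits onto it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reference import FROZEN_BOUNDS, MODEL_VARIABLES

logger = logging.getLogger(__name__)

#: CSV dialect: canonical variable name -> column header.
CSV_COLUMNS: dict[str, str] = {
    "ntprobnp": "ntprobnp_pg_ml",
    "na": "na_mmol_l",
    "k": "k_mmol_l",
    "ef": "ef_pct",
    "epi_cysc": "epi_cysc_ml_min",
    "age": "age_y",
    "sex": "sex",
}


class DegenerateColumnError(ValueError):
    """A column has no spread, so min-max scaling is undefined."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (0.005 -> 0.01), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def truncate_decimals(x: float, ndigits: int = 2) -> float:
    """Drop digits beyond ``ndigits`` without rounding (52/90 -> 57.77%)."""
    factor = 10.0**ndigits
    return math.trunc(x * factor) / factor


@dataclass(frozen=True)
class NormalizationParams:
    """Per-variable [vmin, vmax] -> [0, 1] affine map."""

    variable: str
    vmin: float
    vmax: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.vmin) and math.isfinite(self.vmax)):
            raise ValueError(f"{self.variable}: non-finite normalization bounds")
        if not self.vmin < self.vmax:
            raise DegenerateColumnError(
                f"{self.variable}: vmin ({self.vmin}) must be < vmax ({self.vmax})"
            )

    @property
    def span(self) -> float:
        return self.vmax - self.vmin


@dataclass(frozen=True)
class PatientRecord:
    """One subject's raw clinical variables in physical units."""

    ntprobnp: float  # pg/mL
    na: float        # mmol/L
    k: float         # mmol/L
    ef: float        # %
    epi_cysc: float  # mL/min/1.73 m^2
    age: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        for name in ("ntprobnp", "na", "k", "ef", "epi_cysc"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"missing/non-finite value for {name!r}")
            if v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if not self.ef <= 100.0:
            raise ValueError(f"ef must lie in (0, 100], got {self.ef}")
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male', 'female' or None, got {self.sex!r}")


@dataclass
class CohortTable:
    """Ordered collection of patient records plus provenance metadata."""

    frame: pd.DataFrame
    provenance: dict = field(default_factory=lambda: {"source": "unknown"})

    def __post_init__(self) -> None:
        if len(self.frame) == 0:
            raise ValueError("cohort must be non-empty")
        missing = [v for v in MODEL_VARIABLES if v not in self.frame.columns]
        if missing:
            raise ValueError(f"cohort is missing model variables: {missing}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_records(
        cls, records: Iterable[PatientRecord], provenance: dict | None = None
    ) -> "CohortTable":
        rows = [
            {
                "ntprobnp": r.ntprobnp,
                "na": r.na,
                "k": r.k,
                "ef": r.ef,
                "epi_cysc": r.epi_cysc,
                "age": r.age,
                "sex": r.sex,
            }
            for r in records
        ]
        return cls(pd.DataFrame(rows), provenance or {"source": "records"})

    @property
    def records(self) -> list[PatientRecord]:
        out = []
        for row in self.frame.itertuples(index=False):
            age = getattr(row, "age", None)
            sex = getattr(row, "sex", None)
            out.append(
                PatientRecord(
                    ntprobnp=float(row.ntprobnp),
                    na=float(row.na),
                    k=float(row.k),
                    ef=float(row.ef),
                    epi_cysc=float(row.epi_cysc),
                    age=None if age is None or (isinstance(age, float) and math.isnan(age)) else float(age),
                    sex=None if sex is None or (isinstance(sex, float) and math.isnan(sex)) else str(sex),
                )
            )
        return out

    def column(self, variable: str) -> np.ndarray:
        if variable not in self.frame.columns:
            raise KeyError(f"unknown cohort variable {variable!r}")
        return self.frame[variable].to_numpy(dtype=float)

    def subset(self, indices: Sequence[int], provenance: dict | None = None) -> "CohortTable":
        prov = dict(provenance or self.provenance)
        return CohortTable(self.frame.iloc[list(indices)].copy(), prov)

    def to_csv(self, path: str | Path) -> None:
        out = pd.DataFrame({"id": np.arange(1, len(self) + 1)})
        for var, col in CSV_COLUMNS.items():
            if var in self.frame.columns:
                out[col] = self.frame[var].to_numpy()
            else:
                out[col] = np.nan
        out.to_csv(path, index=False, lineterminator="\n", float_format=None)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        raw = pd.read_csv(path, float_precision="round_trip")
        inverse = {col: var for var, col in CSV_COLUMNS.items()}
        missing = [
            col for var, col in CSV_COLUMNS.items()
            if var in MODEL_VARIABLES and col not in raw.columns
        ]
        if missing:
            raise ValueError(f"cohort CSV {path} is missing required columns: {missing}")
        frame = raw.rename(columns=inverse)
        keep = [v for v in CSV_COLUMNS if v in frame.columns]
        return cls(frame[keep], {"source": "file", "path": str(path)})


def fit_minmax(cohort: CohortTable, variable: str) -> NormalizationParams:
    """Fit [vmin, vmax] to the observed extremes of one cohort column."""
    col = cohort.column(variable)
    vmin, vmax = float(np.min(col)), float(np.max(col))
    if vmin == vmax:
        raise DegenerateColumnError(
            f"column {variable!r} is constant ({vmin}); min-max scaling undefined"
        )
    return NormalizationParams(variable, vmin, vmax)


def frozen_params(variable: str) -> NormalizationParams:
    """Default bounds for a model variable, frozen from the published cohort."""
    if variable not in FROZEN_BOUNDS:
        raise KeyError(f"no frozen bounds for variable {variable!r}")
    vmin, vmax = FROZEN_BOUNDS[variable]
    return NormalizationParams(variable, vmin, vmax)


def default_norm_params() -> dict[str, NormalizationParams]:
    return {v: frozen_params(v) for v in FROZEN_BOUNDS}


def normalize(value, params: NormalizationParams, clamp: bool = False):
    """Map physical values to [0, 1]; scalar in, scalar out.

    With ``clamp`` the result is pinned to [0, 1] and a warning is logged for
    out-of-range inputs; without it they raise.
    """
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{params.variable}: non-finite value passed to normalize")
    u = (arr - params.vmin) / params.span
    out_of_range = (u < 0.0) | (u > 1.0)
    if np.any(out_of_range):
        if not clamp:
            raise ValueError(
                f"{params.variable}: value outside [{params.vmin}, {params.vmax}] "
                "(pass clamp=True to pin to the boundary)"
            )
        logger.warning(
            "%s: %d value(s) outside [%s, %s] clamped to the unit interval",
            params.variable, int(np.count_nonzero(out_of_range)),
            params.vmin, params.vmax,
        )
        u = np.clip(u, 0.0, 1.0)
    return float(u) if np.isscalar(value) or arr.ndim == 0 else u


def denormalize(u, params: NormalizationParams):
    """Exact inverse of :func:`normalize` on [0, 1]."""
    arr = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{params.variable}: non-finite value passed to denormalize")
    x = params.vmin + arr * params.span
    return float(x) if np.isscalar(u) or arr.ndim == 0 else x


def reference_band_normalized(ref_limit: float, params: NormalizationParams) -> float:
    """Project a physical reference limit onto [0, 1], reported at 2 dp."""
    if ref_limit < params.vmin or ref_limit > params.vmax:
        logger.warning(
            "%s: reference limit %s outside [%s, %s]; clamping",
            params.variable, ref_limit, params.vmin, params.vmax,
        )
        ref_limit = min(max(ref_limit, params.vmin), params.vmax)
    return round_half_up(normalize(ref_limit, params), 2)
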