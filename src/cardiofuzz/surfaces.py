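"""Response surfaces over input pairs and normalized risk-band classification.

Boundary conventions: output thresholds are strict ("below" means ``<``),
stability bands are inclusive on both edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .anfis import AnfisModel, predict_batch
from .normalization import CohortTable, PatientRecord, denormalize, normalize
from .reference import (
    DEFAULT_BAND_EDGES,
    EF_REDUCED_PCT,
    EF_THRESHOLD_NORM,
    EPI_THRESHOLD_NORM,
    INPUT_VARIABLES,
)

#: The six standard surface panels: output x input pair (remaining input fixed).
STANDARD_PANELS: tuple[tuple[str, str, str], ...] = (
    ("ef", "ntprobnp", "k"),
    ("ef", "ntprobnp", "na"),
    ("ef", "na", "k"),
    ("epi_cysc", "ntprobnp", "k"),
    ("epi_cysc", "ntprobnp", "na"),
    ("epi_cysc", "na", "k"),
)


@dataclass(frozen=True)
class RiskBands:
    """Normalized stability bands and output thresholds (all configurable)."""

    k_band: tuple[float, float] = DEFAULT_BAND_EDGES["k"]
    na_band: tuple[float, float] = DEFAULT_BAND_EDGES["na"]
    bnp_band: tuple[float, float] = DEFAULT_BAND_EDGES["ntprobnp"]
    ef_threshold: float = EF_THRESHOLD_NORM
    epi_threshold: float = EPI_THRESHOLD_NORM

    def __post_init__(self) -> None:
        for name, band in (("k", self.k_band), ("na", self.na_band), ("bnp", self.bnp_band)):
            if not band[0] < band[1]:
                raise ValueError(f"{name} band must have lower < upper, got {band}")
        for name, thr in (("ef", self.ef_threshold), ("epi", self.epi_threshold)):
            if not 0.0 < thr < 1.0:
                raise ValueError(f"{name} threshold must lie in (0, 1), got {thr}")

    def to_dict(self) -> dict:
        return {
            "k_band": list(self.k_band),
            "na_band": list(self.na_band),
            "bnp_band": list(self.bnp_band),
            "ef_threshold": self.ef_threshold,
            "epi_threshold": self.epi_threshold,
        }


@dataclass
class SurfaceGrid:
    """Predicted output over a 2-predictor grid with the third input fixed."""

    output_name: str
    var_x: str
    var_y: str
    fixed_var: str
    fixed_value: float
    x_grid: np.ndarray
    y_grid: np.ndarray
    z_norm: np.ndarray      # shape (len(x_grid), len(y_grid))
    z_physical: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        xi, yi = np.meshgrid(self.x_grid, self.y_grid, indexing="ij")
        return pd.DataFrame(
            {
                "output": self.output_name,
                "var_x": self.var_x,
                "var_y": self.var_y,
                "fixed_var": self.fixed_var,
                "fixed_value": self.fixed_value,
                "x": xi.ravel(),
                "y": yi.ravel(),
                "z_norm": self.z_norm.ravel(),
                "z_physical": self.z_physical.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


def response_surface(
    model: AnfisModel,
    var_x: str,
    var_y: str,
    fixed_value: float = 0.5,
    grid_n: int = 41,
) -> SurfaceGrid:
    """Evaluate the model over a normalized grid in (var_x, var_y)."""
    if var_x == var_y:
        raise ValueError("var_x and var_y must differ")
    for v in (var_x, var_y):
        if v not in INPUT_VARIABLES:
            raise ValueError(f"unknown input variable {v!r}; expected one of {INPUT_VARIABLES}")
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    fixed_var = next(v for v in INPUT_VARIABLES if v not in (var_x, var_y))
    grid = np.linspace(0.0, 1.0, grid_n)
    xi, yi = np.meshgrid(grid, grid, indexing="ij")
    x = np.empty((grid_n * grid_n, 3))
    pos = {v: i for i, v in enumerate(INPUT_VARIABLES)}
    x[:, pos[var_x]] = xi.ravel()
    x[:, pos[var_y]] = yi.ravel()
    x[:, pos[fixed_var]] = fixed_value
    z, _ = predict_batch(model, x)
    z = z.reshape(grid_n, grid_n)
    return SurfaceGrid(
        output_name=model.output_name,
        var_x=var_x,
        var_y=var_y,
        fixed_var=fixed_var,
        fixed_value=fixed_value,
        x_grid=grid,
        y_grid=grid,
        z_norm=z,
        z_physical=denormalize(z, model.output_params),
    )


def standard_surfaces(
    model_ef: AnfisModel,
    model_epi: AnfisModel,
    fixed_value: float = 0.5,
    grid_n: int = 41,
) -> dict[str, SurfaceGrid]:
    """The six standard panels (both outputs x three input pairs)."""
    out = {}
    for output, vx, vy in STANDARD_PANELS:
        model = model_ef if output == "ef" else model_epi
        out[f"{output}__{vx}__{vy}"] = response_surface(model, vx, vy, fixed_value, grid_n)
    return out


def _in_band(u: float, band: tuple[float, float]) -> bool:
    return band[0] <= u <= band[1]


def _check_shared_normalization(model_ef: AnfisModel, model_epi: AnfisModel) -> None:
    for v in INPUT_VARIABLES:
        a, b = model_ef.input_params[v], model_epi.input_params[v]
        if (a.vmin, a.vmax) != (b.vmin, b.vmax):
            raise ValueError(f"models disagree on input normalization for {v!r}")


def classify_patient(
    record: PatientRecord,
    model_ef: AnfisModel,
    model_epi: AnfisModel,
    bands: RiskBands | None = None,
) -> dict:
    """Risk-band classification of one patient from both model predictions."""
    bands = bands or RiskBands()
    _check_shared_normalization(model_ef, model_epi)
    x = np.array(
        [
            [
                normalize(record.ntprobnp, model_ef.input_params["ntprobnp"], clamp=True),
                normalize(record.na, model_ef.input_params["na"], clamp=True),
                normalize(record.k, model_ef.input_params["k"], clamp=True),
            ]
        ]
    )
    ef_norm, _ = predict_batch(model_ef, x)
    epi_norm, _ = predict_batch(model_epi, x)
    ef_norm, epi_norm = float(ef_norm[0]), float(epi_norm[0])
    ef_phys = float(denormalize(ef_norm, model_ef.output_params))
    epi_phys = float(denormalize(epi_norm, model_epi.output_params))
    return {
        "ef_norm": ef_norm,
        "ef_pct": ef_phys,
        "epi_norm": epi_norm,
        "epi_ml_min": epi_phys,
        "cardiac_class": "serious_adverse_event" if ef_norm < bands.ef_threshold else "at_risk",
        "phenotype": "HFrEF" if ef_phys < EF_REDUCED_PCT else "HFpEF_range",
        "renal_class": "renal_failure" if epi_norm < bands.epi_threshold else "preserved",
        "k_stable": _in_band(float(x[0, 2]), bands.k_band),
        "na_stable": _in_band(float(x[0, 1]), bands.na_band),
        "bnp_in_band": _in_band(float(x[0, 0]), bands.bnp_band),
    }


def batch_report(
    cohort: CohortTable,
    model_ef: AnfisModel,
    model_epi: AnfisModel,
    bands: RiskBands | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-patient classification table plus class counts."""
    bands = bands or RiskBands()
    entries = [
        classify_patient(rec, model_ef, model_epi, bands) for rec in cohort.records
    ]
    frame = pd.DataFrame(entries)
    frame.insert(0, "id", np.arange(1, len(frame) + 1))
    summary = {
        "n": len(frame),
        "bands": bands.to_dict(),
        "cardiac_class": frame["cardiac_class"].value_counts().to_dict(),
        "phenotype": frame["phenotype"].value_counts().to_dict(),
        "renal_class": frame["renal_class"].value_counts().to_dict(),
        "k_stable": int(frame["k_stable"].sum()),
        "na_stable": int(frame["na_stable"].sum()),
        "bnp_in_band": int(frame["bnp_in_band"].sum()),
    }
    return frame, summary


def plot_surface(grid: SurfaceGrid, path: str | Path) -> None:
    """Optional heat-map rendering of one surface panel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(
        grid.x_grid, grid.y_grid, grid.z_norm.T, shading="auto", cmap="viridis"
    )
    fig.colorbar(mesh, ax=ax, label=f"{grid.output_name} (normalized)")
    ax.set_xlabel(f"{grid.var_x} (normalized)")
    ax.set_ylabel(f"{grid.var_y} (normalized)")
    ax.set_title(f"{grid.output_name} | {grid.fixed_var}={grid.fixed_value:g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
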