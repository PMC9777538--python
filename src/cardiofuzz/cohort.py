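"""Synthetic cohort generation calibrated to published summary statistics.

Predictors are drawn from bounded distributions whose truncated/censored
moments are matched to the printed per-variable mean and SD; the outputs are
produced by a latent monotone response (high natriuretic peptide and
electrolyte excursions depress both ejection fraction and filtration rate)
plus Gaussian noise, so a trained model has real structure to recover.

Two bounded families are calibrated analytically:

* ``truncated_normal`` / ``truncated_lognormal`` — the distribution is
  conditioned on the bounds.
* ``censored_lognormal`` — draws are clamped to the bounds, leaving point
  masses at the limits, as an assay with a fixed reporting range produces.
  NT-proBNP defaults to this family: its printed SD (1533.89) exceeds what
  any truncated lognormal on [10, 5000] can reach at the printed mean
  (the family frontier tops out near SD 1400), whereas a ceiling point mass
  reproduces both moments exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import log_ndtr

from .anfis import AnfisModel, predict_batch
from .normalization import (
    CohortTable,
    NormalizationParams,
    denormalize,
    frozen_params,
    normalize,
    truncate_decimals,
)
from .reference import (
    AGE_BOUNDS,
    COHORT_MALES,
    COHORT_N,
    DEFAULT_BAND_EDGES,
    FROZEN_BOUNDS,
    INPUT_VARIABLES,
    VARIABLE_TARGETS,
)

FAMILIES = ("truncated_normal", "truncated_lognormal", "censored_lognormal")

#: Relative tolerance required of the moment match.
CALIBRATION_RTOL = 0.005


class CalibrationError(ValueError):
    """Target moments are unattainable for the family within its bounds."""


@dataclass(frozen=True)
class VariableSpec:
    """Target moments and bounds for one generated variable."""

    name: str
    family: str
    target_mean: float
    target_sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"{self.name}: unknown family {self.family!r}")
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower must be < upper")
        if not (self.lower < self.target_mean < self.upper):
            raise CalibrationError(
                f"{self.name}: target mean {self.target_mean} outside bounds "
                f"({self.lower}, {self.upper})"
            )
        if self.target_sd <= 0:
            raise ValueError(f"{self.name}: target_sd must be > 0")
        if "lognormal" in self.family and self.lower <= 0:
            raise ValueError(f"{self.name}: lognormal families need a positive lower bound")


@dataclass(frozen=True)
class CalibratedVariable:
    """Underlying (log-)normal parameters whose bounded moments hit the targets."""

    spec: VariableSpec
    mu: float
    sigma: float

    def moments(self) -> tuple[float, float]:
        return _bounded_moments(self.spec, self.mu, self.sigma)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        s = self.spec
        if s.family == "truncated_normal":
            a = (s.lower - self.mu) / self.sigma
            b = (s.upper - self.mu) / self.sigma
            return stats.truncnorm.rvs(a, b, loc=self.mu, scale=self.sigma, size=n, random_state=rng)
        if s.family == "truncated_lognormal":
            a = (math.log(s.lower) - self.mu) / self.sigma
            b = (math.log(s.upper) - self.mu) / self.sigma
            y = stats.truncnorm.rvs(a, b, loc=self.mu, scale=self.sigma, size=n, random_state=rng)
            return np.exp(y)
        # censored_lognormal
        return np.clip(rng.lognormal(self.mu, self.sigma, size=n), s.lower, s.upper)


def _log_ndtr_diff(upper: float, lower: float) -> float:
    """log(Phi(upper) - Phi(lower)) computed stably."""
    hi, lo = log_ndtr(upper), log_ndtr(lower)
    return float(hi + np.log1p(-np.exp(min(lo - hi, -1e-300))))


def _bounded_moments(spec: VariableSpec, mu: float, sigma: float) -> tuple[float, float]:
    """Analytic (mean, sd) of the bounded distribution."""
    lo, hi = spec.lower, spec.upper
    if spec.family == "truncated_normal":
        a = (lo - mu) / sigma if math.isfinite(lo) else -np.inf
        b = (hi - mu) / sigma if math.isfinite(hi) else np.inf
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return float(m), float(np.sqrt(v))
    a, b = math.log(lo), math.log(hi)
    al, be = (a - mu) / sigma, (b - mu) / sigma
    if spec.family == "truncated_lognormal":
        log_z = _log_ndtr_diff(be, al)

        def raw(t: float) -> float:
            return math.exp(
                mu * t + 0.5 * sigma**2 * t**2 + _log_ndtr_diff(be - sigma * t, al - sigma * t) - log_z
            )

        m1, m2 = raw(1.0), raw(2.0)
    else:  # censored_lognormal: point masses at the bounds
        def raw(t: float) -> float:
            mid = math.exp(
                mu * t + 0.5 * sigma**2 * t**2 + _log_ndtr_diff(be - sigma * t, al - sigma * t)
            )
            return lo**t * stats.norm.cdf(al) + hi**t * stats.norm.sf(be) + mid

        m1, m2 = raw(1.0), raw(2.0)
    return m1, math.sqrt(max(m2 - m1 * m1, 0.0))


def calibrate_truncated(spec: VariableSpec, rtol: float = CALIBRATION_RTOL) -> CalibratedVariable:
    """Moment-match the underlying parameters to the target mean and SD.

    Raises :class:`CalibrationError` (naming the variable) when no parameter
    choice brings both moments within ``rtol`` relative error.
    """
    # Unbounded truncated normal degenerates to the plain normal: identity.
    if spec.family == "truncated_normal" and not (
        math.isfinite(spec.lower) or math.isfinite(spec.upper)
    ):
        return CalibratedVariable(spec, spec.target_mean, spec.target_sd)

    if spec.family == "truncated_normal":
        x0 = np.array([spec.target_mean, math.log(spec.target_sd)])
    else:
        # lognormal moment match ignoring the bounds as a starting point
        cv2 = (spec.target_sd / spec.target_mean) ** 2
        s2 = math.log1p(cv2)
        x0 = np.array([math.log(spec.target_mean) - s2 / 2, math.log(math.sqrt(s2))])

    def resid(p: np.ndarray) -> list[float]:
        m, sd = _bounded_moments(spec, p[0], math.exp(p[1]))
        return [(m - spec.target_mean) / spec.target_mean, (sd - spec.target_sd) / spec.target_sd]

    best = None
    for scale in (1.0, 0.5, 2.0):
        start = x0.copy()
        start[1] += math.log(scale)
        sol = optimize.least_squares(resid, start, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    mu, sigma = best.x[0], math.exp(best.x[1])
    err = np.abs(resid(best.x))
    if np.any(err > rtol):
        raise CalibrationError(
            f"{spec.name}: {spec.family} on [{spec.lower}, {spec.upper}] cannot reach "
            f"mean={spec.target_mean}, sd={spec.target_sd} "
            f"(best relative errors: mean {err[0]:.2%}, sd {err[1]:.2%})"
        )
    return CalibratedVariable(spec, float(mu), float(sigma))


def _band_distance(x: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    return np.maximum(0.0, np.maximum(lo - x, x - hi))


@dataclass(frozen=True)
class ResponseSpec:
    """Latent monotone map from normalized predictors to normalized outputs.

    output = clip(1 - bnp_coeff*bnp - na_coeff*dist(na, band) - k_coeff*dist(k, band) + noise)
    """

    ef_coefficients: tuple[float, float, float] = (0.7, 0.25, 0.25)
    epi_coefficients: tuple[float, float, float] = (0.7, 0.25, 0.25)
    noise_sd: float = 0.05
    na_band: tuple[float, float] = DEFAULT_BAND_EDGES["na"]
    k_band: tuple[float, float] = DEFAULT_BAND_EDGES["k"]

    def __post_init__(self) -> None:
        for name, coeffs in (("ef", self.ef_coefficients), ("epi", self.epi_coefficients)):
            if coeffs[0] <= 0:
                raise ValueError(
                    f"{name}: the NT-proBNP coefficient must be > 0 so the response "
                    "is strictly decreasing in it"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def latent(self, x_norm: np.ndarray, output: str) -> np.ndarray:
        """Noise-free response before clipping; strictly decreasing in x[:, 0]."""
        cb, cna, ck = self.ef_coefficients if output == "ef" else self.epi_coefficients
        return (
            1.0
            - cb * x_norm[:, 0]
            - cna * _band_distance(x_norm[:, 1], self.na_band)
            - ck * _band_distance(x_norm[:, 2], self.k_band)
        )

    def respond(self, x_norm: np.ndarray, output: str, rng: np.random.Generator) -> np.ndarray:
        noise = rng.normal(0.0, self.noise_sd, size=x_norm.shape[0]) if self.noise_sd else 0.0
        return np.clip(self.latent(x_norm, output) + noise, 0.0, 1.0)


def default_variable_specs() -> dict[str, VariableSpec]:
    specs = {}
    for var in INPUT_VARIABLES:
        mean, sd = VARIABLE_TARGETS[var]
        lo, hi = FROZEN_BOUNDS[var]
        family = "censored_lognormal" if var == "ntprobnp" else "truncated_normal"
        specs[var] = VariableSpec(var, family, mean, sd, lo, hi)
    specs["age"] = VariableSpec("age", "truncated_normal", *VARIABLE_TARGETS["age"], *AGE_BOUNDS)
    return specs


@dataclass(frozen=True)
class CohortSpec:
    n: int = COHORT_N
    male_count: int = COHORT_MALES
    variable_specs: dict[str, VariableSpec] = field(default_factory=default_variable_specs)
    response_spec: ResponseSpec = field(default_factory=ResponseSpec)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0 <= self.male_count <= self.n:
            raise ValueError("male_count must lie in [0, n]")
        missing = [v for v in INPUT_VARIABLES if v not in self.variable_specs]
        if missing:
            raise ValueError(f"variable_specs missing predictors: {missing}")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "male_count": self.male_count,
            "seed": self.seed,
            "variable_specs": {
                k: {
                    "name": s.name,
                    "family": s.family,
                    "target_mean": s.target_mean,
                    "target_sd": s.target_sd,
                    "lower": s.lower,
                    "upper": s.upper,
                }
                for k, s in self.variable_specs.items()
            },
            "response_spec": {
                "ef_coefficients": list(self.response_spec.ef_coefficients),
                "epi_coefficients": list(self.response_spec.epi_coefficients),
                "noise_sd": self.response_spec.noise_sd,
                "na_band": list(self.response_spec.na_band),
                "k_band": list(self.response_spec.k_band),
            },
        }


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a seed-deterministic cohort with the configured structure.

    Predictors are sampled independently from their calibrated bounded
    distributions; outputs come from the latent response plus noise and are
    clamped to their published ranges.
    """
    rng = np.random.default_rng(spec.seed)
    cols: dict[str, np.ndarray] = {}
    for var in INPUT_VARIABLES:
        cols[var] = calibrate_truncated(spec.variable_specs[var]).sample(rng, spec.n)
    x_norm = np.column_stack(
        [normalize(cols[v], frozen_params(v), clamp=True) for v in INPUT_VARIABLES]
    )
    for out, key in (("ef", "ef"), ("epi_cysc", "epi")):
        u = spec.response_spec.respond(x_norm, key, rng)
        lo, hi = FROZEN_BOUNDS[out]
        cols[out] = np.clip(denormalize(u, frozen_params(out)), lo, hi)
    if "age" in spec.variable_specs:
        cols["age"] = calibrate_truncated(spec.variable_specs["age"]).sample(rng, spec.n)
    sex = np.array(["male"] * spec.male_count + ["female"] * (spec.n - spec.male_count))
    rng.shuffle(sex)
    frame = pd.DataFrame(cols)
    frame["sex"] = sex
    return CohortTable(frame, {"source": "synthetic", "seed": spec.seed})


def summarize_cohort(cohort: CohortTable) -> dict:
    """Per-variable min/max/mean/SD plus sex percentages (truncated to 2 dp)."""
    rows = []
    for var in ("na", "k", "ntprobnp", "ef", "epi_cysc", "age"):
        if var not in cohort.frame.columns or cohort.frame[var].isna().all():
            continue
        col = cohort.column(var)
        rows.append(
            {
                "variable": var,
                "min": float(np.min(col)),
                "max": float(np.max(col)),
                "mean": float(np.mean(col)),
                "sd": float(np.std(col, ddof=1)) if len(col) > 1 else 0.0,
            }
        )
    summary = {"variables": pd.DataFrame(rows).set_index("variable")}
    if "sex" in cohort.frame.columns and cohort.frame["sex"].notna().any():
        n = len(cohort)
        male = int((cohort.frame["sex"] == "male").sum())
        summary["sex_pct"] = {
            "male": truncate_decimals(100.0 * male / n),
            "female": truncate_decimals(100.0 * (n - male) / n),
        }
    return summary


def cohort_from_model(
    model: AnfisModel,
    n: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    epi_value: float = 60.0,
) -> CohortTable:
    """Cohort whose output column is generated by a reference model.

    Inputs are uniform on the normalized cube; the model's output variable is
    its (noisy) prediction, the other output is held at a constant filler.
    Used for parameter-recovery experiments.
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, size=(n, 3))
    y, _ = predict_batch(model, x)
    if noise_sd:
        y = y + rng.normal(0.0, noise_sd, size=n)
    cols = {
        var: denormalize(x[:, i], model.input_params[var]) for i, var in enumerate(INPUT_VARIABLES)
    }
    phys = denormalize(y, model.output_params)
    # keep records valid under extreme noise draws (astronomically rare)
    if model.output_name == "ef":
        phys = np.clip(phys, 0.5, 100.0)
        cols["ef"] = phys
        cols["epi_cysc"] = np.full(n, epi_value)
    else:
        phys = np.maximum(phys, 0.5)
        cols["epi_cysc"] = phys
        cols["ef"] = np.full(n, epi_value)
    frame = pd.DataFrame(cols)
    frame["age"] = np.nan
    frame["sex"] = None
    return CohortTable(frame, {"source": "synthetic", "seed": seed, "reference_model": True})


def save_cohort_spec(spec: CohortSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(spec.to_dict(), indent=2) + "\n")
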