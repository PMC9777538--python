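"""Takagi-Sugeno fuzzy inference core: a 3-input, 27-rule, five-layer network.

Layers: (1) trapezoidal fuzzification, (2) rule firing by t-norm,
(3) strength normalization, (4) linear consequents weighted by normalized
strength, (5) summation. All quantities live on the normalized [0, 1] scale;
the embedded normalization parameters recover physical units.
"""

from __future__ import annotations

import copy
import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .normalization import NormalizationParams, default_norm_params, denormalize
from .reference import DEFAULT_BAND_EDGES, INPUT_VARIABLES, OUTPUT_VARIABLES

SCHEMA_VERSION = 1
MF_LABELS = ("low", "normal", "high")
TNORMS = ("product", "min")

DEFAULT_SHOULDER = 0.05


class UncoveredInputError(ValueError):
    """No rule fires at the given input: total strength is zero."""


class ModelSchemaError(ValueError):
    """A serialized model violates the schema or a model invariant."""


@dataclass(frozen=True)
class TrapezoidalMF:
    """Membership 0 left of a, linear up on [a,b], 1 on [b,c], linear down on [c,d].

    Degenerate breakpoints (a == b or c == d) are legal and act as step
    edges evaluating to their plateau side.
    """

    a: float
    b: float
    c: float
    d: float
    label: str = ""

    def __post_init__(self) -> None:
        pts = (self.a, self.b, self.c, self.d)
        if not all(math.isfinite(p) for p in pts):
            raise ValueError(f"MF {self.label!r}: non-finite breakpoints {pts}")
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(f"MF {self.label!r}: breakpoints must satisfy a<=b<=c<=d, got {pts}")

    def __call__(self, x):
        return trapezoid_membership(x, self)


def trapezoid_membership(x, mf: TrapezoidalMF):
    """Evaluate a trapezoidal membership function; scalar or array input."""
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite input to trapezoid_membership")
    y = np.zeros_like(arr)
    y = np.where((arr >= mf.b) & (arr <= mf.c), 1.0, y)
    if mf.b > mf.a:
        rising = (arr > mf.a) & (arr < mf.b)
        y = np.where(rising, (arr - mf.a) / (mf.b - mf.a), y)
    if mf.d > mf.c:
        falling = (arr > mf.c) & (arr < mf.d)
        y = np.where(falling, (mf.d - arr) / (mf.d - mf.c), y)
    return float(y) if np.isscalar(x) or arr.ndim == 0 else y


@dataclass(frozen=True)
class FuzzyRule:
    """One if-then rule: antecedent MF indices (1-based) and linear consequent."""

    antecedent: tuple[int, int, int]
    coefficients: tuple[float, float, float]
    bias: float | None = None

    def __post_init__(self) -> None:
        if len(self.antecedent) != 3 or any(i not in (1, 2, 3) for i in self.antecedent):
            raise ValueError(f"antecedent indices must be a triple in {{1,2,3}}, got {self.antecedent}")
        vals = list(self.coefficients) + ([self.bias] if self.bias is not None else [])
        if len(self.coefficients) != 3 or not all(math.isfinite(v) for v in vals):
            raise ValueError("rule consequent coefficients must be 3 finite numbers (+ finite bias)")


@dataclass(frozen=True)
class Prediction:
    y_norm: float
    y_physical: float
    rule_activations: np.ndarray


@dataclass
class AnfisModel:
    """3 linguistic inputs x 3 trapezoidal MFs, full 27-rule base, one output."""

    input_mfs: dict[str, tuple[TrapezoidalMF, ...]]
    rules: list[FuzzyRule]
    output_name: str
    input_params: dict[str, NormalizationParams]
    output_params: NormalizationParams
    tnorm: str = "product"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if tuple(self.input_mfs) != INPUT_VARIABLES:
            raise ModelSchemaError(
                f"input MFs must be keyed by {INPUT_VARIABLES} in order, got {tuple(self.input_mfs)}"
            )
        for var, mfs in self.input_mfs.items():
            if len(mfs) != 3:
                raise ModelSchemaError(f"input {var!r} must carry exactly 3 MFs, got {len(mfs)}")
            _check_coverage(var, mfs)
        if len(self.rules) != 27:
            raise ModelSchemaError(f"rule base must contain exactly 27 rules, got {len(self.rules)}")
        seen = {r.antecedent for r in self.rules}
        if len(seen) != 27:
            raise ModelSchemaError("every antecedent combination must appear exactly once")
        if self.output_name not in OUTPUT_VARIABLES:
            raise ModelSchemaError(f"output_name must be one of {OUTPUT_VARIABLES}, got {self.output_name!r}")
        if self.tnorm not in TNORMS:
            raise ModelSchemaError(f"tnorm must be one of {TNORMS}, got {self.tnorm!r}")
        if set(self.input_params) != set(INPUT_VARIABLES):
            raise ModelSchemaError("input normalization parameters must cover exactly the 3 inputs")

    # -- convenience views -------------------------------------------------
    @property
    def antecedent_index(self) -> np.ndarray:
        """(27, 3) array of 0-based MF indices, in rule order."""
        return np.array([r.antecedent for r in self.rules], dtype=int) - 1

    @property
    def coefficient_matrix(self) -> np.ndarray:
        """(27, 3) consequent coefficients in rule order."""
        return np.array([r.coefficients for r in self.rules], dtype=float)

    @property
    def bias_vector(self) -> np.ndarray | None:
        if all(r.bias is None for r in self.rules):
            return None
        return np.array([0.0 if r.bias is None else r.bias for r in self.rules], dtype=float)

    def copy(self) -> "AnfisModel":
        return copy.deepcopy(self)


def _check_coverage(var: str, mfs: tuple[TrapezoidalMF, ...]) -> None:
    """Exact coverage check: max membership > 0 everywhere on [0, 1].

    Memberships are piecewise linear, so checking all breakpoints plus the
    midpoints between consecutive ones is exhaustive.
    """
    pts = sorted({0.0, 1.0} | {p for mf in mfs for p in (mf.a, mf.b, mf.c, mf.d) if 0.0 <= p <= 1.0})
    probes = list(pts) + [(p + q) / 2 for p, q in zip(pts, pts[1:])]
    for x in probes:
        if max(trapezoid_membership(x, mf) for mf in mfs) <= 0.0:
            raise ModelSchemaError(f"input {var!r}: MFs leave x={x:.4f} uncovered")


def build_default_model(
    band_edges: dict[str, tuple[float, float]] | None = None,
    shoulder: float = DEFAULT_SHOULDER,
    output_name: str = "ef",
    tnorm: str = "product",
    norm_params: dict[str, NormalizationParams] | None = None,
    bias: bool = False,
) -> AnfisModel:
    """Three-MF Ruspini partition per input, anchored on normalized band edges.

    Adjacent MFs share linear ramps of half-width ``shoulder`` centred on each
    edge (ramps are shortened where they would leave [0, 1]), so memberships
    sum to one everywhere and no input is ever uncovered.
    """
    if shoulder <= 0:
        raise ValueError("shoulder must be > 0")
    edges = dict(DEFAULT_BAND_EDGES)
    if band_edges:
        edges.update(band_edges)
    params = norm_params or default_norm_params()

    input_mfs: dict[str, tuple[TrapezoidalMF, ...]] = {}
    for var in INPUT_VARIABLES:
        lo, hi = edges[var]
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"{var}: band edges must satisfy 0 <= lo < hi <= 1, got ({lo}, {hi})")
        t1 = max(lo - shoulder, 0.0)
        t2 = min(lo + shoulder, 1.0)
        t3 = max(hi - shoulder, 0.0)
        t4 = min(hi + shoulder, 1.0)
        if t2 > t3:
            raise ValueError(
                f"{var}: band ({lo}, {hi}) narrower than 2*shoulder={2 * shoulder}; ramps overlap"
            )
        input_mfs[var] = (
            TrapezoidalMF(0.0, 0.0, t1, t2, "low"),
            TrapezoidalMF(t1, t2, t3, t4, "normal"),
            TrapezoidalMF(t3, t4, 1.0, 1.0, "high"),
        )

    init = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
    rules = [
        FuzzyRule((i, j, k), init, 0.0 if bias else None)
        for i, j, k in itertools.product((1, 2, 3), repeat=3)
    ]
    return AnfisModel(
        input_mfs=input_mfs,
        rules=rules,
        output_name=output_name,
        input_params={v: params[v] for v in INPUT_VARIABLES},
        output_params=params[output_name],
        tnorm=tnorm,
    )


def membership_matrix(model: AnfisModel, x: np.ndarray) -> list[np.ndarray]:
    """Per-input membership degrees; x is (n, 3) normalized. Returns 3 x (n, 3)."""
    return [
        np.column_stack([trapezoid_membership(x[:, v], mf) for mf in model.input_mfs[var]])
        for v, var in enumerate(INPUT_VARIABLES)
    ]


def firing_strengths(x_norm, model: AnfisModel) -> np.ndarray:
    """Rule firing strengths (27,) at one normalized input triple."""
    x = np.asarray(x_norm, dtype=float).reshape(1, 3)
    return _batch_strengths(model, x)[0]


def _batch_strengths(model: AnfisModel, x: np.ndarray) -> np.ndarray:
    mu = membership_matrix(model, x)
    ant = model.antecedent_index
    picked = np.stack([mu[v][:, ant[:, v]] for v in range(3)], axis=0)  # (3, n, 27)
    if model.tnorm == "product":
        return picked.prod(axis=0)
    return picked.min(axis=0)


def normalize_strengths(strengths) -> np.ndarray:
    """Scale strengths to sum to one."""
    w = np.asarray(strengths, dtype=float)
    if np.any(w < 0):
        raise ValueError("firing strengths must be non-negative")
    total = w.sum()
    if total <= 0.0:
        raise UncoveredInputError("all 27 rule strengths are zero: input not covered by any rule")
    return w / total


def rule_consequent(x_norm, rule: FuzzyRule) -> float:
    """Linear consequent value at the crisp normalized inputs."""
    x = np.asarray(x_norm, dtype=float)
    v = float(np.dot(rule.coefficients, x))
    return v + rule.bias if rule.bias is not None else v


def predict(x_norm, model: AnfisModel) -> Prediction:
    """Full forward pass at one normalized input triple."""
    x = np.asarray(x_norm, dtype=float).reshape(1, 3)
    y, wbar = predict_batch(model, x)
    return Prediction(
        y_norm=float(y[0]),
        y_physical=float(denormalize(float(y[0]), model.output_params)),
        rule_activations=wbar[0],
    )


def predict_batch(model: AnfisModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized forward pass: x (n, 3) normalized -> (y_norm (n,), wbar (n, 27))."""
    x = np.asarray(x, dtype=float)
    w = _batch_strengths(model, x)
    total = w.sum(axis=1)
    dead = total <= 0.0
    if np.any(dead):
        raise UncoveredInputError(
            f"{int(np.count_nonzero(dead))} input(s) fire no rule (total strength 0)"
        )
    wbar = w / total[:, None]
    v = x @ model.coefficient_matrix.T
    b = model.bias_vector
    if b is not None:
        v = v + b
    return (wbar * v).sum(axis=1), wbar


# -- serialization ---------------------------------------------------------

def model_to_dict(model: AnfisModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "output_name": model.output_name,
        "tnorm": model.tnorm,
        "inputs": [
            {
                "name": var,
                "vmin": model.input_params[var].vmin,
                "vmax": model.input_params[var].vmax,
                "mfs": [
                    {"label": mf.label, "a": mf.a, "b": mf.b, "c": mf.c, "d": mf.d}
                    for mf in model.input_mfs[var]
                ],
            }
            for var in INPUT_VARIABLES
        ],
        "output": {
            "name": model.output_name,
            "vmin": model.output_params.vmin,
            "vmax": model.output_params.vmax,
        },
        "rules": [
            {"antecedent": list(r.antecedent), "coeffs": list(r.coefficients), "bias": r.bias}
            for r in model.rules
        ],
    }


def model_from_dict(payload: dict) -> AnfisModel:
    try:
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ModelSchemaError(
                f"unsupported schema_version {payload.get('schema_version')!r}; expected {SCHEMA_VERSION}"
            )
        inputs = payload["inputs"]
        input_mfs = {}
        input_params = {}
        for spec in inputs:
            name = spec["name"]
            input_mfs[name] = tuple(
                TrapezoidalMF(m["a"], m["b"], m["c"], m["d"], m.get("label", "")) for m in spec["mfs"]
            )
            input_params[name] = NormalizationParams(name, spec["vmin"], spec["vmax"])
        if set(input_mfs) == set(INPUT_VARIABLES):  # canonical key order
            input_mfs = {v: input_mfs[v] for v in INPUT_VARIABLES}
        out = payload["output"]
        rules = [
            FuzzyRule(tuple(r["antecedent"]), tuple(r["coeffs"]), r.get("bias"))
            for r in payload["rules"]
        ]
        return AnfisModel(
            input_mfs=input_mfs,
            rules=rules,
            output_name=payload["output_name"],
            input_params=input_params,
            output_params=NormalizationParams(
                out.get("name", payload["output_name"]), out["vmin"], out["vmax"]
            ),
            tnorm=payload.get("tnorm", "product"),
        )
    except (KeyError, TypeError) as exc:
        raise ModelSchemaError(f"malformed model payload: {exc!r}") from exc


def save_model(model: AnfisModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2) + "\n")


def load_model(path: str | Path) -> AnfisModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelSchemaError(f"model file {path} is not valid JSON: {exc}") from exc
    return model_from_dict(payload)


def with_coefficients(
    model: AnfisModel, coefficients: np.ndarray, bias: np.ndarray | None = None
) -> AnfisModel:
    """Return a copy of the model with replaced consequent parameters."""
    new = model.copy()
    new.rules = [
        replace(
            r,
            coefficients=tuple(float(c) for c in coefficients[i]),
            bias=None if bias is None else float(bias[i]),
        )
        for i, r in enumerate(model.rules)
    ]
    return new
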