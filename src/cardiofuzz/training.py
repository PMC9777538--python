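"""Supervised fitting of the fuzzy model: data split, MSE, backprop / hybrid.

Training operates entirely on the normalized scale. ``bp`` is full-batch
gradient descent on all trainable parameters; ``hybrid`` solves the linear
consequent subproblem by least squares each epoch and (optionally) moves the
premise breakpoints by one gradient step.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .anfis import AnfisModel, TrapezoidalMF, membership_matrix, predict_batch, with_coefficients
from .normalization import CohortTable, normalize
from .reference import INPUT_VARIABLES

__all__ = [
    "TrainingConfig",
    "FitResult",
    "TrainingDivergedError",
    "split_dataset",
    "mse",
    "fit",
    "evaluate",
]


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite; usually the learning rate is too large."""


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 1000
    mse_tol: float = 0.0005
    learning_rate: float = 0.01
    mode: str = "bp"
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 42
    train_premise: bool = True
    #: Relative singular-value cutoff for the hybrid consequent solve. Rules
    #: that barely fire in the training set span near-null directions whose
    #: unconstrained solution explodes on held-out data; singular values below
    #: this fraction of the largest are treated as null space (min-norm).
    #: None solves the pure unregularized least-squares problem.
    consequent_rcond: float | None = 0.01

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.mse_tol <= 0:
            raise ValueError("mse_tol must be > 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.mode not in ("bp", "hybrid"):
            raise ValueError(f"mode must be 'bp' or 'hybrid', got {self.mode!r}")
        f = self.split_fractions
        if len(f) != 3 or any(x < 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must be non-negative and sum to 1, got {f}")
        r = self.consequent_rcond
        if r is not None and not 0.0 <= r < 1.0:
            raise ValueError(f"consequent_rcond must be None or in [0, 1), got {r}")

    @classmethod
    def from_mapping(cls, data: dict) -> "TrainingConfig":
        known = {k: data[k] for k in cls.__dataclass_fields__ if k in data}
        if "split_fractions" in known:
            known["split_fractions"] = tuple(known["split_fractions"])
        return cls(**known)


@dataclass
class FitResult:
    mse_history: list[float]
    final_mse: dict[str, float]
    epochs_run: int
    stopped_by: str  # "tolerance" | "epoch_limit"

    def to_dict(self) -> dict:
        return asdict(self)

    def history_csv(self, path: str | Path) -> None:
        lines = ["epoch,mse"] + [f"{i + 1},{m!r}" for i, m in enumerate(self.mse_history)]
        Path(path).write_text("\n".join(lines) + "\n")


def split_dataset(
    cohort: CohortTable, config: TrainingConfig
) -> tuple[CohortTable, CohortTable, CohortTable]:
    """Seed-deterministic shuffle into train/test/check; remainder goes to train."""
    n = len(cohort)
    if n < 3:
        raise ValueError(f"need at least 3 records to split, got {n}")
    _, f_test, f_check = config.split_fractions
    n_test = int(math.floor(n * f_test))
    n_check = int(math.floor(n * f_check))
    n_train = n - n_test - n_check
    if min(n_train, n_test, n_check) == 0:
        raise ValueError(
            f"split of {n} records by fractions {config.split_fractions} leaves an empty part "
            f"(train={n_train}, test={n_test}, check={n_check})"
        )
    order = np.random.default_rng(config.seed).permutation(n)
    prov = dict(cohort.provenance)
    parts = (
        order[:n_train],
        order[n_train : n_train + n_test],
        order[n_train + n_test :],
    )
    names = ("train", "test", "check")
    return tuple(
        cohort.subset(idx, {**prov, "split": name, "split_seed": config.seed})
        for idx, name in zip(parts, names)
    )


def mse(predictions, targets) -> float:
    """Mean squared error on the normalized-output scale."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError(f"predictions and targets must share a non-zero shape, got {p.shape} vs {t.shape}")
    return float(np.mean((p - t) ** 2))


def _design(model: AnfisModel, cohort: CohortTable) -> tuple[np.ndarray, np.ndarray]:
    """Normalized input matrix (n, 3) and target vector (n,) for one cohort."""
    x = np.column_stack(
        [normalize(cohort.column(v), model.input_params[v], clamp=True) for v in INPUT_VARIABLES]
    )
    t = np.asarray(normalize(cohort.column(model.output_name), model.output_params, clamp=True))
    return x, t


def _consequent_features(wbar: np.ndarray, x: np.ndarray, bias: bool) -> np.ndarray:
    """Feature matrix of the consequent subproblem: phi[n, l, m] = wbar[n,l] * x[n,m]."""
    n = x.shape[0]
    phi = wbar[:, :, None] * x[:, None, :]  # (n, 27, 3)
    if bias:
        phi = np.concatenate([phi, wbar[:, :, None]], axis=2)
    return phi.reshape(n, -1)


def _solve_consequents(
    model: AnfisModel, x: np.ndarray, t: np.ndarray, rcond: float | None = 0.01
) -> AnfisModel:
    """Least-squares solution of the linear consequent subproblem."""
    has_bias = model.bias_vector is not None
    _, wbar = predict_batch(model, x)
    phi = _consequent_features(wbar, x, has_bias)
    theta, *_ = np.linalg.lstsq(phi, t, rcond=rcond)
    width = 4 if has_bias else 3
    theta = theta.reshape(27, width)
    coeffs = theta[:, :3]
    bias = theta[:, 3] if has_bias else None
    return with_coefficients(model, coeffs, bias)


def _premise_gradients(
    model: AnfisModel, x: np.ndarray, t: np.ndarray
) -> dict[str, np.ndarray]:
    """d(MSE)/d(breakpoints): per input variable a (3 MFs, 4 breakpoints) array.

    Memberships are piecewise linear, so gradients exist off the corners; at a
    corner the plateau-side one-sided derivative (zero) is used, implemented by
    strict inequalities on the ramp masks.
    """
    n = x.shape[0]
    mu = membership_matrix(model, x)  # 3 x (n, 3)
    ant = model.antecedent_index  # (27, 3)
    picked = np.stack([mu[v][:, ant[:, v]] for v in range(3)], axis=0)  # (3, n, 27)

    if model.tnorm == "product":
        w = picked.prod(axis=0)
    else:
        w = picked.min(axis=0)
    total = w.sum(axis=1)  # (n,)
    wbar = w / total[:, None]
    v_mat = x @ model.coefficient_matrix.T
    b = model.bias_vector
    if b is not None:
        v_mat = v_mat + b
    y = (wbar * v_mat).sum(axis=1)
    dl_dy = 2.0 * (y - t) / n
    # d y / d w_l = (V_l - y) / total
    dl_dw = dl_dy[:, None] * (v_mat - y[:, None]) / total[:, None]  # (n, 27)

    grads: dict[str, np.ndarray] = {}
    for v, var in enumerate(INPUT_VARIABLES):
        if model.tnorm == "product":
            others = [o for o in range(3) if o != v]
            dw_dmu = picked[others[0]] * picked[others[1]]  # (n, 27)
        else:
            # subgradient of min: route through the (first) attaining argument
            is_min = picked[v] == picked.min(axis=0)
            earlier = np.zeros_like(is_min) if v == 0 else (
                (picked[:v] == picked.min(axis=0)).any(axis=0)
            )
            dw_dmu = (is_min & ~earlier).astype(float)
        contrib = dl_dw * dw_dmu  # (n, 27)
        # accumulate onto the 3 MFs of this variable
        g_mu = np.zeros((n, 3))
        for m in range(3):
            cols = ant[:, v] == m
            if np.any(cols):
                g_mu[:, m] = contrib[:, cols].sum(axis=1)
        xi = x[:, v]
        g_bp = np.zeros((3, 4))
        for m, mf in enumerate(model.input_mfs[var]):
            gm = g_mu[:, m]
            if mf.b > mf.a:
                on = (xi > mf.a) & (xi < mf.b)
                den = (mf.b - mf.a) ** 2
                g_bp[m, 0] = np.sum(gm[on] * (xi[on] - mf.b) / den)
                g_bp[m, 1] = np.sum(gm[on] * -(xi[on] - mf.a) / den)
            if mf.d > mf.c:
                on = (xi > mf.c) & (xi < mf.d)
                den = (mf.d - mf.c) ** 2
                g_bp[m, 2] = np.sum(gm[on] * (mf.d - xi[on]) / den)
                g_bp[m, 3] = np.sum(gm[on] * (xi[on] - mf.c) / den)
        grads[var] = g_bp
    return grads


def _apply_premise_step(model: AnfisModel, grads: dict[str, np.ndarray], lr: float) -> None:
    """Gradient step on breakpoints followed by sort-and-clip projection."""
    for var in INPUT_VARIABLES:
        new_mfs = []
        for m, mf in enumerate(model.input_mfs[var]):
            pts = np.array([mf.a, mf.b, mf.c, mf.d]) - lr * grads[var][m]
            pts = np.clip(np.sort(pts), 0.0, 1.0)
            new_mfs.append(TrapezoidalMF(*pts, label=mf.label))
        model.input_mfs[var] = tuple(new_mfs)


def _consequent_gradients(
    model: AnfisModel, x: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray | None]:
    y, wbar = predict_batch(model, x)
    dl_dy = 2.0 * (y - t) / x.shape[0]
    grad_c = (dl_dy[:, None] * wbar).T @ x  # (27, 3)
    grad_b = None
    if model.bias_vector is not None:
        grad_b = (dl_dy[:, None] * wbar).sum(axis=0)
    return grad_c, grad_b


def fit(
    model: AnfisModel,
    train: CohortTable,
    config: TrainingConfig,
    validation: CohortTable | None = None,
) -> tuple[AnfisModel, FitResult]:
    """Train a copy of ``model``; the input model is never mutated."""
    work = model.copy()
    x, t = _design(work, train)
    history: list[float] = []
    stopped_by = "epoch_limit"

    for _ in range(config.epochs):
        if config.mode == "hybrid":
            work = _solve_consequents(work, x, t, config.consequent_rcond)
            if config.train_premise:
                grads = _premise_gradients(work, x, t)
                _apply_premise_step(work, grads, config.learning_rate)
        else:  # bp
            grad_c, grad_b = _consequent_gradients(work, x, t)
            coeffs = work.coefficient_matrix - config.learning_rate * grad_c
            bias = work.bias_vector
            if bias is not None and grad_b is not None:
                bias = bias - config.learning_rate * grad_b
            if config.train_premise:
                grads = _premise_gradients(work, x, t)
                _apply_premise_step(work, grads, config.learning_rate)
            work = with_coefficients(work, coeffs, bias)

        y, _ = predict_batch(work, x)
        epoch_mse = mse(y, t)
        if not math.isfinite(epoch_mse):
            raise TrainingDivergedError(
                f"training MSE became non-finite after {len(history) + 1} epoch(s); "
                f"reduce learning_rate (currently {config.learning_rate})"
            )
        history.append(epoch_mse)
        if epoch_mse <= config.mse_tol:
            stopped_by = "tolerance"
            break

    final: dict[str, float] = {}
    if history:
        final["train"] = history[-1]
    else:
        y, _ = predict_batch(work, x)
        final["train"] = mse(y, t)
        stopped_by = "epoch_limit"
    if validation is not None:
        xv, tv = _design(work, validation)
        yv, _ = predict_batch(work, xv)
        final["validation"] = mse(yv, tv)

    return work, FitResult(
        mse_history=history,
        final_mse=final,
        epochs_run=len(history),
        stopped_by=stopped_by,
    )


def evaluate(model: AnfisModel, test: CohortTable, check: CohortTable) -> dict:
    """Normalized-scale MSE on held-out sets plus their relative deviation (%)."""
    out: dict[str, float | None] = {}
    xt, tt = _design(model, test)
    yt, _ = predict_batch(model, xt)
    out["test_mse"] = mse(yt, tt)
    xc, tc = _design(model, check)
    yc, _ = predict_batch(model, xc)
    out["check_mse"] = mse(yc, tc)
    if out["test_mse"] == 0.0:
        out["relative_check_deviation_pct"] = None
    else:
        out["relative_check_deviation_pct"] = (
            100.0 * abs(out["check_mse"] - out["test_mse"]) / out["test_mse"]
        )
    return out


def save_fit_result(result: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")
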