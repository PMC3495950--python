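"""Feed-forward neural-network peak validator.

One hidden layer of 20 sigmoid units (plus bias) maps a standardized
62-dimensional candidate descriptor to a validity probability.  Training
minimizes L2-regularized cross-entropy (bias weights unpenalized) with
Polak-Ribiere nonlinear conjugate gradients under a Wolfe line search;
the regularization weight is chosen on a held-out validation split by
classification error.  A trained model drives the cluster-validation
procedure: for each spectrum, locate the candidate peak near the cluster
m/z, extract features, and keep the peak iff the network says so.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize

from .core_io import Spectrum, SpectrumSet
from .features import (
    DEFAULT_WINDOW_FRAC,
    FEATURE_DIM,
    FeatureScaler,
    apply_scaler,
    extract_features,
    fit_scaler,
)
from .peaks import Peak, PeakCluster, quantify_peak

__all__ = [
    "NNModel",
    "LabeledSet",
    "TrainingError",
    "forward",
    "cost",
    "gradient",
    "train",
    "select_lambda",
    "split_data",
    "evaluate_accuracy",
    "validate_cluster",
    "default_lambda_grid",
    "DEFAULT_HIDDEN_UNITS",
]

DEFAULT_HIDDEN_UNITS = 20  # plus a bias node feeding the output layer
DEFAULT_MAX_ITER = 400
_PROB_EPS = 1e-12


class TrainingError(RuntimeError):
    pass


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class NNModel:
    """Weights, scaler and regularization setting of a trained validator."""

    theta1: np.ndarray  # (hidden, d+1)
    theta2: np.ndarray  # (1, hidden+1)
    scaler: FeatureScaler | None = None
    lam: float = 0.0
    seed: int = 0
    d: int = FEATURE_DIM
    hidden_units: int = DEFAULT_HIDDEN_UNITS
    history: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta1 = np.asarray(self.theta1, float)
        self.theta2 = np.asarray(self.theta2, float)
        if self.theta1.shape != (self.hidden_units, self.d + 1):
            raise ValueError(
                f"theta1 shape {self.theta1.shape} != {(self.hidden_units, self.d + 1)}"
            )
        if self.theta2.shape != (1, self.hidden_units + 1):
            raise ValueError(
                f"theta2 shape {self.theta2.shape} != {(1, self.hidden_units + 1)}"
            )
        if not (np.all(np.isfinite(self.theta1)) and np.all(np.isfinite(self.theta2))):
            raise ValueError("non-finite weights")

    def pack(self) -> np.ndarray:
        return np.concatenate([self.theta1.ravel(), self.theta2.ravel()])

    @classmethod
    def unpack(cls, flat: np.ndarray, d: int, hidden: int, **kw) -> "NNModel":
        n1 = hidden * (d + 1)
        return cls(
            theta1=flat[:n1].reshape(hidden, d + 1),
            theta2=flat[n1:].reshape(1, hidden + 1),
            d=d,
            hidden_units=hidden,
            **kw,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "theta1": self.theta1.tolist(),
                    "theta2": self.theta2.tolist(),
                    "scaler": self.scaler.to_dict() if self.scaler else None,
                    "lambda": self.lam,
                    "seed": self.seed,
                    "d": self.d,
                    "hidden_units": self.hidden_units,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NNModel":
        d = json.loads(Path(path).read_text())
        return cls(
            theta1=np.asarray(d["theta1"]),
            theta2=np.asarray(d["theta2"]),
            scaler=FeatureScaler.from_dict(d["scaler"]) if d["scaler"] else None,
            lam=d["lambda"],
            seed=d["seed"],
            d=d["d"],
            hidden_units=d["hidden_units"],
        )


@dataclass
class LabeledSet:
    """Feature matrix with binary labels and a train/val/test assignment."""

    X: np.ndarray          # (m, d)
    t: np.ndarray          # (m,) in {0, 1}
    split: np.ndarray      # (m,) strings "train" | "val" | "test"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.t = np.asarray(self.t)
        self.split = np.asarray(self.split)
        if not set(np.unique(self.t)) <= {0, 1}:
            raise ValueError("labels must be binary")

    def subset(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.split == which
        return self.X[m], self.t[m]


def forward(x: np.ndarray, model: NNModel) -> np.ndarray | float:
    """Network output probability for one standardized vector or a matrix."""
    X = np.atleast_2d(np.asarray(x, float))
    if X.shape[1] != model.d:
        raise ValueError(f"expected {model.d} features, got {X.shape[1]}")
    A1 = np.hstack([np.ones((X.shape[0], 1)), X])
    hidden = _sigmoid(A1 @ model.theta1.T)
    A2 = np.hstack([np.ones((hidden.shape[0], 1)), hidden])
    p = _sigmoid(A2 @ model.theta2.T).ravel()
    return float(p[0]) if np.ndim(x) == 1 else p


def cost(model: NNModel, X: np.ndarray, t: np.ndarray, lam: float | None = None) -> float:
    """Regularized cross-entropy; bias columns excluded from the penalty."""
    lam = model.lam if lam is None else lam
    m = len(t)
    if m < 1:
        raise ValueError("empty training data")
    p = np.clip(np.atleast_1d(forward(X, model)), _PROB_EPS, 1.0 - _PROB_EPS)
    ce = -np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))
    penalty = (lam / (2.0 * m)) * (
        np.sum(model.theta1[:, 1:] ** 2) + np.sum(model.theta2[:, 1:] ** 2)
    )
    return float(ce + penalty)


def gradient(
    model: NNModel, X: np.ndarray, t: np.ndarray, lam: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of :func:`cost` via forward/back-propagation."""
    lam = model.lam if lam is None else lam
    X = np.atleast_2d(np.asarray(X, float))
    t = np.asarray(t, float)
    m = len(t)
    A1 = np.hstack([np.ones((m, 1)), X])                       # (m, d+1)
    Z2 = A1 @ model.theta1.T
    H = _sigmoid(Z2)                                           # (m, hidden)
    A2 = np.hstack([np.ones((m, 1)), H])                       # (m, hidden+1)
    p = _sigmoid(A2 @ model.theta2.T).ravel()                  # (m,)

    # note: with clipped p the analytic derivative of the clipped loss is
    # (p - t) only where p is interior; clipping is vanishingly rare and
    # ignored here.
    delta3 = (p - t)[:, None]                                  # (m, 1)
    g2 = delta3.T @ A2 / m                                     # (1, hidden+1)
    delta2 = (delta3 @ model.theta2[:, 1:]) * H * (1.0 - H)    # (m, hidden)
    g1 = delta2.T @ A1 / m                                     # (hidden, d+1)

    g1[:, 1:] += (lam / m) * model.theta1[:, 1:]
    g2[:, 1:] += (lam / m) * model.theta2[:, 1:]
    return g1, g2


def _init_weights(d: int, hidden: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    eps1 = np.sqrt(6.0) / np.sqrt(d + 1 + hidden)
    eps2 = np.sqrt(6.0) / np.sqrt(hidden + 2)
    th1 = rng.uniform(-eps1, eps1, size=(hidden, d + 1))
    th2 = rng.uniform(-eps2, eps2, size=(1, hidden + 1))
    return np.concatenate([th1.ravel(), th2.ravel()])


def train(
    X: np.ndarray,
    t: np.ndarray,
    lam: float = 0.0,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
    hidden: int = DEFAULT_HIDDEN_UNITS,
    scaler: FeatureScaler | None = None,
) -> NNModel:
    """Fit the network on standardized features by Polak-Ribiere CG.

    Weights start uniform in +/- sqrt(6/(fan_in+fan_out)); the model with
    the lowest training cost seen during optimization is returned.
    """
    X = np.atleast_2d(np.asarray(X, float))
    t = np.asarray(t, float)
    d = X.shape[1]
    x0 = _init_weights(d, hidden, seed)

    def fun(flat: np.ndarray) -> float:
        m = NNModel.unpack(flat, d, hidden, lam=lam)
        return cost(m, X, t)

    def jac(flat: np.ndarray) -> np.ndarray:
        m = NNModel.unpack(flat, d, hidden, lam=lam)
        g1, g2 = gradient(m, X, t)
        return np.concatenate([g1.ravel(), g2.ravel()])

    best = {"J": fun(x0), "x": x0.copy()}
    trace = [best["J"]]

    def track(flat: np.ndarray) -> None:
        J = fun(flat)
        trace.append(J)
        if J < best["J"]:
            best["J"] = J
            best["x"] = flat.copy()

    res = optimize.minimize(
        fun, x0, jac=jac, method="CG", callback=track,
        options={"maxiter": max_iter, "gtol": 1e-6},
    )
    if not np.all(np.isfinite(res.x)):
        raise TrainingError(f"optimizer produced non-finite weights: {res.message}")
    track(res.x)
    model = NNModel.unpack(
        best["x"], d, hidden, lam=lam, seed=seed, scaler=scaler,
    )
    model.history = {"J_trace": trace, "final_J": best["J"], "n_iter": int(res.nit)}
    return model


def default_lambda_grid(n_points: int = 13) -> np.ndarray:
    """Log-spaced regularization grid over [0.003, 10]."""
    return np.geomspace(0.003, 10.0, n_points)


def split_data(
    X: np.ndarray,
    t: np.ndarray,
    fractions: tuple[float, float, float] = (0.5, 0.25, 0.25),
    seed: int = 0,
) -> LabeledSet:
    """Random 50/25/25 train/val/test assignment with exact rounded counts."""
    X = np.atleast_2d(np.asarray(X, float))
    t = np.asarray(t)
    m = len(t)
    if m < 4:
        raise ValueError("need at least 4 examples to split")
    n_train = int(round(fractions[0] * m))
    n_val = int(round(fractions[1] * m))
    n_val = min(n_val, m - n_train)
    order = np.random.default_rng(seed).permutation(m)
    split = np.empty(m, dtype=object)
    split[order[:n_train]] = "train"
    split[order[n_train : n_train + n_val]] = "val"
    split[order[n_train + n_val :]] = "test"
    return LabeledSet(X=X, t=t, split=split.astype(str))


def evaluate_accuracy(model: NNModel, X: np.ndarray, t: np.ndarray) -> float:
    """Fraction of examples classified correctly at threshold 0.5
    (p >= 0.5 counts as class 1).
    """
    if len(t) == 0:
        raise ValueError("empty evaluation split")
    p = np.atleast_1d(forward(X, model))
    return float(np.mean((p >= 0.5) == (np.asarray(t) == 1)))


def select_lambda(
    data: LabeledSet,
    grid: np.ndarray | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
    hidden: int = DEFAULT_HIDDEN_UNITS,
    scaler: FeatureScaler | None = None,
) -> tuple[NNModel, float]:
    """Train one model per grid value; return the one with the lowest
    validation misclassification rate (ties go to the smallest lambda).
    """
    if grid is None:
        grid = default_lambda_grid()
    grid = np.sort(np.asarray(grid, float))
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    Xtr, ttr = data.subset("train")
    Xval, tval = data.subset("val")
    if len(tval) == 0:
        raise ValueError("empty validation split")
    best_model, best_lam, best_err = None, None, np.inf
    for lam in grid:
        m = train(Xtr, ttr, lam=lam, max_iter=max_iter, seed=seed, hidden=hidden,
                  scaler=scaler)
        err = 1.0 - evaluate_accuracy(m, Xval, tval)
        if err < best_err:  # strict: ties keep the smaller lambda
            best_model, best_lam, best_err = m, float(lam), err
    best_model.history["val_error"] = best_err
    return best_model, best_lam


# ---------------------------------------------------------------------------
# Cluster validation procedure


def _window_candidate(s: Spectrum, c: float, window_frac: float) -> Peak | None:
    """Highest local maximum of ``s`` inside the window around ``c``."""
    lo, hi = c * (1.0 - window_frac), c * (1.0 + window_frac)
    if lo < s.mz[0] or hi > s.mz[-1]:
        raise ValueError(f"window around {c} outside spectrum {s.id!r}")
    y = s.intensity
    i0 = int(np.searchsorted(s.mz, lo, side="left"))
    i1 = int(np.searchsorted(s.mz, hi, side="right"))
    best: int | None = None
    for i in range(max(i0, 1), min(i1, len(y) - 1)):
        if y[i] > y[i - 1] and y[i] >= y[i + 1]:
            if best is None or y[i] > y[best]:
                best = i
    if best is None:
        return None
    left = best
    while left > 0 and y[left - 1] <= y[left]:
        left -= 1
    right = best
    while right < len(y) - 1 and y[right + 1] <= y[right]:
        right += 1
    if left == best or right == best:
        return None
    return Peak(
        mz=float(s.mz[best]),
        height=float(y[best]),
        spectrum_id=s.id,
        left_mz=float(s.mz[left]),
        right_mz=float(s.mz[right]),
        apex_index=best,
    )


def validate_cluster(
    raw_set: SpectrumSet,
    processed_set: SpectrumSet,
    c: float,
    model: NNModel,
    window_frac: float = DEFAULT_WINDOW_FRAC,
) -> PeakCluster:
    """Four-step validation of one predicted cluster m/z.

    Per spectrum: find the candidate peak near ``c`` on the processed
    trace; if present, extract features from the raw/processed pair,
    standardize with the model's scaler, and keep the peak iff the network
    probability is >= 0.5.  Prevalence is kept/n_spectra; kept peaks carry
    quantified heights and areas.
    """
    if model.scaler is None:
        raise ValueError("model has no feature scaler attached")
    raw_by_id = {s.id: s for s in raw_set}
    members: list[Peak] = []
    for proc in processed_set:
        raw = raw_by_id.get(proc.id)
        if raw is None:
            raise ValueError(f"no raw spectrum paired with {proc.id!r}")
        p = _window_candidate(proc, c, window_frac)
        if p is None:
            continue
        fv = extract_features(raw, proc, p.mz, window_frac)
        x = apply_scaler(fv, model.scaler)
        if forward(x, model) >= 0.5:
            members.append(quantify_peak(proc, p))
    return PeakCluster(
        mean_mz=float(np.mean([p.mz for p in members])) if members else float(c),
        members=members,
        n_spectra=len(processed_set),
    )
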