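"""Quadratic variance function (QVF) noise model.

The detector response is modelled as v(mu) = c0 + c1*mu + c2*mu^2: the
across-spectra variance at a grid point is a quadratic function of the
across-spectra mean there.  The model is estimated by ordinary least
squares from peak-free regions and used to variance-stabilize intensities
so that wavelet shrinkage can assume unit noise variance.

The stabilizing transform is the closed-form antiderivative of
1/sqrt(v(y)), with the branch chosen by the sign of c2:

* c2 = c1 = 0:  z = y / sqrt(c0)
* c2 = 0, c1 > 0:  z = 2*sqrt(c0 + c1*y) / c1
* c2 > 0:  z = log(2*c2*y + c1 + 2*sqrt(c2*v(y))) / sqrt(c2)
* c2 < 0:  z = -arcsin((2*c2*y + c1) / sqrt(c1^2 - 4*c0*c2)) / sqrt(-c2)

Each branch inverts in closed form, so round-tripping is exact to
floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import SpectrumSet

__all__ = [
    "QVF",
    "QVFError",
    "pointwise_mean_var",
    "fit_qvf",
    "fit_qvf_nonneg",
    "stabilize_variance",
    "unstabilize_variance",
    "ensure_positive",
    "propose_peak_free_regions",
]

class QVFError(ValueError):
    pass


@dataclass
class QVF:
    """Quadratic detector-response model v(mu) = c0 + c1*mu + c2*mu^2."""

    c0: float
    c1: float
    c2: float
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("c0", "c1", "c2"):
            if not np.isfinite(getattr(self, name)):
                raise QVFError(f"{name} is not finite")

    def variance(self, mu: np.ndarray | float) -> np.ndarray | float:
        mu = np.asarray(mu, dtype=float)
        out = self.c0 + self.c1 * mu + self.c2 * mu * mu
        return out if out.ndim else float(out)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.c0, self.c1, self.c2)

    def to_dict(self) -> dict:
        return {"c0": self.c0, "c1": self.c1, "c2": self.c2}

    @classmethod
    def from_dict(cls, d: dict) -> "QVF":
        return cls(c0=float(d["c0"]), c1=float(d["c1"]), c2=float(d["c2"]))


def pointwise_mean_var(
    sset: SpectrumSet, regions: list[tuple[float, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Across-spectra mean and unbiased sample variance at every grid point
    inside any of the given m/z ``regions``.
    """
    if sset.common_grid is None:
        raise QVFError("pointwise_mean_var requires a common grid")
    if len(sset) < 2:
        raise QVFError("need at least 2 spectra to estimate variance")
    if not regions:
        raise QVFError("no peak-free regions supplied")
    grid = sset.common_grid
    mask = np.zeros(len(grid), dtype=bool)
    for lo, hi in regions:
        mask |= (grid >= lo) & (grid <= hi)
    if not mask.any():
        raise QVFError("regions select no grid points")
    X = sset.intensity_matrix[:, mask]
    return X.mean(axis=0), X.var(axis=0, ddof=1)


def fit_qvf(mu: np.ndarray, var: np.ndarray) -> QVF:
    """Ordinary least squares of variance on [1, mu, mu^2]."""
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    if mu.shape != var.shape or mu.ndim != 1:
        raise QVFError("mu and var must be matching 1-D arrays")
    if len(np.unique(mu)) < 3:
        raise QVFError("need at least 3 distinct mean values to fit a quadratic")
    design = np.column_stack([np.ones_like(mu), mu, mu * mu])
    coef, *_ = np.linalg.lstsq(design, var, rcond=None)
    resid = var - design @ coef
    return QVF(
        c0=float(coef[0]),
        c1=float(coef[1]),
        c2=float(coef[2]),
        fit_diagnostics={"rss": float(resid @ resid), "n_points": int(len(mu))},
    )


def fit_qvf_nonneg(mu: np.ndarray, var: np.ndarray) -> QVF:
    """Least squares of variance on [1, mu, mu^2] with coefficients
    constrained non-negative.

    Peak-free regions only sample low mean intensities, so the
    unconstrained quadratic can extrapolate with negative curvature and
    produce a variance model that collapses at peak-level intensities.
    The non-negative fit guarantees a positive, non-decreasing variance
    for all non-negative intensities and is the model used on the
    stabilization path; :func:`fit_qvf` remains the plain OLS estimate.
    """
    from scipy.optimize import nnls

    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    if len(np.unique(mu)) < 3:
        raise QVFError("need at least 3 distinct mean values to fit a quadratic")
    design = np.column_stack([np.ones_like(mu), mu, mu * mu])
    coef, rnorm = nnls(design, var)
    if coef[0] == 0.0:
        positive = var[var > 0]
        coef[0] = float(np.min(positive)) if positive.size else 1e-6
    return QVF(
        c0=float(coef[0]),
        c1=float(coef[1]),
        c2=float(coef[2]),
        fit_diagnostics={"rss": float(rnorm**2), "n_points": int(len(mu)),
                         "constrained": True},
    )


def propose_peak_free_regions(
    sset: SpectrumSet, quantile: float = 0.25, smooth_window: int = 51
) -> list[tuple[float, float]]:
    """Suggest peak-free m/z intervals: maximal runs of grid points whose
    smoothed set-mean intensity lies below the given quantile.

    A convenience stand-in for manual region selection.
    """
    if sset.common_grid is None:
        raise QVFError("requires a common grid")
    grid = sset.common_grid
    mean = sset.intensity_matrix.mean(axis=0)
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(mean, kernel, mode="same")
    thresh = np.quantile(smoothed, quantile)
    low = smoothed <= thresh
    regions: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(low):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= 3:
                regions.append((float(grid[start]), float(grid[i - 1])))
            start = None
    if start is not None and len(low) - start >= 3:
        regions.append((float(grid[start]), float(grid[-1])))
    return regions


def ensure_positive(q: QVF, y: np.ndarray, floor: float | None = None) -> QVF:
    """Return a QVF whose variance is positive over the values in ``y``.

    OLS fits can dip non-positive at intensities outside (or at the edge
    of) the mean range used for fitting; raising c0 floors the fitted
    variance while preserving the quadratic form and hence the
    closed-form stabilizing transform.
    """
    v = np.asarray(q.variance(np.asarray(y, float)))
    vmin = float(v.min())
    if floor is None:
        positive = v[v > 0]
        floor = float(np.min(positive)) if positive.size else 1e-6
    if vmin >= floor:
        return q
    return QVF(
        c0=q.c0 + (floor - vmin),
        c1=q.c1,
        c2=q.c2,
        fit_diagnostics={**q.fit_diagnostics, "c0_floor_shift": floor - vmin},
    )


# ---------------------------------------------------------------------------
# Variance stabilization


def _check_domain(q: QVF, y: np.ndarray) -> None:
    v = q.variance(y)
    if np.any(np.asarray(v) <= 0):
        raise QVFError("v(y) <= 0 encountered; QVF invalid over this intensity range")


def _effective_coeffs(q: QVF) -> tuple[float, float, float]:
    """Zero out coefficients too small to matter numerically.

    Branch selection must agree between the forward and inverse transforms,
    and near-denormal c1/c2 values make the exact closed forms overflow or
    cancel catastrophically.  Thresholds are scale-aware: sqrt(c0) is the
    natural intensity scale and c2 is dimensionless.
    """
    c0, c1, c2 = q.as_tuple()
    if c2 != 0.0 and abs(c2) < 1e-9:
        c2 = 0.0
    if c1 != 0.0 and c0 > 0.0 and abs(c1) / np.sqrt(c0) < 1e-12:
        c1 = 0.0
    return c0, c1, c2


def stabilize_variance(y: np.ndarray, q: QVF) -> np.ndarray:
    """Map intensities through z = integral dy / sqrt(v(y)) so additive noise
    with variance v(.) becomes approximately unit-variance.
    """
    y = np.asarray(y, dtype=float)
    _check_domain(q, y)
    c0, c1, c2 = _effective_coeffs(q)
    if c2 == 0.0 and c1 == 0.0:
        return y / np.sqrt(c0)
    if c2 == 0.0:
        if c1 < 0:
            raise QVFError("c1 < 0 with c2 = 0 is not a valid variance function")
        return 2.0 * np.sqrt(c0 + c1 * y) / c1
    if c2 > 0.0:
        s = np.sqrt(c2)
        return np.log(2.0 * c2 * y + c1 + 2.0 * s * np.sqrt(q.variance(y))) / s
    # c2 < 0: v has two real roots; valid y lie between them
    s = np.sqrt(-c2)
    disc = c1 * c1 - 4.0 * c0 * c2
    return -np.arcsin((2.0 * c2 * y + c1) / np.sqrt(disc)) / s


def unstabilize_variance(z: np.ndarray, q: QVF) -> np.ndarray:
    """Closed-form inverse of :func:`stabilize_variance`."""
    z = np.asarray(z, dtype=float)
    c0, c1, c2 = _effective_coeffs(q)
    if c2 == 0.0 and c1 == 0.0:
        return z * np.sqrt(c0)
    if c2 == 0.0:
        return ((c1 * z / 2.0) ** 2 - c0) / c1
    if c2 > 0.0:
        s = np.sqrt(c2)
        u = np.exp(s * z)
        disc = 4.0 * c0 * c2 - c1 * c1
        w = (u * u - disc) / (2.0 * u)  # w = 2*c2*y + c1 + ... solved back
        return (w - c1) / (2.0 * c2)
    s = np.sqrt(-c2)
    disc = c1 * c1 - 4.0 * c0 * c2
    w = -np.sin(s * z) * np.sqrt(disc)  # w = 2*c2*y + c1
    return (w - c1) / (2.0 * c2)
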