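"""62-dimensional candidate-peak descriptors and feature standardization.

For a candidate at m/z mu the feature vector is, in fixed order:
[concavity, mass, 30 interpolated processed intensities, 30 interpolated
raw intensities], where concavity is the quadratic coefficient of the
least-squares parabola fit to the raw intensities in the window
mu*(1 +/- window_frac), and both interpolation blocks live on a linear
grid of 30 evenly spaced m/z points spanning that window.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_io import Spectrum

__all__ = [
    "FeatureVector",
    "FeatureScaler",
    "FEATURE_DIM",
    "N_INTERP",
    "DEFAULT_WINDOW_FRAC",
    "extract_features",
    "fit_scaler",
    "apply_scaler",
]

N_INTERP = 30
FEATURE_DIM = 2 + 2 * N_INTERP  # concavity + mass + processed + raw = 62
DEFAULT_WINDOW_FRAC = 0.003


@dataclass
class FeatureVector:
    concavity: float
    mass: float
    processed_interp: np.ndarray  # 30 values
    raw_interp: np.ndarray        # 30 values

    def __post_init__(self) -> None:
        self.processed_interp = np.asarray(self.processed_interp, float)
        self.raw_interp = np.asarray(self.raw_interp, float)
        if len(self.processed_interp) != N_INTERP or len(self.raw_interp) != N_INTERP:
            raise ValueError(f"interpolation blocks must have {N_INTERP} points")

    def to_array(self) -> np.ndarray:
        return np.concatenate(
            [[self.concavity, self.mass], self.processed_interp, self.raw_interp]
        )

    def __len__(self) -> int:
        return FEATURE_DIM


def extract_features(
    raw: Spectrum,
    processed: Spectrum,
    mu: float,
    window_frac: float = DEFAULT_WINDOW_FRAC,
) -> FeatureVector:
    """Build the candidate descriptor from aligned raw and processed spectra.

    Raises a range error if the window extends past either spectrum.
    """
    lo, hi = mu * (1.0 - window_frac), mu * (1.0 + window_frac)
    for s, name in ((raw, "raw"), (processed, "processed")):
        if lo < s.mz[0] or hi > s.mz[-1]:
            raise ValueError(
                f"window [{lo:.3f}, {hi:.3f}] outside {name} spectrum span"
            )

    sel = (raw.mz >= lo) & (raw.mz <= hi)
    if sel.sum() >= 3:
        d = raw.mz[sel] - mu
        design = np.column_stack([np.ones(d.size), d, d * d])
        coef, *_ = np.linalg.lstsq(design, raw.intensity[sel], rcond=None)
        concavity = float(coef[2])
    else:
        concavity = 0.0

    grid = np.linspace(lo, hi, N_INTERP)
    return FeatureVector(
        concavity=concavity,
        mass=float(mu),
        processed_interp=np.interp(grid, processed.mz, processed.intensity),
        raw_interp=np.interp(grid, raw.mz, raw.intensity),
    )


@dataclass
class FeatureScaler:
    """Per-dimension training-set mean/sd used to standardize features."""

    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, float)
        self.sds = np.asarray(self.sds, float)
        if self.means.shape != self.sds.shape:
            raise ValueError("means and sds must have matching shapes")
        if np.any(self.sds <= 0):
            raise ValueError("scaler sds must be positive")

    def to_dict(self) -> dict:
        return {"means": self.means.tolist(), "sds": self.sds.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        return cls(means=np.asarray(d["means"]), sds=np.asarray(d["sds"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureScaler":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, np.ndarray):
        return np.asarray(X, float)
    return np.vstack([x.to_array() if isinstance(x, FeatureVector) else x for x in X])


def fit_scaler(X) -> FeatureScaler:
    """Per-dimension mean and (population) standard deviation of the
    training set.  Constant dimensions get sd 1 with a warning.
    """
    M = _as_matrix(X)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 training vectors to fit a scaler")
    means = M.mean(axis=0)
    sds = M.std(axis=0)
    zero = sds == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} constant feature dimension(s); sd set to 1",
            stacklevel=2,
        )
        sds = np.where(zero, 1.0, sds)
    return FeatureScaler(means=means, sds=sds)


def apply_scaler(x, scaler: FeatureScaler) -> np.ndarray:
    """(x - mean) / sd, vectorized over rows if given a matrix."""
    arr = x.to_array() if isinstance(x, FeatureVector) else np.asarray(x, float)
    return (arr - scaler.means) / scaler.sds
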