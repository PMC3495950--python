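"""Baseline correction and total-ion-current normalization."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import grey_opening

from .core_io import Spectrum, SpectrumSet, Stage

__all__ = ["subtract_baseline", "tic_normalize", "NormalizationError"]


class NormalizationError(ValueError):
    pass


def subtract_baseline(s: Spectrum, window_frac: float = 0.05) -> Spectrum:
    """Remove a slowly varying baseline by morphological opening.

    The baseline estimate is a rolling minimum followed by a rolling
    maximum over a window of ``window_frac * len(s)`` points, subtracted
    pointwise.  Negative residuals are kept (no clipping).
    """
    if s.stage != Stage.RAW:
        raise ValueError(f"subtract_baseline expects a raw spectrum, got {s.stage.value}")
    window = max(int(round(window_frac * len(s))), 1)
    if window > len(s):
        raise ValueError(f"baseline window {window} exceeds spectrum length {len(s)}")
    baseline = grey_opening(s.intensity, size=window, mode="nearest")
    out = s.with_stage(Stage.BASELINE_CORRECTED, s.intensity - baseline)
    out.meta["baseline_window"] = window
    return out


def tic_normalize(
    sset: SpectrumSet, mz_range: tuple[float, float] | None = None
) -> SpectrumSet:
    """Scale each spectrum so its summed intensity over ``mz_range`` equals
    the set's mean pre-scaling sum.  Scale factors are recorded in metadata.
    """
    if sset.common_grid is None:
        raise NormalizationError("tic_normalize requires spectra on a common grid")
    grid = sset.common_grid
    if mz_range is None:
        mask = np.ones(len(grid), dtype=bool)
    else:
        mask = (grid >= mz_range[0]) & (grid <= mz_range[1])
        if not mask.any():
            raise NormalizationError(f"mz_range {mz_range} selects no grid points")
    sums = np.array([float(np.sum(s.intensity[mask])) for s in sset])
    if np.any(sums <= 0):
        bad = [s.id for s, t in zip(sset, sums) if t <= 0]
        raise NormalizationError(f"non-positive total ion current for {bad}")
    target = float(np.mean(sums))
    out = []
    for s, total in zip(sset, sums):
        scale = target / total
        ns = s.with_stage(Stage.NORMALIZED, s.intensity * scale)
        ns.meta["tic_scale"] = scale
        out.append(ns)
    return SpectrumSet(spectra=out, common_grid=grid.copy())
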