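"""Translation-invariant wavelet denoising for the peak-detection path.

The denoiser is variance-stabilized soft-threshold wavelet shrinkage
wrapped in cycle spinning: the signal is circularly shifted, denoised,
unshifted, and the results averaged over a set of shifts, which
suppresses the shift-dependent pseudo-Gibbs artifacts of orthogonal
wavelet thresholding.

The periodized orthogonal DWT is materialized once as an explicit sparse
matrix and cached on disk, so each denoise is a sparse matrix-vector
product instead of a filter-bank cascade.  Daubechies scaling filters are
constructed by spectral factorization of the standard half-band
polynomial, so no external wavelet library is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .core_io import Spectrum, SpectrumSet, Stage
from .noise_qvf import QVF, ensure_positive, stabilize_variance, unstabilize_variance

__all__ = [
    "WaveletOperator",
    "CycleSpinConfig",
    "daubechies_filter",
    "build_wavelet_operator",
    "denoise_shrink",
    "cycle_spin",
    "denoise_spectrum",
    "denoise_spectrum_set",
    "soft_threshold",
    "universal_threshold",
]


def daubechies_filter(vanishing_moments: int) -> np.ndarray:
    """Minimal-phase Daubechies scaling filter with ``vanishing_moments``
    vanishing moments (2*vanishing_moments taps), normalized so the taps
    sum to sqrt(2).

    Built by spectral factorization: the half-band polynomial
    P(y) = sum_k C(p-1+k, k) y^k is rooted, each root in y is mapped to a
    conjugate pair in z, and the root inside the unit circle is kept.
    """
    p = int(vanishing_moments)
    if p < 1:
        raise ValueError("vanishing_moments must be >= 1")
    if p == 1:  # Haar
        return np.array([1.0, 1.0]) / np.sqrt(2.0)
    Py = np.array([comb(p - 1 + k, k) for k in range(p)], dtype=float)
    roots_y = np.roots(Py[::-1])
    zroots = []
    for y0 in roots_y:
        # y = (2 - z - 1/z)/4  =>  -z^2/4 + (1/2 - y0) z - 1/4 = 0
        r = np.roots([-0.25, 0.5 - y0, -0.25])
        inside = r[np.abs(r) < 1.0]
        zroots.append(inside[0])
    h = np.array([1.0 + 0.0j])
    for _ in range(p):
        h = np.convolve(h, [1.0, 1.0])
    for zr in zroots:
        h = np.convolve(h, [1.0, -zr])
    h = np.real(h)
    return h * (np.sqrt(2.0) / h.sum())


def _qmf(h: np.ndarray) -> np.ndarray:
    """Quadrature-mirror highpass filter for an orthogonal scaling filter."""
    g = h[::-1].copy()
    g[1::2] *= -1.0
    return g


def _level_matrix(n: int, h: np.ndarray) -> sp.csr_matrix:
    """One periodized analysis level as an n x n sparse matrix.

    Rows 0..n/2-1 compute approximation coefficients
    a[i] = sum_k h[k] x[(2i + k) mod n]; rows n/2..n-1 the details with
    the mirror filter.
    """
    g = _qmf(h)
    half = n // 2
    L = len(h)
    rows, cols, vals = [], [], []
    for i in range(half):
        for k in range(L):
            j = (2 * i + k) % n
            rows.append(i)
            cols.append(j)
            vals.append(h[k])
            rows.append(half + i)
            cols.append(j)
            vals.append(g[k])
    M = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    return M.tocsr()


@dataclass
class WaveletOperator:
    """Explicit sparse orthonormal analysis operator for the periodized DWT.

    Applying ``matrix`` to a length-n signal yields
    [approx(levels) | detail(levels) | ... | detail(1)] in one vector.
    """

    n: int
    family: str
    levels: int
    matrix: sp.csr_matrix
    cache_path: Path | None = None

    @property
    def approx_len(self) -> int:
        return self.n >> self.levels

    def analyze(self, y: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(y, dtype=float)

    def synthesize(self, coeffs: np.ndarray) -> np.ndarray:
        # orthonormal: inverse = transpose
        return self.matrix.T @ np.asarray(coeffs, dtype=float)


def _parse_family(family: str) -> np.ndarray:
    if family.startswith("db"):
        return daubechies_filter(int(family[2:]))
    if family == "haar":
        return daubechies_filter(1)
    raise ValueError(f"unknown wavelet family {family!r}")


def build_wavelet_operator(
    n: int,
    family: str = "db8",
    levels: int | None = None,
    cache_path: str | Path | None = None,
) -> WaveletOperator:
    """Construct (or load from cache) the sparse n x n orthonormal DWT matrix.

    ``n`` must be a power of 2.  When ``cache_path`` points to an existing
    cache written for the same (n, family, levels), the matrix is loaded
    without reconstruction; otherwise it is built and written there.
    """
    if n < 2 or n & (n - 1):
        raise ValueError(f"signal length {n} is not a power of 2; pad before calling")
    max_levels = int(np.log2(n))
    if levels is None:
        levels = max(max_levels - 4, 1)
    if not 1 <= levels <= max_levels:
        raise ValueError(f"levels must be in [1, {max_levels}], got {levels}")

    if cache_path is not None:
        cache_path = Path(cache_path)
        if cache_path.exists():
            mat = sp.load_npz(cache_path)
            if mat.shape == (n, n):
                return WaveletOperator(
                    n=n, family=family, levels=levels, matrix=mat.tocsr(),
                    cache_path=cache_path,
                )

    h = _parse_family(family)
    W = sp.identity(n, format="csr")
    size = n
    for _ in range(levels):
        lvl = _level_matrix(size, h)
        # embed: transform only the current approximation block
        if size == n:
            step = lvl
        else:
            step = sp.block_diag([lvl, sp.identity(n - size)], format="csr")
        W = step @ W
        size //= 2
    W = W.tocsr()
    W.eliminate_zeros()

    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        sp.save_npz(cache_path, W)
    return WaveletOperator(n=n, family=family, levels=levels, matrix=W,
                           cache_path=cache_path)


def operator_cache_key(n: int, family: str, levels: int) -> str:
    return f"dwt_{family}_n{n}_L{levels}.npz"


# ---------------------------------------------------------------------------
# Shrinkage


def universal_threshold(n: int) -> float:
    """sqrt(2 ln n): the universal threshold for unit-variance noise."""
    return float(np.sqrt(2.0 * np.log(n)))


def soft_threshold(x: np.ndarray, thresh: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thresh, 0.0)


def denoise_shrink(
    y: np.ndarray, op: WaveletOperator, threshold: float | None = None
) -> np.ndarray:
    """Soft-threshold the detail coefficients of a variance-stabilized
    signal at the universal threshold and inverse-transform.

    The coarsest approximation band is left untouched.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != op.n:
        raise ValueError(f"signal length {len(y)} != operator size {op.n}")
    if threshold is None:
        threshold = universal_threshold(op.n)
    coeffs = op.analyze(y)
    out = coeffs.copy()
    a = op.approx_len
    out[a:] = soft_threshold(coeffs[a:], threshold)
    return op.synthesize(out)


@dataclass
class CycleSpinConfig:
    """Shift set and threshold rule for cycle spinning."""

    shifts: tuple[int, ...] = ()
    threshold: float | None = None  # None -> universal

    def resolved_shifts(self, n: int, default_count: int = 32) -> tuple[int, ...]:
        if self.shifts:
            shifts = tuple(sorted(set(int(s) % n for s in self.shifts)))
        else:
            count = min(default_count, n)
            shifts = tuple(sorted(set(int(round(k * n / count)) % n
                                      for k in range(count))))
        if not shifts:
            raise ValueError("empty shift set")
        return shifts

    @classmethod
    def evenly_spaced(cls, n: int, count: int = 32) -> "CycleSpinConfig":
        count = min(count, n)
        return cls(shifts=tuple(sorted(set(int(round(k * n / count)) % n
                                           for k in range(count)))))


def cycle_spin(
    y: np.ndarray,
    cfg: CycleSpinConfig,
    op: WaveletOperator,
    q: QVF | None = None,
) -> np.ndarray:
    """Shift-denoise-unshift-average over the configured shift set.

    When a QVF is given, the signal is variance-stabilized first and the
    averaged estimate is mapped back afterwards; the shrinkage itself
    always assumes unit noise variance.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != op.n:
        raise ValueError(f"signal length {len(y)} != operator size {op.n}")
    shifts = cfg.resolved_shifts(op.n)
    z = stabilize_variance(y, q) if q is not None else y
    acc = np.zeros_like(z)
    for h in shifts:
        shifted = np.roll(z, -h)
        den = denoise_shrink(shifted, op, cfg.threshold)
        acc += np.roll(den, h)
    acc /= len(shifts)
    return unstabilize_variance(acc, q) if q is not None else acc


# ---------------------------------------------------------------------------
# Spectrum-level wrappers (padding to dyadic length)


def _pad_to_pow2(y: np.ndarray) -> tuple[np.ndarray, slice]:
    n = len(y)
    target = 1 << int(np.ceil(np.log2(n)))
    if target == n:
        return y, slice(0, n)
    pad = target - n
    left = pad // 2
    right = pad - left
    padded = np.concatenate([y[1 : left + 1][::-1], y, y[-right - 1 : -1][::-1]])
    return padded, slice(left, left + n)


def denoise_spectrum(
    s: Spectrum,
    q: QVF,
    family: str = "db8",
    levels: int | None = None,
    shifts: int = 32,
    cache_dir: str | Path | None = None,
) -> Spectrum:
    """Cycle-spin denoise one spectrum (detection path).

    Pads to the next power of 2 by symmetric reflection, denoises, crops.
    """
    padded, keep = _pad_to_pow2(s.intensity)
    q = ensure_positive(q, padded)
    cache = None
    n = len(padded)
    if levels is None:
        levels = max(int(np.log2(n)) - 4, 1)
    if cache_dir is not None:
        cache = Path(cache_dir) / operator_cache_key(n, family, levels)
    op = build_wavelet_operator(n, family=family, levels=levels, cache_path=cache)
    cfg = CycleSpinConfig.evenly_spaced(n, shifts)
    den = cycle_spin(padded, cfg, op, q)
    return s.with_stage(Stage.DENOISED, den[keep])


def denoise_spectrum_set(
    sset: SpectrumSet,
    q: QVF,
    family: str = "db8",
    levels: int | None = None,
    shifts: int = 32,
    cache_dir: str | Path | None = None,
) -> SpectrumSet:
    out = [
        denoise_spectrum(s, q, family=family, levels=levels, shifts=shifts,
                         cache_dir=cache_dir)
        for s in sset
    ]
    return SpectrumSet(spectra=out, common_grid=sset.common_grid)
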