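"""Per-spectrum peak detection, quantification, cross-spectrum clustering,
reproducibility filtering, and benchmark metrics.

Peaks detected in individual spectra are grouped into clusters by a
relative mass tolerance (default 0.3%); a cluster is "reproducible" when
its peak is present in at least 80% of the spectra.  Benchmark metrics
score predicted reproducible clusters against known truth: sensitivity is
the fraction of true peaks recovered, FDR the fraction of predictions not
matching any true peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import Spectrum, Stage
from .synthetic import GroundTruth

__all__ = [
    "Peak",
    "PeakCluster",
    "BenchmarkResult",
    "detect_local_maxima",
    "quantify_peak",
    "cluster_peaks",
    "reproducible_clusters",
    "benchmark_sens_fdr",
    "DEFAULT_TOLERANCE_FRAC",
    "DEFAULT_MIN_PREVALENCE",
]

DEFAULT_TOLERANCE_FRAC = 0.003
DEFAULT_MIN_PREVALENCE = 0.8


@dataclass
class Peak:
    """A single detected peak: apex plus flanking valleys."""

    mz: float
    height: float
    spectrum_id: str
    left_mz: float
    right_mz: float
    area: float = np.nan
    apex_index: int = -1

    def __post_init__(self) -> None:
        if not self.left_mz < self.mz < self.right_mz:
            raise ValueError(
                f"peak bounds must bracket apex: {self.left_mz} < {self.mz} < {self.right_mz}"
            )


@dataclass
class PeakCluster:
    """Peaks at the "same" m/z across spectra, presumed one analyte."""

    mean_mz: float
    members: list[Peak]
    n_spectra: int
    flags: dict = field(default_factory=dict)

    @property
    def prevalence(self) -> float:
        return len(self.members) / self.n_spectra if self.n_spectra else 0.0


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    fn: int
    degenerate_fdr: bool = False

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def fdr(self) -> float:
        denom = self.tp + self.fp
        return self.fp / denom if denom else 0.0


def detect_local_maxima(s: Spectrum, min_height: float = 0.0) -> list[Peak]:
    """Strict local maxima above ``min_height``; plateaus resolve to their
    center sample (left of center on even-length plateaus).  Valley bounds
    are the nearest local minima (or spectrum ends) on each side.
    """
    if s.stage not in (Stage.DENOISED, Stage.SMOOTHED):
        raise ValueError(
            f"peak detection expects a denoised or smoothed spectrum, got {s.stage.value}"
        )
    y = s.intensity
    n = len(y)
    if n < 3:
        return []

    apexes: list[int] = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            # scan a potential plateau [i, j]
            j = i
            while j + 1 < n and y[j + 1] == y[i]:
                j += 1
            if j + 1 < n and y[j + 1] < y[i]:
                apexes.append((i + j) // 2)
            i = j + 1
        else:
            i += 1

    peaks: list[Peak] = []
    for apex in apexes:
        if y[apex] < min_height:
            continue
        left = apex
        while left > 0 and y[left - 1] <= y[left]:
            left -= 1
        right = apex
        while right < n - 1 and y[right + 1] <= y[right]:
            right += 1
        if left == apex or right == apex:
            continue
        peaks.append(
            Peak(
                mz=float(s.mz[apex]),
                height=float(y[apex]),
                spectrum_id=s.id,
                left_mz=float(s.mz[left]),
                right_mz=float(s.mz[right]),
                apex_index=apex,
            )
        )
    return peaks


def quantify_peak(smoothed: Spectrum, p: Peak) -> Peak:
    """Fill height and baseline-chord-corrected area from the smoothed trace.

    Area is the trapezoidal integral between the valley bounds minus the
    area under the straight chord joining the valley endpoints.
    """
    if not p.left_mz < p.right_mz:
        raise ValueError("inverted peak bounds")
    mz, y = smoothed.mz, smoothed.intensity
    lo = int(np.searchsorted(mz, p.left_mz, side="left"))
    hi = int(np.searchsorted(mz, p.right_mz, side="right")) - 1
    if lo >= hi:
        raise ValueError("peak bounds span fewer than 2 grid points")
    seg_mz = mz[lo : hi + 1]
    seg_y = y[lo : hi + 1]
    total = float(np.trapezoid(seg_y, seg_mz))
    chord = 0.5 * (seg_y[0] + seg_y[-1]) * (seg_mz[-1] - seg_mz[0])
    apex = int(np.argmin(np.abs(mz - p.mz)))
    return replace(p, height=float(y[apex]), area=total - chord)


def cluster_peaks(
    peaklists: list[list[Peak]],
    tolerance_frac: float = DEFAULT_TOLERANCE_FRAC,
    n_spectra: int | None = None,
) -> list[PeakCluster]:
    """Single-linkage clustering of pooled apexes along the m/z axis.

    The pooled apex list is sorted and split wherever the gap between
    neighbors exceeds ``tolerance_frac`` times the mean m/z of the pair.
    Within a cluster at most one peak per spectrum is kept (the one
    closest to the cluster's running mean); the cluster mean is
    recomputed after member assignment.
    """
    if n_spectra is None:
        n_spectra = len(peaklists)
    pooled = [p for plist in peaklists for p in plist]
    if not pooled:
        return []
    pooled.sort(key=lambda p: p.mz)

    groups: list[list[Peak]] = [[pooled[0]]]
    for prev, cur in zip(pooled, pooled[1:]):
        if cur.mz - prev.mz > tolerance_frac * 0.5 * (cur.mz + prev.mz):
            groups.append([cur])
        else:
            groups[-1].append(cur)

    clusters: list[PeakCluster] = []
    for g in groups:
        mean = float(np.mean([p.mz for p in g]))
        best: dict[str, Peak] = {}
        for p in g:
            cur = best.get(p.spectrum_id)
            if cur is None or abs(p.mz - mean) < abs(cur.mz - mean):
                best[p.spectrum_id] = p
        members = sorted(best.values(), key=lambda p: p.spectrum_id)
        clusters.append(
            PeakCluster(
                mean_mz=float(np.mean([p.mz for p in members])),
                members=members,
                n_spectra=n_spectra,
            )
        )
    return clusters


def reproducible_clusters(
    clusters: list[PeakCluster], min_prevalence: float = DEFAULT_MIN_PREVALENCE
) -> list[PeakCluster]:
    """Keep clusters whose prevalence reaches ``min_prevalence`` (default 80%)."""
    return [c for c in clusters if c.prevalence >= min_prevalence]


def benchmark_sens_fdr(
    predicted: list[PeakCluster],
    truth: GroundTruth | list[float],
    tolerance_frac: float = DEFAULT_TOLERANCE_FRAC,
) -> BenchmarkResult:
    """Score predicted clusters against true centers by greedy 1-1 matching.

    A prediction within the relative tolerance of an unmatched true center
    is a TP; leftover predictions are FPs and unmatched centers FNs.  With
    zero predictions the FDR is reported as 0 with a degenerate flag.
    """
    centers = list(truth.cluster_centers) if isinstance(truth, GroundTruth) else list(truth)
    pred_mz = [c.mean_mz for c in predicted]

    pairs = [
        (abs(pm - tc) / tc, i, j)
        for i, pm in enumerate(pred_mz)
        for j, tc in enumerate(centers)
        if abs(pm - tc) / tc <= tolerance_frac
    ]
    pairs.sort()
    used_pred: set[int] = set()
    used_true: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_pred or j in used_true:
            continue
        used_pred.add(i)
        used_true.add(j)
        tp += 1
    fp = len(pred_mz) - tp
    fn = len(centers) - tp
    return BenchmarkResult(tp=tp, fp=fp, fn=fn, degenerate_fdr=(tp + fp) == 0)
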