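"""Synthetic SELDI-like spectrum sets with known ground truth.

Simulated spectra contain Gaussian peaks whose widths grow linearly with
m/z, a smooth exponentially decaying baseline, and additive Gaussian noise
whose variance is a quadratic function of the clean signal level.  Every
random draw (peak presence, m/z jitter, noise) is recorded so downstream
estimates can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import Group, Spectrum, SpectrumSet, Stage

__all__ = [
    "ClusterSpec",
    "SimConfig",
    "PlantedPeak",
    "GroundTruth",
    "SimulationError",
    "simulate_spectrum_set",
    "generate_annotated_candidates",
    "default_config",
]


class SimulationError(ValueError):
    pass


@dataclass
class ClusterSpec:
    """One analyte: a peak planted at center_mz in a fraction of spectra."""

    center_mz: float
    height: float
    prevalence: float = 1.0
    jitter_frac: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise SimulationError(f"prevalence {self.prevalence} outside [0, 1]")
        if self.jitter_frac < 0:
            raise SimulationError("jitter_frac must be >= 0")


@dataclass
class SimConfig:
    n_points: int = 4096
    mz_range: tuple[float, float] = (2000.0, 20000.0)
    clusters: list[ClusterSpec] = field(default_factory=list)
    width_coeff: float = 0.002  # peak sigma = width_coeff * center m/z
    baseline_amplitude: float = 0.0
    baseline_decay: float = 3000.0
    qvf: tuple[float, float, float] = (1.0, 0.0, 0.0)
    n_spectra: int = 10
    seed: int = 0
    group: Group = Group.QC


@dataclass
class PlantedPeak:
    mz: float
    height: float
    cluster_index: int


@dataclass
class GroundTruth:
    """Per-spectrum planted peaks plus per-cluster realized prevalence."""

    peaks: dict[str, list[PlantedPeak]]
    cluster_centers: list[float]
    true_prevalence: list[float]       # configured Bernoulli probability
    observed_prevalence: list[float]   # realized presence fraction
    config: SimConfig

    def reproducible_centers(self, min_prevalence: float = 0.8) -> list[float]:
        """Centers of clusters actually present in >= min_prevalence of the
        spectra — the ground-truth analog of a reproducible peak.
        """
        return [
            c
            for c, p in zip(self.cluster_centers, self.observed_prevalence)
            if p >= min_prevalence
        ]


def _variance(qvf: tuple[float, float, float], mu: np.ndarray) -> np.ndarray:
    c0, c1, c2 = qvf
    return c0 + c1 * mu + c2 * mu * mu


def simulate_spectrum_set(config: SimConfig) -> tuple[SpectrumSet, GroundTruth]:
    """Generate a spectrum set from ``config``; fully reproducible from its seed."""
    rng = np.random.default_rng(config.seed)
    low, high = config.mz_range
    grid = np.linspace(low, high, config.n_points)

    spectra = []
    peaks_by_id: dict[str, list[PlantedPeak]] = {}
    present_counts = np.zeros(len(config.clusters), dtype=int)

    for i in range(config.n_spectra):
        sid = f"sim{i:04d}"
        clean = np.zeros_like(grid)
        if config.baseline_amplitude:
            clean += config.baseline_amplitude * np.exp(
                -(grid - low) / config.baseline_decay
            )
        planted: list[PlantedPeak] = []
        for ci, cl in enumerate(config.clusters):
            present = rng.random() < cl.prevalence
            jitter = rng.uniform(-cl.jitter_frac, cl.jitter_frac)
            if not present:
                continue
            center = cl.center_mz * (1.0 + jitter)
            sigma = config.width_coeff * cl.center_mz
            clean += cl.height * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
            planted.append(PlantedPeak(mz=center, height=cl.height, cluster_index=ci))
            present_counts[ci] += 1
        var = _variance(config.qvf, clean)
        if np.any(var <= 0):
            raise SimulationError(
                "QVF variance non-positive over the simulated intensity range"
            )
        noisy = clean + rng.standard_normal(len(grid)) * np.sqrt(var)
        spectra.append(
            Spectrum(
                mz=grid.copy(),
                intensity=noisy,
                id=sid,
                subject=sid,
                replicate=0,
                group=config.group,
                stage=Stage.RAW,
            )
        )
        peaks_by_id[sid] = planted

    truth = GroundTruth(
        peaks=peaks_by_id,
        cluster_centers=[c.center_mz for c in config.clusters],
        true_prevalence=[c.prevalence for c in config.clusters],
        observed_prevalence=(present_counts / max(config.n_spectra, 1)).tolist(),
        config=config,
    )
    return SpectrumSet(spectra=spectra, common_grid=grid), truth


# Positive share of the default annotated-candidate fixture.
DEFAULT_TRUE_FRACTION = 0.5707


def generate_annotated_candidates(
    sset: SpectrumSet,
    truth: GroundTruth,
    n_candidates: int = 4000,
    true_fraction: float = DEFAULT_TRUE_FRACTION,
    seed: int = 0,
) -> list[tuple[str, float, int]]:
    """Draw labeled peak candidates: positives at planted apexes, negatives
    at local noise maxima at least 3 sigma away from every planted peak.

    Returns (spectrum id, candidate m/z, label) triples with the positive
    share equal to ``true_fraction`` within one count.
    """
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_candidates * true_fraction))
    n_neg = n_candidates - n_pos

    positives: list[tuple[str, float]] = []
    for sid, planted in truth.peaks.items():
        for p in planted:
            positives.append((sid, p.mz))
    if not positives and n_pos > 0:
        raise SimulationError("no planted peaks available for positive candidates")

    width_coeff = truth.config.width_coeff
    decoys: list[tuple[str, float]] = []
    for s in sset:
        planted = truth.peaks.get(s.id, [])
        centers = np.array([p.mz for p in planted]) if planted else np.empty(0)
        sigmas = (
            np.array([width_coeff * truth.config.clusters[p.cluster_index].center_mz
                      for p in planted])
            if planted
            else np.empty(0)
        )
        y = s.intensity
        # interior strict-or-plateau local maxima of the raw trace
        idx = np.where((y[1:-1] >= y[:-2]) & (y[1:-1] > y[2:]))[0] + 1
        for j in idx:
            m = s.mz[j]
            if centers.size and np.any(np.abs(m - centers) < 3.0 * sigmas):
                continue
            decoys.append((s.id, m))
    if len(decoys) < n_neg:
        raise SimulationError(
            f"insufficient decoy locations: need {n_neg}, found {len(decoys)}"
        )

    chosen_pos = [positives[k] for k in rng.integers(0, len(positives), size=n_pos)]
    chosen_neg = [decoys[k] for k in rng.choice(len(decoys), size=n_neg, replace=False)]
    out = [(sid, mz, 1) for sid, mz in chosen_pos] + [
        (sid, mz, 0) for sid, mz in chosen_neg
    ]
    order = rng.permutation(len(out))
    return [out[k] for k in order]


def default_config(seed: int = 0, n_spectra: int = 10, n_clusters: int = 8) -> SimConfig:
    """A reasonable QC-like configuration used by fixtures and the CLI."""
    rng = np.random.default_rng(seed + 997)
    centers = np.sort(rng.uniform(3500.0, 18000.0, size=n_clusters))
    # enforce separation so clusters never merge under the 0.3% tolerance
    for i in range(1, len(centers)):
        centers[i] = max(centers[i], centers[i - 1] * 1.03)
    clusters = [
        ClusterSpec(
            center_mz=float(c),
            height=float(rng.uniform(30.0, 80.0)),
            prevalence=float(rng.uniform(0.85, 1.0)),
            jitter_frac=0.001,
        )
        for c in centers
    ]
    return SimConfig(
        n_points=4096,
        mz_range=(2000.0, 20000.0),
        clusters=clusters,
        width_coeff=0.002,
        baseline_amplitude=20.0,
        baseline_decay=4000.0,
        qvf=(1.0, 0.05, 1e-4),
        n_spectra=n_spectra,
        seed=seed,
    )
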