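"""End-to-end orchestration: import -> baseline -> TIC -> replicate
averaging -> QVF estimation -> cycle-spin denoising (detection path) ->
zero-phase FIR smoothing (quantification path) -> peak detection ->
clustering -> reproducibility filter -> neural-network validation ->
group statistics.

Both processed tracks are retained: the denoised track drives detection
and the FIR-smoothed track drives quantification, since no single
smoother is best at both jobs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    core_io,
    features,
    fir_quant,
    group_stats,
    noise_qvf,
    nn_validator,
    peaks,
    preprocess,
    synthetic,
)
from .core_io import SpectrumSet
from .noise_qvf import QVF

logger = logging.getLogger("seldikit.pipeline")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "train_validator"]


@dataclass
class PipelineConfig:
    baseline_window_frac: float = 0.05
    tic_range: tuple[float, float] | None = None
    qvf_regions: list[tuple[float, float]] | None = None  # None -> proposed
    qvf_quantile: float = 0.25
    wavelet_family: str = "db8"
    wavelet_levels: int | None = None
    shifts: int = 32
    fir_order: int = fir_quant.DEFAULT_ORDER
    min_peak_height: float = 0.0
    tolerance_frac: float = peaks.DEFAULT_TOLERANCE_FRAC
    min_prevalence: float = peaks.DEFAULT_MIN_PREVALENCE
    window_frac: float = features.DEFAULT_WINDOW_FRAC
    alpha: float = 0.05
    seed: int = 0
    cache_dir: str | None = None

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    qvf: QVF
    denoised: SpectrumSet
    smoothed: SpectrumSet
    clusters: list[peaks.PeakCluster]
    reproducible: list[peaks.PeakCluster]
    validated: list[peaks.PeakCluster] | None = None
    report: pd.DataFrame | None = None
    stage_log: list[str] = field(default_factory=list)


def train_validator(
    sset: SpectrumSet,
    truth: synthetic.GroundTruth,
    processed: SpectrumSet,
    n_candidates: int = 2000,
    window_frac: float = features.DEFAULT_WINDOW_FRAC,
    seed: int = 0,
    lam: float = 0.1,
    max_iter: int = nn_validator.DEFAULT_MAX_ITER,
) -> nn_validator.NNModel:
    """Train a peak validator from synthetic annotated candidates.

    Candidates are labeled from ground truth, featurized from the
    raw/processed pair, split 50/25/25 and fit at a fixed regularization
    weight (use :func:`nn_validator.select_lambda` for a grid search).
    """
    cands = synthetic.generate_annotated_candidates(
        sset, truth, n_candidates=n_candidates, seed=seed
    )
    raw_by_id = {s.id: s for s in sset}
    proc_by_id = {s.id: s for s in processed}
    X, t = [], []
    for sid, mz, label in cands:
        raw, proc = raw_by_id[sid], proc_by_id[sid]
        lo, hi = mz * (1 - window_frac), mz * (1 + window_frac)
        if lo < raw.mz[0] or hi > raw.mz[-1]:
            continue
        fv = features.extract_features(raw, proc, mz, window_frac)
        X.append(fv.to_array())
        t.append(label)
    X = np.vstack(X)
    t = np.asarray(t)
    data = nn_validator.split_data(X, t, seed=seed)
    Xtr, ttr = data.subset("train")
    scaler = features.fit_scaler(Xtr)
    model = nn_validator.train(
        features.apply_scaler(Xtr, scaler), ttr, lam=lam, seed=seed,
        max_iter=max_iter, scaler=scaler,
    )
    Xte, tte = data.subset("test")
    model.history["test_accuracy"] = nn_validator.evaluate_accuracy(
        model, features.apply_scaler(Xte, scaler), tte
    )
    return model


def run_pipeline(
    raw_set: SpectrumSet,
    config: PipelineConfig | None = None,
    model: nn_validator.NNModel | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full method on a raw spectrum set.

    When ``model`` is given, reproducible clusters are re-validated with
    the neural network and group statistics are computed whenever the set
    carries two or more group labels.  When ``out_dir`` is set, each stage
    writes its table there.
    """
    cfg = config or PipelineConfig()
    log: list[str] = []

    def stage(name: str, **params) -> None:
        msg = f"[{name}] {json.dumps(params, default=str)} seed={cfg.seed}"
        logger.info(msg)
        log.append(msg)

    stage("import", n_spectra=len(raw_set))
    common = core_io.resample_to_common_grid(raw_set)

    stage("baseline", window_frac=cfg.baseline_window_frac)
    based = SpectrumSet(
        spectra=[preprocess.subtract_baseline(s, cfg.baseline_window_frac)
                 for s in common],
        common_grid=common.common_grid,
    )

    stage("tic_normalize", mz_range=cfg.tic_range)
    normed = preprocess.tic_normalize(based, cfg.tic_range)

    stage("average_replicates")
    averaged = core_io.average_replicates(normed)

    regions = cfg.qvf_regions
    if regions is None:
        regions = noise_qvf.propose_peak_free_regions(averaged, cfg.qvf_quantile)
    stage("qvf", n_regions=len(regions))
    mu, var = noise_qvf.pointwise_mean_var(averaged, regions)
    q = noise_qvf.fit_qvf(mu, var)          # reported diagnostics (plain OLS)
    q_stab = noise_qvf.fit_qvf_nonneg(mu, var)  # model driving stabilization

    stage("denoise", family=cfg.wavelet_family, shifts=cfg.shifts)
    from .wavelet_denoise import denoise_spectrum_set

    denoised = denoise_spectrum_set(
        averaged, q_stab, family=cfg.wavelet_family, levels=cfg.wavelet_levels,
        shifts=cfg.shifts, cache_dir=cfg.cache_dir,
    )

    stage("smooth", order=cfg.fir_order)
    filt = fir_quant.design_quant_filter(order=cfg.fir_order)
    smoothed = fir_quant.smooth_spectrum_set(averaged, filt)

    stage("detect", min_height=cfg.min_peak_height)
    peaklists = [peaks.detect_local_maxima(s, cfg.min_peak_height) for s in denoised]

    stage("cluster", tolerance_frac=cfg.tolerance_frac)
    clusters = peaks.cluster_peaks(peaklists, cfg.tolerance_frac)

    stage("reproducible", min_prevalence=cfg.min_prevalence)
    kept = peaks.reproducible_clusters(clusters, cfg.min_prevalence)

    validated = None
    report = None
    if model is not None:
        stage("nn_validate", n_clusters=len(kept))
        validated = [
            nn_validator.validate_cluster(
                averaged, smoothed, c.mean_mz, model, cfg.window_frac
            )
            for c in kept
        ]
        groups = {s.id: s.group.value for s in averaged}
        labels = sorted(set(groups.values()))
        if len(labels) == 2:
            counts = {g: sum(1 for v in groups.values() if v == g) for g in labels}
            stage("group_stats", groups=labels)
            try:
                report = group_stats.cluster_report(
                    validated, groups, labels[0], labels[1],
                    counts[labels[0]], counts[labels[1]], cfg.alpha,
                )
            except ValueError:
                report = None

    result = PipelineResult(
        config=cfg, qvf=q, denoised=denoised, smoothed=smoothed,
        clusters=clusters, reproducible=kept, validated=validated,
        report=report, stage_log=log,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _cluster_frame(clusters: list[peaks.PeakCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mean_mz": c.mean_mz,
                "n_members": len(c.members),
                "n_spectra": c.n_spectra,
                "prevalence": c.prevalence,
            }
            for c in clusters
        ]
    )


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    digest = result.config.digest()
    (out_dir / "qvf.json").write_text(
        json.dumps({**result.qvf.to_dict(), "config_digest": digest})
    )
    _cluster_frame(result.clusters).to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
    _cluster_frame(result.reproducible).to_csv(
        out_dir / "reproducible_clusters.tsv", sep="\t", index=False
    )
    if result.validated is not None:
        _cluster_frame(result.validated).to_csv(
            out_dir / "validated_clusters.tsv", sep="\t", index=False
        )
    if result.report is not None:
        result.report.to_csv(out_dir / "group_report.tsv", sep="\t", index=False)
    (out_dir / "run.log").write_text(
        "\n".join([f"config_digest={digest}"] + result.stage_log) + "\n"
    )
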