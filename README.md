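# seldikit

Preprocessing and peak validation for SELDI-TOF mass spectra.

The toolkit implements a two-track preprocessing strategy for
surface-enhanced laser desorption/ionization time-of-flight (SELDI-TOF)
spectra, plus the downstream statistics used in case/control biomarker
studies:

* **Noise model** — the detector response is modelled as a quadratic
  variance function (QVF), `v(mu) = c0 + c1*mu + c2*mu^2`, estimated by
  least squares from the across-spectra mean/variance in peak-free
  regions (`seldikit.noise_qvf`).
* **Detection track** — variance-stabilized soft-threshold wavelet
  shrinkage wrapped in cycle spinning (shift–denoise–unshift–average),
  with the periodized orthonormal Daubechies DWT materialized once as a
  cached sparse matrix (`seldikit.wavelet_denoise`).
* **Quantification track** — a zero-phase equiripple FIR lowpass
  (Parks–McClellan design, order 67, transition band 0.15–0.25, 0.01
  passband ripple, 60 dB stopband attenuation) that preserves peak
  positions and heights (`seldikit.fir_quant`).
* **Peaks** — local-maximum detection, height/area quantification,
  cross-spectrum single-linkage clustering at 0.3% mass tolerance, an
  80%-prevalence reproducibility rule, and sensitivity/FDR benchmark
  metrics (`seldikit.peaks`).
* **Neural-network validation** — a 62-dimensional window descriptor per
  candidate peak (concavity, mass, 30+30 interpolated processed/raw
  intensities) feeding a one-hidden-layer sigmoid network trained by
  conjugate gradients on regularized cross-entropy, with validation-set
  selection of the regularization weight and a per-cluster validation
  procedure that yields cluster prevalences (`seldikit.features`,
  `seldikit.nn_validator`).
* **Group statistics** — Welch t-tests and Mann–Whitney U on peak
  heights/areas, and the mid-P-corrected Fisher exact test on cluster
  prevalence (`seldikit.group_stats`).
* **Synthetic data** — a generator for SELDI-like spectrum sets with
  known ground truth (mass-dependent peak widths, per-cluster prevalence,
  m/z jitter, decaying baseline, QVF noise) and labeled candidate-peak
  fixtures (`seldikit.synthetic`).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (published
filter specs, the published mid-P value, operator-vs-oracle equivalence,
translation equivariance, gradient checks, QVF recovery, and the
end-to-end synthetic benchmark).

## CLI

```sh
seldikit simulate --out sim/ --seed 1 --n-spectra 10   # synthetic set + truth.json
seldikit preprocess --in sim/ --out prep/              # baseline + TIC
seldikit qvf-fit --in prep/ --out qvf.json             # noise model
seldikit denoise --in prep/ --out den/ --qvf qvf.json  # detection track
seldikit smooth --in prep/ --out smooth/               # quantification track
seldikit run-all --out artifacts/ --seed 1             # full pipeline
```

`run-all` without `--in` simulates a default set; with `--with-nn` it
also trains a validator on synthetic annotated candidates and runs the
cluster-validation and group-statistics stages.

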