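# fmridecode

Kernel-regression decoding of fMRI time series: predict continuous
experimental variables ("feature ratings") from 4D brain scans.

In a decoding experiment, each fMRI volume **x**ᵢ ∈ ℝᴰ (D in-mask voxels,
one scan every TR seconds) is paired with a target tᵢ — a rating in [0, 1]
convolved with the canonical hemodynamic response function (HRF). With
D ≫ N, the regression is solved in the dual: similarities between scans
are collected in a kernel matrix **K** = **XX**ᵀ and all model fitting
happens in the N×N kernel space. `fmridecode` implements the full pipeline:

- **Preprocessing** — Gaussian spatial smoothing (6 mm FWHM default),
  gray-matter masking, and removal of low-frequency scanner drift by
  projecting out L discrete-cosine (DCT) bases with the residual-forming
  matrix **R** = **I** − **GG**ᵀ. Detrending is applied *directly to the
  kernel*, **R**ᵀ**KR**, which is equivalent to detrending every voxel but
  dramatically cheaper when D ≫ N. With L = 8 bases over a 704-scan run at
  TR = 1.75 s the high-pass cutoff is 1/352 Hz.
- **Kernel ridge regression (KRR)** — dual ridge, β = (**K** + λ**I**)⁻¹**t**,
  prediction t\* = Σᵢ βᵢ K(**x**ᵢ, **x**\*); equivalent to MAP estimation
  under an isotropic Gaussian weight prior with λ = ασ².
- **Relevance vector regression (RVR)** — sparse Bayesian regression on the
  design Φ = [**1**, **K**] with one ARD precision αᵢ per weight, fitted by
  type-II maximum likelihood; precisions that diverge prune their training
  scans, leaving a small set of relevance vectors.
- **Evidence-based hyperparameter tuning** — maximize the Gaussian-process
  marginal likelihood of **C** = θ₁**I** + θ₂**K** (+ θ₃), giving the
  evidence-implied ridge parameter λ = θ₁/θ₂.
- **HRF-aware post-processing** — the target is **t** = **Hz**_raw with
  **H** a lower-triangular Toeplitz matrix of HRF samples and
  **z**_raw ∈ [0, 1]ᴺ. Predictions are deconvolved by the box-constrained
  QP min_z ‖**Hz** − **t**\*‖² s.t. 0 ≤ **z** ≤ 1, re-convolved, and
  smoothed (3-scan FWHM); discrete temporal shifts absorb non-canonical
  hemodynamic delays; stereotyped event ratings are reconstructed by match
  filtering against an averaged event template.
- **Scoring** — Pearson correlation per held-out session, Fisher-transformed
  (z = atanh r) and averaged.
- **Synthetic data** — a generator of multi-run 4D datasets with known
  ground truth (gray-matter-confined activation blobs, block/event/continuous
  ratings, sub-0.0015 Hz drift, Gaussian noise), so that every stage is
  validated by parameter recovery.

RVR weight maps and KRR dual weights can be scattered back to voxel space
(**w** = **X**ᵀ**Rβ**) for anatomical inspection.

## Worked example

```python
from fmridecode import (SimulationConfig, PipelineConfig,
                        generate_dataset, cross_validate, aggregate_score)

ds = generate_dataset(SimulationConfig(n_runs=2, seed=7))
table = cross_validate(ds, PipelineConfig(lam=100.0))
print(table.rows.to_string(index=False))
print(f"aggregate Fisher-z: {aggregate_score(table):.4f}")
```

```
      rating train_run  test_run  pearson_r  fisher_z
     block_0         1         0   0.905040  1.499401
     block_0         0         1   0.930459  1.661799
    spikes_1         1         0   0.968321  2.064645
    spikes_1         0         1   0.989260  2.610767
continuous_2         1         0   0.042363  0.042388
continuous_2         0         1   0.371156  0.389763
aggregate Fisher-z: 1.3781
```

Each row scores one session-wise cross-validation direction (train on one
run, predict the held-out run) for one rating. Block and event ratings are
recovered at r ≈ 0.9–0.99 under the default noise and drift conditions;
the continuous rating is intrinsically harder because its slow fluctuations
overlap the drift band removed by detrending. The aggregate is the mean
Fisher z over all cells.

The same pipeline is scriptable from the shell:

```bash
fmridecode simulate --config sim.yaml --out data/ --seed 1
fmridecode crossval --data data/ --config pipeline.yaml --out scores.csv
```

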