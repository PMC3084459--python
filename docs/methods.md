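# Methods

This note documents the models implemented in `fmridecode`, their
assumptions, the default parameter choices, and what the synthetic-data
validation does and does not establish.

## Signal model and preprocessing

A decoding dataset is a set of runs (sessions) of N scans each, acquired at
repetition time TR. After masking, scan i is a vector **x**ᵢ of D gray-matter
voxel intensities; the target tᵢ is a feature rating z_raw ∈ [0, 1] convolved
with the canonical HRF. All model fitting operates on the N×N linear kernel
**K** = **XX**ᵀ.

**Spatial smoothing.** Separable Gaussian smoothing with per-axis
σ = FWHM/(voxel size · 2√(2 ln 2)). Default FWHM 6 mm: BOLD signal is
spatially smoother than thermal noise, so smoothing improves voxel-level
SNR (a Wiener-filter argument) and suppresses residual interpolation error
from upstream realignment. Boundaries use a truncated, renormalized kernel
(smoothed data divided by the smoothed mask indicator), which conserves
interior mass and avoids darkening brain edges. FWHM = 0 is the identity.

**Masking.** Analysis is restricted to a binary gray-matter mask (BOLD
changes are predominantly of gray-matter origin; masking typically removes
~80% of voxels and speeds up kernel construction proportionally).
Probabilistic region masks are binarized at a strict threshold
(p > 0.3 by default). Voxel columns follow a fixed raster order — x fastest,
then y, then z, 0-based — so weight maps are reconstructable bit-exactly.

**Drift removal.** Scanner drift concentrates below ~0.0015 Hz. The drift
basis is the orthonormal DCT-II: G[n, l] ∝ cos(π/N (n+½) l) for
l = 0 … L−1, including the constant term, with the l = 0 column scaled by
1/√2 so GᵀG = I. Basis l completes l/2 cycles over the run, so L bases
remove frequencies up to (L−1)/(2·N·TR); with L = 8, N = 704, TR = 1.75 s
this is 1/352 Hz. The count L = 8 includes the constant term: that
convention reproduces the 1/352 Hz cutoff, whereas excluding it would give
1/308 Hz. Detrending is the projection **R** = **I** − **GG**ᵀ (generally
**I** − **CC**⁺ for an arbitrary basis C, via pseudo-inverse so rank
deficiency is harmless). For a linear kernel the projection commutes with
the Gram product, K_detrended = **R**ᵀ**KR** — an O(N²D) → O(N²(D+N))
saving that makes detrending essentially free once the kernel exists.
Detrending is per run by default (block-diagonal R over run boundaries;
drift is session-specific); concatenated-run detrending is available by
flag.

## Regression models

**KRR.** Ridge regression min_w ½Σ(wᵀxᵢ − tᵢ)² + (λ/2)‖w‖² in dual form:
β = (**K** + λ**I**)⁻¹**t**, prediction t\* = Σᵢ βᵢ K(**x**ᵢ, **x**\*).
The solve is a symmetric (Cholesky) factorization — never an explicit
inverse — with a logged jitter fallback (10⁻¹⁰·trace/N added on failure).
λ = 0 is allowed only for invertible kernels. Probabilistically, KRR is the
MAP estimate under w ~ N(0, α⁻¹I) and Gaussian noise σ², with λ = ασ².
On synthetic data at moderate SNR the held-out correlation is flat across
λ ∈ [10², 10⁵] (verified as a test property), so the default grid spans
10⁻²…10⁸ in decade steps and selection follows the session-wise
cross-validation rule: evaluate each λ on the held-out session and keep the
best.

**RVR.** Sparse Bayesian regression on Φ = [**1**, **K**] with independent
priors βᵢ ~ N(0, αᵢ⁻¹). Type-II ML maximizes the marginal likelihood
p(**t**|**α**, σ²) = N(**t**; 0, σ²**I** + **ΦA**⁻¹**Φ**ᵀ) by the standard
fixed-point iteration: Σ = (σ⁻²ΦᵀΦ + A)⁻¹, μ = σ⁻²ΣΦᵀt,
γᵢ = 1 − αᵢΣᵢᵢ, αᵢ ← γᵢ/μᵢ², σ² ← ‖t − Φμ‖²/(N − Σγᵢ). Numerical choices:

- initialization αᵢ = 1/N², σ² = 0.1·var(t) (standard sparse-Bayes practice);
- pruning when αᵢ exceeds 10⁹× the mean active α or 10¹² absolutely;
  pruned weights are exactly zero, pruned α reported as +∞;
- convergence at |Δ log-evidence| < 10⁻⁶ or 1000 iterations;
- the log evidence is evaluated through the Woodbury/determinant identities
  in the M×M active space, which stays conditioned as σ² → 0 on noise-free
  targets;
- the fixed-point α update is not literally an EM step and can overshoot;
  the fitter records the evidence each iteration and stops (returning the
  best iterate) if an update would decrease it, so the recorded evidence
  path is monotone by construction.

The type-II ML surface is multimodal for small, noisy problems; the
fixed-point iteration finds a local maximum. On well-posed problems (target
genuinely generated from a sparse kernel expansion) it reaches the dominant
mode and recovers the exact support, as the test suite verifies against a
global multistart simplex search.

**Evidence hyperparameters.** For KRR-style models the marginal likelihood
of **C** = θ₁**I** + θ₂**K** (optionally + θ₃, a constant matrix absorbing
target offsets) is maximized in log θ with L-BFGS-B from a moment-matched
start plus 3 seeded random restarts. Without the constant term the kernel
is eigendecomposed once, making each evaluation O(N) with an analytic
gradient; with it, each evaluation is a Cholesky solve. The implied ridge
parameter is λ = θ₁/θ₂. θ₁ and θ₂ are identified by the *spread* of K's
spectrum: a low-rank or near-identity kernel leaves their ratio poorly
determined, which is why the recovery study uses a full-rank kernel with a
wide Marchenko–Pastur spectrum.

**Weight maps.** For linear kernels, **w** = **X**ᵀ**Rβ** (R = I for
undetrended fits; for RVR, β is the posterior mean without the bias). The
prediction identity t\*ⱼ = **w**ᵀ(**Rx**ⱼ) holds exactly and is asserted
in tests.

## HRF post-processing

The canonical HRF is the standard double-gamma difference: a gamma density
peaking at 6 s minus 1/6 of an undershoot gamma peaking at 16 s, unit
dispersions, 32 s support, sampled at TR and peak-normalized to 1.
Peak normalization (rather than unit area) preserves the amplitude scale of
[0, 1] ratings, which the deconvolution box constraints rely on.
Convolution is the lower-triangular Toeplitz product **t** = **Hz**_raw.

**Constrained deconvolution.** Because raw ratings are bounded,
min_z ‖**Hz** − **t**\*‖² subject to 0 ≤ z ≤ 1 is a convex bound-constrained
least-squares problem, solved by an active-set method (BVLS). Any convex QP
solver meeting KKT tolerance is acceptable — the tests pin the objective
against an independent projected-gradient solver, not an algorithm.
Re-convolving the feasible solution and smoothing with a 3-scan-FWHM
Gaussian (truncated-renormalized at the edges) projects noisy predictions
onto the set of signals an admissible rating could have produced; on
synthetic noisy predictions this reliably raises the held-out correlation.

**Temporal shifting.** Self-paced behaviors can lead the canonical
hemodynamic delay. Rather than refitting a five-parameter HRF, the training
target is shifted by whole scans (edge-replicating padding, so no spurious
onsets; |k| < N/4) and predictions are inversely shifted. On data whose
signal HRF peaks one TR early, k = −1 beats k = 0 systematically.

**Match filtering.** Event ratings with a stereotyped shape (k events per
run, default 7) are reconstructed by cross-correlating the prediction with
an averaged, onset-aligned, peak-normalized event template; the k best lags
are selected greedily with an exclusion radius of one template length (ties
to the earliest lag) and fixed-amplitude template copies are inserted on a
zero baseline. Detected lags are reported relative to the template's
supra-threshold onset, which trails the raw event onset by the hemodynamic
rise time (~3 scans at TR 1.75 s).

## Scoring

Per held-out session, the Pearson correlation between the post-processed
prediction and the true convolved rating; reported per
(rating, train-run, test-run) cell plus the arithmetic mean of Fisher
z = atanh(r) over cells. The Fisher transform stretches high correlations:
improving r from 0.8 to 0.9 gains about three times as much z as improving
0.2 to 0.3, so effort concentrates on ratings that can be predicted well.
|r| is clipped at 1 − 10⁻⁷ (with a warning) because match-filter
reconstructions on synthetic data can be near-perfect.

## Synthetic data: what it emulates, and what it does not

`generate_dataset` composes, per voxel and scan:

    baseline + drift + effect_amplitude · Σ_r weight_map_r · t_r + noise

- **baseline**: a smooth positive field (~100 intensity units), constant in
  time — exercises masking and detrending realistically (a constant image
  is a huge shared kernel component until detrended).
- **drift**: per run, three cosine components with frequencies drawn below
  0.0015 Hz, each with voxel-specific amplitude and phase (quadrature pairs
  of smooth random fields), total amplitude ~5 units. Spatial heterogeneity
  matters: spatially coherent (low-rank) drift is nearly harmless to ridge
  regression, while voxel-specific drift degrades held-out accuracy the way
  scanner drift does in practice — which is what makes the detrending
  ablation meaningful.
- **signal**: per rating, Gaussian blobs (σ = 1.5 voxels, truncated at 3σ,
  confined to the gray-matter mask) times the HRF-convolved rating, at
  amplitude 1 — a weak single-voxel effect (SNR ≈ 1 against the noise)
  that becomes decodable only by pooling voxels, as in real data. The
  scoring target always uses the canonical HRF; optionally the injected
  signal can follow an HRF with a different peak delay to create the
  hemodynamic mismatch that temporal shifting addresses.
- **noise**: iid Gaussian, σ = 1.
- **ratings**: binary blocks (~10-scan blocks), spike trains (7 copies of
  the HRF response to a 3-scan boxcar, clipped to [0, 1], non-overlapping,
  with an end margin of one template length so every event's response
  completes within the run), and smoothed random walks rescaled to [0, 1].

Randomness is divided into independent named streams (baseline/mask,
weights, ratings, drift, noise), so the injected signal is exactly
proportional to `effect_amplitude` and null simulations share everything
but the effect.

Default problem sizes are desk-scale — a 16×16×8 grid with 128 scans per
run — chosen so the full test suite and the acceptance studies run in
minutes on one core while preserving every structural feature of the
full-scale design (64×64×34, 3×704 scans, TR 1.75 s, available via
`SimulationConfig.full_scale()`). Two consequences of desk scale are worth
noting: the continuous rating kind overlaps the drift band more severely at
128 scans than at 704 (its low frequencies fall inside the per-run DCT
removal band), and the drift-vs-DCT leakage property is only meaningful at
the full run length.

What passing the synthetic studies does **not** show: the generator has no
subject motion, no physiological (cardiac/respiratory) noise spectra, no
temporal autocorrelation in the noise, no spatial noise correlations beyond
smoothing, and no inter-subject variability. Recovery results here certify
the correctness of the machinery, not expected accuracy on real scanner
data.

## Known limitations

- RVR sparsity on these clean synthetic problems (~2–4% relevance vectors)
  is far below what heterogeneous real data produce (tens of percent);
  sparsity levels are design-dependent and should not be compared across
  data regimes.
- The evidence optimizer assumes iid noise; temporally autocorrelated noise
  biases the implied λ (a known failure mode of evidence-based tuning on
  fMRI data, and one reason cross-validated λ selection is the default).
- Match filtering assumes a fixed event amplitude; events with graded
  amplitudes would need per-event scaling, which is deliberately not
  implemented.
- The CLI `predict` command rebuilds the kernel from the stored dataset
  directory; cross-dataset prediction (train on one directory, predict
  another) is only supported through the library API, where the joint
  detrending choices are explicit.
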