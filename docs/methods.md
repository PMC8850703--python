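# Methods

This note documents the models, conventions and numerical choices behind
`ecgsubband`, in the order the pipeline runs.

## Signal model and preprocessing

The unit of analysis is a short single-lead ECG segment: 2 s at 250 Hz
(500 samples) by default, covering 2–3 QRS cycles at typical heart rates.
Segmentation cuts non-overlapping windows (window and hop configurable);
trailing partial windows are dropped, and a window longer than the record
yields an empty list with a warning rather than an error.

Amplitude normalization is the two-step form `y(n) = x(n) − x̄`,
`z(n) = y(n)/max|y(n)|`, with the mean taken over the full segment
(population form). The result has zero mean and maximum absolute value
exactly 1, removing inter-recording gain differences while preserving
morphology. Constant segments are rejected with a typed error: the
division is undefined, and silently mapping to zeros would later poison
mobility with 0/0. Resampling to a common rate uses rational polyphase
resampling with an anti-aliasing low-pass filter, the standard approach
for fixed-ratio rate conversion.

## Wavelet sub-bands

A 5-level 1-D DWT splits each normalized segment into six sub-bands
(cA5, cD5 … cD1). The mother wavelet defaults to Daubechies-4 and the
boundary mode to symmetric padding; both are configurable
(`wavelet.name`, `wavelet.mode`) and recorded in every feature vector's
metadata. Energy bookkeeping (coefficient energy = signal energy to
1e−8) holds for orthogonal wavelets under periodization, which the test
suite uses; symmetric padding trades exact energy conservation for fewer
edge artifacts and remains the extraction default.

**Features are computed on band-limited reconstructions, not on the raw
coefficient sequences.** At level 5 a db4 coefficient has an effective
support of roughly 218 samples, so a 2 s segment leaves only ~22
coefficients in cA5/cD5, every one of them overlapping a beat. Sample
entropy (m = 2, r = 0.2 σ) is then frequently undefined — no
(m+1)-template pair falls within tolerance — and records would have to be
dropped wholesale. Reconstructing each band alone (all other bands
zeroed, inverse transform, truncated to the original length) keeps the
band's spectral content at full temporal resolution, and every entropy is
well defined on all default records. The coefficient decomposition
remains available (`dwt_decompose` / `reconstruct`) for users who want
the decimated representation.

## Hjorth descriptors

Activity, mobility and complexity are computed from the population
standard deviations (divide by N) of the sequence and its first and
second backward differences; the difference sequence is defined for
n = 1..N−1 (length N−1), the only consistent reading of a backward
difference. Degenerate inputs raise typed errors — a constant sequence
(mobility undefined) and an exact linear ramp (complexity undefined) —
so a poisoned sub-band is visible in logs instead of propagating NaNs.

## Entropy measures

All six measures share lag τ = 1 by default and are deterministic
(ordinal ties break by order of appearance via stable argsort).
Hyperparameter defaults follow each measure's originating literature:

| measure | parameters (default) | normalizer (on by default) |
|---|---|---|
| Shannon | energy distribution p_i = x_i²/Σx_j² | ln N |
| sample | m = 2, r = 0.2 σ (population SD), Chebyshev | none (unbounded) |
| permutation | m = 3 | ln m! |
| dispersion | m = 2, a = 6 normal-CDF classes | ln aᵐ |
| bubble | m = 8, Rényi-2 swap-count entropies | log((m+1)/(m−1)) (built in) |
| slope | m = 3, γ = 1.0, δ = 1e−3 | ln min(#windows, 5^(m−1)) |

Sample entropy counts both the m- and (m+1)-point template matches over
the first N − mτ templates (self-matches excluded), so a strictly
periodic sequence scores exactly 0. When no template pair matches, the
value is undefined and a typed error is raised; at the feature-matrix
level such records are dropped with a logged reason, never imputed.
Shannon (energy form) and slope entropy are intentionally not
shift-invariant; the other four are.

Slope entropy normalizes by the log of the *achievable* pattern count —
the smaller of the number of windows and 5^(m−1) — so short sequences
can still reach 1.

## Feature matrix and ANOVA screen

The 54 features are ordered band-major (cA5 block first, then cD5 … cD1;
within a block Hjorth then entropies), a frozen ordering that makes
feature CSVs reproducible byte for byte. The CSV embeds the resolved
wavelet/entropy configuration and the run's config hash in `#` comment
lines. Feature families: `hjorth` (18 columns), `entropy` (36), `all`
(54).

The screen is a one-way fixed-effects ANOVA per feature with raw
p-values by default (an optional Bonferroni column multiplies by the
number of features). If every group has zero within-group variance the F
ratio is degenerate: equal means report p = 1, unequal means p = 0, both
flagged. Because the per-band screen has 54 rows, a convenience view
(`family_mean_features`) averages each feature kind across bands,
clearly labeled `mean_*`.

No feature scaling is applied before classification by default; an
optional z-score switch exists for distance- and gradient-based
classifiers and its use is logged.

## Classifiers and model selection

The train/test split holds out 12 AF / 14 CHF / 12 NSR records (38 of
150) by seeded per-class sampling without replacement. Grid search is
exhaustive, scored by mean accuracy over stratified 5-fold CV with folds
fixed across cells; ties break toward the first cell in documented grid
order, so selection is fully deterministic given a seed. Grids: k-NN
k ∈ {1,3,…,31} × {euclidean, minkowski (order 3, so it differs from
euclidean), chebyshev}; SVM kernel {linear, rbf, poly (degree 3)} ×
γ ∈ {1e−1…1e−6} × C ∈ {1…1e5} in decade steps, one-vs-rest; random
forest trees {10,50,100,150,200,300,400,500} × {gini, entropy}. k-NN
cells with k larger than the smallest CV training fold are skipped with
a warning (they arise only far below the study's sample sizes).

The ANN is a single-hidden-layer perceptron (input-32-3), ReLU hidden,
softmax output with cross-entropy loss, Adam at learning rate 1e−3, 200
epochs, batch 16, seeded initialization. The RBF network uses 32
Gaussian centers initialized by seeded k-means on the training features,
a shared width equal to the mean nearest-center distance, and a linear
output layer trained with RMSprop (ρ = 0.9) on mean-squared error
against one-hot targets for 500 epochs at learning rate 1e−3, batch 16.
Both have fixed architectures, so their "grid" is a single cell and the
CV table still reports their fold accuracies.

## Synthetic data generator

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) with
class-specific amplitudes and widths; beat onsets follow a normal RR
distribution clipped at 0.3 s. The class models emulate:

* **NSR** — RR 0.80 s, CV 4%, full P-QRS-T, noise SD 0.010;
* **AF** — RR 0.55 s, CV 22% (irregular), P amplitude 0, a band-limited
  4–10 Hz fibrillatory oscillation (RMS 0.12), noise SD 0.020;
* **CHF** — RR 0.95 s, CV 3% (low variability), R reduced to 0.45 with a
  broadened, taller T, noise SD 0.060.

These constants were tuned once and frozen. After peak normalization the
reduced-amplitude CHF morphology yields the highest signal variance and
NSR the lowest, giving the qualitative ordering activity(NSR) <
activity(AF) < activity(CHF) with NSR also lowest in mobility, and the
54-feature matrix separates the classes (grid-searched k-NN reaches 1.0
test accuracy on the frozen master seed and ≥ 0.95 across master seeds).
The generator reproduces statistical class structure — RR variability,
fibrillatory band energy, morphology differences — not physiological
waveforms: it has no beat-to-beat morphology drift, no baseline wander,
no electrode artifacts, and Gaussian bumps only approximate real P-QRS-T
shapes. Passing tests therefore demonstrate that the pipeline recovers
class structure of this kind when present; they say nothing about
accuracy on real recordings.

Per-record seeds are spawned deterministically from the master seed, so
a dataset is a pure function of (n_per_class, duration, fs, seed).

## Problem sizes and determinism

The shipped experiments use the 150-record, 2 s / 250 Hz dataset: large
enough for the 112/38 split and stable CV, small enough that the full
pipeline (including the RF and SVM grids) runs in a few minutes on one
core. Every stochastic step — dataset generation, splitting, CV fold
shuffling, network initialization — derives from explicit integer seeds;
rerunning a configuration reproduces feature CSVs and reports byte for
byte. Artifacts embed a 12-hex-digit hash of the scientific
configuration (output paths excluded), and downstream subcommands refuse
artifacts whose hashes disagree.

## Known limitations

* Real-data validation requires PhysioNet recordings, which are read via
  the bundled CSV/WFDB readers but are not downloaded or tested here.
* The WFDB reader supports single-file records in formats 16 and 212
  only.
* Sample entropy remains undefined on sequences with no template
  matches; such records are dropped, which can shrink datasets built
  from very short or very noisy segments.
* The RBF network's shared-width Gaussian layer is a deliberate
  simplification; per-center widths or supervised center refinement are
  out of scope.
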