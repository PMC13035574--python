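# Methods

## Phantom model

Tissue reflectance is generated from a single-layer Beer–Lambert
approximation, R(λ) = S(λ)·10^(−A(λ)). The absorbance A combines three
chromophores through smooth synthetic extinction templates:

* **oxyhemoglobin** — Gaussian bands at 542 nm (σ 12) and 577 nm (σ 10),
  plus a small near-infrared shoulder at 900 nm (σ 40, amplitude 0.10).
  The shoulder is deliberately weak: it overlaps the 880–900 nm
  denominator window of the water index, and a strong shoulder would let
  hemoglobin confound the water signal.
* **deoxyhemoglobin** — a broad 555 nm band (σ 20) and the 760 nm band
  (σ 22, amplitude 0.45).
* **water** — the dominant 970 nm band (σ 35) and a minor 740 nm band.

S(λ) = a·(λ/500)^(−b) is a power-law scattering baseline. These
templates are qualitative stand-ins chosen to place absorption structure
in the 500–600 nm and 750–800 nm oxygenation regions and around 970 nm;
they are not published molar extinction tables, so index values are
meaningful only ordinally (more water ⇒ higher TWI), never absolutely.

Default class physiology (oxygen saturation, total Hb, water fraction,
scatter amplitude, scatter slope):

| class | f | c_Hb | w | a | b |
|---|---|---|---|---|---|
| esophagus | 0.55 | 0.80 | 0.35 | 0.95 | 0.75 |
| stomach | 0.65 | 1.20 | 0.45 | 1.00 | 0.85 |
| cancer | 0.85 | 1.60 | 0.70 | 0.95 | 0.70 |

Cancer is programmed blood-richer, wetter and more oxygenated than
healthy mucosa — the physiology the group comparisons are designed to
detect. Within-class heterogeneity comes from per-pixel multiplicative
log-normal jitter on c_Hb and w (default SD 0.15, clipped to valid
ranges) plus additive Gaussian reflectance noise (SD 0.01); both produce
the large within-class spectral variance real mucosa shows. Cohorts add
a patient level: per-patient log-normal draws (SD 0.10) of c_Hb, w and
a around the class defaults. Tumor stage is a per-patient label whose
only programmed effect is a water-fraction increment (default +0.15) in
all tissue of T3/T4 patients, emulating peritumoral edema.

The default layout is esophageal mucosa left of a 0.42 split, gastric
mucosa right, and a central cancer ellipse covering ≈ 7.5 % of pixels —
the same order of magnitude as the class imbalance in annotated surgical
cohorts (≈ 2.18 M gastric, 1.47 M esophageal, 0.30 M cancer spectra).
Default cube size is 64×64×100 (desk scale); the spatial dimensions are
configurable up to the camera's native 480×640.

**What the phantom does not model:** radiative transfer and multiple
scattering, specular highlights, instrument artifacts, spatial texture
within a tissue class (pixels are conditionally independent given the
patient), annotation errors, and the histological heterogeneity of real
carcinomas. Passing tests therefore demonstrate that the pipeline
recovers *programmed* structure, not that clinical performance would
reach the same numbers — the benchmark macro summaries (74 ± 8 %
sensitivity, 89 ± 2 % specificity, 81 ± 3 % AUC) come from the published
clinical study, and this package reproduces the *arithmetic* of those
summaries, not the clinical experiment.

## Preprocessing

Order: spectral median filter → SNV → crop to [520, 1000] nm (closed
interval; on the default 100-band grid 96 bands survive). The median
filter runs along the spectral axis with reflect padding, kernel 5 — the
smallest kernel that removes single-band spikes. SNV uses the sample SD
(n−1); spectra with SD below 1e−8 (fully shadowed pixels) map to zero
rather than raising, so one dead pixel cannot abort a run. Whether SNV
precedes or follows the crop is genuinely open; both orders are
supported (`snv_before_crop`), the default applies SNV to the full
spectrum first, and the non-commutativity of the two orders is asserted
in the tests rather than hidden.

## Physiological indices

Each index is mean absorbance (A = −log10 max(R, 1e−4)) over a numerator
window divided by mean absorbance over a denominator window, mapped
through a fixed scaling interval onto [0, 1]:

| index | numerator | denominator | scaling |
|---|---|---|---|
| StO2 | 570–590 nm | 740–780 nm | (0.5, 6.5) |
| NIR-PI | 825–925 nm | 655–735 nm | (1.75, 4.0) |
| OHI | 530–590 nm | 785–825 nm | (0.25, 9.5) |
| TWI | 955–980 nm | 880–900 nm | (1.15, 3.2) |

The scaling intervals were fixed once, numerically, so that (i) an
absorber-free scattering baseline sits at or below each floor and (ii)
the physiologically plausible phantom range spans the interior without
saturating. Indices are computed from the raw cube — SNV destroys the
absolute absorbance scale band ratios need — and pixels whose
denominator absorbance falls below 1e−6 are flagged invalid rather than
silently clamped. Vendor formulas for these indices are not public;
windows and scalings are configuration keys and all downstream claims
are ordinal.

## Classifier

Architecture for a p×p×B′ patch (defaults p=3, B′=96): Conv3D(8,
kernel 3×3×7) → ReLU → Conv3D(16, kernel collapses remaining spatial
extent ×7) → ReLU → collapse spatial dims into channels → Conv1D(32, k=5)
→ ReLU → Conv1D(64, k=5) → ReLU → flatten → dropout 0.5 → dense softmax
over 3 classes (28,915 parameters at the defaults). Convolutions are
valid (no padding); prediction maps shrink by (p−1)/2 per side and
border pixels are reported as no-prediction. The patch label is the
center pixel's class; softmax ties break toward the lower class index.

The implementation is pure numpy: im2col windows feed one BLAS matmul
per layer, backward passes are explicit, and the backward pass is
verified against numerical differentiation in development. He-normal
initialization, shuffling and dropout all derive from `ModelConfig.seed`,
so builds and training runs are bit-reproducible on a fixed thread
configuration.

Training minimizes class-weighted cross-entropy with balanced weights
w_c = N/(K·n_c) (their weighted mean over the labels is exactly 1, so
weighting reallocates gradient mass without changing the loss scale).
After each epoch the validation cancer F1 is computed; training stops
once it fails to improve for `early_stop_patience` consecutive epochs
and the best-epoch parameters are restored.

**Optimizers.** `ModelConfig` defaults mirror the published training
setup: batch 128, learning rate 1e-4, Adadelta (the nearest named
optimizer to the published "delta optimizer"; the learning rate
multiplies Adadelta's self-scaled step, so lr = 0 provably leaves
parameters untouched). Adadelta at lr 1e-4 is, however, extremely slow
from a cold start — appropriate for long GPU schedules, not for
desk-scale runs. The evaluation entry points therefore use Adam at
lr 1e-3 for the seeded desk-scale experiments; the optimizer and rate
remain plain configuration switches. A seeded random-search helper
(`random_search`) over patch size, learning rate, dropout and 1-D kernel
stands in for full Bayesian hyperparameter optimization.

**Problem sizes.** Desk-scale LOPO experiments use 8 patients with
64×64×100 cubes, at most 2,500 training and 1,500 validation patches per
fold (stratified subsampling), 6 epochs with patience 2. These sizes
were chosen so a full 8-fold run completes in minutes on one CPU core
while still training to near-perfect separation of the phantom classes.

## Evaluation

All metrics are patient-wise: a confusion matrix per held-out patient,
one-vs-rest collapse per class, sensitivity TP/(TP+FN), specificity
TN/(TN+FP), F1 2TP/(2TP+FP+FN), MCC (TP·TN−FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
Zero denominators return 0 with a warning — this keeps patient-wise
averaging total. A class absent from a patient's annotation produces a
*missing* row that is excluded from averages, never zero-filled; this
matters because not every specimen contains all three tissues. AUC is
the tie-corrected rank-sum (Mann–Whitney) statistic, which equals
trapezoidal ROC integration exactly; single-class inputs give a missing
AUC, not 0.

Aggregation: per class, mean and sample SD (n−1) across patients; the
across-tissue ("macro") summary is the unweighted mean of the three
per-class means, with the sample SD *of those three means*. This is the
convention under which per-class sensitivities (0.65, 0.77, 0.81)
summarize to 74 ± 8 % — reproduced exactly by `aggregate()` on the
benchmark values in `esohsi.benchmark`.

LOPO folds: one test patient per fold, three validation patients drawn
uniformly without replacement from the remainder under the fold seed,
rest training. A cohort must have ≥ 5 patients.

## Statistics

The analysis unit is the per-patient region mean, not the pixel:
within-patient pixels are strongly correlated, and testing them directly
would pseudo-replicate by three orders of magnitude. The default test is
Welch's unequal-variance t (group variances differ visibly between
healthy and tumor regions); pooled-variance Student is a configuration
switch, as is Holm correction (off by default, matching per-comparison
star annotation: * p<0.05, ** p<0.01, *** p<0.001, strict inequalities).
Two all-constant equal groups return p = 1 rather than NaN.

Calibration is checked by simulation: under a null cohort (stage water
increment 0) the TWI stage comparison rejects at the nominal 5 % rate
(1,000 seeded replicates, tolerance ± 0.02). The null simulation runs at
the parameter level — per-patient chromophore draws mapped through the
noise-free template to a TWI value — because rendering full cubes leaves
the null distribution of per-patient means unchanged while costing three
orders of magnitude more time.

## Numerical conventions and edge cases

* Reflectance floor 1e−4 before the log transform (A ≤ 4).
* SNV degenerate guard: SD < 1e−8 ⇒ zero spectrum.
* Median filter: reflect padding, odd kernels only.
* ENVI I/O: BSQ/BIL/BIP accepted on read, float32 little-endian BSQ
  written; all metadata inconsistencies (band/wavelength count mismatch,
  truncated binaries, unknown interleaves) raise rather than coerce.
* Argmax ties: lowest class index wins (documented, deterministic).
* Checkpoints: config JSON plus raw parameter blobs in one `.npz`.

## Known limitations

* The extinction templates and index scalings are synthetic; absolute
  index values do not transfer to any clinical device.
* The classifier's near-perfect phantom performance reflects the
  programmed class separation, not expected clinical difficulty.
* No spatial correlation within tissue regions; patch context therefore
  adds less information than it would on real texture.
* Adadelta's published learning rate is honored as a default but is not
  practical for short CPU schedules (see Optimizers above).
* Only the hybrid 3D-1D architecture is provided; inception-style
  variants would slot in behind `build_model` but are not implemented.
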