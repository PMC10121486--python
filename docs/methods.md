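# Methods

`asbestoscreen` re-implements, at desk scale and on synthetic data, a
three-stage AI system for screening applications to an asbestosis state-aid
programme, together with the clinical-panel statistics and lung-function
rules that surround it. This note records the models, the knobs that
matter, the synthetic-data design, and the numerical choices, so that a
maintainer can tell which behaviours are intrinsic to the method and which
are artifacts of the phantom setting.

## The screening problem

Applicants with occupational asbestos exposure are assessed by a panel of
three pulmonologists; the majority vote decides eligibility. The diagnosis
rests on chest CT (diffuse fibrosis preferentially peripheral and basal)
and on lung-function loss, summarised by an AMA impairment class derived
from FVC and DLCO (% of predicted). The pipeline replicates that decision:

1. **Localisation/curation** — Hounsfield units are clipped to
   [−1024, 3072] HU and scaled to [0, 1]; the lungs are segmented; the mask
   is dilated by a 13 × 13 × 5 voxel box so pleura and adjacent chest wall
   survive masking; non-lung voxels are zeroed; the volume is cropped to
   the mask bounding box and resampled to the working grid.
2. **Detection** — a variational autoencoder (VAE) trained only on healthy
   lung slices reconstructs each axial slice; the absolute reconstruction
   error, smoothed and max-normalised, is an anomaly heatmap.
3. **Classification** — a small 3-D residual network maps CT (+ heatmap)
   to a probability of a positive panel verdict, trained with binary
   cross-entropy against hard labels (the verdict) or soft labels (the
   fraction of positive votes, 0/⅓/⅔/1).
4. **Fusion and triage** — the simple combination averages the imaging
   probability with the DLCO deficit, `((1 − DLCO) + AI)/2` with DLCO as a
   clipped fraction of predicted; the advanced combination feeds DLCO/100
   into the classifier head as an extra pooled feature. Probabilities in
   the closed band [0.35, 0.60] are triaged to full panel review, the rest
   are "clear".
5. **Panel statistics** — majority verdicts, unanimity decomposition and
   Krippendorff's nominal alpha quantify the panel itself.

## Lung segmentation

Production pipelines often localise the lungs with a pretrained neural
segmentation model; this package deliberately does not assume any
pretrained weights. Here the localizer is a threshold/morphology
segmenter: voxels below −320 HU are
connected-component labelled, components touching the grid border (outside
air) are discarded, the two largest internal components are kept, and holes
are filled. This is self-contained, deterministic, and adequate for any
volume in which the lungs separate from outside air at an attenuation
threshold — which includes the phantoms by construction and most real chest
CTs. Manual mask editing is replaced by a quality-control warning when the
mask occupies an implausible fraction of the grid (outside [0.05, 0.6]).
Order of operations: segmentation runs on true HU *before* intensity
scaling, dilation runs at native resolution before resampling; the volume
is masked, cropped and trilinearly resampled (masks: nearest-neighbour, and
the resampled mask is re-applied so voxels outside it are exactly zero).

## The neural networks

No deep-learning framework is used: both networks are compact NumPy
implementations (`asbestoscreen.nn`) with explicit backpropagation —
N-dimensional convolution via im2col/GEMM, dense layers, ReLU,
nearest-neighbour upsampling, global average pooling, Adam. Every layer's
backward pass is verified against finite differences in the test-suite, and
the classifier's input gradient doubles as the saliency map.

**VAE (detector).** Per-slice, 48 × 48: two stride-2 convolutions
(8, 16 channels) → dense → 16-dimensional Gaussian latent; decoder mirrors
with upsample + convolution and a sigmoid output. Loss: mean squared
reconstruction error + `kl_weight` · KL(q‖N(0, I)) with `kl_weight = 1e-3`
(small, because the heatmap only needs a reconstruction bottleneck, not a
calibrated generative model). Heatmaps use the posterior mean, so they are
deterministic given a trained model; they are smoothed with a 1-voxel
Gaussian and max-normalised per volume so the classifier's second channel
is scale-free. "Healthy" training slices are the axial slices (lung-mask
fraction ≥ 5 %) of severity-zero phantoms in the *training split only*.

**Classifier.** Stride-2 stem, then stages of (8, 16, 32) channels with
stride-2 downsampling convolutions in between and identity-connection
residual blocks in the two coarser stages (block counts (0, 1, 1)); global
average pooling and a sigmoid head. A scalar sigmoid output with binary
cross-entropy handles hard and soft targets uniformly. The exact
depth/width of the original network is unknown; both are configuration
here, and the defaults are sized so that training a model on 200 phantoms
takes a few minutes on one CPU core.

Training on cohorts of a few hundred volumes has a characteristic failure
mode: the loss sits at the constant-predictor level for many epochs before
the network breaks symmetry, and on some initialisations it never does
within the epoch budget. Three choices address this: inputs are multiplied
by 4 before the stem (unit-interval CT intensities are small and early
gradients starve otherwise); activations are leaky rectifiers (slope 0.1 —
with nonnegative image inputs a fully dead unit cannot recover); and a run
whose best validation loss has not at least roughly halved the
constant-predictor baseline by the extension cap is treated as a failed
initialisation and retrained with a deterministically derived seed (up to
2 restarts, best attempt kept). Optimisation is Adam at 3 × 10⁻³, batch
size 8, a minimum of 25 epochs per attempt — extended up to 48 when the
bar is crossed late, plus 8 polish epochs after crossing — with the
best-validation-loss checkpoint returned; optional sagittal mirroring
augmentation exists but is off by default (the phantom task gains nothing
from it).

## The phantom cohort

The generator's purpose is to exercise the pipeline with the statistical
structure of an applicant cohort, not radiological realism. Each case has:

* **Anatomy** — two ellipsoidal lungs (−800 HU) in a soft-tissue body
  (40 HU) surrounded by air (−1024 HU), Gaussian noise of 20 HU inside the
  body; default grid 48 × 48 × 24 (sagittal, coronal, axial; the full-size
  192 × 192 × 96 grid is supported but not the default, to keep CPU
  training in minutes).
* **Lesions** — band-pass-filtered noise scored with a spatial prior
  (peripheral + basal for asbestosis-like fibrosis; central + apical for
  non-asbestos interstitial disease), thresholded so the lesion voxel count
  is exactly `round(severity_img · 0.25 · n_lung_voxels)` — lesion burden
  is monotone in the latent imaging severity by construction. Lesion
  voxels take fibrosis-like attenuation around −150 HU.
  `plaques_only` phantoms instead raise a thin pleural shell to 150 HU with
  no parenchymal lesion.
* **Latent severities** — 30 % of cases have zero imaging severity, the
  rest uniform on [0.05, 1]. The functional severity is
  `0.5 · severity_img + 0.5 · u` with an independent uniform latent `u`;
  this mixing weight is the single knob decoupling lung function from
  imaging, and 0.5 lands the cohort-level DLCO–imaging r² near 0.28
  (inside the intended [0.1, 0.4] band at n = 500).
* **Lung function** — DLCO% = 100 − 55 · severity_func + N(0, 12),
  FVC% = 100 − 30 · severity_func + N(0, 15), VC similar, clipped to
  [15, 130]. DLCO declines faster and with less noise than FVC, making it
  the more informative parameter, as observed clinically.
* **Votes** — each of three raters votes positive iff
  `0.7 · severity_vote + 0.3 · severity_func + ε > τ` with i.i.d.
  ε ~ N(0, 0.15). The rater noise was calibrated once so that cohort
  unanimity sits near 0.76 (inside [0.70, 0.85] at n = 500); the threshold
  τ is solved per cohort so the *expected* majority prevalence matches the
  target (default 0.46) — rater noise, and hence unanimity, is untouched by
  that root-finding. The panel votes on *asbestosis*: non-asbestos
  interstitial disease is heavily discounted (vote severity 0.15 × imaging
  severity) and plaques/healthy lungs carry no parenchymal vote signal.
  This creates a small admixture (~4 %) of "contradictory" cases (ILD
  pattern without an asbestosis verdict, or a positive verdict with no
  parenchymal disease); mirroring the evaluation practice of holding such
  cases out, the experiment flags them (`contradictory_mask`) and excludes
  them from all splits.

What the phantoms do **not** model: airway/vessel trees, scanner protocol
heterogeneity, slice-thickness effects, partial lung coverage, real
fibrosis texture, or rater identity (all three raters share one noise
scale). Consequently, passing the end-to-end tests shows the pipeline is
correctly wired and learns lesion-driven verdicts under weak imaging–
function coupling; it says nothing about performance on patient data.

## Evaluation choices

* AUC is the rank statistic with ties counted ½; confidence intervals are
  percentile bootstrap with 2000 seeded resamples (single-class resamples
  are discarded). Confusion-matrix metrics default to a 0.5 operating
  point; ratios with zero denominators are reported as missing (NaN).
* McNemar's test on paired correctness uses the exact two-sided binomial
  form below 25 discordant pairs, otherwise chi-square with continuity
  correction.
* Krippendorff's alpha is computed from per-unit category counts (for
  nominal data with interchangeable raters this is a sufficient statistic)
  with the finite-sample N(N−1) denominator. When every rating falls in
  one category the expected disagreement is zero; alpha is then defined as
  1.0 with a warning. On the reconstructed 507-case vote table
  (219/55/67/166 cases with 0–3 positive votes) the formula yields
  α ≈ 0.676.
* Saliency is the plain absolute input gradient of the predicted
  probability, summed over channels and max-normalised.

## Desk-scale experiment sizes

The shared end-to-end experiment uses n = 200 phantoms on the 48 × 48 × 24
grid (train/val/test ≈ 0.63/0.16/0.21, stratified by verdict), 40 VAE
epochs on the healthy training slices, and 25 minimum epochs per classifier; the
cohort-calibration statistics use a clinical table of n = 500 (no volumes).
These sizes were chosen so the complete experiment, including training two
classifiers, runs in a few minutes on one CPU core while leaving the
measured properties (held-out AUC, detector contrast, dispersion ordering)
clearly resolved.

## Known limitations

* The plateau phase of CNN training on small cohorts makes the first
  epochs uninformative; the input scaling, leaky activations and
  deterministic restarts mitigate but do not fully remove seed-to-seed
  variability in convergence speed.
* The VAE is a deliberately small bottleneck model; on data with richer
  healthy anatomy it would need more capacity before reconstruction error
  is a usable anomaly signal.
* The threshold segmenter assumes air-filled lungs separated from outside
  air; consolidated lungs or CTs with the patient touching the field edge
  would need the QC warning path and manual review.
* Bootstrap CIs at n ≈ 40 test cases are wide; the package reports them
  rather than pretending otherwise.
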