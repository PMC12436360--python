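# Methods

## Problem and approach

Orbital fractures in young patients with facial trauma are screened on
plain radiographs (orbital-rim view) but confirmed on CT; a classifier
that reliably identifies *normal* orbits on the radiograph could avoid
unnecessary CT. `crossrad` implements a dual-input strategy for that
problem: a model sees both the full radiograph and a crop restricted to
the diagnostically relevant region of interest (ROI, the head/orbit
area), and during training the two inputs are *decoupled* by
cross-sequence pairing so the model sees many more distinct
(original, crop) combinations than the dataset contains.

## Cross-sequence pairing

Let `x_1..x_n` be the training originals and `c_1..c_n` their ROI crops,
with binary labels `y_i`. Each image is resampled bilinearly to a fixed
similarity resolution (default 64×64) and flattened to its raw pixel
vector — deliberately without any per-image standardization, so the
similarity reflects actual intensity patterns. Walking the originals in
ascending dataset index order, original `i` is paired with the crop

    argmin_j cos(x_i, c_j)   over unused j with y_j = y_i, j ≠ i,

ties broken toward the lowest index, and the chosen crop is removed from
the pool (matching without replacement). The self-pair `j = i` is
excluded unless it is the only candidate left in the class, which keeps
the plan total; within each label class the map is therefore a
permutation. Minimizing similarity maximizes the diversity of input
pairs, while the same-label constraint guarantees each pair carries one
unambiguous label. Validation and test *always* use identity pairing
(each original with its own crop): pairing is a training-time
augmentation, not part of the predictive model.

The processing order and tie-break are recorded in the plan's
provenance because they change the result; the plan is built once per
training run by default (a `replan_each_epoch` flag exists, but with a
deterministic rule and fixed data the plan is identical each epoch).

## Classifier

Two parallel transformer encoders — one per input stream — with plain
concatenation fusion and a small fully connected head:

* patch embedding (non-overlapping patches, row-major), a learned
  classification token, learned positional embeddings;
* pre-norm transformer blocks (multi-head self-attention + GELU MLP,
  residual connections, layer normalization), final layer norm, and the
  classification-token feature as the branch output;
* fused feature = `[feat_original ; feat_crop]` (concatenation only; no
  cross-attention or other dedicated fusion modules), then one hidden
  fully connected layer and a single logistic output.

A `single` mode keeps only the original-image branch and serves as the
baseline; `multi` mode without cross-sequence pairing isolates the
contribution of the pairing itself.

Profiles: the *desk* encoder (image 64, patch 8, embed 96, depth 4,
4 heads, ~0.9 M parameters in multi mode) is sized so the whole study
runs in minutes on one CPU; a *paper-like* encoder (image 224, patch 16,
embed 192, depth 12, 3 heads) mirrors a conventional small ViT. No
pretrained weights are used anywhere; parameters are drawn from the
config seed (normal, std 0.02) with the final head layer zero-initialized
so optimization starts exactly at probability 0.5.

The model, its training loop and the reverse-mode differentiation
engine behind them are implemented directly on NumPy arrays
(`crossrad.nn`); analytic gradients are verified against central finite
differences in the test suite.

## Training

AdamW on mean binary cross-entropy, 10% linear warmup then cosine decay,
global gradient-norm clipping at 1.0, inputs centered to [-1, 1].
Desk profile: 40 epochs, batch 16, peak learning rate 5e-4, weight decay
1e-4. These values were chosen because a from-scratch ViT on a
~50-sample balanced training split needs a short, strongly regularized
schedule: higher rates intermittently collapse the token features (train
loss snapping back to ln 2), and clipping plus warmup removes most of
that instability. The paper-like profile keeps the conventional ViT
recipe (400 epochs, peak rate 1e-4). The checkpoint kept is the epoch
with the best tuning-set AUROC, ties resolved toward the later (more
converged) epoch; checkpoints from the warmup phase (first 10% of
epochs) are excluded from selection because their tuning metrics are
noise from an undertrained model. Small from-scratch runs occasionally
fall into a non-learning trajectory; when the best tuning AUROC of a
finished run stays below `restart_tune_auroc` (default 0.9), training
restarts from a seed derived from the configured one, at most
`max_restarts` (default 2) times, and the attempt with the best tuning
AUROC is kept — a convergence guard decided on tuning data only, with
the test split never consulted. All randomness (initialization, batch
order, dropout, restart seeds) derives from the seeds in the configs,
so runs are bit-reproducible.

Two evaluation protocols are provided, mirroring common practice: a
7:1:2 stratified train/tune/test split, and stratified k-fold
cross-validation in which each fold's training portion donates a
stratified eighth for model selection. The cross-validation summary
reports both per-fold AUROC (mean ± sd) and the AUROC of pooled
out-of-fold scores, labeled as such, since the two summaries answer
different questions.

## Synthetic phantoms

No real radiographs ship with the package; a generator emulates the
features of the clinical dataset that the method actually exercises:

* an elliptical head outline with soft-tissue fill on a vertical
  background gradient, two bright annular orbital rims (mirror-symmetric
  about the image midline), additive Gaussian noise (default sd 0.02);
* positives interrupt one rim with a gap of amplitude
  `fracture_contrast` (default 0.45; the desk study uses 0.6, a
  strongly visible discontinuity) over an angular sector whose position
  encodes the fracture site — inferior for floor fractures, nasal for
  medial, etc., two sectors for "multiple";
* 18% prevalence by default, and fracture sites drawn from the emulated
  population's distribution (floor 116/330, medial 91/330, superior
  16/330, lateral 3/330, multiple 104/330);
* the ROI is the head bounding box (an `orbits` tightness option gives a
  tight orbital-area box instead);
* the per-sample noise and anatomy streams are independent of the label,
  so the positive and negative renders of one seed differ *only* inside
  the fracture sector — a property the tests exploit to verify signal
  locality.

What the phantoms do **not** model: bone texture, projection geometry,
exposure variation, anatomy of real skulls, subtle non-displaced
fracture appearance. Passing the phantom study shows the pipeline is
correct and that the architecture can learn a localized rim
discontinuity; it says nothing about performance on hospital
radiographs.

Study protocol defaults follow the emulated study: 7:1:2 stratified
split, then negatives in the train and tune splits randomly subsampled
to a 1:1 negative:positive ratio (the test split keeps natural
prevalence). The desk acceptance study uses 200 phantoms, which after
splitting and balancing leaves ≈50 training and ≈8 tuning samples and a
40-sample natural-prevalence test set; these sizes keep a full
three-mode study within minutes on one CPU while leaving the
cross-sequence pairing with a meaningful pool.

## Evaluation statistics

* **AUROC** is computed as the Mann–Whitney statistic (ties ½), which
  equals the trapezoidal area under the empirical ROC; the equivalence
  is asserted against scikit-learn in the tests.
* **Operating point**: Youden's J = sensitivity + specificity − 1,
  maximized over the distinct observed scores with the convention
  "positive when score ≥ threshold"; ties go to the higher-sensitivity
  (lower) threshold, matching the screening intent of ruling fractures
  out.
* **Confusion metrics** (sensitivity, specificity, PPV, NPV, F1) carry
  95% CIs. Sensitivity/specificity use the exact binomial
  (Clopper–Pearson) interval — the method uniquely consistent with the
  reference report's printed intervals; for the predictive values a
  standard-logit interval is also available because source software
  differs there. Undefined ratios (zero denominators) are reported as
  explicit missing values with a reason, never as 0.
* **DeLong test** for paired AUROC differences via per-case placement
  values, with a normal two-sided p and a CI for the difference; its
  calibration is checked against a sign-flipping permutation oracle and
  a null-simulation rejection-rate band.
* **McNemar test** on discordant pairs: exact binomial below 25
  discordances, continuity-corrected chi-square above (a conventional
  switch point), p = 1 when no pairs are discordant.
* **Reader studies**: five-point confidence scores (1 definitely normal
  … 5 definite fracture) give AUROC directly as a rank statistic and
  are dichotomized at ≥ 4 for the confusion metrics; session-to-session
  comparisons use DeLong (on the 1–5 scores) and McNemar restricted to
  truth-positive cases (sensitivity) or truth-negative cases
  (specificity).

## Localization

Gradient-weighted class activation mapping adapted to the transformer:
the fracture logit is differentiated with respect to the patch-token
activations entering the original-image branch's final layer norm;
channel weights are token-mean gradients; the map is the rectified
weighted sum over channels per token, reshaped to the patch grid,
min-max normalized and bilinearly upsampled. The saliency is computed on
the original-image branch only, since that is the image a reader sees.
A single bounding box — the largest 4-connected component of patch cells
at or above the activation threshold (default 0.5) — is emitted *only*
when the model's score clears the operating point; a negative call
yields no box. All-zero gradient maps are flagged and skipped rather
than normalized.

## Numerical and degenerate-input choices

* Boxes are 0-based, half-open, row-major everywhere.
* Cosine similarity is clamped to [−1, 1] against rounding; zero-norm
  vectors raise instead of silently comparing equal to everything.
* Images store as 8-bit PNG and are min-max normalized to [0, 1] on
  load; DICOM ingestion (read-only) applies rescale slope/intercept
  then the same normalization.
* Split counts use largest-remainder rounding per class; a class smaller
  than the number of non-empty splits produces a recorded warning, never
  a silently empty part.
* The exact-binomial CI returns closed bounds 0 and 1 at k = 0 and
  k = n.

## Known limitations

* On the phantoms, the desk-profile model reaches high AUROC largely
  through diffuse intensity cues (a rim gap lowers the summed rim
  brightness and breaks left–right symmetry), not by attending to the
  fracture patch specifically. Its activation maps are therefore not
  expected to peak at the fracture site, and the acceptance study
  reports the measured argmax-in-fracture-region hit rate honestly
  rather than asserting localization. The box-gating contract (a box is
  offered only with a positive call) holds regardless of where the
  activation lies.

* Phantom realism is intentionally minimal (see above); absolute
  performance numbers on phantoms do not transfer to radiographs.
* The desk-scale study trains on ~50 images; tuning-set model selection
  over 8 samples is coarse, and held-out AUROC varies by a few points
  across seeds.
* The pure-NumPy training loop is single-threaded and unsuited to
  paper-scale images (224²) at realistic dataset sizes.
* Reader-study machinery computes per-reader statistics only; no
  multi-reader multi-case variance components.
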