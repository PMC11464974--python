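# Methods

## Problem and pipeline

The package estimates *ordinal* pain intensity from facial image sequences
and turns the estimates into a five-group expression schedule suitable for
driving a pain-expressing avatar in caregiver training. Pain intensity has no
absolute scale across people; what is well defined is the *ordering* of
expressions within and across frames. The pipeline therefore learns a metric
embedding rather than a regressor:

1. **PSPI labeling.** Frame-level ground truth is the Prkachin–Solomon Pain
   Intensity computed from six FACS action units:
   `PSPI = AU4 + max(AU6, AU7) + max(AU9, AU10) + AU43`, an integer in 0–16
   (graded AUs 0–5, AU43 binary). Some descriptions give the range as 0–15
   and call the score a plain sum; we implement the max-pair form (the plain
   sum is available via `compute_pspi(..., mode="sum")`) and assign PSPI 16
   to the "strong" state rather than clipping. Pain states bin PSPI into
   closed integer intervals: none = 0, trace = 1, weak = 2–3, strong = 4–16.

2. **Class balancing.** Pain corpora are heavily skewed toward neutral
   frames. `balance_by_minority` downsamples every state uniformly without
   replacement to the minority class size, preserving within-subject frame
   order; the seed is recorded on the output for provenance.

3. **Metric learning.** Two or three weight-sharing branch networks embed
   frames into R^48. With g(.) the branch output and Euclidean distance,

       L_siamese = sum over same-state pairs  exp(||g(x0) − g(x1)||)
       L_triplet = sum over triplets          exp(d(anchor, positive))
                                            − exp(d(anchor, negative))

   A branch is 3 (optionally 4 or 5) 3x3 stride-2 conv layers with ReLU and
   a doubling channel plan (16/32/64/...), flattened into a 48-unit fully
   connected layer.

4. **SNPI inference.** The sequential pain intensity of frame t is the
   embedding distance to a neutral reference frame (default: the sequence's
   first frame; a consecutive-frame delta variant exists). SNPI is reported
   in raw embedding-distance units — no published normalization exists for
   this quantity.

5. **Pain groups and timelines.** Four ascending thresholds cut SNPI into
   PG1..PG5 (half-open intervals, ties go up). Absent a published rule for
   deriving the cuts, the default calibration takes the 20/40/60/80th
   percentiles of pooled calibration traces. Group sequences are run-length
   encoded into expression segments, with a 0.5 s transition inserted at
   every group change (the neutral→expression→neutral animation convention).

## Numerical and training choices

* **Bounded embeddings.** exp(distance) is unbounded above, and the triplet
  loss is unbounded below in the negative term. The final embedding passes
  through tanh, bounding every pairwise distance by 2*sqrt(48), which bounds
  both losses; the squash can be disabled per `BranchSpec`.
* **Distance at zero.** The gradient of ||a−b|| is undefined at a = b; the
  implementation uses a zero subgradient there.
* **Optimization.** Plain SGD at the conventional defaults (learning rate
  0.1, batch size 64, 30 epochs). The parameter update uses the batch-mean
  loss and clips the global gradient norm at 5.0; without clipping the
  exponential losses occasionally produce steps large enough to destabilize
  training at lr 0.1. Loss *values* reported by `siamese_loss`/`triplet_loss`
  remain the raw sums. Non-finite loss aborts with the failing epoch.
* **Sampling.** The published workflow does not define its pair construction;
  `make_pairs` draws same-state pairs and `make_triplets` draws
  (anchor, positive) within-state and negatives uniformly from other states,
  with replacement across draws, all under one seed. The train/holdout split
  is frame-level, stratified by pain state, 80/20 by default. Training on a
  balanced manifest uses 512 triplets per run by default.
* **Checkpoints.** Single-file npz containing spec+metadata JSON and raw
  weight arrays; round-trips are byte-identical, and the whole
  simulate→train→infer chain is bit-reproducible under fixed seeds on one
  machine.

## Evaluation protocol

`evaluate` pools SNPI over all (subject, level) sequences and compares with
PSPI labels. PCC is computed on raw SNPI (correlation is scale-free). SNPI
units are not PSPI units, so for MAE and the four-state confusion matrix the
predictions are placed on the label scale by *rank matching*: the k-th
smallest SNPI receives the k-th smallest test label. This is the
rank-preserving assignment with no fitted parameters; a perfect ordinal
predictor attains MAE 0 and a diagonal confusion matrix, and any monotone
rescaling of the predictions leaves the result unchanged.

## Synthetic data generator

The generator stands in for elicited-pain corpora so every stage is testable
offline:

* **Protocol.** Each of `n_subjects` (default 2) experiences 5 stimulation
  levels; a level yields `frames_per_level` (default 12, emulating 3–5 fps
  over a few seconds) with a trapezoidal latent intensity p(t): linear rise
  over floor(`ramp_fraction`·frames) frames (default 1/3), plateau at the
  level's peak, linear fall. Peaks default to (0.2, 0.4, 0.6, 0.8, 1.0),
  nondecreasing in level.
* **AU model.** Graded AU_k = round(5·clip(gain_k·p, 0, 1)) with
  round-half-away-from-zero (stated so examples are exactly reproducible);
  AU43 = 1 iff gain_43·p ≥ 0.5. Default gains (1.0, 0.7, 0.6, 0.5, 0.4, 0.6)
  for (AU4, AU6, AU7, AU9, AU10, AU43) are spread so the default corpus
  contains all four pain states — AU4 responds first (trace), the eyes close
  only near maximal pain — and so no sampled latent value sits on a rounding
  boundary.
* **Render.** 64x64 grayscale (the published input resolution is not
  recoverable; size is configurable, minimum 32): a light face oval with
  brow bars that lower/darken with AU4, eye ellipses whose aperture shrinks
  with AU7 and closes with AU43, nose-wrinkle lines with contrast rising
  with AU9, an upper-lip band rising with AU10, cheek shading with AU6, plus
  additive Gaussian pixel noise (default sigma 0.01) and clipping to [0, 1].
  Feature regions are disjoint rectangles exposed by `region_masks` for
  testing.
* **Survey.** SPS (0–5) and SAM valence/arousal (1–9) means are linear in
  level before clipping, with i.i.d. Gaussian response noise. Defaults
  (41 subjects, SPS slope 0.5 from intercept 1.0, valence slope −0.5,
  arousal slope +0.5, noise sd 0.6) give a level-1→5 SPS gap of 2.0 —
  the magnitude typical of graded electrical pain elicitation — and noise
  plausible for a 6-point scale.

What the generator does *not* emulate: identity/appearance variation, head
pose, illumination, AU co-articulation beyond shared dependence on one latent,
temporal noise in stimulus timing, and ordinal-scale (integer) questionnaire
responses. Passing tests on this corpus demonstrate the pipeline's mechanics
and the learnability of a clean monotone latent, not performance on real
faces.

## Statistics

`anova_oneway` is the classical fixed-effects one-way ANOVA;
`tukey_hsd` computes pairwise Q = |mean_i − mean_j| / sqrt(MSW/n_h) with the
harmonic-mean group size n_h for unbalanced groups, flagged against the
studentized-range quantile at alpha (default 0.05). Each subject rates every
level, so the observations are repeated measures; the default analysis
ignores that structure (matching common applied practice) and is therefore
anticonservative — a deliberate, documented caveat. Monte-Carlo calibration
under the generator's null (no level effect) keeps the type-I rate at
nominal alpha, and the default effect sizes give essentially full power at
alpha = 0.01 with 41 subjects.

## Known limitations

* The class-level losses only see the four pain states, so trained
  embeddings saturate distances *between* states and compress gradations
  *within* the strong state (PSPI 4–16). Rank metrics (triplet ordering,
  Spearman against the latent) reflect training gains directly; pooled
  linear PCC against PSPI may not exceed that of an untrained network on
  synthetic corpora whose raw pixel distances are already monotone in the
  label.
* Single-device determinism only; BLAS reductions may differ in the last
  bits across batch shapes, so sequence values are compared at 1e-12 rather
  than bitwise when batch composition differs.
* CPU-scale training only: no GPU path, augmentation, or pretrained
  backbones.
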