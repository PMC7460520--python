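# Methods

## The problem

FIGO sub-stages early endometrial cancer by myometrial invasion depth:
stage IA means the tumor invades less than half of the uterine wall
thickness, IB means half or more. Pre-operatively this is read from
sagittal MR images, and automated reading proceeds in two steps:
segment the uterus and the endometrial lesion, then convert the two masks
into an invasion fraction and threshold it at 50%. Patient MRI from the
motivating study is institutional and cannot be shared, so this package
pairs the analysis pipeline with a synthetic phantom generator whose
ground truth is known analytically; every quantitative claim the test
suite makes is a claim about this synthetic world, not about patient data.

## Phantom model

A phantom slice is built from radial profiles around the uterine center:

- `r_serosa(θ)`: an ellipse (semi-axes ~52×40 px on a 128-px canvas,
  jittered and rotated per case), the outer uterine boundary;
- `r_junction(θ)`: the baseline endomyometrial junction, a trigonometric
  polynomial of order ≤ 3 (mean radius 13–18 px, harmonic amplitudes
  ≤ 1.8 px) — smooth by construction, which is what makes baseline
  reconstruction well-posed;
- `r_lesion(θ)`: the junction plus a cosine-tapered protrusion over a
  60–120° sector whose peak reaches exactly `target_fraction` of the local
  wall thickness.

Masks are rasterized from these profiles (uterus; endometrial compartment
= cavity + lesion, matching how the study's annotators labeled "lesion of
the endometrium"). Tissue intensities per modality mimic the clinical
contrast pattern — enhancing myometrium with hypointense tumor on
contrast-enhanced T1w, bright endometrium/lesion on darker myometrium on
T2w — with additive Gaussian noise (σ = 0.03 on a unit intensity scale;
no bias fields, partial-volume or 3D effects are modeled).

**Realized truth.** The recorded `true_fraction` is measured back from the
emitted masks: the maximum over 1440 rays of penetration depth (lesion
radial extent minus the rasterized baseline cavity's extent) over local
thickness, with bilinear sub-pixel boundary localization. Measuring depth
relative to the rasterized baseline rather than the analytic junction
makes a no-invasion phantom score exactly zero and cancels most
rasterization error; the residual truth-vs-target drift is within ±0.03.
Stage labels obey `IB ⇔ fraction ≥ 0.5` exactly; a sampled case whose
realized fraction lands on the wrong side of its allocated stage is
resampled during cohort generation.

**Leiomyoma.** A fibroid is a disc in the myometrium that bulges the
serosa outward and dents the junction inward around its angular position
(a deformation above the junction's harmonic order). Cohort sampling
places the fibroid adjacent to the lesion sector (angular offset
N(0, 0.4 rad)): clinically it is the fibroid near the tumor bed that
obscures depth assessment, and this is the configuration that makes the
confounder measurable — staging accuracy on leiomyoma-bearing phantoms is
lower than on matched leiomyoma-free twins, reproducing the direction of
the published condition-effect analysis. A uniformly placed fibroid
usually does not intersect the measurement and would dilute the effect to
zero.

**Cohort composition** defaults to the published population: 26.4%
stage IB, 40.3% leiomyoma, ~18% type-II histology (a covariate label
only), per-stage fractions uniform over the pathological ranges observed
in the source (IA: 0–0.48, IB: 0.5–0.87). Counts are allocated exactly
(rounded expectation, shuffled assignment), so the default 72-case cohort
reproduces the study's 53/19/29 composition.

## Invasion-fraction estimator

The estimator sees only the two masks. From the erosion-stable centroid
of the uterus (the lesion centroid is unusable: a deep invasion front
drags it off-center), 720 rays record the outermost lesion and uterus
crossings. The unobservable pre-invasion junction is reconstructed by
fitting `r_lesion(θ)` with a trigonometric polynomial under iterative
asymmetric trimming: each pass drops up to 40% of the most outward-lying
residuals (the invasion front) and refits, converging to the non-invaded
lower envelope. The fraction is the per-ray depth/thickness ratio
maximized over rays, clamped to [0, 1]; rays with < 2 px of estimated
wall are excluded as degenerate. Cases are staged by the maximum fraction
over their slices (deepest invasion governs), IB at an inclusive 0.5.

Numerical choices: default fit order 2 — one order *below* the
generator's junction order, because an order-3 fit has enough flexibility
to bend into a 60–120° invasion front and absorb it into the baseline
(measured RMSE 0.10 at order 3 vs 0.04 at order 2); denominators floored
at 10⁻⁶ px; 0.25-px radial sampling with bilinear interpolation.
Measured on 200 leiomyoma-free phantoms with fractions uniform on [0, 1],
recovery from ground-truth masks achieves RMSE ≤ 0.04 and ≥ 95% stage
agreement; residual errors concentrate, as in the source study, near the
50% cutoff.

## Segmentation

One multi-output U-Net predicts both structures with independent
per-channel sigmoids (the two structures are labeled independently;
lesion ⊆ uterus is enforced after thresholding rather than by a softmax
partition). Training minimizes the soft-Dice loss with smoothing ε = 1,
by plain SGD with momentum 0.9; the checkpoint with the smallest
validation loss is retained, not the last epoch. Predicted masks are
thresholded at 0.5 and reduced to their largest connected component.

Two numerical safeguards address the known failure modes of pure Dice
training from random initialization: gradients are clipped to unit global
norm (occasional Dice-loss spikes can otherwise slam a whole output
channel into empty-prediction saturation), and the head bias starts at −2
so initial predictions are near-empty rather than at p ≈ 0.5, next to the
all-ones plateau where large structures can linger. With both in place,
desk-scale training converges across every initialization seed tried
(uterus IoU ≥ 0.987, lesion ≥ 0.911 over seeds 0–6).

Because the deployment environment has no deep-learning framework, the
layers (3×3 convolutions, max-pooling, nearest-neighbor upsampling,
residual blocks) implement their own backprop in numpy; gradients are
verified against numeric differentiation in the test suite. Encoder
families reproduce the *pattern* of the study's candidates — VGG11-style
(one conv per stage), VGG16-style (two), ResNet34-style (residual
blocks) — at desk-scale widths; ImageNet pretraining is deliberately
unsupported (random He initialization always). The `tiny` family
(~60k parameters, depth 3) is the one actually trained in tests.

Published defaults are kept where they are statements about the method
(batch size 16, Dice loss, SGD, best-validation selection); the published
learning rate 0.001/150 epochs belongs to ImageNet-pretrained encoders at
896² and remains the `TrainConfig` default, but desk-scale runs use
lr 0.01–0.02 for 4–15 epochs, chosen from loss-curve behavior on the
training fold. On 60 phantoms at 128², 15 epochs of the tiny model reach
validation IoU ≈ 0.99 (uterus) and ≈ 0.92 (lesion) on the best-validation
checkpoint. Deliberately under-trained runs (the few-epoch smoke
configurations) can still yield poor lesion masks; the pipeline tolerates
this by flagging empty or unstageable masks rather than failing.

## Concordance statistics

`stats` implements the analysis toolkit: 2×2 diagnostic summaries
(over-staging = calling IB on pathological IA; the over-diagnosis rate is
the share of *discordant* calls that are over-staged), Pearson χ² on 2×2
tables **without** continuity correction, Pearson correlation with the
t-transform p-value, one-way ANOVA from the between/within decomposition,
and type-7 (linear interpolation) five-number summaries.

The published contingency counts are embedded in
`printed_counts.yaml`, and `reproduce_printed_tables()` recomputes every
derivable statistic, comparing at printed precision with half-up rounding
(the source demonstrably rounded 9/16 = 56.25% to "56.3"). The absence of
a continuity correction is likewise pinned by the printed values
themselves (0.0327 → "0.033"). Four printed values are internally
inconsistent with their own counts (a χ² pair printing 0.738/0.392 where
the counts give 0.741/0.389, and two condition-effect p-values); these
are reported side by side and never asserted. The published per-patient
invasion fractions, correlation coefficients, ANOVA F-values and
segmentation IoUs on patient data are not derivable from printed numbers
and are therefore exercised on synthetic cohorts only.

## Evaluation pool

The source study appraised its model on the 42 test patients *plus* the 6
validation patients (48 total). The default evaluation pool follows that
convention and is labeled "study-faithful" in reports; `strict_evaluation`
restricts to the untouched test fold. Augmented images exist only in the
training fold, asserted at the manifest level.

## What a green test establishes — and what it does not

The phantom world is 2D, single-slice, noise-additive, and star-shaped by
construction; its lesions always protrude radially from a smooth
baseline. Green recovery and learning tests establish that the estimator
and network are correct and well-behaved under this stated world. They do
not establish clinical performance: real uteri flex, real junctions are
irregular, real tumors grow exophytically or diffusely, and the published
patient-data accuracies (79.2%/70.8% vs radiologists' 77.8%) cannot be
reproduced without the institutional images. Known further limitations:
no 896² training in tests (supported but slow in pure numpy), no
DICOM ingestion, no 3D volumetry.
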