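# Methods

## Problem and model

A nanoliter-well plate images 3984 wells, each as one 8-bit grayscale frame
(natively 511×511 pixels). Cells are loaded at low density, so a well holds
0, 1, 2 or occasionally more than 2 cells; the task is to classify each
frame into those four categories. `wellcount` implements this as a
convolutional network that maps the raw frame to a softmax posterior
`(p₀, p₁, p₂, p_{>2})`. The predicted category is the argmax; the maximum
entry `h(s) = max_c p_c(s)` is the confidence score used for triage.

The architecture (see `wellcount.network`) is, apart from input and output,
18 layers: a local-response-normalization (LRN) layer applied directly to
the image, four 2×2 stride-2 max-pooling stages, eight 5×5 convolutions
with channel plan 32-32 / 64-64-64 / 32-32-32, four LRN layers, and two
fully connected layers (32, then 512 units) into the 4-way softmax. ReLU
activations are used everywhere except the output; dropout (rate 0.3) acts
on both fully connected layers during training only. At 511×511 input the
weight tensors hold exactly 468,768 elements (biases excluded;
`NetworkSpec.count_parameters()` also reports the total with biases).

Several details are not fixed by the published layer table and were chosen
as the unique minimal assignment reproducing its node counts: all pools are
2×2 stride 2 with ceil ("same") padding; conv3 and conv6 use stride 2; all
other convolutions stride 1 with size-preserving padding. LRN
hyperparameters are the AlexNet-style defaults (radius 2, α=1e-4, β=0.75,
bias 1), exposed on `NetworkSpec`; the first LRN is applied to the raw
single-channel input exactly as the layer order dictates, where it is a
near-identity rescaling. Weights are He-initialized, i.i.d. normal with
mean 0 and variance 2/N_in, N_in being the number of input nodes feeding
one unit (kernel area × input channels for convolutions); biases start at
zero.

Because the spatial arithmetic is pure ceil division, the same channel plan
instantiates at any input side ≥ 64 (`scaled_spec`); only the first fully
connected weight shape changes. This is how the package trains and tests
the architecture at desk scale.

## Training protocol

The optimizer is plain SGD on the softmax cross-entropy (no momentum, no
weight decay — none is part of the protocol). The default learning rate is
0.01 with a config override; on the desk-scale task this step size learns
quickly but can oscillate late in training, which the best-validation
checkpointing absorbs.

Mini-batches are stratified with a fixed per-category composition, by
default 77/21/10/11 samples from the 0/1/2/>2 categories (119 per batch).
This composition is treated as a contract: the sampler always emits exactly
those counts, drawing without replacement within a category when the pool
allows and with replacement when a rare category has too few members (a
category that is entirely absent is an error naming the category). About
20% of the drawn images are augmented with one transform chosen uniformly
from {mirror flip, rot90, rot180, rot270}. "Mirror" is a left-right
reflection; a config switch (`invert="intensity"`) provides the photometric
reading (255 − p) instead. Rotations are counter-clockwise; images are
row-major with the origin top-left, so augmented fixtures are
bit-reproducible.

Plates are the scheduling unit ("subsets", 3984 wells at full scale). The
reference schedule trains 20,000 iterations on the first 5 plates, 10,000
on the next 5, 5,000 on the next 5, then repeated 5,000-iteration stages on
6 plates drawn at random from all training plates. Mini-batches are only
drawn from the plates active in the current stage. Validation runs every
`eval_every` iterations (default 100); training stops when validation loss
has not improved for `patience` (default 10) evaluations, and the
parameters returned are the best-validation checkpoint. Validation loss
(not accuracy) is the early-stopping criterion. A non-finite training loss
aborts with a diagnostic pointing at the learning rate.

Images are conditioned in two steps: a per-image min-max rescale so the
minimum maps to 0 and the maximum to 255 (cancelling per-acquisition
illumination offsets; a constant image maps to all zeros), then division by
255 at the network input. Normalization is per-image; nothing in the data
model precludes a per-plate variant, but none is implemented. No
augmentation and no dropout act at prediction time, so repeated predictions
are bit-identical.

## Synthetic plates

The generator (`wellcount.synth`) emulates the statistical structure of
real plates rather than their photorealism:

* **Occupancy** — counts are Poisson(λ) with default λ = 0.2; with
  probability `cluster_excess` (default 0.05) a nonzero draw is incremented
  by one. This one-parameter mechanism reproduces the observed excess of
  multi-cell wells over the Poisson expectation (attributed to division and
  adhesion) without asserting a particular clustered point process. With
  `cluster_excess = 0` counts are exactly Poisson, which the tests verify
  by goodness of fit.
* **Wells** — square or round walls at intensity 40 on background 96, wall
  thickness and all other lengths expressed at the 511-pixel scale and
  shrunk proportionally for smaller images.
* **Cells** — bright discs with a soft edge and a slightly darker rim,
  radius uniform in 8–20 px and peak intensity 150–230 (at 511 scale),
  placed uniformly inside the wall without overlap by rejection sampling
  (bounded attempts, then an error). The appearance approximates unstained
  bright-field lymphocytes: easy to count by eye, occasionally ambiguous.
  No pixel-size calibration exists for the real system, so these radii are
  plausible rather than measured.
* **Artifacts** — the two failure modes that make real wells hard to call:
  small irregular low-contrast debris polygons (probability 0.04 per well)
  and whole-image Gaussian defocus blur (probability 0.02); plus a
  per-image uniform illumination offset (±25 gray levels — the reason
  min-max normalization exists) and Gaussian pixel noise (σ = 4).

Every well has an independent random stream spawned from the plate seed, so
plates are bit-reproducible and insensitive to evaluation order. What the
generator does **not** model: real cell morphology and its change over
time, fluorescence, well-to-well optical variation within a plate, crowded
wells (counts are capped at `max_render` = 5 drawn cells; the label is
`gt2` regardless), and time-series structure. Passing the learning tests
therefore demonstrates that the architecture and protocol learn *this
family* of counting tasks end to end — not that they reach any particular
accuracy on real microscope data.

## Desk-scale study conditions

The full-resolution protocol (511×511 inputs, 30 plates of 3984 wells,
tens of thousands of iterations) is far beyond a laptop-class CPU, so the
package fixes one desk-scale condition set used by the acceptance tests and
`scripts/acceptance.py`:

* 64×64 wells (the smallest side the six stride-2 stages allow), square and
  round geometries;
* two training plates of 2000 wells, one validation plate of 400, one test
  plate of 800, at λ = 0.2, cluster excess 0.05, default artifacts;
* mini-batch composition (26, 7, 3, 4) — the 119-batch composition scaled
  by one third, preserving the 77:21:10:11 ratios;
* a single 400-iteration stage drawing from both training plates (at 2000
  wells per plate the rare `gt2` category can be nearly absent from a
  single plate, so the desk schedule starts in the regime the staged
  protocol reaches once several plates are active), learning rate 0.01,
  validation every 50 iterations, patience 6.

Under these conditions the trained network exceeds 90% held-out accuracy
for both well shapes, and resolving the 5% least-confident wells strictly
raises concordance — the qualitative behaviour of the full-scale system.

## Triage ("enhanced system")

The ambiguous set at threshold `t` is `{s : h(s) < t}` — strict inequality,
ties retained. `threshold_for_proportion` inverts this: it returns the
largest observed `h` value whose ambiguous fraction does not exceed the
target proportion, so with ties the realized fraction may undershoot but
never overshoots (the ambiguous set is a human workload; the target is a
cap). Two policies quantify the gain: `resolve_by_human` assumes reviewed
wells become correct, giving rate (concordant retained + ambiguous)/total,
monotone non-decreasing in `t`; `exclude` drops them, giving concordant
retained/retained. At `t ≤ min h` both reduce to the raw concordance rate.
Imperfect human re-annotation is deliberately not modelled. For display,
confidence comparisons use the natural log of `h`; the Mann-Whitney test is
rank-based, so the transform does not affect it.

## Evaluation statistics

* Confusion matrices are rows = technician (truth), columns = classifier.
  Sensitivities are diagonal/row totals, positive predictive values
  diagonal/column totals; zero marginals yield flagged NaNs, never silent
  zeros.
* The occupancy rate λ is estimated by maximizing the multinomial
  likelihood of the categorized counts (n₀, n₁, n₂, n₍>2₎) with cell
  probabilities P(0), P(1), P(2), 1−P(0)−P(1)−P(2) — the >2 class treated
  as right-censored, since raw counts above 2 are not resolved. The
  optimum is found by bounded scalar minimization to |Δλ| < 1e-7; all wells
  empty gives λ̂ = 0 exactly.
* The 2×2 rater-comparison chi-square is Pearson's, without continuity
  correction by default (a corrected variant is a flag, since either
  convention is defensible).
* The Mann-Whitney U test uses exact enumeration for tie-free groups of at
  most 8 and the tie-corrected normal approximation otherwise.

## Known limitations

* The numpy engine is single-threaded GEMM-bound; full-resolution training
  is out of reach, which is why the desk-scale conditions above exist.
* The generator's artifact realism is deliberately limited (see above);
  accuracy numbers on synthetic plates do not transfer to real microscopy.
* The λ MLE from four categories is slightly less efficient than one from
  raw counts; at n = 10⁵ wells the difference is well below the 0.01
  tolerance the tests use.
* With `cluster_excess > 0` the generator's occupancy is not Poisson, and
  the fitted Poisson model under-predicts multi-cell wells — by design, as
  this mirrors the deviation observed on real plates.
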