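# Methods

This note documents the models implemented by `sayolo`, the defaults
and numerical choices, what the synthetic generators emulate, and the
known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Box geometry and conventions

Boxes live in continuous pixel coordinates (x rightward, y downward)
and are stored center/size, `(cx, cy, w, h)` with `w, h > 0`; the
corner view is derived on demand and `convert` round-trips the two
views exactly. Degenerate boxes (zero width or height) are rejected at
construction rather than propagated as NaN, because every loss term
divides by a size or an enclosing extent.

Intersection extents are clamped at zero before multiplying, so
disjoint boxes score IoU 0 rather than a spurious positive product,
and the final ratio is clipped to [0, 1] to absorb the few ulps of
corner-arithmetic rounding that appear when boxes sit far from the
origin relative to their size. The enclosing-box diagonal is computed
and exposed (it appears in the classical DIoU/CIoU penalties) but the
iSD-IoU distance term normalizes by the enclosing width and height
separately and never uses the diagonal.

## The iSD-IoU loss

`L = (1 − IoU^in) + Δ + Ω`, exactly the sum of its three parts; the
`LossBreakdown` container enforces that no hidden reweighting exists.
All three terms are built from translation- and scale-free ratios, so
the loss is invariant under joint translation and joint positive
scaling of the pair (property-tested at 1e−9 over 10³ random pairs).

Hyperparameters, with admissible ranges enforced by the validator:

| name  | range      | default | role |
|-------|-----------|---------|------|
| ratio | [0.5, 1.5] | 1.0     | inner-box side scaling; at 1.0 the inner IoU reduces to the plain IoU |
| k     | (0, 1]     | 0.5     | weight of the distance term (Δ ≤ 2k) |
| Θ     | [2, 6]     | 4.0     | shape-term exponent; larger values damp small mismatches |
| s     | ≥ 0        | 1.0     | scale exponent of the shape weights; s = 0 disables shape weighting |

The defaults sit at the centers of the admissible ranges; the range
endpoints are inclusive except k = 0, which is excluded (Δ would
vanish identically).

Two deliberate reading choices are exposed as switches rather than
silently resolved:

* **Cross-paired shape weights.** The width-mismatch term is weighted
  by `h₁` and the height-mismatch term by `w₁` (the *crossed* pairing).
  This is implemented as the default because it is the printed form of
  the formula set this package follows; `shape_weight_pairing:
  "direct"` selects the more conventional direct pairing so the two
  variants can be compared.
* **Inner-intersection clamping.** The inner-box intersection formula,
  read literally, can go negative for disjoint boxes; extents are
  clamped at zero, keeping `IoU^in ∈ [0, 1]`.

The loss is asymmetric in (pred, gt) — the shape weights derive from
the ground-truth box only — while `IoU^in` itself is symmetric; the
tests assert both.

## Receptive fields and the SPPMC block

The receptive-field recurrence is `R₁ = k₁`,
`R_n = R_{n−1} + (k_n − 1)·Π_{i<n} s_i`; for stride-1 stacks this is a
sum and hence order-independent (asserted by permutation tests).

The block's exact wiring is a design choice: the constraints taken as
fixed are the pool-kernel ladder 5/9/13/17, SILU after every
convolution, a CSP-style shortcut, and the pre-fusion receptive-field
set {1, 5, 7, 11, 15, 19}. The minimal topology satisfying them is six
parallel branches:

| branch   | layers                    | RF |
|----------|---------------------------|----|
| shortcut | 1×1                       | 1  |
| local    | 1×1 → 3×3 → 3×3           | 5  |
| pool-k   | 1×1 → 3×3 → 1×1 → pool k  | 3 + (k−1) = 7, 11, 15, 19 |

The local path and the four pooled views of the shared stem are
concatenated on channels, fused by 1×1 → 3×3 convolutions,
concatenated with the shortcut and projected back to the input channel
count by a final 1×1 convolution, so output shape equals input shape.
All convolutions are stride-1, zero-padded; max pooling is stride-1
with −∞ padding semantics (padding never wins), so spatial shape is
preserved everywhere. Hidden width defaults to half the input
channels. The `activation: "identity"` escape hatch exists only for
wiring diagnostics (with Dirac-kernel weights the pooled branches
reproduce the bare max pools exactly, which the tests exploit); the
block's semantics use SILU.

## The UECA block

Input is a `(C, H, W)` array. The squeeze-excitation branch computes
the per-channel global mean `z` and the gate
`s₁ = σ(M₁ ReLU(M₂ z))`, with `M₂: C → C/r_se` then `M₁: C/r_se → C`
(the reduce-then-restore composition of the SE family). The
coordinate branch computes directional means `z^h` (over columns) and
`z^w` (over rows), reduces their concatenation with a 1×1 channel
mixing `F₁: C → C/r_ca` under ReLU, splits per direction, and restores
per-direction gates `g^h = σ(F_h v^h)`, `g^w = σ(F_w v^w)`; their
broadcast product is `s₂`. All transforms are bias-free; the
nonlinearity between the two linear maps is ReLU in both branches.

The two branches combine as the attention-gated **sum**
`Y = X⊙s₁ + X⊙s₂` (so `|Y| ≤ 2·max|X|`); a `combine="product"` switch
keeps the literal cascaded reading `Y = X·(X·s₁ + X·s₂)` available for
comparison. The parallel combination is unweighted; learnable scalar
weights on the two branches would be a training-time concern and this
library is inference-semantics only. Reduction ratios default to
r_se = 16 and r_ca = 32 (the conventions of the SE and coordinate-
attention families) and must divide C. Weight initialization is
seeded fan-in-scaled uniform, for deterministic tests; there is no
optimizer.

## Detection metrics

Matching is greedy within each (image, class) group: detections in
descending score order claim the unmatched ground-truth box of highest
IoU at or above the threshold, ties broken toward the lowest
ground-truth index; each ground truth matches at most once. The
sweep of score cuts gives the PR curve, and AP is the 101-point
interpolated area (precision envelope sampled at recalls 0.00 … 1.00),
the COCO convention used throughout the YOLO ecosystem. mAP0.5
averages per-class AP at IoU 0.5; mAP0.5-0.95 additionally averages
over IoU thresholds 0.5 : 0.05 : 0.95. Degenerate conventions:
precision, recall and F1 are defined as 0 when their denominators
vanish; AP for a class with no ground truth is *absent*, not 0.
Greedy matching is prefix-stable in the score ordering, which is what
makes the threshold sweep equivalent to re-matching each thresholded
subset from scratch (the test suite checks AP against exactly such an
exhaustive-enumeration oracle, to 1e−9).

## The convergence simulator

The simulator emulates, at desk scale, the bounding-box-regression
comparison protocols of the DIoU literature: 10×10 px targets at the
nodes of a square grid (default 7×7 = 49), each with 9 anchors — the
cross product of aspect ratios {0.5, 1, 2} and scales {0.75, 1, 1.25}
— placed at equal angles on a ring of radius 25 px around the target
center, the ring phase drawn per target from the experiment seed. The
default radius keeps every anchor disjoint from its target (initial
mean IoU exactly 0), the regime in which the plain IoU loss provides
no gradient at all.

Descent runs in `(cx, cy, log w, log h)` — the log parametrization
keeps sizes positive without projection — using central finite
differences (step 10⁻⁶) instead of closed-form derivatives, which
keeps the loss module free of per-loss gradient code. Two numerical
guards make the descent well-behaved:

* a per-dimension trust region (1 px per step for centers, 0.05 per
  step in log-size): center gradients (units px⁻¹) and log-size
  gradients (dimensionless) live on different scales, and raw steps
  with one global rate either stall the centers or destabilize the
  sizes;
* a gradient deadband at 10⁻⁸: central differences of a unit-scale
  loss carry ≈10⁻¹⁰ round-off noise, and zeroing sub-noise gradients
  keeps an anchor that sits exactly on its target exactly fixed.

The default step size (20) is chosen in the *gradient-limited* regime,
where per-step motion is set by each loss's own gradient magnitude —
which is what a convergence comparison between losses measures. At
much larger rates every loss saturates the trust-region caps and the
dynamics degenerate to sign-gradient descent, washing out the
differences between loss families. 200 steps suffice for the
gradient-carrying losses to converge on this population. Curves are
compared *normalized* (each divided by its step-0 mean) because the
loss families live on different absolute scales; the comparison is
between curve shapes, not values.

This simulator is an acknowledged surrogate: it probes the loss
surfaces directly and says nothing about interactions with a full
detector's other loss terms, its optimizer schedule, or real image
data.

## Phantom images

The phantom generator produces seeded grayscale images — dark
background, additive Gaussian noise, one to three bright ellipses per
image — loosely evoking short-axis cardiac MRI frames. Each ellipse
gets one of the five class labels (NOR, MINF, HCM, DCM, ARV), and the
class conditions its geometry (eccentricity range and the relative
size of the dark inner "cavity", i.e. wall thickness), so classes are
statistically distinguishable. Ground truth is the tight axis-aligned
box of the outer ellipse; placements whose box would cross the image
border are resampled, never clipped. The phantoms share none of the
anatomy, contrast characteristics, modality artifacts or annotation
noise of real cardiac MRI: tests passing on phantoms validate the
*metric and loss machinery*, not clinical detection performance.

`perturb_detections` corrupts ground truth into scored detections
(center/size jitter, drops, spurious boxes; scores decrease with
relative jitter), which gives metric tests known answers: the
noiseless round trip is a perfect detector (mAP0.5 = 1), full drop
gives recall 0, and growing jitter degrades mAP in expectation.

## Problem sizes

Defaults were chosen so the full test suite and the simulator run
comfortably on a single CPU core: the convergence experiment descends
441 anchors for 200 steps per loss (a few seconds, vectorized over the
population); oracle comparisons use 100 small random record sets and
100 small random tensors; property suites use 10³–10⁴ random pairs.

## Known limitations

* No training: blocks are forward-semantics only; the loss ships no
  closed-form gradients (the simulator differentiates numerically).
* No full detector: backbone/neck/head assembly, dataset handling and
  benchmark reproduction are out of scope by design.
* Axis-aligned 2-D boxes only; no rotated boxes, 3-D boxes or masks.
* The crossed shape-weight pairing and the unweighted branch sum in
  UECA are faithful readings of ambiguous sources; the switches
  documenting the alternatives are the escape hatch, not a tuned
  choice.
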