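# Methods

## The procedure

The package tunes five CNN training hyperparameters — learning rate, batch
size, base filter count, dropout rate and optimizer kind — by minimizing a
composite objective with a two-phase population metaheuristic, then refits
the best configuration and evaluates it on held-out data.

**Search space.** AO and HHO are real-vector algorithms, so the mixed
space is relaxed onto `[0,1]^5`.  The learning rate is decoded
log-uniformly over [1e-4, 1e-2] (the range spans two decades; linear
decoding would under-sample small rates).  Each categorical coordinate is
decoded by equal-width binning, with the closed-cube edge case `u = 1`
assigned to the last bin so decoding is total.  `encode` inverts `decode`
(categoricals to bin centers), giving an exact round trip on valid
configurations.  Proposals that leave the box are clipped component-wise.

**Aquila phase.** Four position updates: high soar toward a blend of the
incumbent best and population mean; contour flight combining a Lévy-flight
step, a random other agent and a spiral offset (`r = r1 + 0.00565·D1`,
`θ = −ω·D1 + 3π/2`, with `r1 ~ U[1, 20]` per call and `D1` sweeping the
coordinate indices); a low-flying strike with exploitation adjustments
`α = δ = 0.1`; and bow hunting driven by the quality function
`QF = t^((2r−1)/(1−T)²)`, mobility `G1 = 2r−1` and flight slope
`G2 = 2(1 − t/T)`.  The first two (exploration) are used for the first
two-thirds of the iteration budget, the exploitation pair afterwards, with
a 50/50 choice inside each phase — the standard AO schedule, chosen because
the update set alone does not determine a switching rule.  Each scalar
`rand` appearing in an update draws one fresh uniform (scalar per update,
not per coordinate).

**Lévy flight.** Mantegna's scheme: steps `s·u·σ(β)/|v|^(1/β)` with
`u, v` standard normals, `s = 0.01`, `β = 1.5`.  The `1/β` exponent on the
denominator is deliberate — it produces the heavy-tailed step distribution
the algorithms rely on; a `strict_exponent_beta` flag exposes the `|v|^β`
variant for side-by-side comparison only.

**Harris Hawks phase.** Per agent and iteration, an initial energy
`E0 ~ U[−1, 1]` is drawn and decays as `E = 2E0(1 − t/T)`; together with an
escape probability `r ~ U[0, 1]` it gates the update: exploration when
`|E| ≥ 1` (two perching strategies chosen by a uniform `q`), soft besiege
(`r ≥ 0.5, |E| ≥ 0.5`), hard besiege (`r ≥ 0.5, |E| < 0.5`), and the two
progressive-dive modes when `r < 0.5`.  Dives propose `Y` (an energy-scaled
pull toward the best with jump strength `J = 2(1−rand)`) and
`Z = Y + S·LF(D)` with `S ~ U[0,1]^D`, evaluate both, and keep the fitter
only if it improves on the agent.  `q` and `r` are treated as uniform
reals, `E0` is redrawn per agent per iteration, and `|·|` is the
component-wise absolute value — the standard conventions.  The hard-dive
mode reuses the same `Y`/`Z` equations with the agent itself as anchor; a
`canonical_hard_dive` flag substitutes the population mean instead
(default off).

**Hybrid driver.** One hard switch at `⌈switch_fraction · I⌉` iterations
(default 0.5): AO iterations before, HHO after, on the same population and
RNG stream, so the incumbent best is preserved exactly and the
`switch_fraction = 1` (resp. 0) trajectories are bit-identical to pure AO
(resp. HHO).  Greedy retention everywhere (a proposal replaces its agent
only if not worse), which makes the best-so-far history monotonically
non-increasing — an invariant the tests rely on.  Early stopping triggers
when the best objective changes by less than `ε = 1e-4` for 10 consecutive
iterations; both values are exposed and were chosen for stability on noisy
CNN objectives.  A fitness cache keyed by the decoded configuration serves
duplicates (categorical plateaus) without re-training; the evaluation count
reported is the cache-miss count.  Because each dive evaluates two
candidates, the worst-case evaluation count is `P·(2I + 1)` rather than the
`P·(I + 1)` of dive-free runs.

## The CNN and the objective

The classifier is a fixed two-block network — `Conv(F, 3×3, same, stride 1)
→ ReLU → MaxPool(2×2)`, `Conv(2F, …) → ReLU → MaxPool(2×2)`, `Flatten →
Dense(128) → ReLU → Dropout(p) → Dense(C) → Softmax` — implemented directly
in NumPy (float32; convolutions as im2col matrix products so the work runs
on BLAS).  The single filter hyperparameter sets block 1; block 2 doubles
it, generalizing the printed 32→64 template.  The tuned dropout overrides
the sketch's fixed 0.5.  Kernel 3×3, pool 2×2, stride 1 are the universal
defaults for this architecture family.

Training minimizes multi-class cross-entropy with mini-batch Adam
(β₁ = 0.9, β₂ = 0.999) or plain SGD at the tuned learning rate and batch
size.  Two stabilizers are applied: the output layer is initialized at
small scale (0.01) so initial logits are near zero and the initial loss is
≈ ln C, and gradients are clipped to a global L2 norm of 5 — without this,
Adam at the top of the learning-rate range (1e-2) reliably kills the ReLU
units on small datasets.  Hidden layers use He initialization.  Max-pool
gradients are routed to the first maximal entry of each window so tied
maxima (common after ReLU) receive the gradient exactly once.

**Fitness of a candidate.**  The training stack is split 80/20 into
fit/validation folds, stratified by class and fixed by the run seed; the
candidate's CNN is trained for `tune_epochs` (default 3) on the fit fold
and scored by validation cross-entropy.  The cost term defaults to the
deterministic complexity proxy `epochs · n_batches · N · Σᵢ Lᵢ·Fᵢ²`
normalized by the most expensive configuration in the space, so the whole
evaluation is a pure function of (configuration, data, seed); wall-clock
measurement is available (`time_mode="measured"`) but excluded from every
reproducibility check as hardware-dependent.  λ₁ = 1, λ₂ = 0.1 weight the
loss against the normalized cost.  A non-finite loss maps to a large
finite penalty (1e6) rather than an exception, so one diverged training
cannot abort a run.  After the search, the best configuration is refit on
the full training stack for `refit_epochs` (default larger than
`tune_epochs`; the short tuning budget ranks configurations, the refit
realizes one).

**Metrics.** Accuracy is the confusion-matrix trace over the total;
precision, recall and F1 are computed one-vs-rest per class and
macro-averaged (the published per-metric values differ from accuracy,
which rules out micro-averaging).  A class never predicted contributes
precision 0 and is logged.  Accuracy equals the support-weighted mean of
per-class recalls — kept as a property test.

## Synthetic data generator

The generator emulates the statistical shape of a 4-class brain-MRI slice
collection: a smooth elliptical "brain" with mild shading on a dark
background, plus a class-specific lesion — a large diffuse off-center blob
blend (glioma-like), a compact bright peripheral blob (meningioma-like), a
small central bright blob (pituitary-like), or nothing (no-tumor).  Lesion
geometry and amplitude are jittered per image around class-anchored
locations; Gaussian pixel noise (`noise_sd`, default 0.05) and a
`class_overlap` dial in [0, 1] (blending each lesion field toward the
across-class mean) harden the task continuously.  Default class counts
follow a 1321/1339/1595/1457 train and 300/306/405/300 test composition
(glioma/meningioma/notumor/pituitary).  Generation is a pure function of
`SynthesisParams`.

At zero noise and overlap the classes are deliberately easy: a nearest
class-mean classifier is perfect, and the minimum between-class mean
distance exceeds five times the mean within-class spread (calibrated once
and frozen as a test).  These are geometric caricatures, not anatomy — no
MRI physics, 3-D structure, scanner artifacts, inter-subject variability
or class imbalance pathology.  Passing tests on this generator therefore
demonstrates that the optimization loop can recover configurations that
learn separable image classes, not that the pipeline reaches any
particular accuracy on clinical data.

Preprocessing mirrors the standard recipe: intensities divided by exactly
255; augmentation by rotation within ±15°, horizontal flip with
probability 0.5, zoom in [0.9, 1.1] and shifts within ±10% of the image
side, composed into one bilinear warp with edge padding.  Augmentation is
applied during final-model training only (never to validation or test
folds, to avoid leakage); tuning evaluations skip it by default so the
short-budget fitness stays deterministic and cheap, and it can be enabled
per run.  Labels are encoded as integers or one-hot in stable alphabetical
class order.

## Statistical protocol

Experiments are repeated over seeds (default five); each metric is
reported as mean ± sample standard deviation (n−1).  Pairwise comparisons
between optimizer arms use a paired two-sided t-test on runs paired by
shared seed — the ablation helper runs AO-only, HHO-only and the hybrid
from identical seeds so the pairing is real — with a 95% t-based
confidence interval on the mean difference.  The degenerate zero-variance
case reports p = 1 (zero difference) or p = 0 (constant nonzero
difference) with a width-zero interval.  No multiple-testing correction is
applied; the report footnote says so.  Failed runs are excluded with a
warning and recorded.

## Problem sizes and numerical choices

* Optimizer validation: sphere/Rastrigin in 5-D, populations 15–20,
  100–150 iterations, 10 seeds — seconds of CPU.
* End-to-end checks and the acceptance script run a reduced-scale study —
  32×32 images, 80 training images per class, population 4, 6 iterations,
  3 epochs per evaluation, refit 12 epochs — chosen so a full run stays in
  the minutes range on one CPU core.  The accuracy bar (≥ 0.90 held-out)
  is not relaxed; at these settings the refit model typically scores 1.0.
* The iteration counter is 1-based so `QF = t^x` is well-defined, and a
  budget of a single iteration is rejected (the QF exponent denominator
  `(1−T)²` vanishes).
* Probabilities are floored at 1e-12 before logs; prediction rows are
  validated to sum to 1 within 1e-6.
* All optimizer randomness flows through one seeded NumPy generator per
  run; dataset generation, splitting, weight initialization, shuffling,
  dropout and augmentation are seeded separately and documented per
  function.

## Known limitations

* The search space is flat; conditional or architecture-level
  hyperparameters (depth, dense width) are out of scope.
* Fitness evaluations are sequential; no parallel population evaluation.
* The NumPy CNN targets small images and short budgets; it is not a
  general-purpose deep-learning stack (no GPU, no batch norm, no
  checkpointing).
* The time proxy models convolutional cost only; it is nearly independent
  of batch size (by design it tracks arithmetic, not latency), so the cost
  term mostly penalizes filter count.
* Wall-clock comparisons between optimizers are hardware-dependent and
  intentionally excluded from automated checks.
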