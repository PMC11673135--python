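# Methods

## Model and procedure

The package treats frame alignment as a 3-parameter rigid-motion estimation
problem.  A transform p = (tx, ty, θ) rotates an image by θ degrees
(positive = counter-clockwise in the displayed orientation) about its
geometric center ((n−1)/2, (m−1)/2) and then translates it by (tx, ty)
pixels; samples falling outside the source support are filled with 0.
Interpolation is bilinear by default (the cost surface must be continuous in
p for the optimizers); nearest-neighbour is available.  The warp kernel and
the fused warp+MSE cost are compiled with numba for throughput; the test
suite verifies the kernel against `scipy.ndimage.affine_transform(order=1,
mode='grid-constant')` to ≤ 1e-9 on random images.

The registration objective is the full-frame MSE between the fixed image
and the warped moving image, with the zero-filled border pixels included
(they penalise excessive shifts the same way the black borders do in real
registered frames); an overlap-only mode is not provided because the full
pipeline uses the validity-mask machinery instead when *measuring* quality.

### Search

* **GA phase.**  Real-coded chromosomes (tx, ty, θ); population 50,
  50 generations, roulette-wheel selection, one-point crossover with
  probability 0.8 at a random cut among the 3 genes, per-gene Gaussian
  mutation with probability 0.05 and sigma = 2% of the parameter's bound
  width; elitism carries the incumbent best unmodified; early stop after 10
  stagnant generations (relative improvement < 1e-8).
  The roulette fitness is the inverted cost `1/(1 + Δ/median(Δ))` with
  Δ = cost − min(cost).  The median normalisation matters: an unnormalised
  `1/(1+Δ)` makes selection pressure depend on the cost units, and with MSE
  spreads of order 10²  the population collapses onto an early incumbent
  before θ is explored (the smooth object constrains rotation only weakly
  until its markers align), which loses multi-start robustness precisely on
  the large-rotation scenarios.  The scale-free form keeps the selection
  pressure constant across problems.
* **CPSO phase.**  Swarm of 30, 100 iterations, c1 = c2 = 2.05 (φ = 4.1,
  the canonical constriction setting), inertia decaying linearly
  0.9 → 0.4, velocities multiplied by the constriction factor
  χ = 2/|2 − φ − √(φ² − 4φ)| ≈ 0.7298 ("conventional") or its square
  ≈ 0.5327 ("squared", the default).  One particle starts exactly at the
  GA hand-off; the rest are Gaussian-jittered around it with sigma = 5% of
  each bound width; velocities start at 0; positions are clipped to the
  bounds and velocities capped at 20% of each bound width per step.
  Because the seeded particle's personal best is evaluated before any
  update, the hybrid's final cost can never exceed the GA phase's.
* **Guard rail.**  `register_pair` evaluates the zero transform first and
  returns the identity if the optimizer somehow ends worse, so
  `final_cost ≤ initial_cost` holds unconditionally.
* **Stand-alone CPSO baseline** (`method="cpso"`): identical swarm but
  uniformly random initial positions — the configuration the hybrid is
  compared against.

Default search bounds are ±100 px translation and ±20° rotation; ground
truths in all experiments lie strictly inside.

Sequences are registered **fixed-reference** (every frame to frame 0),
not chained pairwise, to avoid compounding alignment errors.  Per-frame RNG
seeds are derived from the base seed plus 10000·frame_index, so a sequence
run is reproducible while frames stay independent.

### Accumulation and SNR

Frames are summed in float64 (no 8-bit wraparound); metrics are computed on
the mean-normalised sum so that the frame count does not trivially scale
gradient metrics, and the raw sum is retained (8-bit export divides by m,
rounds half-even, clips).  For independent zero-mean noise the noise SD of
the mean falls as σ/√m, so the empirical SNR (signal level divided by the
SD of the residual against the known signal) rises by √m — the law the
acceptance suite verifies for m ∈ {4, 16} at 10% tolerance.  When
registration precedes accumulation, pixels invalid under any frame's
estimated transform are excluded through a mask intersection and a centered
fully-valid crop, so zero-filled borders cannot masquerade as edges in the
quality comparison.

### Metric conventions

* Accuracy is implemented as 100 − mean-relative-error %, with absolute
  values of the true parameters in the denominators (negative true shifts
  are published and must not flip the sign of a relative error).  The raw
  relative-error formula alone evaluates to the *error* percentage; every
  published accuracy table is consistent with 100 minus that quantity, which
  is what the function returns.  A true parameter of exactly 0 makes its
  term undefined: the function raises by default, with an absolute-error
  fallback behind `zero_policy="absolute"`.
* Mutual information and entropy are in bits (log base 2).  Histograms
  quantise intensities round-half-even onto an evenly spaced level grid over
  [0, 255] (default 256 levels/bins); the joint histogram uses the same
  quantisation rather than bin-edge conventions, so MI(a,a) = entropy(a)
  holds exactly at matched binning and marginals equal the 1-D histograms.
* SD is the population standard deviation (divisor m·n).  Gray level is the
  mean intensity (published values ~40–60 on 8-bit images are consistent
  with a mean, not with a count of occupied levels; the alternative reading
  is noted but not used).
* EOG sums squared one-pixel forward differences along both axes; the
  Brenner gradient sums squared two-pixel-lag differences along the row
  axis (f(x, y) indexes x as row); MMD sums products of orthogonal absolute
  differences.  All three truncate their sums to positions whose neighbours
  exist (no padding).
* SNR "increased by a factor of m": the standard derivation gives √m
  (noise SD → σ/√m), and √m is what the package implements and tests;
  the frequently garbled linear-in-m phrasing is not used.

## The phantom

Real subject sequences are not redistributable, so every experiment runs on
a synthetic transmission-like phantom: background 20, a bright blob
(default radius 31 px on a 256×256 frame, peak +120, sigmoid edge ~3 px)
slightly off center, a deterministic band-limited interior texture
(amplitude 12, wavelength 12 px) and three high-contrast fiducials (two dark
bars, one bright disc).  Additive Gaussian noise (default sigma 5 on the
0–255 scale) is drawn independently per frame from a spec-level seed;
an optional signal-dependent shot term is off by default.  Frames are
clipped to [0, 255] after noising, as a camera would.

Design intent of each ingredient:

* the smooth blob mimics diffuse transmitted light and gives the MSE cost a
  wide basin for translations;
* the fiducials pin down rotation and make the sharpness metrics (EOG,
  Brenner, MMD) respond strongly to ghosting;
* the texture reproduces a key property of real tissue images: misaligned
  accumulation *averages texture away* (lowering SD and entropy), whereas a
  piecewise-flat object would gain intermediate gray levels from edge smear
  and bias the entropy comparison the wrong way.

Two configurations are used.  The compact default keeps all content within
47.5 px of the image center so that every published displacement scenario —
up to (−80, 60, 15) — keeps the object inside the frame
(`enforce_margin` rejects violations).  `PhantomSpec.full_field()`
(blob radius 90) fills the frame the way acquired tissue images do and is
used for the accumulation-quality and small-jitter studies; its content may
touch the frame edge, so the margin check is off there.  `PhantomSpec.scaled`
shrinks the compact geometry proportionally for small test frames.

Inter-frame motion is modelled by `jitter_model`: zero-mean Gaussian
per-frame transforms (frame 0 forced to identity), defaults 2.5 px / 0.5°
— hand-held-camera-scale shake.

## What the experiments show (and problem sizes)

* **Worked examples** — the 16 published accuracy cells recompute from
  their printed displacement rows in milliseconds; two cells differ by one
  unit in the third decimal because the published inputs are themselves
  rounded (see tests).
* **√m law** — 256×256 constant-signal stacks, σ = 10, m ∈ {2, 4, 9, 16, 25}.
* **Parameter recovery** — every published shift applied to the denoised
  256×256 compact phantom; the reference is the same frame transformed
  (so the cost at truth is exactly 0, matching the published protocol where
  the reference was generated from the moving image).  10 seeds per
  scenario; median hybrid accuracy ≥ 99% on all eight scenarios, and the
  hybrid's median never falls below the stand-alone CPSO's at print
  precision.
* **SCF vs CCF** — 20 paired-seed registrations of a 128×128 phantom
  (10, −8, 3) displacement; the squared factor's first-attainment iteration
  is ≤ the conventional factor's in the majority of pairs.  Wall-clock
  registration times are hardware-dependent and are not modelled.
* **Accumulation quality** — 20-frame full-field jittered phantom
  (2.5 px / 0.5° jitter, fixed seed); EOG, Brenner, SD and entropy of the
  registered accumulation all exceed the direct accumulation's on the
  common valid crop.  Gray level moves very little on the phantom (its mean
  is nearly motion-invariant) and is reported but not asserted.

These are phantom analogues: they demonstrate the direction and rough
magnitude of every published effect, not the absolute metric values of the
original subject data (which depend on unreleased images and hardware).

## Numerical notes and limitations

* MSE registration of *noisy* pairs is slightly biased: warping resamples
  the moving image and smooths its noise, lowering the cost at fractional
  offsets/rotations.  Denoising before registration (the default pipeline
  order) keeps the bias near 0.2° / 0.1 px at the default noise level; the
  test suite asserts error floors at these magnitudes rather than zero.
* The inertia schedule interprets the decay horizon T as `max_iterations`
  (linear decay from w_max to w_min over the run).
* First attainment is the first iteration whose global-best cost equals the
  final best exactly; the full per-iteration trace is retained, so other
  readings (e.g. tolerance-based) can be derived.
* Ties in personal/global best keep the earlier incumbent; equal-cost
  updates do not churn state, which makes runs bit-reproducible under a
  fixed (config, seed) pair.
* The cost may optionally be evaluated on a decimated grid
  (`downsample=k`, translations rescaled); off by default and unused in the
  shipped experiments.
* Non-goals: non-rigid/affine deformation, multi-resolution pyramids,
  sub-pixel phase-correlation initialisation, SSIM/NMI/NCC metrics, video
  hardware control.  Video decoding is optional and degrades gracefully
  without the ffmpeg plugin.
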