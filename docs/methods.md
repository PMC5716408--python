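# Methods

## Model

Two planar dose distributions are compared: a *reference* (conventionally
the measurement) and an *evaluated* (the calculation) field, both
absolute dose in cGy on regular 2D grids. Two pointwise metrics are
computed on the reference grid.

**MDdiff.** The signed dose difference δD(r) = D_eval(r) − D_ref(r),
taken at identical positions, is divided by 1 + β(r) with
β(r) = |∇D_ref(r)| · DTA⁰/δD⁰. β is dimensionless: it is the dose change
produced by moving one DTA criterion along the reference gradient,
expressed in units of the dose criterion. The construction gives three
algebraic guarantees that the tests exercise directly:

* shrinkage — |MDdiff| ≤ |δD|, with equality iff β = 0;
* sign preservation — sign(MDdiff) = sign(δD), since 1 + β > 0;
* limits — MDdiff → δD as ∇D_ref → 0, MDdiff → 0 as ∇D_ref → ∞.

A closed form used as a test oracle: for a reference ramp of slope g
rigidly shifted by s, interior MDdiff = −g·s·δD⁰/(δD⁰ + g·DTA⁰).

The gradient is taken from the reference distribution only (the
measurement is the physical ground truth, and using the evaluated
gradient would let a miscalculated penumbra suppress its own error).
It is estimated with second-order central differences on interior
points and one-sided differences on boundaries; central differences are
exact on affine fields, which anchors the ramp oracles.

A point fails when |MDdiff| ≥ ½ δD⁰. The absolute value is a deliberate
choice: the one-sided reading of the rule would ignore under-dosed
regions, which carry the same clinical weight; the literal one-sided
rule remains available via `signed_rule=True` / `--signed-mddiff-rule`.
The ½ factor is an empirical calibration constant aligning the MDdiff
critical value with γ = 1; it is exposed as `critical_fraction` and
defaults to 0.5.

**Gamma.** The comparator is the standard global-normalization gamma:
γ(r_r) = min over r_e of √(|r_e − r_r|²/DTA⁰² + (D_eval(r_e) −
D_ref(r_r))²/δD⁰²), failing at γ ≥ 1. The evaluated grid is bilinearly
refined by an integer `subsample_factor` (default 4) and searched within
`search_radius` of each reference point, default
max(3·DTA⁰, DTA⁰ + 2·max spacing): at the rim of that disc the spatial
term alone is ≥ 3, so any point with γ ≲ 3 has its true minimum inside
the disc. Closed form used as an oracle: a ramp of slope g shifted by s
gives interior γ = g·s/√(δD⁰² + g²·DTA⁰²) in the continuum; the discrete
search converges to it as the refinement grows (the displacement lattice
step bounds the error, property-tested).

`gamma_bruteforce` recomputes the same contract by enumerating every
refined node in pure Python with hand-written bilinear interpolation —
no windowing or vectorized shortcuts — and is the independent oracle
against which `gamma_map` is tested to 1e−9.

## Conventions and numerical choices

* Geometry: pixel-center convention; array axis 0 is physical x; spacing
  in mm; all doses absolute cGy. Percentage dose criteria are converted
  once at `Criteria` construction (global normalization against the
  prescribed dose), matching the 3%-of-prescription clinical standard
  (δD⁰ = 6 cGy at 200 cGy, DTA⁰ = 3 mm — the defaults used throughout
  the tests and the acceptance script).
* Resampling: bilinear only, never extrapolated. Reference points
  outside the evaluated extent are flagged invalid and excluded from all
  counts; extrapolated dose would be fabricated data. Bilinear
  interpolation is exact on affine fields, which the property tests pin
  down to machine precision.
* Gamma edge handling: a reference point whose search disc is clipped by
  the evaluated extent still receives a γ from the available candidates
  but is flagged invalid, so summaries are not biased by artificially
  truncated searches. Consequently the gamma and MDdiff summaries of the
  same case may have different `total_points`; ratios are always per
  metric over its own valid points.
* Pass rules are boundary-inclusive (γ ≥ 1, |MDdiff| ≥ ½ δD⁰ fail).
* Summary statistics: means over all valid points (not only failing
  ones); maxima are of absolute values; MDdiff additionally reports the
  signed mean. Spearman rank correlation uses average ranks on ties and
  is reported as not-applicable when a ratio vector is constant.
* No low-dose threshold is applied by default; every valid point counts.

## Synthetic data

No measured film/array planes are distributed, so all experiments run on
generated fields:

* `ramp_field` — affine fields for the closed-form oracles.
* `imrt_like_field` — sums of rectangular apertures with erf-shaped
  (Gaussian-convolved) edges: flat plateaus realize the β ≈ 0 regime,
  penumbras of dose/(σ√(2π)) peak gradient (≈ 40 cGy/mm for 200 cGy and
  σ = 2 mm) realize β ≫ 1, with low-dose background in between — the
  three regimes the gradient normalization is designed around.
* `apply_perturbation` — rigid sub-pixel shift (bilinear, edge-extended),
  multiplicative dose scaling, and seeded Gaussian noise, clipped at
  zero. These emulate setup error, output/calibration error, and
  detector noise respectively.
* `synthetic_cohort(n, seed)` — one fixed reference plane (three
  apertures of 95–210 cGy on an 80×80 mm, 1 mm grid, modulated by a
  smooth low-gradient dome so plateau dose spans a continuum) and n
  perturbations of strictly increasing severity: case 0 is exact;
  cases 1..n−1 ramp the scaling error 3.5%→10%, the shift 1→6 mm, and
  the noise 0.3→1.2 cGy. The starting points are chosen so that even the
  mildest imperfect case fails a few points under 3%/3 mm criteria and
  the dose continuum converts each severity increment into a strictly
  larger failing area for *both* metrics — the construction that makes
  rank concordance between the methods a theorem of the design rather
  than a coincidence of one seed. The severity range spans
  clearly-passing to grossly-failing deliveries, comparable to the
  spread seen across real QA practice.

What the generator does **not** emulate: detector spatial response and
calibration curves, TPS beam modelling, setup rotations, grid
misregistration other than rigid translation, and spatially correlated
noise. Passing tests therefore demonstrate the correctness of the
metrics and their documented algebra on controlled inputs, not clinical
performance on measured data.

## Problem sizes

Defaults were picked so the full test suite and the acceptance script
each run in well under a minute on one CPU: property tests use 15–25 mm
fields at 1 mm spacing, oracle-equivalence tests use ≤ 12×12 grids
(the brute-force gamma is quadratic by design), sweeps use 40 mm fields
with subsample 2, and the cohort uses the 81×81 grid with subsample 4.
All are comfortably above the scales at which the tested properties
could degenerate (several pixels per penumbra, search discs of hundreds
of candidates).

## Known limitations

* 2D only. The types would extend to a third axis, but no 3D metric is
  implemented.
* Global normalization only; no local-dose gamma, no ROI restriction.
* The gamma search is exact on its refinement lattice but is not an
  analytic continuum minimization; with the default subsample factor the
  γ discretization error is of order 1/(2·subsample) pixel along the
  steepest direction (the convergence test quantifies it).
* MDdiff suppresses penumbra dose errors by construction; a genuinely
  wrong penumbra dose is down-weighted exactly like a benign alignment
  error. The signed map and the gradient field are both exposed so such
  regions can be inspected.
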