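# Methods

This note records the statistical model behind `isobolar`, the choices
made where the classical isobolographic recipe leaves room, and what the
synthetic-data generators do and do not emulate.

## Effect scale and normalisation

Raw OD450 absorbances are normalised per plate: viability% =
100·A / mean(A of that plate's untreated controls), and the effect of a
condition is E = 100 − viability%. Effects are not clamped; treatments
that promote proliferation yield negative effects, which keeps the sign
convention of "effect = percent reduction in viability" coherent across
agonists and antagonists. Normalising per plate (rather than against a
global control pool) absorbs plate-to-plate gain differences in the
reader. Background (blank) subtraction is off by default and exposed as
an option, since a measured blank is not always available.

## ED interpolation

ED_E is the smallest dose at which a monotone (shape-preserving,
Fritsch–Carlson/PCHIP) piecewise cubic through the per-dose mean effects,
anchored at (0, 0), first reaches E.

* **Why PCHIP and not a natural cubic spline:** with 3–7 dose points a
  natural spline can overshoot between nodes and manufacture spurious
  crossings; PCHIP keeps the interpolant inside the range of neighbouring
  node values, so on monotone data every ED root is genuine.
* **Why an interpolant and not a 4PL/Hill fit:** the workflow is
  deliberately model-free at this step; the linear OLS fit of mean effect
  on dose (with its slope F-test) is used only as a *significance screen*
  — a non-significant dose-effect trend warns, it does not abort.
* **Anchor at (0, 0):** follows from the effect definition (untreated
  wells have zero effect by construction).
* **First-crossing rule:** if noisy means cross E more than once, the
  smallest dose is returned — the conservative (smallest effective dose)
  choice.
* **No extrapolation:** a level above the maximum observed mean effect is
  an error. Root-finding is bisection on the piecewise-cubic
  coefficients (80 halvings, i.e. resolution ~2⁻⁸⁰ of a dose interval),
  vectorised over bootstrap resamples; it is exact on nodes by an
  explicit equality check.

## Bootstrap uncertainty

CIs are percentile intervals over B (default 2000) nonparametric
resamples of the replicate wells within each dose; the interpolant and
ED_E are recomputed per resample. Resamples in which E is unreachable
are dropped and counted; if more than half fail, the interval is declared
unreliable — an error for direct requests, and for the pipeline's
boundary-level (R_max) stage a logged downgrade that skips the constancy
test rather than aborting the analysis. Levels requested at exactly the
observed maximum mean effect sit on the boundary of the bootstrap
distribution and are intrinsically fragile; this is a property of the
design, not of the implementation.

Known limitation: with very small replication the within-dose percentile
bootstrap undercovers (the bootstrap SD of a mean of n replicates is
s·√(n−1)/n, i.e. 0.91 of the true SE at n = 3–6, plus the usual
small-sample percentile loss). Empirically the 95% interval for a known
ED50 covers ~85–87% at n = 6 per dose and converges to ~94–95% by
n = 15–30 (the test suite asserts the measured behaviour at both ends).
Consumers with n ≤ 6 should read the intervals as optimistic.

## Isobole, potency ratio, and verdicts

At level E the additivity isobole is the segment from (ED_E^A, 0) to
(0, ED_E^B); its pointwise 95% envelope is built from index-paired
bootstrap draws of the two intercepts (the B-axis value of each resampled
line, quantiled at each A-dose). Zero-variance draws collapse the
envelope onto the line.

The linear isobole is justified when relative potency is dose-independent
(Tallarida's condition). This is screened by a likelihood-ratio G-test
(G = 2·ΣO·ln(O/E), χ², 1 df) on a 2×2 table counting bootstrap draws of
R_50 and R_max that fall above versus at-or-below 1; a zero expected cell
triggers a +0.5 continuity adjustment. "Maximum effect" is defined as
the smaller of the two curves' maximum mean effects — the only level at
which both EDs exist without extrapolation. Because the table's counts
are bootstrap draws (n = B), the test is extremely powerful: tiny,
practically irrelevant differences in the two ratio distributions reach
significance, so the flag should be read as descriptive. The analysis
records it and proceeds with the linear isobole either way.

Verdicts: *synergistic* strictly below the lower envelope;
*antagonistic-consistent* strictly above the upper; within the band,
*inconclusive* when γ < 1 (sub-additive point not resolvable from the
line) and *additive-consistent* otherwise. Ties with an envelope bound
count as within the band.

**Effect-level escalation.** When the combination's replicate effects are
consistently above 50% (two-sided one-sample t-test, α = 0.05, and mean
> 50), the analysis level becomes ⌊mean effect⌋ — e.g. an 84.6% mean
effect moves the analysis to the 84% isobole. Zero-variance replicates
equal to 50 define t = 0. If the escalated level exceeds the maximum
common observed effect it is clamped to ⌊that maximum⌋ with a warning.

## In-vivo statistics

Tumor volume V = ½·L·W² (mm³) with L ≥ W enforced by swapping (the two
caliper axes are interchangeable up to convention; violating rows are
swapped on read with a warning). Group comparisons use the endpoint
volume at the last day measured in every group (configurable), with
nearest-day matching within ±1 day. Two groups: pooled-variance
(Student) independent t-test — the common default in the clinical
statistics packages this mirrors — with Welch available as an option.
More than two: one-way ANOVA plus all pairwise t-tests with Bonferroni
adjustment over the number of pairs (min(1, m·p)). Groups with fewer
than two animals at the endpoint are excluded with a warning. No
longitudinal mixed-effects modelling or survival analysis is attempted.

## Synthetic data

The plate generator draws, per well, absorbance =
control_mean·(100 − true_effect − ε)/100 with ε ~ N(0, σ) on the
viability scale (σ in percentage points; default 8, a typical XTT
replicate spread), floored at a tiny positive OD since a reader never
reports non-positive raw density. Controls get an independent
multiplicative CV (default 0; 2% in the study-mimicking scenario).
Defaults: n = 3 replicates per condition, 6 control wells per plate.
Effect functions are validated as monotone with f(0) = 0.

The study-mimicking scenario uses near-linear truths min(95, m·d) with
ED50s of 51 µM (naloxone, m = 50/51) and 44 µM (cisplatin, m = 50/44),
and a (10, 20) µM combination with true effect 85%. The reported
naloxone gradient (0.1–40 µM) tops out below its own ED50, so both dose
grids extend to 110 µM (keeping the reported doses as grid points) to
make the 50% and ~84% levels interpolable without extrapolation. The
additive null scenario places the combination exactly on the 50%
additivity line (γ = 1, true effect 50%).

The xenograft generator grows volumes exponentially, V(t) = V₀·e^(r·t),
from a 100 mm³ baseline, measured twice weekly for six weeks across four
arms (control / naloxone / cisplatin / cisplatin+naloxone, 7 animals
each); per-day rates 0.100 / 0.089 / 0.060 / 0.0357 were chosen so the
six-week endpoint shows ~37% volume reduction for naloxone versus control
and a further ~64% for the combination versus cisplatin alone. Volumes
are emitted as caliper pairs (aspect ratio 1.2) with 5% multiplicative
noise per dimension.

What the generators do **not** emulate: plate-edge and positional
effects, shared plate-level noise (replicates are independent),
heteroscedasticity across the dose range, censoring of animals reaching
a humane-endpoint volume, and any pharmacokinetics. Passing tests
therefore certify the statistical machinery under the assumed noise
model, not robustness to those real-data artefacts. One consequence is
visible in the Monte-Carlo suite: with independent wells at σ = 8 and
n = 3, bootstrap ED50 intervals are a few µM wide — much tighter than
intervals from between-experiment biological replication — so a truly
supra-additive (10, 20) combination is usually detected as synergistic
already at the 50% isobole rather than only after escalation.

## Problem sizes used in the checks

The automated checks run 100 seeded plate simulations for the two-stage
verdict rates and 200 for the false-synergy rate (B = 2000), 500
Monte-Carlo repeats for ED50 CI coverage (B = 1000), and 500 random
curves for the interpolation oracle — sizes at which the binomial error
on the measured rates is ~1–3 percentage points.

## Numerical details

* Percentile CIs use linear-interpolated quantiles (`numpy.quantile`).
* All randomness flows through `numpy.random.default_rng(seed)`; the
  pipeline derives independent child seeds for the two agents' bootstraps
  from one user seed, so results are bit-reproducible.
* Degenerate inputs: identical doses reject the OLS screen; plates
  without controls, non-positive control means, combinations with a
  single replicate, and empty groups all raise typed errors naming the
  offending object.
* CSV floats are written with `repr` and parsed with pandas'
  round-trip parser, so write→read is lossless; JSON reports serialise
  non-finite floats as null and are versioned (`schema_version: "1.0"`).
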