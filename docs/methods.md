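# Methods

This note documents the models, numerical choices and limitations behind
`tomoqa`. Everything stated here is computed by the test suite or the
acceptance script; nothing is an external claim.

## Dose representation and geometry

Planned dose lives on a regular, axis-aligned grid in Gy — 2D `(y, x)` or
3D `(z, y, x)` — with millimetre coordinates and the origin at the first
sample. The default grid step is 1.87 mm, the high-resolution export step
of the treatment planning system. Measured doses are point samples on the
*unwrapped* cylindrical detector plane: `u` is arc length around the
circumference (angle 0 at top, clockwise seen from the gantry), `v` the
axial position. The analysis is fixed to this unwrapped-2D convention; the
package does not attempt volumetric (3D) gamma.

The detector geometry (cylinder radius 105 mm, 10 mm diode spacing axially
and circumferentially, 210 mm axial extent) is a plausible diode-array
layout chosen as a default; no vendor geometry is published, and every
computation is valid for any positive geometry — the tests exercise small
custom geometries as well.

Measured doses can be scaled by a daily machine-output correction factor;
factors outside (0.5, 1.5) are rejected as unit mistakes. Corrections
compose multiplicatively and are recorded in the point-set metadata.

## Gamma engine

`compute_gamma` minimizes the continuous gamma function per reference
point, with evaluation doses bilinearly interpolated:

1. **Lattice scan** — candidates on a regular lattice of step
   `interp_step_mm` (default `dta/10`) within `max_search_radius_mm`
   (default `3*dta`) around the reference point.
2. **Basin selection** — every lattice candidate whose value could still
   contain the global minimum survives, judged with a Lipschitz bound on
   gamma (`sqrt(1/dta^2 + (Gmax/dD)^2)`, `Gmax` the maximal grid
   gradient); survivors are thinned best-first to at most 64
   representatives separated by more than one lattice step.
3. **Refinement** — a projected compass (pattern) search halves its step
   from `interp_step/2` down to `1e-3*dta`, then a damped-Newton descent
   of gamma² (analytic gradient and Hessian of the bilinear interpolant)
   handles the ill-conditioned valleys where the dose gradient dwarfs the
   distance term, and a final fine compass pass down to `1e-7*dta` covers
   minima on bilinear cell edges, where the gradient is discontinuous and
   Newton can oscillate. Newton steps are accepted only when they decrease
   gamma², so polishing never worsens a candidate.

Design decisions, all configurable: measured points are the scored
reference and the planned grid the searched evaluation (sparse vs dense);
the global normalization dose is the evaluation maximum over the analysed
region, and the 10% threshold uses that same maximum in both
normalizations; `gamma = 1.0` passes (`<=`); threshold-excluded points are
reported but never enter GP%; an all-excluded comparison is an error, not
0% or 100%. Local normalization requires a positive threshold so a zero
denominator cannot occur. A convergence check re-runs with a halved step
and requires GP% to move by less than 0.1 points.

The engine is verified against an independent brute-force oracle
(exhaustive dense lattice over the whole grid, no radius cap, Nelder-Mead
polish of the surviving candidates) to 1e-6 per point on random small
fields, and property-tested for
monotonicity in the criteria, global-mode scale invariance, translation
equivariance, and the local-vs-global GP% ordering.

## Plan metrics

TTDF is treatment time divided by prescribed dose per fraction (s/cGy).
Leaf-open-time (LOT) descriptors are min, mean, max and the sample SD
(n−1) of the per-plan LOT array, which is treated as one flat array — no
per-leaf or per-projection structure is modelled. Singleton arrays get
SD = 0 by convention so degenerate plans stay processable. Cohort
summaries report mean, SD (n−1), min and max per parameter plus the
field-width percentage split.

## Statistical process control

The individuals/moving-range formulation: `mR` is the absolute difference
between consecutive deliveries in date order (the constant 2.660 = 3/d2
with d2 = 1.128), and the limits are `AL_cs = 100 − 3·sqrt(σ² + (x̄−100)²)`
and `TL_cs = x̄ − 2.660·mR̄`, with σ using the n−1 denominator. The
deliverability filter is strict (`GP% > 90`); filtered-out records stay in
the dataset but never enter limit computation. Baselines use the first 40
deliveries; re-evaluation periods are ~6 months.

Bootstrap intervals are percentile intervals over 10,000 resamples drawn
with replacement; each resample is consumed in its drawn order, which
matters only for the order-dependent TL statistic (whether the clinical
procedure preserved order is unknowable from the outside; this choice is
explicit and tested). A period is in control iff no delivery lies below
its own AL_cs. Drift between consecutive periods is flagged when their
bootstrap intervals for AL or TL are disjoint — a deliberately
conservative rule whose false-positive rate on stationary series is
verified to stay at or below 10%; a Kruskal-Wallis comparison across
periods is available in the stats layer as the complementary test.

## Cohort statistics

Kruskal-Wallis (tie-corrected, chi-square reference) compares GP% across
sites; an all-identical response degenerates to H = 0, p = 1 rather than
an error. Post-hoc comparisons are two-sided Wilcoxon rank-sum tests over
all k(k−1)/2 pairs with Bonferroni adjustment `min(1, m·p)`.

Predictor screening is greedy in a fixed, documented parameter order: a
parameter is excluded when its Pearson |r| against an already-included
parameter reaches 0.8. The inclusion rule is the correlation magnitude;
the correlation-test p-value is logged alongside, since a rule mixing both
("p > 0.05 and/or r < 0.8") is ambiguous. Zero-variance parameters are
excluded with a reason, not an error.

The influence analysis is a main-effects-only OLS ANOVA with Type II sums
of squares (order-invariant, asserted against an explicit full-vs-reduced
model-comparison oracle). Continuous predictors enter as tertile bins —
an n-way ANOVA needs factors, and tertiles are the simplest choice that
keeps every parameter comparable; the binning is a parameter of
`nway_anova`. Aliased designs raise an error listing the offending
factors.

## Synthetic data

`make_dose_pair` builds the planned field as a mixture of 2–5 Gaussian
blobs on the unwrapped plane and the "measurement" as a bilinear sample of
a perturbed copy at the diode positions, with perturbations applied in a
fixed order: global scale → rigid shift → Gaussian hotspot → per-point
relative noise. Because measurement sampling is bilinear against the same
grid the engine searches, an identity perturbation yields gamma exactly 0
at every diode — the generator is pinned to the engine's identity
contract. Negative doses after noise are clipped at zero and counted.

`make_plan_cohort` draws planning parameters from truncated normals
(rejection sampling) honoring the published cohort's mean/SD/range per
parameter, sites from the published case mix (28/32/77/71/84/52/41 over
385), and field width from the 2.1/92.0/5.9 percent split. Treatment time,
dose per fraction and couch travel are drawn; TTDF and couch speed are
*recomputed* from them so derived fields stay internally consistent (their
marginals therefore only approximate the published ones). LOT arrays are
normal draws (400 per plan) clamped at the ~18 ms binary-MLC latency
floor. GP% per criteria set is a truncated normal on [0, 100]; with a mean
of 97.6 and SD 2.6 the upper truncation pulls the realized mean ~0.8
points below nominal, so all moment tests compare against truncated-normal
moments (scipy `truncnorm`), not the nominal inputs. Global-normalization
GP% moments are the published ones (3G2: 97.6 ± 2.6; 3G3: 99.2 ± 1.3); no
SDs are published for local normalization, so 3L2 uses 90.9 ± 5.0 and 3L3
94.5 ± 3.5 — free parameters chosen once for realism. Per-criteria draws
are independent across criteria sets; cross-criteria correlation of a
single delivery is not modelled. Optional per-site offsets and a level
shift after a changepoint feed the power and drift studies.

What the generator does *not* emulate: anatomical structure, TPS
optimization behaviour, delivery-log physics, detector calibration drift,
or correlated spatial noise. Passing tests therefore demonstrate the
correctness and calibration of the *analysis* under the stated statistical
assumptions, not the clinical performance of any machine.

## Problem sizes and numerical tolerances

The test suite validates the engine-vs-oracle agreement on 100 random
fields of 20–30 mm extent (lattice comparisons at 1e-6), calibration of
the statistical tests with 1000 null simulations, bootstrap coverage with
200 nested replications at n = 40 with 10,000 resamples, and drift rates
over 50 seeds per arm — sizes chosen so the full pipeline's statistical
contracts are measurable with tight Monte-Carlo error while the suite
stays convenient to run. The acceptance script analyses a full 395-plan
synthetic cohort end to end.

## Known limitations

* 2D unwrapped-plane gamma only; no 3D, film, or time-resolved analysis.
* No per-site control limits in the default pipeline (the machinery
  accepts any record subset, so site-specific limits can be computed by
  filtering before `evaluate_period`).
* The moving-range bootstrap treats deliveries as exchangeable; if the
  real series is strongly autocorrelated the TL interval is approximate.
* DICOM support is read-only RT Dose with uniform frame spacing; plan
  (RTPLAN) parsing, CT/density handling and couch models are out of scope.
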