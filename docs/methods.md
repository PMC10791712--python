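# Methods

`emwater` implements a before/after (BACI-style, without a control site)
assessment of an effective-microorganism (EM) treatment in a eutrophic
reservoir. This note documents the statistical model behind each stage, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions.

## Study design and period labeling

The design is fixed: 9 sampling dates (three per year, 2019–2021), 3 sites
inside a floating dam, 2 depths (30 and 100 cm), 3 laboratory replicates —
162 replicate determinations per parameter, for 15 parameters (6
microbiological, 9 physicochemical). The EM application date (default
2021-08-09) splits the schedule into periods with a **≤ boundary**: the
application-day series is sampled immediately *before* the treatment acts,
so it pools with the before period (7 before dates × 18 = 126 values; 2
after dates × 18 = 36 values per parameter).

Values are stored in the units of the field campaign (CFU·mL⁻¹ for counts,
mg·L⁻¹ for chemistry, µS·cm⁻¹ for conductivity); any unit conversion
(e.g. per-100-mL regulatory limits, µg·L⁻¹ nutrient inputs) is explicit at
the call site, never implicit. Validated datasets admit no missing values;
the reader can drop incomplete rows with a logged count. Replicates are
never averaged before analysis — the period-wise spreads are only
meaningful at replicate level — though callers can aggregate via
`subset`/`describe` if they need series means.

## Synthetic-data generator

The generator exists because the raw campaign measurements are not
published; it reproduces the design exactly and, per parameter, a
two-period distributional model:

* **Bacterial counts** (HBN22, HBN36, CBN, FCBN, FEN): lognormal. The
  reported period summaries (SD ≈ 2–3 × mean, maxima three orders of
  magnitude above minima) are consistent only with a heavy-tailed
  non-negative family. Each period is parameterized by its arithmetic mean
  and SD, converted exactly to (µ, σ) of the lognormal; the before-period
  medians were not reported, so the scale is identified from the mean/SD
  pair rather than a (median, geometric SD) pair. For the headline count
  this gives a geometric SD ≈ 4, i.e. the pooled multi-year dispersion.
* **Physicochemical parameters**: normal truncated to [0, ∞) (pH to
  [0, 14]), with the location solved numerically (Brent) so the truncated
  mean equals the calibrated mean — material for parameters whose SD is
  comparable to the mean (TP, COD, BOD5).
* **Salmonella presence**: constant 0. None was detected during the
  campaign; the parameter is excluded from inference by the
  constant-parameter rule.

The after period applies a multiplicative factor (`after_effect`) to the
expected value with its own spread (`sd_after`); the default factors are
the reported after/before mean ratios (e.g. 0.280 for HBN22, 2.370 for
FEN). One deliberately resolved ambiguity: the fecal-coliform before mean
is set to 676.5 CFU·mL⁻¹, the value consistent with the reported after
mean (902) and the reported +33.33% change.

Randomness uses per-parameter substreams seeded from
`(seed, crc32(parameter code))`, so adding or removing a parameter never
reshuffles the others, and a given seed reproduces a dataset bit for bit.
Optional per-site multiplicative offsets (default: homogeneous) exercise
the per-point effectiveness analysis.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: within-year seasonal dynamics (each period is
i.i.d.; the real before period mixes summer blooms with November lows),
cross-parameter correlation (parameters are drawn independently, so the
PCA/Spearman stages see only noise structure unless the test constructs
correlated inputs itself), spatial autocorrelation between sites, and
detection-limit censoring.

## Descriptives and percent change

Per (parameter, period): n, min, max, sample SD (ddof = 1; n = 1 cells get
SD 0 by convention so tables stay total), median, mean over replicate-level
values. The effectiveness metric is the percent mean difference
`100·(after − before)/before` — negative for reductions, undefined (an
error) for a zero baseline. Internal values are unrounded; reported values
round **half away from zero** to 2 decimals, matching how such tables are
conventionally printed.

## Rank tests

`mann_whitney_u(x, y)` computes U for the first group from midrank sums
(U = R₁ − n₁(n₁+1)/2, so 0 ≤ U ≤ n₁n₂ and swapping groups maps
U → n₁n₂ − U), the tie-corrected normal deviate

    z = (U − n₁n₂/2) / σ,   σ² = (n₁n₂/12)·[(n+1) − Σ(tⱼ³−tⱼ)/(n(n−1))],

and the two-sided normal p. No continuity correction by default (a flag
enables it). When the smaller group has ≤ 8 values an exact two-sided p is
also computed by enumerating all C(n, n₁) group assignments of the observed
(possibly tied) pooled values. All values tied is a degenerate test and
raises. In the pipeline the before/after z is computed on the *after*
group's U, so a reduction after treatment yields a negative z; the reported
U is the smaller of the two complementary statistics, the common reporting
convention.

Spearman's rho is the Pearson correlation of midranks, with the two-sided
t-approximation p (df = m − 2). The matrix stage matches observations on
(date, site, depth, replicate), uses pairwise complete cases, reports
undefined entries (constant columns, m < 3) as absent, and annotates
|rho| ≥ 0.70 as strong — an annotation, never a filter. No multiple-testing
correction is applied anywhere, mirroring the assessment practice this
package reproduces; treat marginal p-values across 14 parameters or 91
pairs accordingly.

## Effectiveness and duration of action

The short-horizon table compares the application-day series mean with the
pooled means of the two following series, per (site × depth) point. The
overall row pools raw records across points before taking means; the
arithmetic mean of the per-point percentages is reported as an alternative
aggregate (the two agree exactly under homogeneous effects).

Duration of action asks when a reduced parameter returns to its
application-day baseline, given only three series means v₀ (day 0), v₁
(day 7), v₂ (day 14). The rule assumes the return is proportional to the
observed rate of change — operationalized as linear rebound:

* v₂ ≥ v₀: re-crossing time of the piecewise-linear path (0 if the value
  never dropped below baseline);
* v₂ ≤ v₁ < v₀: still declining — censored at the horizon;
* v₁ < v₂ < v₀: T = 14 + (v₀ − v₂)/ρ with ρ = (v₂ − v₁)/7, capped
  (censored) at the horizon.

The default horizon is 60 days: with two post-application series no decay
kinetics can be fitted, and unbounded linear extrapolation is not
defensible. The rule is deliberately pluggable; T is scale-invariant and
non-increasing in ρ. Hours are the canonical unit; minutes =
round(hours·60) and days = round(hours/24, 2) are derived, never stored
independently.

## Regulatory scoring

Compliance: each sample scores 1 if ≤ the regulatory maximum; the rating is
the compliant fraction rounded to 2 decimals, with 0.51 the exact
compliance boundary (rounding precedes the verdict so the printed boundary
is sharp). Percent improvement is computed on the unrounded fractions.
Ecological status: each observation is weighted 1/2/3 points by its class
boundaries, the mean (rounded to 2 decimals) maps to class I/II/III via the
bands 1.00–1.66 / 1.67–2.33 / 2.34–3.00 — total on 2-decimal scores by
construction. The scoring logic is fixed; the threshold tables are
configuration. Shipped compliance defaults are the Polish bathing-water
maxima (total coliforms 1000, fecal enterococci 400 per 100 mL) converted
to per-mL; the status boundaries are **documented placeholders** — the
applicable regulation assigns boundaries by abiotic water-body type, so
users must supply the table for their water body. Assessment is
per-replicate by default (switchable to series means).

## Trophic state

TSI(TP) = 10·(9.40 + 1.62 ln TP), TSI(TN) = 10·(5.24 + 1.86 ln TN),
combined as their arithmetic mean, with concentrations in mg·L⁻¹ (the
equations are applied to whatever unit the caller declares; the `ug` flag
divides by 1000 first). Classification bands are configuration with the
conventional Carlson defaults (< 40 oligotrophic, 40–50 mesotrophic, 50–70
eutrophic, > 70 hypereutrophic), left-closed. Useful closed form: doubling
TP raises TSI(TP) by exactly 16.2·ln 2 ≈ 11.23.

## PCA and diagnostics

PCA is an eigendecomposition of the correlation matrix of the complete-case
observations-by-parameters table (no rotation — the output is a component
matrix). Loadings are eigenvectors scaled by √eigenvalue; the sign of each
component is fixed so its largest-magnitude loading is positive, making
results deterministic. Retention follows the Kaiser rule, eigenvalue
strictly > 1, applied with a 1e-9 epsilon so eigenvalues equal to 1 up to
rounding (identity correlation) fall below the boundary. Communalities are
row sums of squared retained loadings; over all components they total the
number of variables, and the full loading matrix reconstructs R to machine
tolerance — both are tested invariants. Constant columns are excluded with
a warning. KMO is Σr²/(Σr² + Σq²) over off-diagonal entries, with q the
anti-image partial correlations from the scaled inverse of R (exactly 0.5
for any 2×2 matrix; undefined for the identity). Bartlett's sphericity is
χ² = −(n−1−(2p+5)/6)·ln|R| with df = p(p−1)/2; a singular R makes the test
undefined and the pipeline reports it as absent.

## Pipeline

`run_pipeline` executes: constant-parameter exclusion → descriptives →
rank tests → effectiveness + duration → compliance + status → TSI by
period → PCA + Spearman, writing plain CSV/JSON (no figures; scree data is
exported for external plotting) plus a manifest with the seed, a SHA-256
configuration hash and per-stage record counts. Runs are deterministic
under a fixed seed; no stage reads the clock or environment.

## Problem sizes and verification

Unit and property tests run at the study's native size (162 events per
parameter) or smaller; enumeration oracles (exact Mann–Whitney null,
brute-force permutation distributions, closed-form block-matrix
eigenvalues, analytic lognormal/truncated-normal moments) are kept
independent of the code paths they check. The replicated effect-recovery
experiment uses 200 simulations of the study design with a −70%
multiplicative effect on the 22 °C heterotrophic count. At those sample
sizes (126 vs 36) and the calibrated before-period dispersion (geometric
SD ≈ 4, the pooled multi-year spread), the expected rank-test deviate is
z ≈ 2.7 and the measured two-sided rejection rate at α = 0.05 is ≈ 0.75–0.80,
not ≥ 0.95: the i.i.d. moment-matched generator places the full seasonal
spread inside every date, which depresses the before/after rank separation
relative to a campaign whose post-application values fall cleanly below
most of the historical record. The mean recovered percent change is within
~2 points of −70 (small positive ratio bias from the noisy denominator).
This is a property of the declared study conditions, documented rather
than tuned away; a generator with an explicit between-date variance
component would raise the power but is out of scope here.

## Known limitations

* No multiple-testing correction (by design, see above).
* Durations rest on a linear-rebound assumption and two post-application
  series; they are order-of-magnitude estimates, not kinetics.
* Ecological-status defaults are placeholders, not a regulation.
* The generator's independence across parameters means multivariate
  structure in synthetic runs is noise; tests of the PCA/Spearman stages
  construct their own correlated inputs.
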