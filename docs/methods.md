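# Methods

## Design model

The package targets replacement-series intercropping trials: two crops
(maize M, alfalfa A) grown as alternating row strips at several row-ratio
configurations alongside sole-crop controls, in a completely randomized
design with a fixed number of replicates, analyzed one year at a time.
Every analysis is anchored on the yield quadruple (Y_IM, Y_IA, Y_MM, Y_AM)
— the intercrop and sole-crop yields of the two species — plus the sowing
proportions (Z_M, Z_A).

**Sowing proportions.** Z is taken as a crop's share of rows,
Z_M = r_M / (r_M + r_A). This assumes uniform inter-row spacing and equal
per-row sowing rates across treatments; if the two crops used different row
spacings, an area-based Z would differ and every Z-bearing index (K, A, CR)
with it. Z is therefore exposed on `RowConfiguration` rather than hidden in
the index functions.

**Yield policy.** The index definitions do not fix which alfalfa yield
accompanies maize grain yield. The default pairs maize grain with alfalfa
*forage* yield for the ratio indices (pLER/LER/LEC/K/A/CR); an alternative
`biomass` policy uses alfalfa biomass dry matter. Cumulative yield is by
definition maize grain + alfalfa biomass dry matter and ignores the policy.
SPI follows the active policy. The policy is an explicit, logged argument
(`yield_policy`), never inferred.

**Averaging modes.** `ratio_of_means` evaluates each formula once on
treatment means; `per_replicate_mean` evaluates it on every replicate
pairing and averages the results. For linear quantities the modes agree in
expectation; for ratios they do not. The crowding coefficient
K_IM = Y_IM Z_A / ((Y_MM − Y_IM) Z_M) is convex in the denominator, so
per-replicate averaging is biased upward — at a replicate CV of 0.07 the
Monte-Carlo gap for the 2:2 pattern's system K is large and systematic
(see `recovery_report`). Published K/SPI values computed from replicate
data will therefore generally exceed what the printed treatment means imply;
the built-in verification lists the affected anchors as documented
discrepancies rather than asserting them.

**Degenerate coefficients.** When a crop yields at least its sole-crop
reference in a replicate or mean (Y_IM ≥ Y_MM), the crowding denominator is
≤ 0. The coefficient is reported as `inf` with an explicit flag
(`k_maize:infinite`), never as a signed number; in per-replicate averaging,
degenerate replicates are excluded from the mean and counted in the flags.
Zero partial LERs likewise flag the competitive ratio instead of raising.
At CV 0.07 with three replicates, roughly 2–3% of 2:2-like replicates are
degenerate, so silent propagation would poison every summary.

**Aggressivity sign convention.** A_M is maize's proportion-normalized
relative yield minus alfalfa's, so positive values mean maize dominance and
A_A = −A_M exactly. The formula is applied as defined; published positive
values that the formula renders negative on the same means are reported as
documented discrepancies (most plausibly a reversed term order or reported
magnitudes in the source tables), not silently sign-corrected.

## ANOVA and mean separation

One-way CRD ANOVA is computed from the definition sums of squares, with the
F-tail probability from `scipy.stats.f`. Zero total variance returns F = 0,
p = 1 instead of 0/0. Mean separation uses Fisher's LSD at alpha = 0.05,
LSD = t(1 − α/2, df_error) · √(2·MS_error/n), *protected*: letters split
only when the ANOVA F-test is itself significant — the conventional reading
that avoids inflated pairwise claims; an unprotected mode is a flag away.
The compact letter display uses insert-and-absorb; because all pairs share
one threshold, the resulting letter groups are contiguous in the mean
ordering, and tests check them against an exhaustive all-pairs oracle. Ties
in means are broken by treatment label, which affects presentation only.
Only balanced designs are accepted for LSD (the targeted trials replicate
equally); unbalanced data fail loudly.

Years are analyzed separately; no year × treatment interaction model is
fitted, matching how such trials are conventionally reported.

## Reference tables and pseudo-replicates

The shipped reference tables store printed treatment means ± SD (yields,
biomass, thousand-grain weight, plant heights) for seven planting patterns
over two years. Replicate-level data are not published, so for ANOVA/LSD the
means are expanded to the deterministic 3-point set {m − s, m, m + s},
whose sample mean is exactly m and sample SD (ddof = 1) exactly s. This
preserves every first- and second-moment summary but *not* the real error
structure: the pseudo-replicates are symmetric and perfectly balanced, so
letter displays computed from them are internally consistent with the
printed means/SDs but need not equal the original letters. Accordingly the
tests assert oracle-consistency of the letters, never the published letter
strings.

## Synthetic trial generator

The generator emulates the trial structure, not its biology: sole-crop
means per crop × year × trait; one phenomenological competition multiplier
f per intercrop pattern × crop (expected intercrop yield = f × sole-crop
mean, shared across that crop's traits); multiplicative Gaussian noise
value = mean(1 + cv·ε) truncated at zero, with one CV shared across cells
(printed SDs are roughly proportional to means); no year × treatment
interaction beyond per-year sole-crop means. Defaults mirror the reference
trial: 7 patterns × 2 years × 3 replicates, CV 0.07 (the magnitude of the
printed SD/mean ratios), multipliers equal to the first year's
intercrop/sole ratios (e.g. f_M = 0.824, f_A = 0.710 for the 2:2 pattern).

Because expected yields are proportional to sole-crop means, every ratio
index has a closed form in (f_M, f_A, Z): pLER = f, LER = f_M + f_A,
A_M = f_M/Z_M − f_A/Z_A, CR_M = (f_M/f_A)(Z_A/Z_M), K_IM = f_M Z_A/((1 −
f_M) Z_M). `theoretical_indices` evaluates these exactly and
`recovery_report` measures estimator bias/spread against them in both
averaging modes. What the generator does **not** emulate: spatial structure
and edge effects, correlated noise between crops sharing a plot, year ×
treatment interactions, non-Gaussian error, or any mechanistic light/N
competition — passing recovery tests show the estimators are computed
correctly under the stated noise model, not that the model describes a
given field.

Randomness: one root seed, with an independent stream per (year, pattern,
crop, trait) cell derived via a CRC-32 of the cell key, so draws are
deterministic, independent of configuration ordering, and stable when a
pattern is added. Monte-Carlo trial seeds are derived from the root seed
and trial index and kept below 2³¹.

## Numerical and verification choices

* Reported index values carry full double precision; comparisons with
  printed anchors use the printed precision (1 d.p. for LER/LEC, 0.1%
  relative for kg ha⁻¹ totals, integer percent for heights).
* Percent-of-control returns the exact value plus both integer renderings
  (truncated and half-up rounded), since published integer percentages mix
  the two conventions.
* Monte-Carlo sizes: recovery checks use 500 trials of the pattern under
  test with its two sole-crop controls (≈ 5 s); the generator-mean sanity
  check accepts ≥ 97% of cells within 3 standard errors, the expected
  coverage at 3 replicates.
* The CLI writes no timestamps, so repeated runs on identical inputs are
  byte-identical; exit codes distinguish validation (2) from I/O (3)
  failures.

## Known limitations

* Two crops only; the index algebra (A antisymmetry, CR reciprocity) is
  inherently pairwise.
* No economic indices (monetary advantage, area–time equivalent ratio) and
  no mixed or repeated-measures models across years.
* The gas-exchange helper treats the 0.6 × 0.6 chamber constant as given;
  it is not dimensionally derived, so readings from other chamber
  geometries need their own factor.
* Pseudo-replicate expansion is defined for n = 3 only; other replicate
  counts would need a different moment-matching set.
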