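# Methods

## The measurement problem

Operating-room (OR) air quality for infection control is certified by
culture: an active air sampler draws 1 m³ through a gelatine filter over 10
minutes, the filter is incubated for 48 hours, and aerobic colony-forming
units per m³ (CFU/m³) are counted. The result arrives days after surgery. A
real-time alternative counts fluorescing bioparticles (FBP): a laser
illuminates 5-second air draws at 5 dm³/min and particles whose NADH or
riboflavin autofluorescence indicates biological activity are counted in six
optical size bins (0.5–<1, 1–<2, 2–<3, 3–<5, 5–<10, ≥10 µm). Summing 120
consecutive 5-second counts gives a 10-minute total per 50 dm³ —
commensurate with one culture sample. Because the culture filter retains
particles ≥3 µm, the comparison quantity on the optical side is the ≥3 µm
total (FBP ≥3 µm/50 dm³).

The package implements the complete comparison pipeline: ingest and
validation of both measurement streams, detection of diathermy-distorted
periods, pairing and exclusion bookkeeping, and the method-comparison
statistics, plus a synthetic session generator with exact ground truth.

## Distortion detection

Electrosurgical cautery (diathermy) vaporizes tissue and floods the counter
with small fluorescent particles, inflating FBP counts without any change in
viable bacterial load. The detector flags a 10-minute period when all three
hold, with every threshold configurable (`DistortionRule`):

1. a run of ≥12 consecutive 5-second counts of 0.5–<1 µm particles ≥10,
2. at least one count in that run ≥20,
3. within the run's records, at least one 3–<5 µm count ≥3 **and** one
   5–<10 µm count ≥2.

Runs are maximal, half-open index intervals found by a linear scan and do
not span period boundaries; the exclusion unit is the whole 10-minute
period. Whether requirement 3 should be evaluated over the run or over the
whole period is genuinely open; the default is the run span
(`clause_scope="run"`), with `"period"` available, and the packaged worked
example is flagged identically under both. All clauses are lower-bound
thresholds, so the verdict is monotone: raising any count never un-flags a
period (a property test).

## Pairing and exclusions

FBP periods and CFU samples join on (surgery id, period index) — the two
instruments sample in the same scheduled slot, so the join is by slot, never
by clock alignment. A pair leaves the analysis set for exactly one recorded
reason: `cfu_discarded` (contaminated or condensed culture plate) or
`distorted`; when both apply the plate discard takes precedence so the two
groups stay disjoint, giving the exact identity

    n_analyzed = n_total − n_cfu_discarded − n_distorted.

No unit normalization is applied before statistics: the pipeline correlates
FBP ≥3 µm per 50 dm³ against CFU per m³ on their native scales, as the
instruments report them (a ×20 helper `fbp_per_m3` exists but is unused).
Surgery-level analyses use arithmetic means over the surgery's non-excluded
periods, however many remain; incomplete 10-minute windows (<120 records)
are rejected by default because the complete window is the unit of analysis
(`policy="drop"` skips them with a warning instead).

## Statistics

**Spearman correlation.** r is the Pearson correlation of midranks (ties
get the mean of the ranks they span — essential for count data). The CI is
the Fisher-z interval `tanh(atanh r ± z·(n−3)^{−1/2})`, defined for n > 3.
This plain variant reproduces the reference interval for r = 0.87, n = 18
as (0.68, 0.95) to two decimals, which is the anchor the implementation is
checked against. Reported values round half-away-from-zero to two decimals.

**Passing–Bablok regression.** For paired measurements the slope is the
shifted median of all pairwise slopes S_ij = (y_j − y_i)/(x_j − x_i), i<j:
coincident points contribute nothing, vertical pairs enter as ±∞ at the
extremes, slopes exactly −1 are discarded, and K = #{S < −1} offsets the
median index. The slope CI comes from the order statistics at ranks
M1 = ⌈(N − C)/2⌉ and M2 = N − M1 + 1 shifted by K, with
C = z·√(n(n−1)(2n+5)/18); CI ranks are clipped into [1, N] for very small
samples. The intercept is median(y − b·x); no intercept CI is computed.
The estimator assumes a positive method relation; it is exactly
scale-equivariant only while no pairwise slope crosses the −1 threshold
under the scaling (K unchanged), which holds in the monotone regime it is
designed for. Correctness is established by exact agreement with an
exhaustive pure-enumeration oracle on 1000+ random small datasets and exact
recovery on noiseless affine data.

**Quartile cross-tabulation.** Pairs are stably sorted by FBP ≥3 µm (ties
keep input order) and the lowest/highest ⌊n/4⌋ pairs selected; for each CFU
cutoff (default 5 and 10 CFU/m³) the fraction of selected pairs at or above
it is reported. The percentile convention (floor quartile size, stable tie
break) is a documented choice; the nested-threshold inequality
frac(≥10) ≤ frac(≥5) always holds.

## Synthetic sessions

The generator is statistical, not mechanistic: no aerosol physics,
ventilation dynamics, or staff covariates. Per 10-minute period a latent
release intensity

    λ = base_intensity · (1 + activity_amplitude · E),  E ~ Poisson(event_rate/6)

is drawn (λ in expected FBP ≥3 µm per 50 dm³); E lumps activity events such
as door openings. Given λ the instruments are conditionally independent:
per-record bin counts are Poisson with mean λ·f_b/f_≥3/120 (f the bin
allocation fractions) and the period's CFU/m³ is Poisson(cfu_coupling·λ).
The shared λ is the sole source of FBP–CFU dependence.

Defaults (plausibility choices on the instruments' reported axes, not
estimates from data): 18 surgeries × 6 periods; base_intensity 12,
activity_amplitude 1.0, event_rate 6/h, cfu_coupling 0.3 CFU per unit λ;
bin fractions (0.40, 0.22, 0.13, 0.13, 0.08, 0.04) putting 75% of mass
below 3 µm; plate-discard probability 8/108 (or an explicit schedule).
These put baseline CFU near 3/m³, period FBP ≥3 µm mostly 10–60, and a
period-level Spearman r around 0.7.

Diathermy bursts are injected on an explicit schedule as *added* Poisson
counts with per-record bin means (80, 33, 11, 3, 1, 0.1) — the magnitude
pattern of the printed diathermy excerpt — so counts only increase and
ground truth is exact. Bursts draw from their own random substream, so runs
of the same seed with and without a burst schedule share identical baseline
draws; this paired design is what the exclusion-recovery checks use.
`study_conditions()` fixes the study-scale bookkeeping: 8 scheduled plate
discards (3+2+1+1+1 across five surgeries) and 4 bursts of 16–28 records
(2 in one surgery, 1 in each of two others), disjoint from the discards.

What the generator does **not** emulate: within-period intensity dynamics
(λ is constant over 10 minutes), overdispersion beyond the event mixture,
spatial gradients between the two sampling heads, instrument dead time, or
counting losses. Passing tests therefore show the pipeline's logic and
statistics are correct under the assumed structure, not that real OR air
satisfies that structure.

## Numerical and design notes

- Timestamps are time-of-day at 1-s resolution; records must be strictly
  increasing at exactly 5-s spacing within a period and midnight wrap is
  rejected (no overnight surgeries).
- The printed 16-record excerpts are handled through an explicit
  `excerpt=True` mode in classification and aggregation; their totals cover
  a partial sampled volume (16 draws = 6.7 dm³), reported via `n_records`.
- Problem sizes: property suites use n ≤ 12 for the exhaustive regression
  oracle (≤66 pairwise slopes), 20 paired seeds for exclusion recovery and
  500 Monte-Carlo replicates for detector sensitivity — large enough for
  the stochastic bounds with comfortable margin at desk scale.
- Degenerate inputs: constant x or y gives a flagged undefined Spearman r;
  Passing–Bablok requires n ≥ 3, non-constant x, and at least one retained
  slope; quartile cross-tabs require n ≥ 4.
- The report (`AnalysisReport`) always contains both the
  distortion-excluded and distortion-retained analyses at period and
  surgery level — the contrast between them is the pipeline's central
  output — and validates against the JSON schema shipped at
  `orair/data/report.schema.json`.

## Known limitations

- The distortion rule is pattern-based and post hoc; it flags the artifact
  signature, not the physical cause, and its thresholds are not validated
  against independent diathermy annotations.
- The Fisher-z interval is one of several CI conventions for Spearman's r;
  alternatives (e.g. with rank-specific variance corrections) differ at the
  second decimal for moderate n.
- Surgery-level correlations rest on 18 points; their CIs are wide and the
  generator's surgery-level r is noticeably lower than its period-level r
  because averaging six periods shrinks the between-surgery signal.
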