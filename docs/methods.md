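# Methods

This note documents the models, conventions and numerical choices
behind the `whitecast` pipeline: what each stage computes, which
parameters matter, what the synthetic-data generator does and does not
emulate, and where the design was genuinely open.

## The measurement problem

Mineral sunscreens scatter visible light and leave a white residue
("white cast") whose visibility depends on the skin it sits on.  The
pipeline works from CIEL\*a\*b\* colorimeter readings taken before and
after product application: L\* (0 = black, 100 = white) carries the
whiteness signal, while b\* enters through skin-tone classification.

Constitutive pigmentation is classified by the Individual Typology
Angle,

    ITA° = arctan((L* − 50) / b*) · 180 / π ,

the standard angle of the (b\*, L\* − 50) vector (Chardon et al., Int J
Cosmet Sci 1991).  Default subtype cut-offs follow the established
convention — very light > 55°, light 41–55°, intermediate 28–41°, tan
10–28°, brown −30–10°, dark ≤ −30° — half-open, with an angle on a
boundary assigned to the lighter subtype.  Both the boundaries and the
tie-break are configuration (`ita_boundaries` in the config file).
Subtypes group into three pigmentation categories: light (very light +
light), medium (intermediate + tan), dark (brown).  The dark *subtype*
has no category because the emulated panel design does not include it;
classifying it raises an explicit error rather than guessing.

## The white cast score

For a substrate with baseline lightness L\*ᵢ and post-application
lightness L\*f,

    score = (L*f − L*ᵢ) / (100 − L*ᵢ).

The denominator is the headroom left below reference white, so the same
additive lightness gain scores higher on lighter skin — the score
measures white cast *relative to the skin tone*.  Anchors: 0 when
nothing changed, 1 at saturation.  Negative scores (post darker than
baseline) are retained and flagged, never clipped: they diagnose
measurement problems.  A substrate already at L\*ᵢ = 100 has no defined
score and raises.

Site-level readings are averaged within (substrate, formulation,
timepoint) before scoring; the alternative (score each site, then
average) is exposed via `per_site=True` for sensitivity checks.  The
default was chosen because the protocol defines the formulation square,
not the site, as the scored unit; on balanced data the two orders agree
to ~1e-4.

### Interpretation bands

Scores map to four bands — no white cast / reasonable / threshold /
unacceptable — through three ascending edges (half-open intervals,
closed on the left).  The numeric edges are **not universal
constants**; they are configuration, and `calibrate_band_edges` derives
them from scored data plus a desired formulation-to-band mapping by
placing each edge midway between adjacent bands' mean scores.  The
shipped defaults were produced by that calibration on the noiseless
generator model and reproduce the published qualitative mapping
(0% → none, 5% → reasonable, 10% and the in vivo benchmark →
threshold, 20–30% → unacceptable; benchmark reasonable in vitro):

* in vivo: 0.02 / 0.055 / 0.12
* in vitro (black acrylic): 0.05 / 0.15 / 0.30

The scales differ per protocol because a dark substrate leaves far more
headroom (denominator ≈ 63 vs ≈ 40 on skin), so identical formulations
produce systematically larger in vitro scores.  Whether one scale could
serve both protocols is an open question; the package keeps them
separate.

## Method validation battery

All validation limits are configuration evaluated by one gate function
(`check_gates`); the defaults are the ICH-style study limits: accuracy
80–120%, precision < 10% RSD, adjusted R² > 0.650.

* **Device suitability** — triplicate readings on black and white
  acrylic sheets; per channel RSD = 100·sd/|mean| (sample sd, n−1)
  must be ≤ 2.0%.  Channels whose |mean| is below a configurable floor
  (default 0.5) would divide by near-zero and are reported
  *indeterminate* instead of failing; on neutral calibration sheets
  this is the expected state of a\* and b\*.
* **Linearity** — OLS of L\* on ZnO % (scipy `linregress`), slope and
  intercept with standard errors, adjusted R² = 1 − (1 − R²)(n−1)/(n−2).
  Requires ≥ 3 distinct ZnO levels.  The benchmark is excluded from all
  fits: it is formulated differently (particle size/coating) and would
  confound the dose-response.
* **Normality-gated correlation** — Shapiro–Wilk on the L\* response at
  α = 0.05 (configurable); Pearson if the gate passes, Spearman
  otherwise.  The gate's p-value is carried in the result so routing is
  auditable.  The gate can be applied per stratum or globally — the
  drivers apply it per stratum, which is the stricter reading.
* **Accuracy, in vivo** — per-subject 100 · measured/reference baseline
  L\* against a user-supplied reference table per ITA subtype,
  aggregated as mean [95% t-interval] across subjects.  The ratio
  convention is the default (an "88–96% of reference" statement is a
  ratio); an absolute-deviation convention (100 − |Δ|) is available.
  Reference values are configuration, never derived by the package; a
  subtype without a reference raises.  Single-subject subtypes report a
  degenerate (NaN-bounded) interval.
* **Accuracy, in vitro** — standard black/white paint readings against
  the theoretical anchors (0,0,0) and (100,0,0).  A ratio is undefined
  against theoretical black, so accuracy = 100 − ΔE₇₆ to the anchor;
  this is an interpretation, documented as such.
* **Precision** — %RSD of L\* per (factor level, formulation) group,
  split by timepoint; `intra_day` additionally conditions on day,
  `inter_day` pools days.  Min–max RSD reported per factor level.
  Groups with one reading are skipped with a warning.  In the in vivo
  protocol each volunteer visits on their own day, so the inter-day
  axis coincides with the between-subject axis.
* **Fisher-Z equivalence** — z = atanh r; two correlations are compared
  by Z = (z₁ − z₂)/√(1/(n₁−3) + 1/(n₂−3)) with the two-sided 5%
  criterion |Z| ≥ 1.96.  The sample sizes are explicit arguments: the
  package does not guess effective n values.

### Color conversions

CIELAB → sRGB hex goes through scikit-image (CIELAB → XYZ → sRGB) under
D65 / 2° by default (configurable); out-of-gamut channels are clamped,
making the conversion total.  The published HEX swatches are
illustrative and device/illuminant-dependent, so bit-exact reproduction
is not attempted.  Color difference is CIE76 (Euclidean in Lab) —
chosen over CIEDE2000 for transparency, and because no specific ΔE
formula is prescribed for this protocol.

## Inter-rater reliability

Raters rank the six formulations from least (1) to most white cast.
Agreement is the intraclass correlation from the two-way items × raters
ANOVA under the absolute-agreement definition (McGraw & Wong 1996):

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)MSE + k/n (MSC − MSE))

with the average-measures form ICC(A,k) and F-based confidence
intervals (Satterthwaite df for the absolute-agreement interval);
the p-value tests ICC = 0 via F = MSR/MSE.  Which of single or average
measures a published value used is often unstated, so both are always
reported.  Two degenerate cases are handled explicitly and flagged:
zero total variance (ICC reported as 1) and zero residual variance
(perfect agreement; point estimates exact, interval collapses).
Feeding ordinal ranks to an ICC designed for continuous ratings mirrors
field practice and is documented as an approximation.

Continuous line-scale marks are converted to ranks per rater; exact
ties become midranks and are flagged.  Rank summaries are per-item
median [Q1, Q3] with Tukey's inclusive hinges (halves include the
median at odd n) — the quartile convention is configurable in the sense
that the function is small and documented; no published convention is
assumed.

## Group comparisons

* Kruskal–Wallis H with tie correction across formulations; an
  all-identical input returns the degenerate H = 0, p = 1 rather than
  an error.
* Dunn's post hoc pairwise z statistics from the pooled midranks with
  the Σ(t³−t)/(12(N−1)) tie correction; raw two-sided normal p-values
  adjusted by Bonferroni over all k(k−1)/2 pairs by default (an
  interpretation of the Prism convention; any statsmodels
  `multipletests` method name is accepted).
* Wilcoxon signed-rank for before/after shifts; zero differences are
  dropped by default (`wilcox` policy; `pratt` available), the exact
  null distribution is used up to 25 nonzero differences and the
  normal approximation above.  All-zero differences return a flagged
  degenerate result.
* Significance stars: \* < 0.05, \*\* < 0.01, \*\*\* < 0.001,
  \*\*\*\* < 0.0001.
* Across-formulation comparisons default to per-site measurements
  (n = 39 = 13 volunteers × 3 sites per formulation) rather than
  per-subject means; the drivers operate at site level.

## The synthetic study generator

No raw measurements are deposited for studies of this kind, so the
pipeline ships a generator whose **defaults are the study conditions**,
not tuning knobs.

**Design.**  13 volunteers: 1 very light, 4 light, 1 intermediate,
2 tan, 5 brown — realizing the published category counts (5 light,
3 medium, 5 dark).  Six formulations (0/5/10/20/30% ZnO + 14.7%
benchmark), six forearm squares, three sites per square, before/after
timepoints: 13 × 5 × 3 = 195 non-benchmark post measurements (75 light,
45 medium, 75 dark).  In vitro: VITRO-SKIN over black or white acrylic,
6 replicates per formulation = 3 sites × 2 days (the decomposition of
the published "n = 6" into sites × days is an assumption, documented
here), giving 30 non-benchmark post measurements per background.

**Response model.**  Post-application lightness follows the published
per-category linear responses: baselines 63.66 / 55.94 / 46.28 L\* and
slopes 0.2801 / 0.3570 / 0.5057 L\* per ZnO % (light / medium / dark);
in vitro baselines 36.59 / 87.22 and slopes 1.274 / 0.09224 (black /
white acrylic).  The benchmark's whitening is expressed as an
equivalent laboratory ZnO %: 7.5 in vivo (between the 5% and 10%
formulations) and 3.0 in vitro (below the 5% formulation), reproducing
the published reversal of its position between protocols.

**Noise calibration.**  Residual noise SDs are not published directly;
two published summaries constrain them: the per-stratum correlation
strengths (r = 0.822 / 0.841 / 0.883) and the precision envelopes
(before-application inter-day RSD within [2.2, 3.87] / [4.18, 5.66] /
[6.46, 9.28] %).  A calibration to the envelope centers would put the
medium category's expected adjusted R² below the 0.650 gate, so the
calibration targets the correlation strengths — total within-category
noise SD 2.09 / 2.47 / 3.00 L\* (`calibrate_total_noise` implements the
closed form σ = slope · sd(ZnO) · √(1/r² − 1)) — which lands inside the
envelopes as well (expected RSD 3.28 / 4.42 / 6.48%).

The totals decompose into between-subject (0.8), between-square (0.5)
and site (1.87 / 2.28 / 2.85) components.  Most variance sits at site
level for two reasons: (i) conditioning on ITA subtype bounds
between-subject spread — subjects sharing a subtype occupy a narrow
lightness window; (ii) the published slope standard errors equal
σ_total/√(n·var(ZnO)), i.e. they presume independent per-measurement
noise, and a site-dominant decomposition is the one under which that
assumption (and hence 2-SE coverage of the generating slope) actually
holds.  Baseline b\* is chosen per subject so the computed ITA lands at
the midpoint of the feasible stretch of the assigned subtype's interval
given the drawn L\* and a plausible skin b\* range (4–30); an
infeasible combination raises a generation error.

In vitro noise decomposes into per-piece (1.3 / 0.3 for black / white),
per-day (1.2 / 0.25) and per-site (0.8 / 0.2) components, sized from
the published inter- vs intra-day envelope gap.  One published quantity
cannot be reconciled here: the black-acrylic fit's stated adjusted R²
of 0.722 with slope 1.274 implies residual scatter ≈ 8.6 L\*, which
contradicts the ≤ 6.41% precision envelope on a mean of ≈ 37.  The
generator follows the precision envelopes; its in vitro fits are
correspondingly tighter (adjusted R² ≈ 0.98) than the published value.

**Perception layers.**  Rankings: each rater perturbs the true order
(0%, BM, 5%, 10%, 20%, 30%) by one sweep of adjacent transpositions at
swap rate 0.05 (expert-like agreement, ICC > 0.95).  Questionnaire:
categorical draws with the published response proportions as
probabilities.  Generated L\* is clipped to [0, 100] with clip events
counted in `DataFrame.attrs["n_clipped"]` (zero under the defaults).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: skin-tone-dependent *score* perception
beyond the linear L\* model; heteroscedasticity across formulations;
within-subject left/right-arm or time-of-day effects; device drift;
non-Gaussian residuals; correlation between a volunteer's objective
score and their subjective ranking errors; panel attrition.  The
generator's role is to carry the published first- and second-moment
structure so every pipeline stage runs and its statistical behavior
(parameter recovery, gate logic, ordering properties) can be verified.

## Problem sizes and determinism

The test suite and the acceptance script run the full default study
(468 in vivo + 144 in vitro readings) and a 100-replicate
parameter-recovery ensemble — sizes chosen to estimate coverage
fractions to a few percent while keeping the whole suite in seconds.
All generators consume a `numpy.random.default_rng` seed and are
byte-deterministic given (design, model, seed); the study default seed
is 0.  With 3–5 subjects per category the realized per-category
adjusted R² of any *single* replicate fluctuates by ±0.05–0.10, so
ensemble statements (coverage, mean R²) are asserted over replicates
while the end-to-end band mapping is asserted on the default-seed
study.

## Known limitations

* Band edges are calibrated, not derived; transferring them to a
  different panel composition or device requires recalibration.
* The in vivo accuracy check inherits whatever reference table it is
  given; the package ships no literature reference values.
* ICC on ranks is an approximation (ordinal data in a continuous-model
  ANOVA); with k = 6 items and unanimous raters the interval
  degenerates.
* The Fisher-Z comparison assumes independent samples; in vivo and in
  vitro measurements of the same formulations are only approximately
  so.
* Exact Wilcoxon p-values with tied |differences| are computed on
  midranks; the suite verifies them against full 2ⁿ enumeration up to
  n = 12, but very heavy tie structures at larger n rely on the
  normal approximation.
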