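# Methods

This note records the statistical model behind `lipidflux`, the
conventions and defaults it adopts, what the synthetic-data generator
does and does not emulate, and the numerical choices a maintainer would
want written down.

## The inference problem

Plasma carries several hundred lipid species whose levels are maintained
by tissue production, secretion and uptake. An acute stress that remodels
lipid metabolism quickly — here, cold exposure of mice for a few hours —
perturbs both tissue and plasma lipidomes, and the co-variation between a
tissue lipid and a plasma lipid *beyond* the shared temperature response
is evidence that the tissue interacts with the circulating pool. The
pipeline operationalizes this as a lipidome-wide screen of bivariate
regressions with temperature as a covariate, surrounded by the standard
stages of an LC-MS lipidomics analysis: annotation curation,
internal-standard semiquantification, differential screening, and
cross-tissue correlation.

## Stages and their models

### Lipid nomenclature

Shorthand names (`Class[_subclass] [d|t]C:D[_C:D…]`) are parsed into a
class token, optional subclass, and a list of chains with roles (acyl,
sphingoid, or a single unresolved "sum" chain). Identity is the
canonical key: class + subclass + the chain multiset, so chain order
never matters for resolved species. Two deliberate conventions:

* **Sum vs resolved compositions are distinct identities.** `PC 34:4`
  and `PC 16:0_18:4` never merge; inferring chains from a sum
  composition is not attempted.
* **Sphingoid bases count as chains** in all chain tallies by default
  (toggleable). The d18:0/d18:1 backbone of a ceramide is an 18-carbon
  signature in its own right, and ignoring it would hide exactly the
  saturated-18 sphingolipid signal that distinguishes adipose depots.

Ether/oxidized species are accepted as opaque identities (class token
plus verbatim chain text, unresolved) rather than rejected, since they
appear in annotation output but play no role in chain analytics.

### Annotation curation

Automated annotation produces redundancies: adducts, re-integrations of
the same peak shifted slightly in retention time, in-source fragments.
Within one ionization mode and one identity, an annotation is dropped
when it elutes within 0.10 min of a retained annotation, or when its
abundance is below 25% of the identity's dominant annotation. Across
modes, an identity annotated in both keeps only the higher-abundance
mode. Choices the rules leave open, fixed here:

* Candidates are visited in order of descending abundance and greedily
  retained, so the dominant annotation anchors every comparison; ties go
  to the earlier retention time, then input order. This makes the filter
  deterministic and idempotent, and it provably matches an exhaustive
  pairwise fixed-point filter (tested against one).
* The 25% rule is measured against the identity's maximum-abundance
  record by default; a pairwise variant exists for sensitivity analysis
  and coincides with the default under the greedy order.
* Rules never compare different identities, regardless of how close they
  elute.

### Semiquantification and transforms

Abundance = (peak area / class internal-standard area) x spiked pmol /
tissue amount, giving pmol/mg (pmol/ml for plasma). Per-class spiked
amounts are configuration, not constants; the acylcarnitine standard
defaults to 300 pmol of deuterated oleoyl-carnitine and other classes to
100 pmol of a SPLASH-style class standard. The result is invariant to
joint rescaling of a sample's areas, which is the point of
ratio-to-standard quantification.

Nonpositive and missing measurements are treated as missing, never as
zeros — log2 of zero is never taken. For regression, each lipid is log2
transformed, mean-centered and scaled to unit sample SD (ddof = 1)
within its own tissue's 12 samples; whether to center within tissue or
across pooled tissues is genuinely open, and within-tissue is chosen
because each tissue is screened as its own panel with its own 12
samples. Rows with fewer than 3 observed values or zero variance are
excluded with a logged reason.

Outliers are values beyond 2 sample SDs of the mean of the vector
entering a given comparison, flagged in a single pass (no re-flagging
after removal, which would be a stricter, different rule). For the
differential screen the rule is applied per temperature group — a
genuine group shift must not flag valid points — and for correlations
per tissue vector before pairing.

### Differential screen

Per lipid: equal-variance two-sided Student's t between the temperature
groups on normalized (not standardized) abundances; log2 fold change is
cold over room, so standardization never distorts ratios.
Benjamini–Hochberg correction is applied within each tissue's screen
(pooling tissues would mix very different panel sizes and effect
densities), and a lipid is called changed at q < 0.30 — a deliberately
permissive, discovery-oriented threshold. "Increased in cold" means
q below threshold and positive fold change. Welch's t is available
behind a flag. PCA of tissues runs on complete-case lipids, samples as
observations, with the sign convention that each component's
largest-magnitude loading is positive.

### Cross-tissue correlation

Pearson r on mouse-paired vectors pooled across both temperature groups,
with the exact two-sided p from t = r·sqrt(n−2)/sqrt(1−r²) on n−2 df.
Pairing is pairwise-complete after per-tissue outlier removal. No
multiplicity correction is applied to correlation p-values. As a
consistency anchor: r = 0.87 over 12 pairs gives p ≈ 2.3 x 10⁻⁴ under
this transform, i.e. below a printed bound of 0.001.

### Regression screen

For a plasma lipid of interest Y and each tissue lipid X (both
standardized), fit

    Y = b0 + b1·Temperature + b2·X,    Temperature: cold = 0, room = 1.

X is *significantly predictive* only when both the temperature and lipid
terms have two-sided P < 0.05. The dual criterion is the screen's core:
a lipid that merely tracks temperature will show a strong marginal
association with Y, but conditioning on temperature removes it; and
requiring the temperature term too restricts calls to settings where the
stress actually moved the plasma lipid. Positive b2 is read as candidate
contribution to the circulating pool, negative b2 as candidate uptake.
No multiplicity correction enters the flag; BH q-values across each
screen are reported as a diagnostic only. The temperature-by-lipid
interaction model is available as a diagnostic and never enters the
flag. Outlier removal is off by default in the screen (the >2 SD rule
attaches to pairwise comparisons, not to the regressions) and available
behind the standard flagging utilities. Mice align across tissues by
mouse id; a tissue missing a mouse drops that mouse from its own fits
only. With standardized y and x the intercept satisfies
b0 = −b1·mean(T) exactly — "effectively zero" after centering — and this
identity is asserted in tests.

The OLS machinery is a direct least-squares solver (QR via
`numpy.linalg.lstsq`, SEs from the residual variance times the diagonal
of (X'X)⁻¹) because the screen performs tens of thousands of 12 x 3
fits; `statsmodels.OLS` and a hand-written normal-equations solver serve
as independent oracles in the tests. Exact fits (residual SS below
1e−10 of total SS) are flagged degenerate, with zero SEs and p = 0 for
coefficients distinguishable from zero.

### Chain analytics

Two counting semantics, implemented separately on purpose: *occurrence*
counts how many species contain a chain at least once (per class), while
*composition* counts chain slots with multiplicity among the
cold-increased lipids and reports percentages, with chains under a 5%
display share hidden but retained in the full output. Sum-composition
species are excluded from per-chain tallies (their chains are unknown)
and surface in an explicit `unresolved` bucket.

## The synthetic-data generator

`synthetic.generate_study` emulates the target study design: plasma plus
nine solid tissues (liver, BAT, iWAT, eWAT, kidney, intestine, lung,
heart, gastrocnemius), two temperature groups of n = 6 mice, and
class-structured panels whose default sizes follow the magnitudes of
deep multi-tissue profiling (plasma 457 species — the smallest panel —
up to kidney 855); `small_design()` scales panels to tens for fast runs.

The measurement model is multiplicative log-normal noise: lipid i in
sample s has log2 abundance

    base_i + shift_i·[cold] + noise_sd·z_is,

with baselines N(10, 2) in log2-pmol units, default noise_sd 0.5 (a
realistic ~40% CV for semiquantitative LC-MS), a default 10% of lipids
temperature-responsive at ±1 log2 unit, and 2% missingness. Plasma
lipids of interest (major acylcarnitines and ceramides are always in the
plasma panel) receive a +2 log2 cold shift.

Contributor/consumer structure is planted on the standardized log scale,
where the screen operates. Each plasma target owns a latent standard
normal factor f; the target's noise is sqrt(|b2|)·f + sqrt(1−|b2|)·e,
and every linked tissue lipid's noise is ±sqrt(|b2|)·f +
sqrt(1−|b2|)·e′. Each link therefore has population partial correlation
exactly ±b2 with the target given temperature — for any number of links
per target, which a direct "y as a weighted sum of x's" construction
cannot deliver once the squared weights exceed 1. Consumer-tissue links
carry the negative sign; the generator encodes sign only, not mechanism.
The regression *coefficient* on standardized variables additionally
carries the ratio of marginal SDs (temperature shifts inflate marginal
variance), so recovery is assessed on the planted partial correlation
and the significance test, which are invariant to that scaling.

Raw peak areas are emitted by inverting the normalization formula
(area = pmol x amount x IS area / spiked pmol), so the quantify stage
recovers the planted pmol values exactly. Every random draw comes from
a substream keyed by (seed, stage, tissue, lipid) — adding lipids,
classes or tissues never perturbs existing draws, and a fixed seed
reproduces every table byte for byte.

What the generator does **not** emulate: chromatographic peak shapes and
raw spectra, adduct mass relationships, retention-time drift between
runs, batch effects, heteroscedastic class-dependent noise, correlated
missingness (censoring at a detection limit), or biologically structured
covariance beyond the planted links. Passing tests therefore demonstrate
that the statistical machinery is correct and calibrated under the
stated noise model, not that the pipeline is robust to every failure
mode of real instrument data.

The annotation fixture generator plants duplicate groups that each
violate exactly one curation rule (an RT twin within 0.10 min kept above
the intensity cutoff; a far-eluting satellite below 25%; a dual-mode
pair with one weaker mode), so the curated survivor set is forced by
construction and recovery can be asserted exactly.

## Calibration and power checks

`evaluate_recovery` scores a screen against the ground truth:
sensitivity (flagged planted / planted), false-flag rate on null links,
sign accuracy among correctly flagged links, and whether the planted
contributor tissue has the most flagged positive predictors.

The analytic reference for sensitivity is the exact power of the
two-sided partial-correlation t-test: the sample partial correlation
given k covariates is distributed as a plain sample correlation on
n − k observations, whose exact density (Gaussian-hypergeometric form)
is integrated beyond the critical |r| of the t-test with n − 2 − k df.
At planted b2 = 0.8, n = 12, k = 1 this gives power ≈ 0.905, and the
simulated screen's sensitivity over hundreds of studies matches it to a
few points. Under an all-null design with a real temperature effect the
dual-criterion flag rate is bounded by the nominal 5% (it is
P(p_temp < .05)·P(p_lipid < .05 | null) ≤ 0.05), which the calibration
runs reproduce.

Problem sizes used in the shipped checks — panels of 8–50 lipids, 25 to
500 simulated studies per property — were chosen so the full suite runs
in a few minutes on one core while keeping Monte-Carlo error well inside
the asserted tolerances.

## Known limitations

* Equal-variance t and no moderated (limma-style) shrinkage: fine at
  n = 6 + 6 with permissive q, but underpowered designs may prefer
  moderation.
* The screen fits each tissue lipid marginally; joint or regularized
  models across correlated predictors are out of scope.
* The curation rules assume annotation identity is already correct;
  mis-annotation (e.g. sphingolipid over-annotation) is upstream of this
  pipeline.
* No batch/drift correction; inputs are assumed to come from one
  acquisition batch per tissue.
* The outlier rule is the simple >2 SD single-pass convention; it is not
  a robust-statistics treatment.
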