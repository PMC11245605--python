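# Methods

## Scope and data model

`srtkit` analyses manually scored exploration durations from spontaneous
recognition task (SRT) variants in which a "context" distinguishes two
otherwise similar exposure episodes. The atomic observation is one
duration (seconds) for one stimulus in one phase of one trial
(`ExplorationRecord`); a trial is two exposure phases followed by a test
phase holding one stimulus copied from each exposure. Durations are
pre-aggregated per phase — bout-level timestamps, video, and automated
detection are out of scope. Missing data are absent rows; a zero duration
is a real observation ("present, never explored") and is kept.

Validation treats duplicated (animal, session, trial, phase, side) entries
among to-be-recognised stimuli as hard errors and missing trials/phases as
warnings with per-animal completeness counts, because the analysis
tolerates unequal n: group tests simply run on fewer animals, and the
report logs every exclusion with its reason.

## D2 scoring

D2 = (t_target − t_other)/(t_target + t_other), undefined when the
denominator is zero. Undefined trials are excluded from per-animal means
rather than imputed as zero — zero would assert an observed indifference
that never happened. The per-animal-mean-first convention is used
throughout: D2 is computed per trial, averaged within animal, then across
animals. Configuration labelling derives from stimulus provenance: the
exposure-2 stimulus is context-novel when the test sits in the first
context and vice versa; the exposure-1 stimulus is always recency-novel.
The package enforces the resulting identity (d2_recency = ±d2_context with
sign set by trial type) by construction and checks it property-wise.

Outlier flagging uses quartile fences Q1 − k·IQR, Q3 + k·IQR with
k = 2.07 by default and quartiles by linear interpolation between order
statistics (the "type 7" rule — the common spreadsheet/`numpy` default;
the multiplier is configurable). Fences are computed per measure across
animals, and exclusion applies only to tests on that measure. Below four
values no fence is computed.

## The strategy circle

Each consecutive trial pair (one test per context) maps to
θ = atan2(y = test-in-1st-context D2, x = test-in-2nd-context D2) in
degrees on (−180, 180]. The argument convention deserves a note:
spreadsheet ATAN2 takes the horizontal argument first, the mathematical
convention takes the vertical first. Here the vertical component is
*always* the test-in-first D2 — the API takes named `(d2_first,
d2_second)` so the convention cannot be silently transposed — which places
equal novelty preference in both trial types at exactly +45°. 225°/315°
style inputs are accepted and normalised. The angle is undefined only for
the (0, 0) pair, which is dropped with a warning, as are pairs with a
missing trial.

Descriptives: θ̄ and R̄ from the unit-vector mean; the secondary direction
v is the circular median (the angle minimising mean absolute circular
deviation, ties resolved by the circular mean of tied minimisers — the
midpoint rule for even n). The circular median is a package convention for
v and is labelled as such in all outputs. R̄ = 0 (antipodal data) leaves
θ̄ undefined rather than arbitrary.

### Rao's spacing test

U = ½ Σ|Tᵢ − λ|, λ = 360/n, over the n sorted gaps including the
wrap-around. The null distribution is simulated: p is the proportion of
uniform-sample U values at the same n reaching the observed U, with the
(1 + r)/(1 + m) continuity correction, and the critical value is the
empirical (1 − α) null quantile; both are deterministic given the seed.
The default 100 000 replicates put the Monte-Carlo standard error of a
p ≈ 0.05 near 0.0007. Monte Carlo was chosen over published critical-value
tables so the test is exact-by-simulation at any n and α without
transcription; the test refuses n < 4, where spacing calibration is
unreliable. Rejection uses U > critical value at the requested α.

Classification takes the nearest of the four ideal directions by circular
distance. Exact axis angles (0°, ±90°, 180°) are equidistant from two
ideals and are reported as axis cases — preference expressed in a single
trial type — with no strategy label.

## Inferential layer

Implemented from the defining formulas (scipy supplies distributions
only):

* t tests: classical one-sample/paired, two-tailed; Cohen's d =
  (mean − μ₀)/sd. Zero-variance inputs return a `degenerate` result with
  no p rather than an exception or an infinite statistic.
* Cohen's d CI: noncentral-t inversion of t = d√n on the noncentrality
  parameter via root finding on the survival function; the method is
  recorded in the result metadata since several CI conventions circulate.
* RM-ANOVA (1–2 within factors): per-effect error terms
  (subject × effect), partial η² = SS_eff/(SS_eff + SS_err), and
  Greenhouse–Geisser ε from the eigenvalues of the orthonormally
  contrast-projected sample covariance, clamped to [1/(k−1), 1] (so a
  2-level factor has ε = 1 exactly). Both uncorrected and ε-corrected p
  values are always reported; no sphericity test is computed, matching the
  practice of applying the correction when normality/sphericity screening
  fails. Incomplete subjects are dropped listwise with a loud warning.
* Post-hocs: marginal-mean contrasts on the pooled ANOVA error term with
  its df; Fisher's LSD leaves p uncorrected, Bonferroni multiplies by the
  number of comparisons, capped at 1. With two levels the methods
  coincide.
* ICC(A,k): McGraw–Wong two-way random, absolute agreement, average
  measure, from the two-way mean squares; F = MSR/MSE with
  (n−1, (n−1)(k−1)) df; CI from the single-measure bounds stepped up by
  Spearman–Brown. Incomplete matrices are a domain error.
* Pearson r with Fisher-z CI.

The test suite cross-checks the ANOVA and ICC against `pingouin` and the t
tests against `scipy.stats` — the implementations themselves never call
those routines.

## Synthetic cohorts

The generator emulates the features the analysis is sensitive to:

* **Phase totals**: gamma(shape 4, scale 5) ≈ mean 20 s, positively
  skewed, matching the order of magnitude of object test phases; the
  conspecific design is typically run with a smaller scale (~2.5,
  mean 10 s per phase). These defaults are conveniences, not claims.
* **Preference split**: the strategy-predicted stimulus takes a fraction
  f ~ Beta(μκ, (1−μ)κ) of the total, μ = (1+δ)/2, so E[D2] = δ exactly
  and Var(D2) = (1−δ²)/(κ+1); κ = ∞ collapses to D2 ≡ δ. The default
  study condition is δ = 0.6, κ = 20 with 10 animals. Orientation
  respects trial type, so context and recency strategies predict opposite
  stimuli in test-in-first trials.
* **Context-specifier facilitation**: in the object design, exposure
  phases accompanied by the conspecific partner (always the phase whose
  context is *not* revisited at test, since the subject is tested alone)
  have object exploration multiplied by 1.33, the ratio of the published
  present/absent means; a context-specifier bout record marks the phase.
* **Opposite-sex salience**: the conspecific design's third session scales
  all durations by 4, the approximate published ratio of opposite- to
  same-sex exploration.
* **Raters**: score = truth + per-rater bias + cell noise, truncated at 0.

All draws flow from one `numpy` Generator in a fixed order (animal, trial,
phase), so generation is a pure function of (config, seed).

What the generator does **not** model: within-animal trial-to-trial
correlation (trials are exchangeable given the strategy), habituation
dynamics, dominance or scent-marking effects, side biases, and bout-level
timing. Passing recovery tests therefore show that the pipeline inverts
its own generative assumptions at realistic sizes and noise — not that
real cohorts satisfy those assumptions.

One known approximation: under δ = 0 the two D2 scores entering an angle
are iid symmetric Beta-derived variables, whose atan2 is only
approximately circular-uniform (exact uniformity needs a radially
symmetric joint density). At κ = 20 the split is near-Gaussian and the
empirical rejection rate of the Rao test on such cohorts is
indistinguishable from α at the simulation sizes used.

## Pipeline and problem sizes

`run_full_report` chains validation → scoring → summaries → configuration
t tests (with per-measure outlier exclusion) → D2 one-sample tests overall
and by trial type → side-bias check → exposure controls (summed exposure
exploration divided by the number of exposure phases when compared with
test totals — an equal-opportunity scaling assumption, flagged in output
notes) → circular analysis (paired designs) or session × conspecific
RM-ANOVAs (conspecific design). The JSON summary embeds the convention
notes (arctangent orientation, the definition of v, the exposure scaling)
and the exclusion log, and is byte-identical across reruns with the same
input and seed.

Simulation-based checks run at deliberately modest sizes chosen to keep
estimates stable: 2000 uniform cohorts (n = 20 angles each, 5000-replicate
null per test) for type-I calibration, and 200 cohorts per condition for
parameter recovery; at these sizes the binomial 95% bands quoted in the
tests are computed, not tuned.

## Known limitations

* The ingestion of externally deposited raw data is a stub: the deposit's
  schema is not published, so conversion to the bout-table CSV dialect is
  left to the user.
* Only Rao's spacing test is provided for circular uniformity; Rayleigh,
  Kuiper and Watson tests are out of scope, as is polar plotting beyond
  the histogram CSV.
* Mauchly's sphericity test, Bayesian analyses and mixed models are out of
  scope.
* The circular median convention for v and the noncentral-t convention for
  d CIs are documented choices where multiple definitions exist in the
  field.
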