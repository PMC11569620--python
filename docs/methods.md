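# Methods

## Problem and modeling unit

The package models moderate-to-severe depression symptoms in pregnancy from
four kinds of app self-reports. The modeling unit is an *observation
window*: a run of usable free-text entries concatenated together and paired
with the average of the EPDS screens that follow it within a 30- or 60-day
frame. The continuous averaged EPDS total (0–30) is the regression outcome;
the binary *flag* — averaged total ≥ 14, or any matched screen reporting
suicidal ideation — is the discrimination label. Fitting targets the
continuous outcome (Gaussian selective inference applies directly);
AUC is computed from the predicted continuous score against the flag. Both
readings of the outcome are exposed because a screen-positive threshold and
a continuous severity score answer different clinical questions.

## Window construction

Entries are lowercased, punctuation-stripped, filtered against a standard
English stopword list (extended with the removal examples "i", "be", "did"
and a small set of common single-response words such as "yes"), and Porter-
stemmed. An entry is *usable* if at least one token survives. "Close
temporal proximity" is operationalized as: consecutive usable entries form
one group while no EPDS response falls strictly between them and adjacent
gaps are at most the window length. A response at day `e` matches a group
with last entry day `t` iff `t < e ≤ t + L` and `e` is strictly before the
next entry day; day-level granularity means a same-day entry and response
cannot be ordered, so such a response is not credited to the older group.
Groups without matches and responses without preceding text are dropped.
The matcher is verified against a brute-force enumeration of these
conditions on random timelines.

Mood covariates (min/max/mean) aggregate reports in the look-back interval
`(t − L, t]`; windows with no mood report there carry the participant-level
mean with `mood_missing=True`. The canonical mood block stays 3 columns
(matching the printed block widths); an opt-in flag adds the missingness
indicator as a fourth column. Symptom covariates are four binary
indicators, one per severity class, set by any report in the same
interval.

## Language features

* **Sentiment** — each stem carries a positive and a negative score in
  [0, 1] from a valence lexicon; window scores are averages with
  out-of-lexicon tokens contributing (0, 0) and the denominator counting
  all tokens (a hit-only denominator is available). *Fluctuation* =
  average positive − average negative.
* **Themes** — 119 ordered categories of stems/prefix patterns, bundled as
  an open LIWC-style lexicon (function words, affect, social, cognitive,
  drives, health, lifestyle, plus the study-specific `covid19` and
  `pregnancy_terms`). Output is the proportion of tokens matching each
  category; a token may match several. Raw counts are additive under
  concatenation.
* **Topics** — latent Dirichlet allocation (k = 7 by default, seeded batch
  variational fit) trained on the *training-split* windows only; every
  window is scored with posterior topic proportions.
* **Embeddings** — mean vector of in-vocabulary tokens from a
  word2vec-format table (d = 300 by default), after an orthogonal rotation
  that maximizes the Kaiser row-normalized varimax criterion by sweeps of
  closed-form pairwise planar rotations (tol 1e-6 on the criterion
  increment, max 1000 sweeps, deterministic given input order). Each planar
  step is the exact optimum for its column pair, so the criterion ascends;
  right-multiplication by an orthogonal matrix preserves all pairwise
  geometry, which tests assert to 1e-8.

Default language width: 3 + 119 + 7 + 300 = 429; with history (9), mood
(3), and symptoms (4) the full candidate set is 445. The block composition
is configurable and logged; the split of the 429 among families is a
package convention.

## Penalized fit and selective inference

The lasso `(1/2n)‖y − β₀ − Xβ‖² + λ‖β‖₁` is solved by cyclic coordinate
descent on internally standardized columns (population SD; constant
columns get scale 1 and stay at zero). The solver alternates full sweeps
with cheap sweeps over the current active set and declares convergence
only when a full sweep moves no coordinate by more than `tol` (default
1e-9); every returned fit carries its KKT residual. λ is chosen on a
50-point log grid spanning [1e-3·λmax, λmax]: the path is fit from the
sparse end with warm starts at a moderate tolerance (validation MSE is
insensitive to the last decimals), ties go to the sparser penalty, and the
winner is refit tightly before inference.

Inference conditions on the selection event {active set, signs}, a
polyhedron `Ay ≤ b` in the response (both the active-set sign conditions
and the inactive-coordinate subgradient bounds). For each selected feature
the contrast η is the corresponding row of the active-set pseudo-inverse on
standardized columns; ηᵀy restricted to the polyhedron is Gaussian
truncated to [V⁻, V⁺]. The p-value is the truncated-Gaussian tail beyond
the observed statistic in the direction of the selected sign (exactly
uniform under the null, conditionally on selection), computed with
log-space complementary-normal ratios stable to |z| ≈ 10. The CI inverts
the pivot by bisection; the reported point estimate is the median-unbiased
value (pivot = 1/2), which by monotonicity always lies inside the
equal-tailed interval — the raw ηᵀy and the penalized coefficient are
reported alongside. Conditioning on the signs (rather than the union over
sign patterns) keeps the polyhedron simple at the cost of slight
conservatism. λ is treated as fixed at the validation choice; the
selection of λ itself is not conditioned on, and the calibration
guarantees hold exactly only for fixed λ (the test suite checks them in
that regime). The noise scale σ defaults to the residual SD of an
unpenalized refit on the active set (sample SD of y if nothing is
selected; an error directs the user to supply σ when the active set
saturates the sample).

## Evaluation

Splitting is by participant — 70% train / 15% validation / 15% test, floors
on the two small cells with the remainder to training — so no participant's
windows straddle partitions, and standardization, topic fitting, and λ
selection never touch test rows. AUC uses the Mann–Whitney rank form with
ties counted ½; its CI is a class-stratified bootstrap (B = 2000 in the
default config; smaller in simulation loops where the CI is not under
test). A model whose active set is empty predicts a constant and scores
AUC 0.5 by the tie convention. Descriptive summaries report the EPDS
severity bands (0–6 / 7–13 / 14–19 / 20–30, with band edges applied to the
averaged outcome), mood summaries, and the Pearson correlation between
window token count and outcome.

## Synthetic cohort generator

Each pregnancy has a latent trait `z ~ Normal(0, trait_sd²)` shifted by
history of depression/anxiety (+0.8 SD), age < 25 (+0.4), and low income
(+0.4) — signed so younger age and lower income raise risk. The trait is
constant within pregnancy by default (windows are repeated measures of a
slowly varying state); an AR(1) day-level component can be switched on.
Streams:

* mood: `clip(round(3.9 − beta_mood·z + Normal(0, 0.8)), 1, 5)`;
* EPDS: `clip(round(7 + 5z + Normal(0, 3)), 0, 30)`, suicidal ideation
  `Bernoulli(logit⁻¹(−5.5 + 1.5z))` (≈1% positive at the defaults);
* text: token pools are derived by scoring a fixed generator vocabulary
  against the bundled lexicons (positive/negative valence, mental-health,
  finances, covid, pregnancy, neutral); pool weights tilt exponentially
  with `z` scaled by `text_valence_link` / `theme_link`, giving strict
  monotonicity for positive links and exact independence at zero. Entry
  lengths are lognormal with mean 19 words and a heavy right tail
  (CV ≈ 1.5).

The intercepts 3.9 (mood) and 7 (EPDS slope 5) are simulator calibration
constants chosen so null-configuration marginals resemble a realistic
prenatal cohort (mean mood ≈ 3.9; most windows in the 0–13 EPDS range);
they are not claims about any particular population. Reporting gaps are
independent thinned Bernoulli days per stream at the configured weekly
rates (defaults: 0.25 text entries, 0.17 mood reports, 0.10 symptom
report-days per week over 238 days, EPDS completions Poisson(0.85) per
trimester with at least one forced per participant) — real reporting is
bursty and state-dependent, which this does not emulate. Race/ethnicity
and parity are generated with realistic margins but zero structural
effect. Because text is a bag-of-pools draw, grammar, discourse structure,
and topic burstiness are absent: passing tests show the pipeline recovers
the statistical structure it assumes, not that it would reach any
particular accuracy on real clinical text.

Identical config and seed give byte-identical serialized cohorts.

The bundled embedding fixture (`synthetic_embeddings_8d.txt`) and the
default 300-dimensional table are synthetic: each word pool gets a Gaussian
anchor direction and words scatter around their pool anchor, so words
sharing a pool cluster as distributionally trained vectors would. The
table is deterministic given its own seed and is treated like a pretrained
artifact — fixed across pipeline runs, not resampled per seed.

## Numerical choices and degenerate inputs

* Truncated-Gaussian tails: mirrored log-space ratios with `expm1`;
  arguments outside the truncation interval clamp to {0, 1} with a
  warning; `a ≥ b` is an error.
* Degenerate truncation (V⁻ ≥ V⁺) raises with diagnostics rather than
  returning a silent answer; a loosely converged lasso is the usual cause.
* Empty token lists give zero sentiment/theme vectors (logged); all-OOV
  windows give zero embeddings; LDA profiles of empty documents fall back
  to the prior (uniform at the symmetric default).
* `window_days` outside {30, 60} is accepted with a warning.
* Exact validation-MSE ties on the λ grid resolve to the sparser penalty.

## Simulation sizes

The test suite runs the calibration checks at 2000 replicates (p-value
uniformity) and 1000 replicates (CI coverage) on 50×10 designs with fixed
λ = 0.25 and known σ = 1, and the end-to-end checks on cohorts of 1000
participants: 20 signal seeds (10 with the full 15-model grid, 10 with the
full model only) and 20 null seeds. `scripts/acceptance.py` uses the same
designs with 15 signal seeds (5 with the full grid) and 10 null seeds.
These sizes give Monte-Carlo error comfortably inside the asserted margins
(e.g. the null-AUC check's tolerance of ±0.05 against a per-seed SD of
about 0.04).

## Known limitations

* Selective inference is exact for fixed λ and known σ; plugging in the
  refit σ̂ and a validation-chosen λ is the pragmatic standard but voids
  exactness in small samples.
* The 60-day frame is supported structurally and tested for matching
  logic, but all default analyses use 30 days.
* Theme and valence lexicons are compact open stand-ins with the same
  format and granularity as the proprietary tools they replace, not
  re-creations of their contents.
* The AUC unit defaults to the window; participant-level aggregation is a
  flag (`participant_level_auc`) since repeated windows per participant are
  not independent.
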