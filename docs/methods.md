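# Methods

## The two fit statistics

Both measures quantify how similar one person's *pattern* over a fixed feature
set is to the normative pattern of a cultural group, separately for each of
four situation types (valence × interpersonal motive: `pos_rel`, `pos_auto`,
`neg_rel`, `neg_auto`).

**Emotional fit.** The feature vector is a participant's Likert 1–5 intensity
ratings over the active emotion terms (default 15: the four three-term
subscales minus `frustrated`, plus `worried`, `nervous`, `fearful`, `sad`;
`good`/`bad` are valence anchors only, and `calm`/`surprised` are excluded by
default as cross-culturally non-equivalent).  The statistic is the Pearson
correlation between the participant's vector and the element-wise mean vector
of a target culture's members for the same situation type, Fisher-transformed:
z = arctanh(r).

**Language fit.** The feature vector is the percentage of a document's tokens
falling into each category of a LIWC2007-dialect lexicon (either every
category or only the psychological-processes subtree), computed from the
participant's description of the situation.  The correlation/arctanh step is
identical.

**Leave-one-out references.** When a person is scored against their *own*
culture, their profile is removed from the reference mean.  Including it
shares a component between the two vectors and biases r upward; the test suite
demonstrates the bias directly on small groups.  Against the other culture the
full group mean is used.  A reference needs at least `min_group = 3` members
(leave-one-out then still averages ≥ 2); smaller cells yield missing scores
with a warning rather than silently shrinking.

**Numerical choices.** r is clipped to ±(1 − ε), ε = 1e-6 (configurable in
(0, 0.01]), before arctanh so degenerate perfect correlations stay finite.  A
zero-variance profile (a participant who rated every term identically, or a
degenerate category vector) has no defined correlation: the score is missing,
never 0 — an undefined correlation is not evidence of zero fit.  Missing
situations propagate as missing scores; no imputation anywhere.  Profile
correlations are invariant to adding a constant to, or positively rescaling,
an entire profile, which is why raw category percentages are correlated
without re-standardisation.

**Composites.** Situation-level scores are the primary quantity; per-person
composites (mean z across situation types) are opt-in and always shipped with
the Cronbach alpha of the four situation columns, so callers can reject
composites when situation-level fit is inconsistent.  Emotional fit typically
has much lower cross-situation reliability than language fit — in the
synthetic generator this arises because emotion-term means are redrawn per
situation while token-emission distributions are shared across situations.

## Word counting

A token is a maximal run of letters/digits with internal apostrophes,
lowercased; punctuation separates tokens; the token count is the denominator
of every score.  An entry is either a literal word or a wildcard stem
(`happ*`) matching any token it prefixes.  A token increments a category at
most once regardless of how many of that category's entries fire.  Hyphenated
compounds split into separate tokens (the rule is fixed and documented rather
than configurable).  Numerals count toward the denominator and match only if
listed.  Empty documents yield missing profiles, not zero profiles.  The
`.dic` dialect is: a `%`-delimited header of `id<TAB>name[<TAB>parent]`
lines, then `word<TAB>id [id ...]` entries; the optional third header field
is this package's extension for expressing sub-category trees, which the
LIWC2007 format leaves implicit.  Parent counts are **not** auto-propagated:
an entry lists every id it should increment (the multi-id convention of
LIWC2007-style dictionaries).

## Screening

**Valence prompt check.** Criterion A: consensus coder label vs the prompted
valence (match / neutral when `unclear` / contradiction).  Criterion B: sign
of `good − bad` (neutral on ties).  Any contradiction excludes the situation
report; otherwise one match keeps it; if both are neutral, the strict sign of
`happy − angry` must match the prompted valence and a tie excludes (the rule
chain ends there).  The function is total and deterministic; the test suite
checks all 27 cells of the (A × B × tiebreak) table against a hand-written
enumeration.  Coder adjudication itself is out of scope: consensus labels are
an input.

**Manipulation check.** Per culture × situation, the prompt-matching
three-term subscale is compared with each of the other three subscales by
paired t tests (two-sided, Bonferroni ×3).  `maximal` is True when the
matching subscale is strictly highest with all corrected p < α, False when
another subscale significantly dominates, and indeterminate (NA) otherwise.

**SCA equivalence screen.** The SCA-P variant: each cultural block is
column-standardised within block (population sd), blocks are stacked, and
loadings are the leading principal axes of the stacked matrix — common across
blocks, which is what makes cross-block comparison of term behaviour
meaningful.  Per-block term-component correlations are computed from the
common component scores within each block.  A term is flagged *cross-loading*
when its strongest per-block loading (≥ a salience threshold, default 0.30 —
the conventional cut, exposed in config) sits on different components in
different blocks.  Theory-driven exclusions require an explicit
expected-component map; the package does not guess.  No rotation is applied
and the component count is user-chosen from the reported cumulative variance
curve; an automatic scree rule would hide a judgment call that should be
visible.

## Inference layer

Two-sided tests and 95% intervals throughout; listwise deletion within each
analysis cell.  Independent comparisons use pooled-variance Student t by
default (df = n₁+n₂−2, matching the conventional reporting for these designs),
Welch behind a flag.  Correlation p values use the exact t transform; CIs use
Fisher z ± z₀.₉₇₅/√(n−3).  Cronbach's alpha is the standard
k/(k−1)·(1 − Σ item variances / variance of totals) with n−1 variances.

**Comparing two dependent, non-overlapping correlations** — corr(a,b) vs
corr(c,d) on the same participants with four distinct variables — uses Zou's
CI: each correlation's Fisher-z interval combined via the asymptotic
correlation of the two sample correlations, computed from the six pairwise
correlations (Pearson–Filon covariance over the product of the variance
terms).  The overlapping-variable case is a different procedure and is
explicitly rejected.  The implementation is cross-checked against a
nonparametric bootstrap and a null-coverage simulation rather than asserted.

**Minimal detectable correlation.** `detectable_r(n, α, power)` root-finds the
power function of the two-sided test of ρ = 0.  Power is computed under the
noncentral-t representation (noncentrality r·√n/√(1−r²)) — the fixed-score
power model used by standard power software, which at n = 100, α = .05,
power = .80 gives 0.272 (reported as 0.27 at two decimals).  The fully exact
bivariate-normal sample-correlation distribution gives a slightly larger root
(0.276); the noncentral-t representation was chosen deliberately as the model
conventional sensitivity analyses report.  The unrounded root is always
returned alongside the 2-dp report.

## Synthetic data generator

The generator emulates the data structure the measures assume, with defaults
as the study conditions: 100 participants per cultural group, 4 situations ×
20 terms on Likert 1–5, rating noise sd 0.7, valence boost 1.0, a 64-category
lexicon with a 25-category psychological-processes subtree, 500 tokens per
document with 30% filler (≈ 70% dictionary coverage).

* **Emotion means.** Per situation, term baselines are drawn uniformly inside
  a box that keeps every constructed mean in [1.5, 4.5]; the prompt-matching
  subscale is elevated by the valence boost (same-valence subscales and
  valence-congruent extra terms by half of it); `good`/`bad` are set to a
  strong valence-consistent anchor so generated data pass the package's own
  valence screen (keep rate ≥ 99% at boost ≥ 1).  Heritage and host means sit
  at ± d/2 along a random unit direction over the non-anchor terms, so their
  Euclidean separation is exactly `d_emotion`.  Infeasible combinations
  (d + boost > 3, which cannot fit in the box) are rejected.
* **Likert discretisation.** Participant vector = group mean + iid N(0, σ),
  rounded then clamped to {1..5}.  Rounding preserves means away from the
  bounds but compresses them near 1 and 5 — a known, documented distortion.
* **Migrants.** The migrant group's generating mean is the exact convex
  combination (1−λ)·heritage + λ·host, in both the rating means and the
  token-emission log-weights.  Mean interpolation (rather than individual
  trajectories) is the minimal structure that makes the expected fit
  orderings recoverable, since fit operates against group references.
* **Language.** Per-culture token-emission log-weights diverge by
  `d_language` along a random unit direction; a participant adds individual
  Gaussian noise (sd 0.3) to the log-weights before softmax; documents mix
  multinomial category tokens with filler tokens drawn from a disjoint
  alphabet so filler can never match an entry.  Emission distributions are
  shared across situations (making language fit more reliable across
  situations than emotional fit, as observed empirically for real data).
* **Seeding.** One master seed is expanded by `SeedSequence.spawn` into
  independent substreams (ratings, lexicon, corpus); identical config + seed
  reproduces every artifact bit-identically.

What passing tests on this generator show: the pipeline recovers orderings
and interpolations that are true of the generating process, with correctly
calibrated error rates.  What they cannot show: anything about real
interview speech (no syntax, no translation noise, no topic structure, no
demographic covariates), or about the true effect sizes of any particular
pair of cultures — divergence defaults are chosen for testability and are
labelled as such.

## Problem sizes used in the reproduction script

`scripts/acceptance.py` regenerates everything from one seed: the
sensitivity-analysis root at n = 100; leave-one-out exactness over 100 random
datasets (2 × 20 participants, 4 situations, 15 terms); word-counter
exactness over 200 random lexicon/document pairs; parameter recovery over
100 replicates at d = 1.0, σ = 0.7, n = 50/group for both measures;
acculturation monotonicity over λ ∈ {0, .25, .5, .75, 1} with 60 replicates
per point; type-I error of the between-culture test over 500 null replicates;
dependent-CI coverage over 500 null replicates at n = 80; the 27-cell
screening truth table plus the generator keep rate; and SCA oracle agreement
over 50 random two-block instances.  These sizes were chosen so the whole
script reruns in a few minutes on one CPU while keeping Monte-Carlo error
well inside the acceptance bands.

## Known limitations

* SCA-P is the only SCA variant; block-weighting schemes and rotations are
  not implemented.
* The dependent-correlation comparison covers only the non-overlapping case.
* Wildcard stems are prefix-only; multi-word phrases and language-specific
  morphology are out of scope (the measures are designed to run on documents
  already normalised to one language).
* Composite fit uses an unweighted mean over available situations; no
  shrinkage or reliability weighting.
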