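# Methods

This note documents the statistical machinery, the default parameters and
why they have the values they do, what the synthetic-data generator does
and does not emulate, and the design choices made where more than one
defensible option existed.

## Form variables

Every word is described by 60 numeric surface-form variables computed from
its ARPAbet transcription and spelling:

* whole-word: length in letters, in phonemes, and in syllables (syllable
  count = vowel-phoneme count; no syllabification algorithm is used — the
  vowel-count proxy is standard and exact for the generator's templates);
* counts over the word: vowel height (high/mid/low) and frontness
  (front/central/back); consonant place (bilabial, labiodental,
  linguodental, alveolar, palatal, velar, glottal) and manner (stop,
  fricative, affricate, nasal, liquid, glide); voiced and voiceless
  phonemes;
* first- and final-phoneme indicators: is-vowel, one per place, one per
  manner, voiced, voiceless (16 each);
* primary-stress position: initial, final, medial, multiple.

The phoneme → category map ships as `data/arpabet_features.csv` and is
overridable. Diphthongs are classified by their nucleus; AO sits with the
low vowels (the vowel of *tall*). Monosyllables are coded
`stress_initial = 1`: treating the lone syllable as initial keeps the
initial- and final-stress indicators from being perfectly collinear in
monosyllable-heavy samples, so the final-stress coefficient measures
*multisyllabic* final stress. A multisyllabic word with no primary-stress
digit carries 0 on all four indicators (the generator never produces one;
CMUdict marks primary stress on virtually every entry). An external
per-word stress pattern can override the dictionary digits.

## Exclusion recipe

Norm entries are filtered in a fixed order: flagged homograph alternates
first, then words whose rating SD exceeds 1.5 (strictly — a word at
exactly 1.5 is retained), then proper names by part-of-speech label. The
homograph flag must come with the norms; homography is not inferable from
spelling alone. Counts per stage are reported and logged; the filter is
idempotent.

## Pruning and the intercept

The 60 variables are exactly collinear by construction: heights and
frontness each sum to the syllable count, places and manners to the
consonant count, voicing to the phoneme count, and each edge-indicator
group sums to one. `find_linear_combos` removes, scanning left to right in
the canonical column order, any column within relative tolerance 1e-8 of
the span of the previously retained ones (two-pass Gram–Schmidt; the
default tolerance detects integer-arithmetic identities while tolerating
float noise).

By default the screen considers only the columns themselves. The pipeline,
however, calls it with `assume_intercept=True`, seeding the basis with the
constant vector: the unit-sum indicator groups place the constant inside
the span of the 60 columns, so a design that is full rank on its own
becomes singular the moment an intercept is added, and the subsequent
regression requires affine pruning. On the generator's lexicon this
removes 13 columns (5 count identities, 3 per edge group, 2 stress), the
last-ordered member of each dependency.

## Best-subset selection under Mallow's Cp

Convention: `Cp = RSS_p/σ̂²_full + 2p − n`, intercept always included and
counted in `p`, with `σ̂²_full` from the model containing every pruned-in
column. The full model then satisfies `Cp = p` identically, which the
tests assert. Ties go to the smaller subset, then to lexicographically
earlier column sets, so selection is deterministic.

The search is exact. Subsets are explored depth-first over
include/exclude decisions on the centered Gram system; residual sums of
squares come from Cholesky solves, so node cost is independent of sample
size. A node with forced-in set F and undecided candidates C (union U) is
fathomed using `RSS(U)` plus a decision-cost bound: including a candidate
costs 2 penalty units, excluding candidate c raises RSS by at least its
drop-one increment δ_c = β_c²/(G_U⁻¹)_cc (dropping several raises RSS by
at least the largest single increment), so
`min_j [2(j−1) + δ_(j)]` over the descending-sorted increments bounds any
completion's extra cost from below. The incumbent is seeded by
forward/backward stepwise passes; branching prefers the candidate whose
exclusion hurts most, and the union-model inverse is maintained by Schur
downdates. On the full-scale pruned problem (≈ 2,750 × 47) selection runs
in seconds to tens of seconds; plain enumeration (available as
`method="exhaustive"`, capped at 15 columns) serves as a readable
reference path and as the independent oracle in the tests.

No significance filter is applied after Cp minimization: variables whose
partial chi-square sits near the inclusion threshold (≈ 2) may enter with
|t| < 2, which is the criterion behaving as designed.

Typicality is the fitted value of the selected model, z-transformed with
the *fitting set's* mean and SD; both constants are serialized with the
model so new words score on the same scale, bit-for-bit reproducibly.

## Group comparisons

Typicality across lexical categories is compared with Bartlett's test
(delegated to scipy), then Welch's heteroskedastic one-way ANOVA — F with
Satterthwaite denominator df — because rating-derived scores routinely
violate homogeneity of variance. Effect size is ω² ≈ df₁(F−1)/(df₁(F−1)+N)
applied to the Welch F, the conventional approximation for
heteroskedastic designs (slightly negative values for F < 1 are possible
and reported as computed). Pairwise contrasts use Games–Howell:
Welch-type SE √(s²ᵢ/nᵢ + s²ⱼ/nⱼ) with Satterthwaite df, q = |diff|·√2/SE,
and p from the studentized-range distribution with k groups, taken from
scipy's implementation rather than hand-rolled quadrature. With two
groups this reduces exactly to the Welch t-test; with equal variances and
group sizes it tracks Tukey's HSD closely (the agreement degrades only as
a *ratio* in the far tail, where both p values are tiny).

## Hierarchical regressions with robust errors

Outcomes are modelled by cumulative OLS steps — controls, then the size
rating, then typicality — so typicality is only credited with variance
nothing else can claim. Predictors are mean-centred by default (changes
only the intercept, asserted exactly in tests); listwise deletion is
applied with a logged count. Coefficient uncertainty uses
heteroskedasticity-consistent sandwich covariances
`(X'X)⁻¹ X' diag(w e²) X (X'X)⁻¹` with w = 1 (HC0), n/(n−p) (HC1,
computed literally as scaled HC0 so the identity is exact), 1/(1−hᵢ)
(HC2, the default — the convention of the robust-regression tooling this
design follows) or 1/(1−hᵢ)² (HC3). HC2/HC3 refuse leverage-one
observations by name.

ΔR² is reported on unadjusted R² (adjusted R² may decrease and is
tabulated alongside). The significance of each increment is a robust Wald
chi-square on the newly added block — the natural companion to sandwich
fitting, and a documented choice: it is *not* the classical hierarchical
F on ΔR², and the two can differ in small samples. Calibration: at
megastudy scale (≈ 2,000 items) the null rejection rate of the increment
test is 5% ± 1% (asserted over 2,000 seeded replicates); at a few hundred
items HC-based Wald tests over-reject mildly (≈ 6% at n = 500), the
well-known finite-sample behaviour of sandwich estimators, so inferences
from small item sets should prefer HC3 or larger samples.

## The synthetic-data generator

The generator's job is to produce inputs whose ground truth is known, in
exactly the file formats the pipeline reads.

* **Word forms**: (onset)(vowel)(coda) syllable templates over the full
  ARPAbet inventory; syllable counts follow {1: .33, 2: .42, 3: .18,
  4: .06, 5: .01} (the observed mono-through-pentasyllabic mix of a large
  size-norm lexicon); onset probability .85, coda .60; one uniformly
  placed primary stress, occasional secondary stress (which must never
  affect coding — asserted). Spelling is derived from the phonemes. This
  spans every phonetic category (a coverage test asserts it) but is *not*
  English phonotactics: cluster constraints, positional frequencies and
  morphology are absent. Passing recovery tests therefore demonstrates
  that the estimators work, not that real lexicons behave this way.
* **Ratings**: true size = intercept 3.017 plus the 18 planted slopes
  (e.g. +0.361 per syllable, −0.113 per high vowel) on the generated
  features, plus word-level noise calibrated so the refit adjusted R²
  lands near the observed ≈ .20 for such models; then 30 raters each add
  N(0, 1.2) noise, responses are rounded to the 1–7 scale and clamped,
  and the across-rater mean/SD become the norms. The calibration accounts
  for the rater-noise and rounding variance passed through the mean of 30
  raters. With true means inside [2.5, 5.5], clamping bias on the rating
  mean stays below 0.1 Likert units (Monte-Carlo checked).
* **Covariates**: independent normals matched to published
  megastudy-scale means/SDs (e.g. Zipf frequency 3.94 ± 0.73, AoA
  4.10 ± 1.19); an optional correlation matrix adds realistic
  collinearity when a test needs it.
* **Outcomes**: latent outcome = scaled standardized controls + planted
  orthogonalized size and typicality components + Gaussian noise. Because
  the size and typicality components are residualized against everything
  entered before them, their planted unique-variance shares (ΔR²) are
  exact by construction: defaults .001 (size) and .005 (typicality) for
  zRT with facilitatory (negative) signs, zero effects for accuracy,
  .004/.001 inhibitory for corrected hit probability — small increments
  of the size such analyses report. zRT is standardized across items;
  accuracy and corrected hits pass through clamped affine maps into
  [0, 1] and [−1, 1].
* **Seeding**: one global seed fans out to independent per-stage child
  streams (lexicon, ratings, covariates, outcomes), so a stage can be
  regenerated alone and every artifact is byte-identical under a fixed
  seed.

### What recovery looks like

At 2,900 generated words, the pruned OLS refit brackets each planted
nonzero coefficient within 3 classical standard errors in ≥ 95% of seeds,
and the planted step-3 typicality increment of .005 is recovered with
median well inside ±40%. Best-subset selection reliably keeps the
*strongly* planted variables (full-fit |t| ≥ 3.5); variables planted at
|t| < 2 sit at the Cp inclusion threshold and enter only in a fraction of
replicates — the same borderline behaviour such models show on real
norms, and the reason the containment property is asserted only for the
strong set.

## Problem sizes and numerical choices

Test and verification sizes are chosen to exercise each claim at the
scale it is about: oracle equivalence on 200 random problems of ≤ 12
features; Welch type-I calibration over 10,000 five-group draws of 30;
increment-test calibration over 2,000 replicates at 2,000 items;
end-to-end recovery over 100 seeds at 2,900 words; selection containment
over 3 full-scale seeds (exact search is seconds-per-run there).
Numerical tie-breaks (smaller subset, then column order), the 1e-8
pruning tolerance, the 1e-9 Cp tie tolerance, and degenerate-input errors
(no-vowel words, zero-variance groups, perfect full-model fit, leverage-1
observations) are all exercised in the unit tests.

## Known limitations

* The 60-variable inventory is one defensible reconstruction of "surface
  form"; other codings (frontness dropped, different diphthong classes)
  would change the pruned set and possibly the selected model. The
  decision table is data, not code, precisely so this can be varied.
* ω² for Welch designs is an approximation; no exact small-sample effect
  size is attempted.
* The robust Wald increment test is not the classical ΔF; at small n it
  over-rejects mildly (see above).
* The generator's phonotactics are deliberately naive, its covariates
  uncorrelated by default, and its outcome model linear with exact
  orthogonalized effects — none of which real megastudies guarantee.
* Grapheme-to-phoneme conversion, syllabification, IPA input, mixed-effects
  or trial-level modelling are out of scope.
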