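# Methods

## Instrument coding and scores

MOS-SS items 3–12 are coded "All of the time" = 1 … "None of the time" =
5.  Items 4 and 12 describe positive experiences, so their raw ranks are
already worst-high; the remaining scored items are negative experiences
and are reversed (`6 − r`) before summation.  This is the only coding
direction consistent with SQ spanning 6 (best) to 30 (worst) and DTS 4
to 20.  Items 1 (sleep latency) and 2 (hours slept) are carried in the
data model but never enter SQ or DTS.

SLP9 is implemented as the standard MOS Sleep Problems Index II (items
1, 3, 4, 5, 6, 7, 8, 9, 12), each item linearly rescaled to 0–100 with
the problem direction up and averaged.  The exact constituent list is
configurable (`score_slp9(..., items=...)`) because conventions differ
between six- and nine-item indices in the literature.

Missing data: the default policy is strict — any missing constituent
makes the score undefined — matching the exclusion of incomplete records
from the Rasch stage.  A lenient half-rule (prorate the mean of
available oriented items when at least half are present) is provided for
clinical use; prorated scores need not be integers.

Cut-offs: `sq >= 14` and `dts >= 9` flag clinically relevant disruption;
both are parameters, not constants.

## Polychoric correlation

Two-step estimation: per-item thresholds are fixed at inverse-normal
quantiles of the marginal category proportions, then each pair's latent
correlation maximises the multinomial likelihood of the contingency
table over the single parameter ρ (bounded Brent search on
(−0.999, 0.999), `xatol = 1e−6`).  Two-step is standard, much faster
than full-information ML, and adequate at the n ≈ 90–300 scale this
package targets.  Bivariate-normal rectangle probabilities are evaluated
by 48-node Gauss–Legendre quadrature of the conditional-normal CDF,
which is accurate to ~1e−10 (cross-checked against
`scipy.stats.multivariate_normal` in the test suite) and fast enough to
assemble full 10-item matrices inside 100-replicate simulation loops.

Pairwise-complete deletion builds the matrix; items with a single
observed category are excluded with a warning.  If assembly produces an
indefinite matrix it is repaired by clipping negative eigenvalues at
zero and renormalising the diagonal; the repair magnitude is recorded so
tests can assert it is ~0 on clean data.

## Factor analysis

Retention uses the eigenvalue > 2 rule (the rule under which the SQ/DTS
structure was originally identified) rather than the conventional
Kaiser > 1; the threshold is configurable.  Extraction is principal-axis
factoring with communalities iterated from squared multiple correlations
(tol 1e−6, max 100 iterations; Heywood communalities capped at 0.998 and
logged).  Rotation defaults to varimax — the reported cross-loading
pattern is consistent with an orthogonal solution, and orthogonality
matches the finding that SQ and DTS changes are uncorrelated — with
promax (κ = 4) as an oblique option; rotation itself is delegated to
`statsmodels.multivariate.factor_rotation`.  Items are assigned to their
max-|loading| factor, ties broken toward the lower factor index with a
warning.  Analysis runs on problem-oriented codes (negative items
reversed first) so within-factor loadings come out positive; orientation
changes loading signs only, never retention or assignment.

## Partial credit model

The category probability for score x in 0..m is
`exp(−Σ_{k≤x} τ_k + x(β − δ))` over the sum of the same numerators for
x′ = 0..m, with the empty threshold sum for x = 0, computed via
log-sum-exp so extreme locations cannot overflow.  With m = 1 this is
the dichotomous Rasch model.

Estimation is joint maximum likelihood: alternating Newton blocks on
each item's category parameters (internally the free log-numerators
ζ₁..ζ_m) and on person locations, the latter solved per raw-score group
because the total raw score is the sufficient statistic for β under
complete data — this also guarantees equal-raw-score persons get equal
estimates.  Both blocks use step-halving, so the joint log-likelihood is
non-decreasing across iterations (asserted in tests).  Convergence:
largest parameter change < 1e−5, cap 200 sweeps.  Identification: mean
item location zero, per-item thresholds mean-centred.  Person updates
are boxed at ±12 logits.

Exclusions before fitting, reported by reason: persons with incomplete
response vectors (strict policy), and persons at the score floor or
ceiling, whose ML locations are infinite.  Item categories never
observed in the estimation sample are collapsed onto the adjacent
category (recode to consecutive observed values, logged per item), and
the item's m is reduced accordingly.

JML item estimates are biased away from zero with few items; the classic
multiplicative correction K/(K−1) (K = number of items) is inverted
here, shrinking item locations and thresholds by (K−1)/K, after which
person locations are re-solved once against the corrected items.  At
n = 500 persons and 6 five-category items this yields item-location MAE
≈ 0.05 logits (vs ≈ 0.15 uncorrected).

"Dislocation" is read as threshold disorder: an item is flagged when its
τ sequence is not strictly increasing, meaning some response category is
never the most probable one anywhere on the continuum.
`targeting_spread` — the SD of all absolute threshold locations δ + τ —
operationalises how broadly an instrument's category boundaries cover
the severity axis, enabling the SQ-vs-DTS spread comparison.  Residual
fit statistics (infit/outfit) are deliberately out of scope.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not any real
dataset:

* Latent traits (θ_SQ, θ_DTS) per patient from a bivariate normal with
  `trait_corr = 0` (the observed independence of the two scores) and
  `trait_sd = 1.4` logits.  The SD sets the within-factor polychoric
  correlations; 1.4 puts rotated loadings in the 0.65–0.85 band and the
  two-factor explained variance near two thirds, the magnitude reported
  for this instrument.
* MOS items respond through the partial credit model on their factor's
  trait (membership {3,4,5,7,8,12} → SQ, {6,9,10,11} → DTS; items 1–2
  ride on θ_SQ but are unscored).  Default item locations sit at
  +0.5..+1.4 logits so most mass falls in the low-disruption categories,
  the marginal skew typical of these cohorts.  All item parameters are
  config, not constants.
* Sex: 37% women; women get `sex_effect_dts = −1.6` logits on θ_DTS
  only.  The size was chosen so a two-group t-test on DTS at n = 75
  rejects in well over 80% of cohorts while SQ is untouched — the
  qualitative pattern the scores are meant to show — and with the effect
  set to 0 the rejection rate falls to ≈ α.
* Anamnesis poor-sleep label: θ_SQ plus N(0, 1.3) noise thresholded at
  the 75th percentile of the noisy latent, giving ≈ 23–26% poor
  sleepers, the reported marginal rate (the exact confusion cells of any
  real cohort are not targeted).
* EORTC items 10 and 18 load on θ_DTS, item 11 on θ_SQ, via noisy
  thresholding at quantiles matched to reported category marginals.
  Sleep-medication use (none / as-needed / daily, marginals ≈
  76/12/12%) derives from θ_SQ the same way.
* Biomarkers (melatonin/creatinine, cortisol/creatinine, CRP, IL-2,
  Bmal1, Per2) are log-normal and trait-independent; their only role is
  powering null-screen tests.
* Follow-up traits = baseline + drift + N(0, 1): `followup_shift_sq = 0`
  and `followup_shift_dts = −0.45` (a slight improvement in daytime
  sleepiness, the direction of the observed significant signed-rank
  change), with independent noise making per-patient ΔSQ and ΔDTS
  uncorrelated by construction.
* Attrition: of 90 enrolled, 75 questionnaire-complete and 54
  biomarker-complete by default (configurable; `GeneratorConfig.scaled`
  keeps the fractions at other cohort sizes).  Incomplete patients lose
  a random subset of items, which is what feeds the Rasch exclusion
  accounting.

What the generator does **not** emulate: secondary cross-loadings
(items load on exactly one trait), item-specific discrimination (the
PCM fixes it at 1), the coupling of tumour type with sex and treatment
intent, medication effects on sleep, or real category-frequency tables
(unpublished).  Passing recovery tests therefore show the pipeline is
correct under its own assumptions, not that real MOS-SS data satisfy
them.

## Statistics conventions

* Correlations: Pearson for continuous pairs, Spearman (average-tie
  ranks) for ordinal ones; both report r, r², n and a two-sided p.
* Signed-rank change test: centred statistic
  S = Σ(positive ranks) − n(n+1)/4 (zero differences dropped, average
  ties), so S = 0 under exact symmetry and flips sign when the visits
  are swapped.  Exact two-sided p by convolution over the tie-adjusted
  doubled-rank distribution for n ≤ 25, otherwise the Student-t
  approximation t = S·√((n−1)/(nV − S²)) with V = Σrank²/4 on n − 1 df.
* Group comparisons: two-sided pooled-variance Student's t (Welch
  optional), group means with 95% confidence intervals.
* Cut-off tables: 2×2 of (score ≥ cutoff) × label with sensitivity and
  specificity.
* Biomarker screen: Pearson on log-transformed values against each score
  per timepoint; raw p-values by default (the screen is a per-test null
  check), Benjamini–Hochberg available but off.

## Problem sizes

The test suite and acceptance script use: exhaustive enumeration of all
5⁶ + 5⁴ response vectors; 1000 random draws for probability
normalisation; 20 replicates of n = 500 × 6 items for JML recovery; 100
cohorts of n = 300 for factor-structure recovery; 100 default cohorts
(n = 90) for the comparator-scale and change statistics; 1000 cohorts
for the biomarker type-I rate; 40 cohorts of n = 75 for the sex-effect
power check.  These sizes give Monte-Carlo error comfortably inside the
asserted tolerances while keeping a full run to a few minutes.

## Known limitations

* JML with few items relies on the (K−1)/K correction; conditional or
  marginal ML would avoid the incidental-parameter bias at the cost of
  closed-form sufficiency diagnostics.  Bit-level agreement with
  proprietary Rasch software is not attempted.
* The polychoric stage assumes latent bivariate normality; heavy-tailed
  or skewed latent responses will bias ρ.
* The lenient half-rule scores are prorated sums, not calibrated
  imputations.
* Single-category and structural-zero handling is heuristic (exclusion
  and adjacent collapsing) and logged rather than modelled.
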