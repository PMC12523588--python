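# Methods

This note documents the models, conventions and design choices behind
`mcdaval`, in the order the pipeline runs.

## Criterion weighting (AHP)

Judgment matrices are positive reciprocal matrices on the Saaty scale
{1/9, …, 1/2, 1, 2, …, 9}.  Inputs may supply only the upper triangle (the
lower is filled with exact reciprocals); full matrices are validated for
reciprocity to a 1e-6 relative tolerance, and entries outside [1/9, 9] are
rejected unless a permissive flag admits them with a warning.

**Priority extraction.**  Weights are the normalized principal right
eigenvector, computed by power iteration (L1 tolerance 1e-10, at most
10,000 iterations; Perron–Frobenius guarantees convergence for positive
matrices).  The row-geometric-mean method is provided as a cross-check; the
two coincide on perfectly consistent matrices and are tested to agree there
to 1e-9.

**Consistency.**  CI = (λ_max − n)/(n − 1) and CR = CI/RI, with Saaty's
random-index table hard-coded for n = 1…15 (0, 0, 0.58, 0.90, 1.12, 1.24,
1.32, 1.41, 1.45, 1.49, 1.51, 1.48, 1.56, 1.57, 1.59).  A reciprocal 2×2
matrix is always consistent, so CR ≔ 0 there.  The acceptability threshold
defaults to Saaty's CR < 0.1 and is configurable.  Orders outside the table
raise a configuration error.

**Group aggregation.**  Experts' matrices for the same node are combined by
the element-wise geometric mean before weight extraction — the standard
aggregation-of-individual-judgments approach, which preserves reciprocity
(enforced exactly by aggregating the upper triangle and mirroring).  An
authority-weighted variant uses exponents u_k = Cr_k / ∑Cr, where
Cr = (Ca + Cs)/2 averages an expert's influence and familiarity; a panel is
flagged "authoritative" when every Cr exceeds 0.8.

## Evidence scoring

Scores are integers in [1, 10]; per (criterion, strategy) the panel is
summarized as mean ± sample SD (n − 1 denominator; 0 for a single score).
Missing cells are excluded pairwise and counted.  Qualitative bands — poor
[1, 3], moderate [4, 7], excellent [8, 10] — are defined on integers;
fractional means are banded by their nearest integer (half-up).

Comprehensive scores are CS = W_c × ES_c and overall values their sum.  All
arithmetic is on unrounded values; two-decimal half-up rounding happens only
at presentation (Python's built-in banker's rounding would misprint values
like 7.7059).  Ranking is competition-style with exact ties reported as
ties.

## Sensitivity analysis

A domain's *effective score* is the local-weight-weighted mean expert score
of its criteria, which equals (domain CS total) / (domain weight) on
unrounded inputs.  A scenario assigns domain weights in percent (validated
to sum to 100); its overall value per strategy is the weighted sum of domain
effective scores.  Applying the baseline weights as a scenario reproduces
the weighted-sum overall to 1e-9.  The result is "stable" iff every
scenario's full ranking equals the baseline ranking; top-two margins are
kept at full precision (displayed at 4 decimals) so near-ties stay visible.

The scenario builder refuses weight sets that upset the baseline
hierarchical order unless explicitly overridden.  Because published scenario
sets routinely bump one minor domain while keeping the two leading domains
dominant, the guard's default sense is leading-domain dominance (first ≥
second ≥ every other domain); a strict full-order check is available.

**Two computation routes.**  With unrounded inputs the model route (local
weights × mean scores) is exact.  When only a printed, rounded table of
domain CS totals is available, the division route (totals / domain weights)
is used instead; the two agree on unrounded data (tested) and differ on
rounded fixtures by up to ~0.02 points, which is the tolerance used in
regression tests against published values.

## Pharmacovigilance disproportionality

For a drug–event pair the report database collapses to a 2×2 table
(a = drug ∧ event, b = drug ∧ other, c = other ∧ event, d = other ∧ other).

* PRR = (a/(a+b)) / (c/(c+d)); positive when PRR > 2 (strict) and χ² ≥ 4.
* χ² is the Pearson statistic of the 2×2 table via
  `scipy.stats.chi2_contingency`, Yates-corrected by default (the
  convention accompanying the PRR criterion); an uncorrected variant is a
  flag away.
* ROR = ad/(bc) with Woolf CI = exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)),
  z = 1.959964 at 95 %; positive when the case count N = a ≥ 3 and the CI
  lower bound exceeds 1 (strict).
* A signal requires both rules to fire; the conjunction can only reduce
  positives relative to either rule alone (tested under a null simulation).

Zero cells raise an error by default; an optional Haldane–Anscombe +0.5
correction (all four cells, both estimators) makes sparse tables
admissible and is on by default in the bulk screening path, where arbitrary
sparse tables occur.  Event/drug names are normalized by case-folding and
whitespace trimming only; dictionary (MedDRA) coding is out of scope.
Screens sort by case count, then PRR, then event name.

## Economics and access

* Annual cost = price per vial × vials per administration × administrations
  per year.  The bundled case study uses 12 administrations per year
  (monthly dosing of an every-4-weeks regimen priced per calendar year),
  exposed as a regimen parameter.
* Daily cost = annual / 365 (calendar convention of the source tables).
* Affordability = 100 × annual cost / (per-capita disposable income ×
  household size).  The household-size multiplier is not stated in the
  source material; `calibrate_household_size` recovers it by brute force
  (grid h ∈ [1, 4], step 0.01, minimizing the maximum absolute deviation
  from the published percentages), landing at **2.62**, which reproduces all
  six published cells at two decimals.  It is a documented, overridable
  default.
* Coverage = 100 × stocked/total per institution type; the overall rate uses
  summed counts and therefore equals the count-weighted mean of the per-type
  rates.
* Money is plain floating point with two-decimal half-up presentation
  rounding; no currency conversion.

## Synthetic-data generators

Each generator draws from its own stream, derived from the master seed via
`SeedSequence(seed, spawn_key=(offset,))` with fixed offsets (judgments 1,
scores 2, reports 3), so adding a generator never shifts existing draws and
identical specs are bit-reproducible.

**Judgments** around a true weight vector w: entry ij is (w_i/w_j)·exp(ε),
ε ~ N(0, σ²), mirrored for exact reciprocity; optional snapping maps ratios
to the nearest Saaty value in log space.  Defaults mirror the bundled case
study: 17 experts, σ = 0.1.  Snapping bounds attainable recovery precision:
weights whose ratio is closer to 1 than to 2 in log space (e.g. 0.0824 vs
0.0784) collapse to identical rows and recover as exact ties, so order
recovery is guaranteed only weakly (no strict inversions).

**Score panels** draw integers from a normal discretized to the nearest
score and clipped to [1, 10].  The latent mean is calibrated by root-finding
on the exact discretized mean so the *realized* integer-score mean equals
the specified target; without this, clipping at 10 biases high-mean,
high-dispersion criteria downward by 0.1–0.3 points and panel means would
converge to the wrong truth.  Zero dispersion degenerates to every expert
emitting round(mean).  Target means too extreme to realize at the given
dispersion raise an error.  At 17 experts the overall value carries a
sampling SE of ≈ 0.1 points (√(∑ W_c² SD_c² / n)); tests assert recovery
within 3 SE at fixed seeds, and within 0.02 points at n = 10,000.

**Reports**: each of n reports (default 50,000) gets one drug — the target
with probability 5 % by default, else one of 20 background drugs — and one
event from a Zipf-like 20-event background distribution; implanted signals
multiply the target drug's probability for chosen events by λ and
renormalize.  Detection probability of the dual rule rises monotonically in
λ (checked empirically at λ ∈ {1, 2, 5, 10}).

What the generators deliberately do *not* emulate: real MedDRA vocabularies,
FAERS field layouts and duplicate-report artifacts, correlated expert
judgments, and criterion-score correlations within experts.  Passing
recovery tests therefore demonstrates the pipeline's correctness under the
stated noise models, not robustness to real-world reporting artifacts.

## The bundled case study

The published criterion weights cannot be recomputed from first principles
(the underlying expert matrices were never released), so they enter as
fixture inputs.  The per-criterion global weights bundled here were derived
from the published per-criterion comprehensive scores (CS / ES_c) under the
constraint that domain sums match the published domain weights.  The
published effectiveness figures are internally inconsistent at printed
precision: the guideline-recommendations criterion's comprehensive score
implies a global weight of ≈ 0.1439, while the separately printed percentage
is 15.34 %.  The bundle follows the table arithmetic (0.1439), so its global
weights sum to 0.9906 and are deliberately **not** renormalized —
renormalizing would shift the overall values ≈ 0.08 points away from the
published totals.  Published tables also carry small internal rounding
inconsistencies (criterion CS columns summing 0.01–0.02 below their printed
domain totals); regression tests therefore use a 0.02-point tolerance
against printed values, while exact identities are asserted on unrounded
synthetic data.

## Known limitations

* Two hierarchy levels only; no incomplete-matrix completion or fuzzy AHP.
* No uncertainty intervals on overall values (bootstrap over experts is a
  natural extension), and no probabilistic (Dirichlet) weight sensitivity.
* Disproportionality is frequentist only (no BCPNN/GPS), with no
  deduplication heuristics for report versions.
* Economics covers deterministic cost/affordability arithmetic, not
  cost-effectiveness modelling.
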