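# Methods

This note documents the statistical procedures implemented in
`mirnapair`, the choices made where the design was genuinely open, and
the limitations a user should know before trusting a call list.

## Setting and assumptions

All expression values are assumed normalized and on a log scale;
platform-specific preprocessing (background correction, quantile
normalization, probe summarization, endogenous-control scaling) is
upstream of this package. Features are matched across studies by exact
id string. Missing values are explicit (`NA`) and handled pairwise; they
are never imputed or zero-filled.

The biological premise is that miRNAs act as negative regulators: a
genuine pair must change in opposite directions. Both measures therefore
test a *directional* null and both apply a direction filter before any
test is run, which keeps the multiple-testing family well defined
(filtered pairs are reported with status `filtered` and never enter the
Benjamini–Hochberg family).

## Differential expression and discretization

For each non-reference condition, each feature is tested with a Welch
two-sample t-test of its log expression against the reference group.
The test is not prescribed by the method itself; Welch is the robust
default for small groups of unequal size and variance. p-values are BH-
adjusted across features *within* a condition (and within feature kind),
matching the per-group framing of the calls. A feature is differentially
expressed (DE) when |FC| > 1.5 (FC = mean(condition) − mean(reference),
log units) **and** adjusted p < 0.05; both inequalities are strict.
Discretization maps DE-and-up to +1, DE-and-down to −1, everything else
to 0. The subtraction order makes −1 mean "overexpressed in the
reference relative to the condition". Features with fewer than two
observed values in either group get p = 1 and are never called.

## Unmatched-data (UD) measure

For a pair (α, β) with discretized vectors over C conditions, the 3×3
contingency table counts conditions by (miRNA value, mRNA value). The
null — a change in mRNA expression is independent of a change in miRNA
expression — is materialized by resampling: pool all Z×C discretized
mRNA values, redraw a Z×C matrix i.i.d. from the pool, resample N_rep of
its rows with replacement (pseudo-mRNAs), tally each against α's vector,
and normalize the pooled counts to unit sum. Both resampling stages are
kept even though their i.i.d. limit has a closed product form; the
row-resampling noise is part of the procedure's definition.
Normalization divides by N_rep·C (counts divided by N_rep alone would
sum to C; the multinomial test requires a probability vector).

Significance is the exact multinomial goodness-of-fit convention: p is
the total null probability of all 9-cell outcomes with total C whose
probability is at most that of the observed table (ties included with a
relative tolerance of 1e−9 to absorb float round-off among
permutation-equivalent outcomes). Enumeration over all C(C+8, 8)
compositions is used while that count is ≤ 5×10⁶; beyond that a
Monte-Carlo multinomial p-value (add-one corrected, standard error
logged) is substituted, and for C > 15 the Pearson χ² upper tail over
cells with positive null probability is used instead, per the measure's
own large-C guidance. An observed count in a zero-probability cell is
impossible under the null and yields p = 0 with a logged warning; a pair
whose two vectors are identically zero is degenerate and reported
`not_testable` with p = 1.

Null probabilities are computed once per miRNA against the full Z-mRNA
pool and shared by all of that miRNA's pairs. Each miRNA receives an
independent child RNG stream spawned from the run seed, so adding or
removing pairs never perturbs another miRNA's null.

## Matched-data (MD) measure

CE-values subtract the per-feature *median* over reference samples
(medians because N_ref is typically very small and means are outlier-
sensitive; the arithmetic mid-median is used for even counts). For
two-channel arrays the values are already case-vs-reference contrasts
and pass through unchanged; naming a reference group in that mode is
rejected as contradictory.

The association parameter λ is the slope of the least-squares fit of
mRNA CE on miRNA CE *through the origin*, λ = Σx̃ỹ/Σx̃². This is the
minimal model consistent with "change in mRNA expression per unit change
in miRNA expression" anchored at the reference medians; a robust or
intercept-bearing fit would estimate a different quantity. The null
distribution resamples pseudo-mRNAs from the pooled Z×N_biol CE matrix
exactly as in the UD measure, and p = Pr(λ ≤ λᵒᵇˢ) with the add-one
correction (1 + #{λ_null ≤ λᵒᵇˢ})/(1 + N_rep), so p > 0 always. A pair
is significant only if λᵒᵇˢ < 0 and BH-adjusted p < 0.05 (strict).

The Pearson-correlation comparator evaluates the same pairs (without the
direction filter, as a correlation screen would) with a left-tail
permutation p against the *same* pseudo-mRNA draws per miRNA, so the two
measures are compared on identical nulls.

## Default parameters

| parameter | default | units / meaning |
|---|---|---|
| `fc_threshold` | 1.5 | log-units; DE effect-size gate |
| `alpha` | 0.05 | FDR level, strict inequality |
| `n_rep` | 10000 | resampling replicates (both measures) |
| `chisq_threshold` | 15 | conditions above which χ² replaces the exact test |
| enumeration cap | 5×10⁶ | compositions; beyond it, Monte-Carlo p |

Note on resolution: with the add-one correction the smallest achievable
raw p is 1/(N_rep+1), so the smallest achievable BH-adjusted p is about
m/(k·N_rep) for m tested pairs and k discoveries. N_rep must comfortably
exceed m/α or true positives are blocked by the permutation floor; the
10000 default is ample for candidate families of a few thousand pairs.

## Synthetic data

`simulate_matched` emulates a matched cohort: per-feature baselines
uniform on [6, 12] log₂ units; reference and background case samples add
Gaussian noise (sd 0.2); planted miRNAs are shifted +3 log-units in
cases with per-sample spread 1.0; planted target mRNAs follow
ỹ = λ·x̃ + N(0, 0.2). `simulate_unmatched` emulates discretized profiles:
background entries nonzero with probability 0.1 (split evenly between
signs); each planted pair gets opposite-signed values in a random subset
of ≥ 5 of the 9 conditions. Default shapes (3 reference / 14 case
samples, 9 conditions, 12 miRNAs / 326 mRNAs / 614 candidate pairs)
mirror a typical pair of combined myeloma cohorts scaled down tenfold,
so tests exercise realistic aspect ratios at desk scale; the validation
scenarios enlarge to 50 miRNAs / 500 mRNAs / 1000 candidates.

Candidate pair lists place each planted mRNA only in its own planted
pair; background candidates draw from non-planted mRNAs. This is
deliberate: both measures test whether the *mRNA* is exchangeable with
the pooled profiles, so a strongly dysregulated (planted) mRNA rejects
against *any* miRNA, and a pair of it with a foreign miRNA has no
well-defined truth label. Keeping such cross-pairs out of the candidate
list makes every non-planted candidate genuinely null, which is what
recall/FDR validation requires. Real prediction lists do contain such
cross-pairs — see limitations.

The generators do not simulate probe-level artifacts, batch effects,
heavy-tailed noise, or correlated genes; passing tests demonstrate
correctness and calibration of the machinery under the stated model, not
performance on any real platform.

## Known limitations

* **Marginal atypicality, not association (UD).** The resampled null
  asks whether the observed table is typical of pseudo-mRNAs drawn from
  the pool. An mRNA whose own profile is atypical (dysregulated in many
  conditions) produces a small p against *every* miRNA that passes the
  direction filter. Calls for pairs involving broadly dysregulated genes
  should be read as "this gene is unusual", not "this miRNA regulates
  it".
* **Reference-median error (MD).** With very few reference samples the
  estimated median carries an error that is a *shared offset* across all
  case CE-values of a feature. The through-origin slope of two features
  with opposite-signed offsets is genuinely negative, the direction
  filter enriches for exactly that configuration, and the i.i.d.
  resampled null cannot represent row-level offsets. At N_ref = 3 and
  noise comparable to the offset error this makes the MD calls
  anti-conservative; the CE-level type-I simulation (no median error)
  confirms the permutation machinery itself is calibrated. Users with
  N_ref ≲ 5 should treat borderline MD calls with caution.
* **Multinomial dispersion.** The exact test treats all nine cells as
  multinomial even though the row margins are fixed by the miRNA's
  vector; this extra dispersion makes the UD p-values conservative on
  truly null pairs (empirically P(p ≤ 0.05) ≈ 0.02–0.05).
* Same-direction co-dysregulation is not tested (the direction filters
  discard it by design), and multi-miRNA cooperative regulation is out
  of scope.
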