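# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limits of what the test suite demonstrates.

## Study design being emulated

The package targets the analysis of a vocal-convergence study in a
multi-level society: grunts of 27 adult males in two gangs, each of two
parties (6, 7, 5 and 9 males), recorded unevenly (5–127 calls per male),
described by 82 numeric acoustic features; genotypes at ~23 polymorphic
autosomal microsatellite loci; male philopatry elevating within-party and
within-gang relatedness. The scientific question is whether dyadic acoustic
similarity follows social-level membership (interaction), genetic
relatedness, or both.

## Acoustic side

**Stepwise DFA.** Individual identity is the grouping variable. For a
candidate set *S* of features, Wilks' Λ(S) = det W_S / det T_S (within /
total scatter). The partial F of adding feature *v* is

    F = (N − g − p)/(g − 1) · (Λ_S/Λ_{S∪v} − 1),   df = (g − 1, N − g − p),

with p = |S|; removal uses the same statistic one set-size down. The
feature with the smallest entry p-value enters while p < P_in (default
0.05); the entered feature with the largest removal p-value leaves while
p > P_out (default 0.10). P_in ≤ P_out is enforced, which together with the
equality of a just-entered feature's entry and removal statistics prevents
immediate cycling; an iteration cap guards the pathological remainder. Ties
in p are broken by larger partial F, then column order. A candidate whose
total scatter is numerically rank deficient (condition number > 1e12) is
skipped and logged. A feature with zero within-group variance and distinct
group means has infinite partial F; it enters, Λ reaches 0, and selection
stops (perfect separation). If nothing qualifies at step 1 the model is
returned empty and flagged rather than raising, because the permuted DFA
must be able to score such subsets as chance.

**Classification.** Linear rule with equal priors: assign a call to the
group with the smallest Mahalanobis distance under the pooled within-group
covariance (equal priors match the 100/g % chance-level framing; group
sizes here are unbalanced, so proportional priors would inflate apparent
performance). Leave-one-out refits the group means and pooled covariance
from scratch with the held-out call excluded — correctness over speed at
this scale. A call whose individual contributed only that call is excluded
from LOO and logged. At chance (labels shuffled), LOO is known to sit
slightly *below* 100/g % (the held-out call drags its own group mean away
from itself); the chance-recovery check therefore uses the rule itself
(resubstitution), and the pDFA handles chance calibration by permutation.

**Pairwise F and dissimilarity.** From the final fitted model (not averaged
over stepwise steps — the selection trace is recorded, so the alternative is
computable), the between-group F for groups i, j is

    F_ij = (N − g − p + 1)/(p(N − g)) · n_i n_j/(n_i + n_j) · D²_ij,

which reduces exactly to the two-sample Hotelling T² F for g = 2 (verified
to 1e-8 relative tolerance against an independent oracle). Dissimilarity is
ln(1 + F), order-preserving. A singular pooled covariance is a hard error
here — no silent regularisation, since F feeds every downstream test.

**Permuted DFA.** Observed statistic: the mean over `n_subsets` balanced
subsets (default: the minimum per-male call count, drawn without
replacement over a canonical call ordering so the statistic is invariant to
row order) of the LOO correct-classification rate, with stepwise selection
re-run inside each subset so selection optimism cannot leak into the null.
Null: the identical procedure on tables whose individual labels are
permuted across calls, with `n_subsets_null` subsets per permutation
(default 1, the standard practice; setting it equal to `n_subsets` makes
the procedure exactly exchangeable and is what the calibration experiments
use). p-values use the add-one correction, so the attainable minimum is
1/(n_perm + 1).

## Genetic side

**Locus screening.** Allele frequencies are observed counts over typed gene
copies. The Hardy–Weinberg test is the exact conditional test with
probability ordering (Levene's conditional distribution): complete
enumeration of allele pairings when a locus has ≤ 14 typed gene copies,
otherwise vectorized Monte-Carlo shuffling of the gene vector (default 1e5
shuffles, seeded, add-one correction). Monomorphic loci return p = 1 by
convention. The null-allele estimate is the heterozygote-deficit form
r = (He − Ho)/(1 + He), floored at 0. A locus is excluded only when r
exceeds its threshold (default 0.05) **and** HWE p < α (default 0.05) — the
conjunction mirrors how such screens are applied in practice; either flag
alone is reported but not fatal. Screening precedes frequency estimation
for the relatedness step, so W is computed from the retained loci only.
Exact conditional HWE tests are conservative at small samples because the
support is discrete; the suite checks the rejection rate from above.

**Wang relatedness.** For a dyad at one locus the genotype pair falls into
one of four similarity categories (identical; homozygote + heterozygote
sharing an allele; two heterozygotes sharing one allele; nothing shared).
Their probabilities are linear in φ (exactly one allele pair identical by
descent) and Δ (two pairs IBD), with coefficients that are polynomials in
the frequency moments a_m = Σᵢ pᵢᵐ (the b…g forms documented in
`relatedness.py`, re-derived from first principles and verified against
brute-force enumeration in the tests). Loci are combined by averaging both
the observed category indicators and the coefficients with weights 1/u,
u = 2a₂ − a₄, i.e. more polymorphic loci weigh more; the overdetermined
3×2 moment system is solved by least squares, and r̂ = φ̂/2 + Δ̂. When
frequencies are estimated from the sample (the default, including the focal
dyad, as the common estimator implementations do), the moments are replaced
by their unbiased factorial-moment estimators; frequencies passed
explicitly are treated as known. Dyads missing a locus use the available
loci with weights renormalised; dyads sharing no typed locus get NaN and
are dropped pairwise downstream (logged). W is not clamped: values outside
[−1, 1] would indicate a defect and fail the suite. Pedigree simulations
recover the expectations (full sibs ≈ 0.5, half sibs ≈ 0.25, unrelated ≈ 0,
with estimator variance decreasing in the number of loci).

## Dyadic tests

**Mantel correlation.** Pearson r over the off-diagonal upper triangle;
null built by simultaneous row/column permutation of one matrix's
individuals; two-sided by default for the acoustic–genetic association.

**Categorical Mantel.** Statistic: mean(different-group dyads) −
mean(same-group dyads) — equivalent in ordering to the point-biserial
Mantel r, but directly interpretable and the same contrast the effect sizes
use. Gang level: all 351 dyads, free permutation, 1000 permutations by
default. Party level: the dyad universe is restricted to same-gang dyads
(169), and party labels are permuted only within gangs (10 000 permutations
by default) — the restriction makes gang structure part of the null, so a
pure gang effect cannot produce a spurious party effect (verified by a
type-I experiment with gang signal and no party signal). Tests are
one-sided in the convergence direction ("same-level dyads more similar /
more related"), two-sided available. With `exhaustive=True` the scheme
enumerates all allowed permutations and the p-value (identity included) is
exact; sampled schemes use the add-one correction.

**Quartile contrast.** Dyads above the empirical 1−q quantile of W versus
below the q quantile (strict inequalities; ties fall in neither side and an
empty side is an error with a tie report). The outcome matrix is compared
between the two dyad sets by permuting the high/low assignment; with
continuous W and q = 0.25 this selects ~175 of 351 dyads.

**Effect sizes.** Cohen's d with (n−1)-weighted pooled SD and
SE(d) = sqrt((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))), normal CI. The convention is
fixed as same-group minus different-group (so convergence gives negative d
on dissimilarity and positive d on relatedness). Dyadic values share
individuals and are not independent; the CI deliberately ignores this —
reproducing how such effect sizes are conventionally computed — and every
report carries the caveat instead of a correction.

## Synthetic data

Feature model: call = gang effect + party effect + individual effect +
residual, each drawn per feature from zero-mean normals with one σ per
level shared across features (the simplest model that produces the nested
signal; real acoustic features are correlated and heterogeneous, which this
deliberately omits). Calls per male are uniform on [5, 127]; the emulated
study reports only min/mean/max (5, 28, 127) of a right-skewed empirical
distribution, so the uniform draw reproduces the range but not the mean.
Genotypes: founder allele frequencies per locus from a symmetric
Dirichlet (concentration 2.0 over 8 alleles — multiallelic with skewed
frequencies, as typical for microsatellites); within each party,
round(prop·size/2) disjoint full-sib and half-sib pairs receive Mendelian
samples from shared simulated parents (one generation; no mutation, no
inbreeding, no linkage); everyone else is an unrelated founder; missingness
is completely at random. The pedigree expectation (0.5/0.25/0) is returned
as `true_kinship` with a unit diagonal.

Defaults (σ_gang = 0.2, σ_party = 0.35, σ_individual = 0.5, σ_resid = 3.0;
sib proportions 0.3/0.3) were chosen once, by a small pilot sweep, to place
the default population in the regime the study describes: clear individual
signatures, significant within-party and within-gang acoustic convergence
of small-to-medium dyadic effect size, modestly elevated within-party
relatedness — and *no* acoustic–genetic coupling, because the generator
links the two channels only through the shared structure. The induced
acoustic–genetic Mantel correlation is then of order d_F·d_W/4 ≈ 0.05,
below the permutation test's detection threshold at 351 dyads, which is
precisely the dissociation the analysis is designed to expose; the
dissociation experiment verifies the pattern in ≥ 80% of seeds. Because
all 82 features carry the same per-feature signal, the stepwise procedure
retains nearly all of them and classification rates are higher than in real
data, where most features are uninformative or redundant — classification
percentages from the generator are therefore indicative, not calibrated to
any field value.

## Determinism and problem sizes

Every stochastic routine takes a seed; `run_study` spawns per-stage seeds
from one master seed via `SeedSequence`, so stages are individually
reproducible and reports are byte-stable. The validation experiments use
problem sizes chosen to keep each in the seconds-to-minutes range on one
CPU: 500 replicates for type-I calibration (with 39–199 permutations per
replicate), 500 dyads × 200 loci for relatedness recovery, 20 seeds for the
dissociation experiment, and reduced pDFA subset/permutation counts in the
scripted study run. All counts are configurable upward.

## Known limitations

* The feature generator has independent, homoscedastic features; no call
  contexts, recording-session effects, or feature correlations.
* Pedigrees are one generation deep; the diffuse multi-generation
  relatedness produced by long-term philopatry is only approximated by sib
  pairs, so relatedness contrasts at gang level are weaker than in real
  populations of this kind.
* Only the Wang estimator is implemented (others are an extension point);
  locus screening covers HWE and null alleles, not stutter or large-allele
  dropout.
* The pDFA supports the single-factor design (individual identity); crossed
  designs with a control factor are out of scope.
* LOO classification recomputes sufficient statistics per held-out call;
  at much larger call counts this is the first thing to optimise.
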