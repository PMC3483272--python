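# Methods

## Model and rationale

A case-control cohort drawn from a structured population mixes subgroups
that may differ both in allele frequencies and in their case/control
sampling ratio. For a 2×2 phenotype-by-genotype table with cells a (diseased
∩ A), b (diseased ∩ ~A), c (healthy ∩ A), d (healthy ∩ ~A), the odds ratio
OR = (a·d)/(b·c) estimates the genotype-phenotype association. When two
subpopulations with OR = 1 are pooled, a subgroup that is simultaneously
enriched for one genotype and for one phenotype produces a non-unity pooled
OR — a false positive driven purely by sampling. Equalizing the
diseased/healthy marginal ratio across subpopulations ("phenotype marginal
matching") removes this mechanism for null genotypes; it does not rescue
false negatives, where genuine within-subgroup associations are concealed by
opposite allele prevalences (that requires genotype-marginal matching too,
or covariate adjustment).

Ancestry is represented by the leading principal components of an LD-pruned
genotype matrix; all spatial notions below are Euclidean in that space.

## The homogenization algorithm

State: per-subject statistical weights, all initially 1. A *sphere* at
requested weight W centered on a subject is the smallest closed ball whose
member weights sum to ≥ W; every subject at exactly the final radius is
included, so membership is independent of input order. Its *sphere OR* is
the Haldane-corrected OR of the phenotype × (inside/outside) table — the
association an idealized genotype tagging exactly that subpopulation would
show.

Each cycle recomputes all subject-centered sphere ORs, selects the sphere
with maximal extremeness max(OR, 1/OR) (ties: subject input order), and
knocks the weight of one member down to w_kd: the member closest to the
center with weight exactly 1 and the over-represented phenotype (diseased
if OR > 1, healthy if OR < 1; at OR = 1 the side with the larger inside
weight, diseased on a full tie). If the selected sphere holds no eligible
member, spheres are tried in decreasing extremeness order; the run stops
early only when no sphere anywhere yields one. The cycle count is
round(total_weight · f / (1 − w_kd)), halves away from zero, which
minimizes the gap between requested and achieved weight reduction f.

Parameters, defaults, and units:

| parameter | default | meaning |
|---|---|---|
| sphere_weight W | 30 | subject-weight scale of the local comparison; smaller = finer spatial resolution, noisier ORs |
| knockdown_weight w_kd | 0.2 | residual weight of selected subjects (nonzero: information is attenuated, not discarded) |
| weight_reduction f | 0.07 | net fraction of cohort weight removed (0.09 in the simulation study) |

Defaults are the values selected for the Parkinson's-cohort application via
the bias-test parameter scan; `weight_reduction_sweep` reproduces that scan.
Because f only sets the cycle count, the sweep runs the algorithm once at
the largest fraction and replays smaller fractions from prefixes of the
knock-down log — exactly equivalent to independent runs, which a test
verifies.

## The potential p-value bias test

For every subject-centered sphere over a ladder of sphere weights (default
25, 50, 100, 200, 400, 800, 1600; weights exceeding the cohort total are
skipped with a warning), build the phenotype × membership table, round each
cell to the nearest integer (halves away from zero; the identity on
unit-weight cohorts), and take the two-sided Fisher exact p. The test value
is the minimum over all spheres and weights: the strongest false-positive
signal any subpopulation-tagging genotype could produce. The attaining
(weight, center) pair is reported to make the diagnostic actionable; ties
resolve to the smaller weight, then the earlier subject. The test bounds
nothing formally — it is a comparative diagnostic, not a false-positive-rate
guarantee.

## Statistical conventions

- **Fisher exact test**: two-sided minimum-likelihood convention (sum of
  hypergeometric probabilities ≤ that of the observed table), delegated to
  `scipy.stats.fisher_exact` and verified in tests against an exact
  integer-combinatorics enumeration for every table with total ≤ 40. Any
  zero row/column margin gives p = 1 (no evidence either way).
- **Haldane correction** (+0.5 per cell) is always used for sphere ORs so
  selection is well defined with empty cells; extremeness is max(OR, 1/OR).
- **Rounding** of weighted cells: nearest integer, halves away from zero
  (language defaults differ; this one is documented and deterministic).
- **Logistic association**: phenotype ~ intercept + genotype + PC1..PCk by
  ML; Wald p-value and coefficient of the genotype term. Cohort weights
  enter as frequency weights (each subject's log-likelihood contribution
  multiplied by its weight). Perfect separation yields the boundary
  p-value (smallest positive float, effect ±∞) with a warning —
  separation is infinitely strong evidence, not a failure. Rank-deficient
  designs are rejected.
- **ROC**: threshold sweep over observed p-values (call significant when
  p ≤ t), trapezoidal AUC, via scikit-learn; AUC standard errors by
  Hanley–McNeil.

## PC-space construction

LD pruning follows the standard sliding-window rule (50-SNP window, 5-SNP
step, removing the later SNP of any retained pair with r² > 0.1,
recursively; r² on subjects non-missing for both SNPs; monomorphic SNPs
contribute r² = 0 with a warning). PCA standardizes each SNP column to unit
variance after per-SNP mean imputation of missing dosages (allele-frequency
scaling is a known alternative that changes PC scale but not the method),
and fixes component signs by making each component's largest-magnitude
loading positive. Distances downstream use raw PC scores without eigenvalue
rescaling.

## Synthetic data: what it emulates and what it does not

`simulate_cohort` draws subjects from a three-component Gaussian mixture in
3 PC dimensions and assigns the diseased label with probability 0.6 inside
an axis-aligned box region and 0.5 outside — the benchmark's imbalance.
The default geometry (~4000 subjects) is built so that:

- the box is a **middle band** of PC2 inside a continuous cloud: the main
  component lies above it, the box component inside it, and a third arm
  below it. The box component straddles the PC2 = −2.68 stratum line used
  by the false-negative scheme, and the below-line stratum extends beyond
  the box — mirroring the described layout of the emulated cohort (the box
  subgroup spans the line; the below-line population includes a further
  subgroup outside the box);
- with population on both sides of the band, box membership is non-monotone
  in the PCs, so logistic regression with *linear* PC covariates can only
  partially absorb box-shaped confounding — the regime in which the
  benchmark compares the four strategies;
- the box holds roughly a fifth of subjects, and the box component is
  contained in the box at the ~3σ level.

Genotypes are binary subject labels (~A = 1), assigned independently per
subject and replicate: true-positive schemes condition on phenotype
(0.57/0.50, 0.15/0.10, 0.06/0.03 → population ORs 1.33, 1.59, 2.06),
false-positive schemes on box membership only (0.90/0.10, 0.80/0.20;
OR = 1 within strata), and the false-negative scheme on stratum × phenotype
(0.08/0.05 below the line, 0.95/0.92 above; OR 1.65 in both strata,
concealed in the pooled cohort). The full study uses 500 replicates per
scheme; the ROC positive class is every genotype with population OR ≠ 1.

Not emulated: real genotype-derived PC geometry (the emulated cohort's PC
cloud is not distributed), linkage between genotypes, diploid dosages for
the scheme genotypes, genotyping error, and relatedness. Passing tests
therefore demonstrate the algorithm's behavior under the benchmark's
statistical structure, not performance guarantees on any real cohort.

## Numerical and design notes

- Neighbor orderings are computed once per cohort (positions never change;
  only weights do) with stable sorts, so distance ties resolve by subject
  input order and runs are deterministic. The vectorized sphere scan caps
  the neighbor columns it touches and doubles the cap until every sphere
  and its tie shell fit; since prefix sums of `np.cumsum` equal sequential
  accumulation, it is bit-identical to per-sphere recomputation (tested on
  100 random weighted cohorts).
- Knocked-down subjects remain candidate sphere centers and members.
- Weight conservation: after t cycles the total weight is exactly
  W₀ − t(1 − w_kd); no subject is knocked twice (eligibility requires
  weight exactly 1).
- Knock-downs of the over-represented phenotype concentrate in the
  imbalanced region at knee-scale reductions (≳60% inside the box at
  f ≈ 4% in the default cohort); far beyond the knee the algorithm
  increasingly chases local sampling fluctuations spread over the whole
  cloud, which is the flattening visible in the parameter sweep.
- Problem sizes in the test suite: the bias-test improvement runs at the
  default n = 4000; the four-strategy comparison at n = 2000 with 50
  replicates per scheme; oracle sweeps on cohorts of n ≤ 200. These sizes
  give stable qualitative outcomes while keeping the suite quick to run.

## Known limitations

- The knock-down sequence is greedy; no optimality in the trade-off between
  achieved homogenization and sacrificed cohort weight is claimed.
- Only the phenotype marginal is matched: false negatives from opposing
  allele prevalences are untouched (combine with PC regression, which the
  simulation shows works well together with homogenization).
- The bias test scans subject-centered spheres only — a dense but not
  exhaustive family of regions.
- Exact numeric parity with other software's two-sided Fisher convention on
  published cohort p-values cannot be verified from the printed values.
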