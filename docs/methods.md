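# Methods

## Problem setting

`admixprec` quantifies how precisely a panel of ancestry-informative markers
(AIMs) recovers individual admixture in a trihybrid population — one drawing
ancestry from African-like (AFR), European-like (EUR), and Native-American-like
(NAM) sources, as is typical of South American cohorts. The package bundles
four pieces: a supervised admixture estimator, marker-panel construction by
balanced differentiation, family-design precision metrics, and a z-score
population-of-origin (biogeographical ancestry) test, plus a synthetic-data
generator that reproduces the statistical structure these analyses assume.

## Supervised admixture model

An individual's genotype at biallelic locus *l* is modelled as two
independent allele draws with ALT probability

    pi_l = sum_k q_k * p_kl,       k = 1..K,

where `p_kl` are reference ALT frequencies held fixed and `q` is the
admixture vector on the K-simplex. The log-likelihood

    l(q) = sum_l [ a_l ln pi_l + (2 - a_l) ln(1 - pi_l) ]

(`a_l` = ALT dosage; missing loci skipped, i.e. marginalized, never imputed)
is concave in `q` for fixed frequencies, so the maximizer is unique up to
flat directions. It is found by EM:

    q_k <- (1/2L') sum_l [ a_l q_k p_kl / pi_l + (2-a_l) q_k (1-p_kl) / (1-pi_l) ],

which conserves the simplex exactly and never decreases `l`. This is the
deterministic, supervised counterpart of population-assisted Bayesian
clustering with fixed reference panels: removing the MCMC removes run-to-run
noise, so no run-merging step is needed and every downstream metric is
exactly reproducible. Estimates will differ from an MCMC posterior mean by
design (mode vs. mean, no prior), particularly near the simplex boundary.

Defaults: uniform initialization (affects only iteration count, checked by
multi-start agreement), `tol = 1e-8` on the absolute log-likelihood change,
`max_iter = 2000`. Reference frequencies are clipped into
`[floor, 1 - floor]` with the add-half floor `1/(2 n_chrom + 2)` per
population and locus, so reference-monomorphic loci (which real AIM panels
contain) cannot produce infinite log-likelihoods. If every locus has
identical frequencies across populations the likelihood is exactly flat and
the estimator returns the uniform vector, flagged.

A brute-force simplex grid search (`grid_search_cohort`, default step 0.001)
evaluates the same likelihood without EM and serves as an independent
cross-check of the maximizer.

## Population-genetic statistics

* Allele frequencies, observed/expected heterozygosity, and Nei's unbiased
  gene diversity `(2n/(2n-1)) (1 - p^2 - (1-p)^2)` are computed per marker
  over non-missing calls; all-missing markers yield NaN, never a crash.
* Hardy-Weinberg testing uses the exact conditional test: given the
  minor-allele count, the two-sided p-value sums the probabilities of all
  heterozygote configurations no more probable than the observed one. The
  enumeration is exact (log-factorial weights), so there is no Monte-Carlo
  error to tune; monomorphic loci return p = 1 and are flagged, not dropped.
* Multiple-testing adjustment exposes both Bonferroni (default, matching
  standard forensic-genetics practice) and Benjamini-Hochberg, delegated to
  `statsmodels.stats.multitest`.
* Pairwise F_ST is the Weir-Cockerham (1984) theta-hat with the standard
  a/b/c variance components, combined across loci as a ratio of sums (never
  an average of per-locus ratios). Negative estimates are reported raw by
  default so balance diagnostics are unbiased; a clamp flag exists. When
  only a frequency table is available (no genotypes), the observed
  heterozygosity term uses its Hardy-Weinberg expectation `2p(1-p)`; with
  genotype input the observed value is used. Different F_ST software makes
  different small-sample choices, so numeric divergence from other tools on
  real data is expected.

## Panel selection

Multi-locus theta-hat is a ratio of summed components, so a panel's
differentiation is not a sum of per-marker scores and selection must
re-evaluate the full ratio. Two objectives are formalized:

* `max_balanced` — maximize the minimum pairwise theta-hat (ties: smaller
  max-min spread, then lexicographic marker ids): "highest and most
  balanced" differentiation.
* `balance_first` — minimize the max-min spread subject to the minimum pair
  staying above a configurable floor; an unreachable floor is reported as
  infeasible, never silently relaxed.

Search is exhaustive when `C(n, size)` is at most the configured limit
(default 1e5). Above it, a deterministic heuristic runs: forward greedy
selection seeded from the empty set and from each of up to 32 single markers
(plus all marker pairs when the pool is small), each run refined by
steepest-ascent single-marker swaps, best panel kept. The multi-start and
swap passes matter: the spread objective is far from submodular and plain
forward greedy stalls in poor local optima; with them, the heuristic
reproduces the exhaustive optimum across the full small-instance sweep used
in the tests. An optional `priority_pair` breaks remaining ties toward a
named population pair (e.g. favouring EUR-NAM, the hardest pair to
separate in this setting).

## Family-design precision metrics

With unlinked markers and Mendelian transmission, an offspring's expected
ancestry equals the parental average and full siblings share it. Observed
deviations — `|q_offspring - mean(q_mother, q_father)|` per component, and
`|q_sib1 - q_sib2|` per sibling pair — therefore measure the precision of
the whole estimation pipeline. The metrics are always computed on estimator
output, never on simulation truth, so they include estimation noise exactly
as a real study would. Group means (parents, offspring 1, offspring 2, all
offspring — the offspring index is file order within family, which is the
only definition available) and cross-panel Pearson correlations per
component complete the set; a zero-variance side yields a flagged NaN
correlation rather than an error.

## Z-score biogeographical-ancestry assignment

A profile is scored against candidate population P by its genotype
log-likelihood `l = sum_l ln P(g_l)` under P's genotype-class probabilities.
Because loci are unlinked, `E[l]` and `Var[l]` under the hypothesis that the
profile is a typical member of P are sums of per-locus moments, giving

    z = (E[l] - l) / sqrt(Var[l]),

rejected one-sided at `z > 1.64` (p < 0.05) by default. Genotype-class
probabilities come in two modes: `plugin` (Hardy-Weinberg at the sample
frequency) and `posterior` (default; moments of a Jeffreys `Beta(x+1/2,
n-x+1/2)` posterior, which accounts for the sampling variance of the
reference frequencies and keeps rare-allele classes off zero). The statistic
is this package's formalization of the published outlier-test idea; it is
not a numeric clone of any particular software, and its absolute outcome
percentages should not be compared digit-for-digit against published tables.
Missing loci leave `l`, `E[l]` and `Var[l]` jointly, so calibration is
preserved per included locus.

References are handled leave-one-out: a query that belongs to a labelled
population is removed from that population's allele counts before scoring,
which is what makes small-reference assignments honest. An admixed cohort
used as a candidate "population" is represented by its pooled genotype
frequencies exactly like a source population. Among accepted populations,
outcomes versus a known truth are classified concordant / discordant /
ambiguous with a log10 likelihood-ratio rule (threshold 1.0 by default; the
literature states no numeric rule, so this is an explicit, configurable
stand-in), or rejected when nothing is accepted.

## Synthetic data: what it emulates, what it does not

Reference populations drift from a shared ancestral frequency
(`Uniform(0.1, 0.9)` per locus) under the Balding-Nichols model
`pi_kl ~ Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k)` with per-population drift
`F_k`, so pairwise differentiation can be made unequal — the regime under
study. Individuals mix alleles with `q ~ Dirichlet(alpha)`; families draw
two parents and transmit one uniformly chosen allele per parent per locus
(unlinked loci). Missingness is uniform; a configurable fraction of loci
can be forced monomorphic in a designated reference population. All
randomness flows through one seeded generator; identical configs are
byte-identical.

Default study design (chosen once): K = 3, L = 210 markers, references of
100/100/47 individuals (AFR/EUR/NAM), 65 families of two offspring, 214
unrelated cohort individuals, `alpha = (3.85, 5.40, 0.75)` — i.e. ten times
a 38.5/54.0/7.5% AFR/EUR/NAM mean profile, concentration matching the wide
individual spread seen in admixed South American cohorts. Drift
`F = (0.70, 0.30, 0.70)` was calibrated so the simulated cohort-vs-reference
theta-hat distances land near the observed values for such cohorts
(≈ 0.21 / 0.11 / 0.31 against AFR / EUR / NAM, EUR closest), which makes the
reference-pair distances AIM-panel-like (0.4-0.7) — appropriate, since AIMs
are selected for differentiation, but far above genome-wide background.

Not emulated: linkage (deviations between sibling ancestries are therefore
somewhat smaller than with linked blocks), ascertainment structure of real
AIM panels beyond overall differentiation, genotyping error, and
population-specific missingness. Passing tests demonstrate correctness of
the estimators under the model's assumptions, not panel performance on any
real population.

## Numerical choices and degenerate inputs

* Exact HWE ties are compared with a `1e-12` relative tolerance so
  floating-point rounding cannot split equal-probability configurations.
* EM per-individual convergence is tracked separately; converged individuals
  freeze while the rest iterate.
* Panel-selection ties always resolve to the lexicographically smallest
  sorted marker-id tuple, making selection order-independent.
* A pair of populations monomorphic at every panel locus yields a flagged
  NaN theta-hat; a query whose removal would empty a reference population is
  an error; zero log-likelihood variance (all loci deterministic) is an
  error rather than an infinite z.
* Report JSON rounds floats to 9 decimals: thread-order jitter in BLAS
  reductions sits below 1e-12 and would otherwise break byte-identical
  reruns.

## Problem sizes used in the checks

The test suite and the acceptance script run the full default design
(L = 210, 214 cohort individuals, 65 families) for single-shot metrics, 20
seeds for the panel-size comparison of family deviations, 5000-10000
profiles at L = 200 for assignment calibration, L = 2000 at n = 100 per
population for theta-hat recovery, and an exhaustive sweep of all genotype
triples with at most 30 individuals for the exact HWE test. These sizes
give Monte-Carlo error comfortably inside each asserted band.

## Known limitations

* The supervised estimator treats reference frequencies as known; reference
  sampling noise enters the metrics but not the likelihood. At very low
  differentiation this produces a visible penalty against the smallest
  reference panel (the 47-individual NAM set fits worse under noise), and
  cohort means shrink only partially toward uniform — the shrinkage is real
  but incomplete at L = 210 unless differentiation is essentially zero.
* `balance_first` beyond the exhaustive regime is a heuristic; optimality is
  verified only on the small-instance sweep.
* The z-test assumes unlinked loci; linked panels would need an effective-
  locus correction that is out of scope here.
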