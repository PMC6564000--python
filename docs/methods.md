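# Methods

This note documents the statistical procedures implemented in `pltr_immuno`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Outcome and variable roles

The outcome is binary inhibitor status (inh+ / inh−), clinically defined by
two consecutive Bethesda assays at ≥0.6 BU in a severely affected (FVIII
activity <1%) patient treated for at least 50 exposure days. Variables carry
one of six roles: `outcome`, `linear` (clinical confounders entering the
parametric part), `tree` (genetic variables eligible for splitting),
`stratum`, `id`, `ignore`. HLA-DRB1/DQB1 alleles are modelled as per-allele
carrier indicators (present on ≥1 chromosome); homozygous carriage is not
distinguished, matching how carrier counts are tabulated in this field. The
raw two-allele columns are retained for haplotype analysis. The HMOX1 (GT)n
promoter repeat is recoded per allele as S (<21 repeats), M (21–29), L (≥30);
the boundary count 30 is assigned to L, consistent with the ≥30 convention
of the repeat-length literature, and the derived L-carrier indicator is the
tree-eligible form (the six-level diplotype exceeds the categorical split
budget and is kept for description only).

Missing data: association and regression analyses are complete-case per
analysis and always report the number excluded. Inside the tree, missing
values are instead routed to the side of each split that minimises the joint
deviance (recorded in the rule as `missing_side`), so the tree retains every
subject complete on outcome and linear terms. Stepwise selection uses one
complete-case set over outcome, forced-in terms and all candidates, so every
likelihood-ratio test in the trace compares the same subjects.

## Univariate association

Odds ratios are cross-products with Woolf (log-normal) 95% intervals,
`exp(log OR ± 1.96·sqrt(1/a+1/b+1/c+1/d))`. With a zero cell the
Haldane–Anscombe correction (add 0.5 to all cells) is applied on request and
flagged. p-values use Pearson's chi-square without continuity correction,
switching to Fisher's exact test when any expected cell of a 2×2 table is
below 5; r×c tables always use the chi-square (no exact network algorithm is
implemented) and the choice is recorded on each result. Genotype tables
report per-genotype odds ratios against the homozygous-reference genotype
plus a global 2×3 chi-square; the additive (allele-dose 0/1/2) model and
dominant/recessive recodes are available as explicit design terms
(`snp:dose`, `snp:dominant`, `snp:recessive`). The Hardy–Weinberg check is
the exact conditional test (sum of probabilities of heterozygote counts no
more probable than observed, given allele counts); the plain exact p is
reported, not the mid-p variant, a deliberately conservative choice.
Monomorphic markers return p=1 with a flag. No multiplicity adjustment is
applied by default.

## Haplotype analysis

Two-locus haplotype frequencies are estimated by EM over phase ambiguity
(gene counting); only double heterozygotes are ambiguous. The EM starts at
linkage equilibrium (product of marginal allele frequencies), which also
resolves the symmetric double-heterozygote configuration — two fixed points
of equal likelihood — deterministically. The log-likelihood is asserted
non-decreasing at every iteration; convergence is a change below 1e-10.
Association with a target haplotype (e.g. DRB1\*15–DQB1\*06) uses the
difference of EM frequencies between outcome groups as the statistic and a
permutation p-value (outcome labels shuffled, both EMs re-run per
permutation, add-one correction). A frequency-difference permutation test
was preferred over a score test because it makes no asymptotic assumptions
at the n≈140 scale this pipeline targets; only per-haplotype tests are
provided, not a global multi-allelic test.

## Logistic engine and stepwise selection

The IRLS fitter is Newton–Raphson with step-halving, convergence at score
infinity-norm < 1e-8 (max 100 iterations), and per-subject offsets that are
never counted as parameters. Deviance equals −2·loglik for binary data, and
the information criteria live on that scale (AIC = deviance + 2p, BIC =
deviance + p·log n), which makes a plain logistic fit and a partially linear
tree fit on the same subjects directly comparable. Coefficients exceeding
±15 log-odds flag the fit as non-converged with a separation advisory — no
Firth penalisation is applied; the advisory points to the Haldane-corrected
crude estimate instead.

Stepwise selection is forward with backward removal: candidates are
prefiltered by the likelihood-ratio p-value against the base model (< 0.2);
at each step the smallest-p candidate enters if p < 0.05 (ties broken
lexicographically for reproducible builds), then any entered term with
removal p > 0.05 is dropped. Entry/removal tests are likelihood-ratio rather
than Wald — the natural choice for deviance-based selection — with Wald
statistics still reported in coefficient tables.

## Partially linear tree (GPLTR)

Model: `logit P(Y=1) = x'β + c_leaf(g)`, leaf effects parameterised as leaf
indicators with one reference leaf so the intercept stays identifiable.

*Growth.* An outer loop alternates (i) an exact joint fit of linear terms
plus current leaf indicators and (ii) a greedy regrowth of the whole tree
with the fitted linear predictor (linear part only) held as an offset.
Within the regrowth, splitting a node decomposes its intercept-with-offset
deviance into the two children's, so candidate evaluation is two 1-D Newton
solves per candidate — fast enough to make bagging at B=100 routine. The
outer loop stops when the joint deviance changes by < 1e-6 (20 iterations
max; non-convergence warns, never errors). Split search space: binary
variables have their single split; genotype variables the two
dose-respecting splits (dominant, recessive), which is exactly the space of
ordered genotype merges such as {T/T, G/T}; unordered categoricals with ≤5
levels all two-set partitions. Admissibility requires `min_leaf` subjects on
both sides and depth ≤ `max_depth` (default 5).

*Minimum leaf size.* Default `max(10, round(0.05·n))`: ten subjects at the
reference cohort size of 125 and five percent of larger cohorts. The 5%
rate is deliberately about half of the ~8% granularity implied by the
reference setting (10/125): a tree can only isolate subgroups larger than
its minimum leaf, so the threshold must sit clearly below the subgroup
sizes of scientific interest; an early design that scaled at 8% placed the
smallest planted subgroup of the default simulation exactly on the
admissibility boundary and intermittently hid its split.

*Nested sequence and selection.* From the root, the forward pass repeatedly
expands the maximal-tree split (under a current leaf) with the largest
deviance gain and re-fits the full joint model after each accepted split.
Candidate screening within a sweep holds the linear predictor as an offset —
an approximation; the recorded deviance/AIC/BIC always come from the exact
joint refit, and nesting guarantees the deviance chain is non-increasing.
The selected tree minimises BIC (or AIC) over the chain, ties resolved
toward the smaller tree; the BIC parameter count is #linear coefficients +
#leaves with the intercept folded into the reference leaf (stated so users
can reconcile other conventions).

*Leaf summaries.* Branch risk is reported both ways: the raw event rate
(events/n) and the covariate-adjusted probability (mean fitted probability
over branch members). The two differ whenever the linear covariates are
unbalanced across branches, which is why both are always emitted rather
than choosing one. Branch-vs-rest odds ratios come from a logistic fit of
the outcome on the branch indicator plus the linear terms.

## Bagging and Deviance Importance Scores

For each of B bootstrap resamples (subjects with replacement; optional
stratification by outcome protects the event count at n≈125), the full
pipeline — growth, nested sequence, BIC selection — is refit, and every
accepted split of the selected tree credits its variable with that split's
joint-model deviance reduction. The DIS of a variable is the mean of these
credited reductions over successful replicates; replicates that fail (e.g.
a degenerate resample) are skipped and counted, with >20% failures fatal.
Aggregation is over the selected tree, not the maximal tree, keeping the
score aligned with what the selection procedure actually reports. Variables
are ranked by DIS, ties by selection frequency then name. The procedure
measures stability and discriminative power; it deliberately offers no
out-of-bag prediction error, because the intended cohort sizes are
underpowered for honest prediction claims.

## Synthetic-data generator

The generator produces cohorts with the joint structure the pipeline
assumes, parameterised by a single `SimConfig` and one seeded RNG per run:

* **HLA**: two haplotypes per subject drawn i.i.d. from a DRB1–DQB1
  haplotype frequency table (classic European pairings; allele frequencies
  back-computed from the inhibitor-negative reference group's carrier
  rates via carrier = 1−(1−h)²). This induces realistic linkage
  disequilibrium — DRB1\*15 and DQB1\*06 co-occur on a haplotype — without a
  population-genetics simulation.
* **SNPs**: genotype = sum of two independent alt-allele draws
  (Hardy–Weinberg by construction), alt frequencies from the same reference
  group.
* **HMOX1**: two allele classes (S/M/L at 0.34/0.51/0.15) with a uniform
  repeat count inside each class's range.
* **Clinical covariates**: independent categoricals at reference-group
  frequencies (F8 high-risk 0.63; family history 0.725/0.226/0.049;
  plasma/recombinant 0.84/0.16; blood group O 0.37; a 3-level birth-cohort
  stratum that carries no effect by default).
* **Outcome**: logit P = baseline + Σ linear effects + leaf offset. Default
  linear log-odds are log 4.34 (high-risk F8), log 7.19 (family history of
  inhibitors, vs history-without-inhibitors), log 1.51 (no family history),
  log 3.69 (recombinant product); baseline = logit(0.464). The planted tree
  mirrors the three-branch stratification (DRB1\*15 → IL-10; DRB1\*15−
  → DQB1\*02 → CD86 rs2681401) with leaf probability targets 0.77 / 0.47 /
  0.12. Because genotypes and clinical covariates are independent, each
  leaf's offset is calibrated exactly: the marginal leaf rate is the
  expectation of expit(baseline + v + c) over the finite distribution of
  linear contributions v, and c is solved by bisection.
* Missingness is injected after outcome generation at configurable
  per-column rates (none by default), so the truth record always reflects
  complete genotypes. Family history is a label, not a transmission model,
  and no treatment-era trend is simulated — limitations to keep in mind:
  passing tests demonstrate recovery of this idealised structure, not
  robustness to ancestry stratification, genotyping error, informative
  missingness, or covariate-genotype dependence found in real registries.

## Numerical choices and degenerate inputs

Leaf constants are capped at ±30 log-odds (all-event/all-nonevent leaves);
IRLS Hessians get a 1e-8 ridge only on singularity; candidate-split ties
keep the first candidate in a fixed variable/level order, making fits
reproducible bit-for-bit for a given seed. Degenerate inputs fail loudly:
empty 2×2 margins, monomorphic markers (flagged p=1), an eligibility filter
that removes everyone, a subject falling outside the planted-tree partition.

## Known limitations

* Forward subtree selection has one-step lookahead. On truths where an
  intermediate split carries no marginal signal but unlocks strong
  descendant splits (XOR-type interactions), the chain can miss the
  globally BIC-optimal subtree; on hierarchical truths the forward optimum
  and the exhaustive optimum coincide in practice (verified by enumeration
  in the test suite).
* BIC selection inherits a multiple-testing effect from greedy growth: each
  candidate split is the maximum over ~20–30 admissible rules, so with many
  null genetic variables the selected tree occasionally (order 20% of
  cohorts at n=2000 with 24 candidates) carries one extra noise split whose
  gain exceeds log n. Users reading selected trees should treat terminal
  splits with gains near log n as tentative and lean on the bagged DIS
  ranking, which is robust to this.
* Exact conditional confidence intervals are not implemented (Woolf
  everywhere); separation is flagged, not penalised.
* Haplotype analysis is limited to two loci.
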