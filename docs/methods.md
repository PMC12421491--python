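# Methods

This note documents the models and estimators implemented in `zwscan`, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical conventions used throughout.

## Cohort simulation (`zwscan.zwsim`)

The simulator generates diploid genotype calls (alt-allele dosage 0/1/2,
−1 for missing) for a cohort structured into populations, each with a stated
number of males and females.

**Autosomal loci.** Each locus draws an ancestral alt-allele frequency
uniformly from `maf_range` (default 0.05–0.5, the ascertained-common-variant
spectrum typical of SNP arrays after a MAF ≥ 0.01 filter). Per-population
frequencies follow the Balding–Nichols model: with differentiation parameter
`F_bg` ∈ [0, 1), the population frequency is Beta-distributed with mean p
and variance `F_bg · p(1−p)`; `F_bg = 0` means all populations share the
ancestral frequency exactly. Balding–Nichols was chosen because it is the
simplest exchangeable-population model whose differentiation parameter
coincides with the quantity the Weir–Cockerham estimator targets, giving the
simulator a closed-form expectation to test against. Genotypes are drawn at
Hardy–Weinberg proportions within each population.

**Z-linked loci.** Males draw two alleles; females draw one and the call is
recorded as the corresponding homozygote — the diploid coding a genotype
caller or SNP chip produces for a hemizygous individual. A simulated female
is therefore *never* heterozygous on the Z, which is exactly the property
the sexing statistic exploits.

**Artifact loci.** Calls are a deterministic function of sex: under
`het_call` every female is heterozygous and every male homozygous reference
(a W-linked copy contributing a second "allele" in the heterogametic sex);
under `split_call` the sexes are fixed for opposite homozygotes (the
W-linked copy replacing the signal entirely). Artifacts are simulated at the
call level rather than the read level because that is the level at which the
confounding operates in array and hard-called data; read-level simulation is
a non-goal.

**Missingness and errors.** Missingness is i.i.d. across cells at
`missing_rate`, independent of sex and genotype (a sex-biased missingness
option is deliberately deferred). An optional per-call `error_rate` replaces
a call with one of the other two dosages uniformly; the default is 0 —
observed real-data θ of ~0.96 rather than 1 at fixed-difference artifacts is
accommodated by the classifier's fuzzy thresholds instead, since the
generating error rate is not identifiable from the available summaries.

**Read depth.** `simulate_depth` overlays Poisson(d0) depths, with female
means multiplied by the artifact's `coverage_multiplier` (default 6, the
upper end of the female coverage excess observed at mis-mapped W regions).

**Seeding.** One master seed; sub-streams for frequencies, genotypes,
errors and missingness are spawned from it, so each stage is independently
reproducible and runs are byte-identical for a fixed seed.

## Sex inference (`zwscan.sexing`)

For each individual, over non-missing Z-linked calls:

    F = (ObsHom − ExpHom) / (L − ExpHom)

where `ObsHom` is the observed homozygous call count, `L` the number of
calls used, and `ExpHom = Σ_l [1 − 2 p_l (1 − p_l) · A_l/(A_l − 1)]` the
summed per-locus expected homozygosity at the cohort allele frequency `p_l`
with the small-sample correction on the non-missing allele count `A_l`
(loci with fewer than two observed alleles are excluded and contribute
nothing). This is the statistic computed by PLINK `--check-sex`. A widely
circulated shorthand divides by `ExpHom` instead; that form does not
normalise to 1 for a fully homozygous individual, so the `L − ExpHom`
denominator is used here — it sends ZZ males (heterozygous at the expected
rate) to ≈ 0 and ZW females (all calls homozygous) to exactly 1.

Labels: `F ≤ 0.2` → male, `F ≥ 0.8` → female, otherwise unknown. Boundary
values are assigned to the decisive class; only the open interval is the
unknown band. Z loci are pre-filtered with the same MAF/missingness filters
as the genome scan. With ~200 informative Z loci the male F distribution has
a standard deviation near 0.09 (dominated by the shared error in cohort
allele-frequency estimates), so occasional males fall into the unknown band;
with ≥ 500 loci assignment is essentially complete. Misassignment to the
*opposite* sex is never observed in clean simulations at either locus count.

## Per-SNP differentiation (`zwscan.fst`)

The Weir & Cockerham (1984) estimator, per site, for r ≥ 2 groups of
`n_i` non-missing diploids with alt frequencies `p_i` and heterozygote
proportions `h_i`:

    n̄  = Σ n_i / r
    n_c = (r·n̄ − Σ n_i² / (r·n̄)) / (r − 1)
    p̄  = Σ n_i p_i / (r·n̄)
    s²  = Σ n_i (p_i − p̄)² / ((r − 1)·n̄)
    h̄  = Σ n_i h_i / (r·n̄)
    a = (n̄/n_c) [ s² − (p̄(1−p̄) − ((r−1)/r)s² − h̄/4) / (n̄−1) ]
    b = (n̄/(n̄−1)) [ p̄(1−p̄) − ((r−1)/r)s² − ((2n̄−1)/(4n̄)) h̄ ]
    c = h̄/2
    θ = a / (a + b + c)

Conventions, matching per-site `vcftools --weir-fst-pop`:

- negative θ is reported as computed (clamping available for summaries);
- monomorphic sites (a+b+c = 0) and sites with n̄ ≤ 1 give `nan`;
- missing genotypes reduce `n_i`; no imputation;
- biallelic SNPs only; other records are skipped and counted;
- output sorted by chromosome then position.

Two fixed points anchor the estimator to the artifact classes: two groups of
54 fixed for opposite homozygotes give exactly a = 0.5, b = c = 0, θ = 1;
54 homozygous-reference vs 54 heterozygous give a = 0.125, b = −0.125,
c = 0.25, θ = 0.5.

For genome-wide summaries, `weighted_fst` returns Σa / Σ(a+b+c) (vcftools'
"weighted FST"). This — not the per-locus average of θ ratios — is the
quantity whose expectation equals the generating `F_bg`: the per-locus
average is a mean of ratios and is noticeably downward-biased with two
groups (≈ 0.15 observed at `F_bg` = 0.2), while the ratio of sums recovers
0.20 within Monte-Carlo error over 5,000 loci.

Variant filters default to MAF ≥ 0.01 and missing-call fraction ≤ 0.8
(PLINK `--maf 0.01 --geno 0.8`), applied in that order with MAF computed on
retained individuals.

## Hardy–Weinberg testing and power (`zwscan.hwe`)

Plain Pearson chi-square of the three genotype classes against expectations
at the estimated allele frequency; no continuity correction, no exact test.
Classes with zero expected count contribute nothing (and monomorphic sites
give χ² = 0, p = 1 — untestable, not significant).

**Degrees of freedom.** Default df = 2; df = 1 (the textbook choice, which
accounts for the estimated allele frequency) is available everywhere. The
df = 2 tail is the variant under which a sample of 30 with only AA and Aa
genotypes first rejects HWE at α = 0.05 when 19 individuals are
heterozygous; df = 1 moves that threshold to 16. Both dfs are exposed
because the choice changes screening decisions; the default is stated
loudly rather than silently assumed. Under simulated HWE genotypes the df=1
test holds its nominal 5% level; df=2 is conservative.

**Sex-aware filtering.** Each locus is tested pooled and within each sex.
A locus failing pooled HWE while conforming (or being monomorphic) within
each sex carries the signature of a sex-linked artifact
(`fail_pooled_only`): a split-call artifact has pooled counts like
(30, 0, 30) — a massive heterozygote deficit — yet is monomorphic within
each sex. A locus departing from HWE *inside* a sex (`fail_within_sex`),
such as an all-heterozygous female sample, is flagged separately. No
multiple-testing correction is applied by default; a Bonferroni option
divides α by the locus count.

## Sex-ratio subsampling (`zwscan.ratio`)

`select_balanced` draws n males + n females per population without
replacement, erroring with the available counts when a population cannot
supply them (mirroring the exclusion of under-sampled populations from
balanced designs). `sexratio_grid` evaluates per-site θ at one focal locus
for every pair of male:female compositions from two pools (default
0:12 … 12:0, the sweep available when both pools hold 12 of each sex).

Numerical conventions worth noting:

- Cells monomorphic in both subsamples are `nan` — *untestable*, which at
  the all-male-vs-all-male corner of a split-call locus is not the same as
  undifferentiated.
- Equal-composition cells at a split-call locus give exactly −1/(2n−1)
  (−1/11 at n = 6+6): the standard negative Weir–Cockerham estimate in the
  absence of between-sample frequency differences. The exact 0 of the
  attainable range comes from contrasts with identical heterozygote-bearing
  compositions (e.g. 12 females vs 12 females at a het-call locus);
  `grid_summary(..., clamp_zero=True)` applies the usual display convention
  that floors negatives at 0.
- Subsample draws are keyed by (seed, pool content, ratio), not by argument
  position: swapping the two pools transposes the grid exactly, and one
  fixed draw per ratio is reused across the grid. `replicates > 1` averages
  independent redraws.

At a sex-determined locus the grid depends only on composition, not on
which individuals are drawn — θ ranges over the full [0, 1] interval purely
as a function of sample sex ratios, which is the bias the module exists to
demonstrate.

## Locus classification (`zwscan.classify`)

Rules applied in order of decreasing specificity, on per-sex genotype
profiles of loci whose male-vs-female θ exceeds the report threshold
(default 0.4):

1. both sexes ≥ 95% fixed for *different* homozygotes and θ ≥ 0.9 →
   `fixed_between_sex_paralog`, action `exclude_and_validate`;
2. one sex ≥ 90% heterozygous, the other ≥ 90% homozygous, and
   0.3 ≤ θ ≤ 0.7 → `sex_limited_het_paralog`, action `exclude_and_validate`;
3. locus on the Z with female heterozygosity ≤ 0.05 → `z_linked_dosage`,
   action `analyze_by_sex`;
4. otherwise `unremarkable`, action `keep`.

The thresholds are deliberately fuzzy (real fixed-difference artifacts show
θ ≈ 0.96, not 1.0, from sporadic genotyping errors) and all configurable.
The fixed-difference rule precedes the heterozygote rule because it is the
rarer and more diagnostic pattern. A female/male coverage ratio ≥ 1.5, when
depth data are supplied, is appended as corroborating evidence for the
paralog categories but never changes the category — so removing depth data
changes evidence strings only. Paralog categories map to
`exclude_and_validate` because both patterns are mapping artifacts whose
molecular basis should be confirmed before any biological interpretation;
Z-linked dosage maps to `analyze_by_sex` because the locus is genuine and
informative when the sexes are analysed separately.

Loci with fewer than 5 non-missing calls in either sex are untestable and
never reported.

## What the simulator does and does not show

Passing tests on synthetic cohorts demonstrate that the estimators and the
classifier behave correctly when the data-generating process matches their
assumptions: unlinked biallelic loci, exchangeable populations, sex-exact
artifact calls, depth independent of genotype. Real data add linkage
disequilibrium, ascertainment bias beyond a uniform MAF window, related
individuals (prune relatives upstream, e.g. PLINK `--rel-cutoff 0.25`,
before scanning), partial rather than total probe collapse, and reference
bias — none of which are modelled. Consequently, simulated results bound
what the method can do under clean conditions; they do not certify
performance on any particular real data set. Pseudoautosomal inheritance
and W structural variants are additional real mechanisms outside the
implemented category set.

## Problem sizes and determinism

The test suite and the acceptance script use desk-scale problems chosen to
make Monte-Carlo error negligible relative to each tolerance: 5,000 loci
for frequency-calibration and false-positive-rate checks, 10,000 replicates
for type-I-error rates, 200–500 Z loci and 100–200 individuals for sexing,
and the exact 5×5 ratio grid on 12+12 pools. All randomness flows from
explicit integer seeds through `numpy.random.SeedSequence` spawning; every
result in the README's worked example and in `results/acceptance.json` is
reproducible byte-for-byte from the logged parameters and seed.
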