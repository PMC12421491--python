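# zwscan

Sex-aware genome scans for species with ZW sex determination (birds,
lepidoptera, some reptiles and fish).

## The problem

In a ZW system the female is the heterogametic sex: she carries one Z and one
W chromosome, while males carry two Z copies. Standard variant-calling and
genotyping pipelines assume every individual is diploid at every locus, and
most reference assemblies lack a finished W. Two kinds of trouble follow:

1. **Hemizygosity looks like homozygosity.** A female's single Z allele is
   recorded as a homozygous diploid genotype, so Z-linked loci show zero
   female heterozygosity.
2. **W-linked paralogs create phantom autosomal SNPs.** When reads or array
   probes from a diverged W-linked copy of a sequence collapse onto its
   autosomal (or Z) counterpart, the resulting calls are a deterministic
   function of sex: either every female appears heterozygous while males are
   homozygous (male-vs-female F<sub>ST</sub> ≈ 0.5), or the two sexes appear
   fixed for opposite alleles (F<sub>ST</sub> ≈ 1). Such loci also show
   inflated female read depth.

If the sample's sex ratio is unbalanced — or differs between two populations
being compared — these sex-determined loci masquerade as dramatic signals of
local adaptation.

## What the package does

- **`zwscan.zwsim`** — simulate ZW cohorts: autosomal loci with
  Balding–Nichols between-population differentiation `F_bg`, Z-linked loci
  with diploid-coded hemizygous females, planted artifact loci of both call
  regimes, missingness, and a Poisson read-depth overlay with
  female-specific inflation at artifact loci.
- **`zwscan.sexing`** — infer individual sex from the Z-chromosome
  inbreeding coefficient `F = (ObsHom − ExpHom) / (L − ExpHom)`, which
  clusters at 0 for ZZ males and 1 for ZW females; labels use the
  0.2 / 0.8 thresholds with an "unknown" band between.
- **`zwscan.fst`** — per-SNP Weir & Cockerham (1984) variance components
  (a, b, c) and θ = a/(a+b+c) for arbitrary group contrasts, with
  PLINK-style `--maf` / `--geno` filters and per-site (window size 1)
  vcftools semantics.
- **`zwscan.hwe`** — Hardy–Weinberg chi-square tests, the minimum
  heterozygote count needed to reject HWE (19 of 30 at α = 0.05, df = 2),
  and a sex-aware filter that separates "fails HWE because sex-linked" from
  "fails HWE within a sex".
- **`zwscan.ratio`** — balanced subset selection and the sex-ratio
  subsampling grid: θ at a focal locus for every pair of male:female
  compositions (default 0:12, 3:9, 6:6, 9:3, 12:0), showing θ sweep the
  full [0, 1] range at a sex-determined locus.
- **`zwscan.classify`** — assign mechanistic categories
  (`fixed_between_sex_paralog`, `sex_limited_het_paralog`,
  `z_linked_dosage`, `unremarkable`) with recommended actions, using per-sex
  genotype profiles, θ between sexes, and optional coverage ratios.
- **`zwscan.io` / `zwscan.cli`** — VCF v4.2 and TSV readers/writers and a
  `zwscan` command with subcommands `simulate`, `sex-infer`, `fst-scan`,
  `hwe-power`, `hwe-filter`, `sexratio-grid`, `classify`.

## Worked example

Simulate two populations of 12 males + 12 females with one artifact locus of
each regime, then run the whole pipeline:

```sh
cat > demo.yaml <<EOF
populations:
  - {name: Harjavalta, males: 12, females: 12}
  - {name: Wytham, males: 12, females: 12}
L_auto: 2000
L_z: 300
seed: 1
artifact_loci:
  - {chrom: '5', pos: 10662578, regime: split_call, coverage_multiplier: 6.0}
  - {chrom: '5', pos: 10700000, regime: het_call, coverage_multiplier: 6.0}
EOF

zwscan simulate --config demo.yaml --out cohort --depth-d0 20
# wrote cohort of 48 individuals x 2302 loci to cohort

zwscan sex-infer --vcf cohort/cohort.vcf --samples cohort/samples.tsv \
    --z-chrom Z --out sex.tsv
# 24 male, 24 female, 0 unknown

zwscan fst-scan --vcf cohort/cohort.vcf --samples cohort/samples.tsv \
    --contrast sex --out scan.tsv
# 2301 loci scanned; max theta = 1.0000

zwscan classify --vcf cohort/cohort.vcf --samples cohort/samples.tsv \
    --depth cohort/depth.tsv --z-chrom Z --out report.tsv
# 2 loci reported: {'fixed_between_sex_paralog': 1, 'sex_limited_het_paralog': 1}

zwscan sexratio-grid --vcf cohort/cohort.vcf --samples cohort/samples.tsv \
    --pop-a Harjavalta --pop-b Wytham --locus 5:10662578 --seed 1 --out grid.tsv
# theta range over grid: [-0.0909, 1.0000]

zwscan hwe-power --n 30 --df 2 | tail -1
# k_min = 19
```

Reading the output: the male-vs-female scan flags exactly the two planted
artifact loci — the split-call locus at θ = 1 (sexes fixed for opposite
alleles) and the het-call locus at θ = 0.5 (females all heterozygous); both
are classified for exclusion and molecular validation, with the sixfold
female coverage excess noted as corroborating evidence. The sex-ratio grid
shows that the *same* locus yields any θ between 0 and 1 depending purely on
the sex composition of the two samples (the −0.09 cells are the usual
Weir–Cockerham negative estimates at undifferentiated contrasts). And an HWE
filter on 30 individuals only catches a het-call artifact once at least 19
of them are the heterozygous sex.

The same commands run on real data: any VCF with GT fields plus a
tab-separated sample table (`id`, `population`, `sex`). Convert PLINK files
with `plink --bfile data --recode vcf --out data` first.

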