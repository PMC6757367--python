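# gsdiv

Genetic gain and genetic diversity under genomic selection.

`gsdiv` is a pipeline for quantifying how the switch from progeny-testing
selection (PTS) to genomic selection (GS) in a dairy-cattle breeding scheme
changed the rate of genetic gain and the rate of loss of genetic diversity.
It is written for quantitative geneticists and breeding-program analysts
who work with bull pedigrees and 50K-chip SNP genotypes, and it ships a
breeding-scheme simulator with exact identity-by-descent (IBD) ground
truth, so every stage of the pipeline can be validated even though real
bull datasets are proprietary.

## What it computes

**Pedigree-based diversity.** Inbreeding coefficients F_ped (the
probability that an individual's two alleles are IBD) via the tabular
Meuwissen–Luo recursion, kinship coefficients f_ped with
f(i,i) = ½(1 + F_i), the five-generation truncated F_ped, pedigree depth,
and the parental generation interval I₁ in months.

**ROH-based diversity.** Runs of homozygosity detected from PLINK
bed/bim/fam genotypes under the usual 50K-chip criteria (≥ 15 SNPs **and**
≥ 1000 kb, ≥ 1 SNP per 75 kb, no gap > 150 kb), after SNP call-rate (≥ 95%)
and MAF (≥ 1%) filtering. Genomic inbreeding is

    F_ROH,i = Σ L_ROH,i / L_auto,

where L_auto is the SNP-covered autosomal length after withholding gaps
longer than 150 kb, plus the per-individual mean ROH length
L_ROH,mean = Σ L_ROH / N_ROH.

**Demography.** Yearly cohort-size ratios S_i = N_i / N_2005, the
effective number of bulls

    Ne = 1 / Σ_i (o_i / Σ_j o_j)²

over offspring contributions o_i, Ne/n ratios, and percentile bootstrap
95% intervals (bulls resampled with replacement).

**Before/after trends.** Each variable Y (merit index, F_ped, mean
kinship, F_ROH, mean ROH length) is regressed on birth year with a
two-segment model around the regime change:

    Y = a₁ + b₁·x + ε          (pre years, 2005–2010)
    Y = a₂ + (b₁ + δ)·x + ε    (post years, 2012–2015)

The slope change δ is tested with an F-test; the relative change
RC = δ / |b₁| gives direction and magnitude of the change, and annual
rates convert to per-generation rates by multiplying by the mean
generation interval in years.

**Simulation.** A two-regime breeding-scheme simulator (shorter
generation interval, altered sire-usage skew and steeper merit trend
after the changepoint) plus gene dropping of labelled founder haplotypes
through the pedigree with Haldane recombination. Founder-origin labels
give each animal's true autozygous genome fraction F_true — the ground
truth against which F_ped and F_ROH are validated.

## Worked example

Simulate a national-breed-scale scheme (cohorts of ~140 bulls/year before
2011, ~120 after; parental age 70 → 36 months), then run the whole
pipeline on the exported files:

```bash
gsdiv simulate --seed 42 --out demo/sim
gsdiv run-all --pedigree demo/sim/sim_pedigree.csv --bfile demo/sim/sim \
              --index demo/sim/sim_index.csv --out demo/out --seed 42
```

`demo/out/trend_table.tsv` from this run (abridged):

| variable | b1      | b2     | delta  | p_delta | RC   |
|----------|---------|--------|--------|---------|------|
| index    | 0.86    | 3.57   | 2.71   | 1.7e-03 | 3.16 |
| F_ped    | 0.00038 | 0.0018 | 0.0014 | 0.23    | 3.61 |
| F_ROH    | 0.00008 | 0.0019 | 0.0018 | 0.25    | 22.1 |

Reading it: the merit index gained 0.86 points/year under progeny testing
and 3.57 points/year under genomic selection — a significant slope change
(p ≈ 0.002), i.e. the annual genetic gain more than tripled. The
inbreeding trends (fractions/year here) rose after the changepoint but not
significantly at this national-breed scale. `rates_per_generation.tsv`
shows the realized generation interval dropping from 5.8 to 3.0 years, and
`demography.json` reports the effective number of bulls (PTS: Ne ≈ 43 of
n = 840; GS: Ne ≈ 15 of n = 360, 95% CIs by bootstrap). On the same run,
F_ped and F_ROH correlate at r ≈ 0.78 across bulls, and F_ROH tracks the
simulator's true IBD fraction at r ≈ 0.98.

Every stage is also callable alone (`gsdiv pedstats`, `gsdiv roh`,
`gsdiv demography`, `gsdiv trends`) or from Python
(`gsdiv.fit_piecewise`, `gsdiv.detect_roh`, ...).

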