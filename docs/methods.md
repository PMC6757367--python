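# Methods

This note records the models, conventions and design choices behind
`gsdiv`, and what the simulated validation does and does not establish
about real data.

## Pedigree measures

Inbreeding F_ped is computed by the tabular (Meuwissen–Luo style)
recursion: with animals ordered parents-before-offspring, the
self-relationship a_ii = 1 + F_i of animal *i* is accumulated by tracing
its ancestor contributions L (halving per meiosis) against the
within-family segregation variances

    D_k = 0.5 − 0.25 (F_sire(k) + F_dam(k)),

with D = 1 for founders and D = 0.75 − 0.25 F_p when only one parent is
known. This is algebraically identical to Wright's sum over inbreeding
loops, Σ (½)^(n+1)(1 + F_A), but runs in polynomial time and handles
10⁵-scale pedigrees; the path-counting formula exists only as a test
oracle. Unknown parents are treated as non-inbred, unrelated founders —
the standard assumption, which makes pedigree estimates a lower bound on
realized autozygosity. Kinship tables are built from the additive
relationship recursion restricted to the ancestors of the requested set,
with f = A/2, so f(i,i) = ½(1 + F_i).

**Truncation to the last five generations.** "The last five generations"
is implemented by severing the parent links of every ancestor whose
minimum path distance from the nearest target equals the depth. Because an
ancestor can sit at different depths relative to different targets, the
truncated coefficient is computed per target on its own extracted
sub-pedigree and the per-target results are merged; this prevents one
animal's deep ancestry re-entering another's window. Truncating at depth
d and then d′ < d equals truncating at d′ directly (tested).

**Pedigree depth.** The primary definition is the longest ancestral path
(founder = 0). A mean-path alternative (1 + average over known parents,
recursively) is provided as `depth_mean_path` since summaries of
"generations traced" are sometimes computed either way.

**Generation interval I₁** is the mean, over parents with known birth
dates, of the child–parent birth-date difference, expressed in fixed
30.4375-day months (the calendar-mean month; no convention is standard, so
a reproducible one was fixed).

## Runs of homozygosity

Coordinates are 1-based inclusive; segment length = end − start + 1, with
segments spanning the physical positions of their first and last SNP.
Detection criteria (defaults): at least 15 SNPs **and** at least 1000 kb —
the conjunction, matching the scanner command line the criteria come from,
not the disjunction a literal reading of "15 SNPs or 1000 kb" would give —
at least one SNP per 75 kb (length_bp / n_snps ≤ 75 000), and no
inter-SNP gap above 150 kb inside a segment. Sex chromosomes and unplaced
contigs are excluded before detection; L_auto sums, over autosomes, the
SNP-covered span minus gaps above 150 kb.

Two modes:

* **windowed** (default, the sliding-window heuristic of common
  scanners): a 15-SNP window is homozygous if it contains ≤ 1
  heterozygote and ≤ 5 missing calls; a SNP is candidate-included when
  ≥ 5% of the windows covering it are homozygous; maximal candidate runs
  are split at oversized gaps and then size/density-filtered. The window
  knobs default to the cited tool's documented defaults and are
  configurable. Bit-exact reproduction of that tool (its kb rounding,
  overlapping-pool postprocessing) is out of scope.
* **strict**: maximal runs of homozygous non-missing calls (missing
  terminates a run), the same gap split and final filters. Only this mode
  admits an exact brute-force oracle; the test suite verifies it against
  exhaustive enumeration of every (start, end) pair on random panels, and
  the windowed mode converges to it as the window tolerances go to zero.

ROH length-class histograms default to half-open classes at
(1, 2, 4, 8, 16) Mb — a conventional choice, configurable, with boundary
segments assigned to the upper class.

## Demography

Ne = 1/Σ p_i² over offspring-contribution proportions; offspring counts
are taken from the pedigree by counting records naming the bull as sire.
The GS window for Ne is birth years 2012–2014 (younger bulls have
incomplete offspring records), distinct from the 2012–2015 trend window.
Confidence intervals are percentile bootstrap (B = 1000 by default),
resampling bulls — a bull with its offspring count — with replacement;
two regimes are declared different only when their 95% intervals are
strictly disjoint (touching counts as overlap, a conservative tie rule).
Bootstrap coverage was checked against a known multinomial contribution
model (100 parents, 5000 offspring): the interval covers the large-sample
Ne at or slightly above the nominal 95%.

## Trend model

The two-segment regression is fit as a single least-squares problem with
an intercept, a post-period indicator, centered year, and the
indicator×year interaction — no continuity constraint at the break, so
the level may jump while δ captures the slope change. Years are centered
at the first pre-period year for conditioning only; reported intercepts
are back-transformed. Animals born in the transition year (2011) are
excluded. p(δ) is the 1-df F-test of the interaction (equal to the
squared t-test); its type-I error at nominal 5% was measured at ≈ 0.04–0.06
over 2000 null simulations. RC = δ/|b₁| is undefined at b₁ = 0: the
scalar operation raises, while bulk trend tables report NaN for such
degenerate rows.

The "annual inbreeding rate" is the fitted slope of inbreeding against
birth year, matching how the published tables are built; the classical
ΔF = (F_t − F_{t−1})/(1 − F_{t−1}) is available separately
(`classical_delta_f`) and clearly labelled. Rates per generation multiply
the annual rate by the period's mean generation interval in years.
Group-mean comparisons use Welch's t-test (unequal variances — the safer
default where no pooling assumption is stated). The
pedigree-vs-genomic inbreeding correlation is Pearson's r with a
Fisher-z interval. Per-individual mean kinship (`f_ped_mean`) defaults to
each animal's mean kinship with the rest of its birth-year cohort, so the
cohort average equals the mean over within-year pairs; a within-period
variant is available (`scope="period"`), the within-year definition being
the default because year is the regression covariate.

A logarithmic-regression variant of the inbreeding trend is deliberately
not provided; linear residual diagnostics (square root of internally
studentized residuals, exported per year and period) cover model checking.

## Simulator

The generator emulates the study conditions of a national-breed bull
population observed 2005–2015 with a regime change in 2011:

| parameter | pre (PTS) | post (GS) | why |
|---|---|---|---|
| cohort size /yr | 140 | 120 | national-breed bull cohorts |
| mean parental age | 70 mo | 36 mo | interval reduction factor ≈ 1.9 |
| sire-usage skew s (w_k ∝ (1−s)^k) | 0.25 | 0.05 | few elite proven bulls vs broader young-bull use |
| sires ranked by | index (accuracy ≈ 0.6) | genomic proxy (≈ 0.86) | genomic evaluations raise selection accuracy |
| sire truncation fraction | 0.30 | 0.20 | intensified post-change selection |

Founders (80 males, 160 females over the nine preceding birth years — a
pool small enough that pedigree inbreeding accumulates at realistic
levels) carry a pre-existing genetic trend of 1 point/year, the
steady-state gain the PTS parameters sustain. The merit index follows the
usual convention: breeding value = parental mean + Mendelian-sampling
deviate (σ_g/√2 with σ_g = 12 points), observed with noise chosen so the
within-cohort SD is ≈ 20 points. Parent cohorts are drawn from the
parental-age distribution (SD 6 months) *before* merit ranking, so
realized generation intervals match the configured ages instead of being
dragged down by the younger cohorts' higher merit.

Gene dropping uses the Haldane model (Poisson crossovers, no
interference) on a uniform 1 cM/Mb map; the default desk-scale genome is
5 chromosomes × 100 Mb with chip-like ~62.5 kb jittered marker spacing
(1600 SNPs/chromosome), and a 29-autosome bovine-like preset is provided.
Founder haplotypes are in linkage equilibrium with per-SNP frequencies
uniform on [0.05, 0.5]; an optional block-copying mode introduces
background LD (relevant to haploblock structure in real breeds) but is
off by default. Allele states are realized lazily, so IBD-only studies
(tens of thousands of gene drops) skip the genotype cost.

## What the validation shows — and does not

* Exact algebra is checked exactly: tabular F against path counting
  (≤ 1e−12), strict ROH detection against exhaustive enumeration, Ne
  properties, published-table identities.
* The central cross-module check, E[F_true(child)] = f_ped(sire, dam)
  over 50 random pedigrees × 500 gene drops, ties the pedigree and
  genomic halves of the pipeline to the same IBD definition. The joint
  95%-CI coverage of (b₁, δ) at published effect magnitudes is ≈ 91%, so
  a 500-replicate estimate of it sits close to the 90% bound the test
  suite requires; the test asserts the bound at 2000 replicates.
* The simulated pedigree is shallow (2–3 generations by 2015): absolute
  F_ped levels stay below real-breed levels, five-generation truncation
  is a no-op on it (F_ped_5gen ≡ F_ped), and windowed F_ROH exceeds
  F_true by an identity-by-state margin at 50K-like density. Passing
  tests therefore demonstrate correctness of the estimators and the
  direction/magnitude mechanics of the regime change, not the absolute
  inbreeding levels of any real breed — those depend on deep real
  pedigrees and real LD structure, which the generator does not emulate.
* Breed-specific published results (effective sizes, mean ROH lengths,
  genome-coverage percentages, correlations of 50–59%) require the
  proprietary datasets and are out of scope; only their internal
  arithmetic is reproduced.

## Degenerate inputs and numerical conventions

Cycles and duplicate ids are load-time errors; unlisted parents become
founders with a warning. A chromosome with fewer SNPs than the window
yields no segments (warning); individuals without segments get F_ROH = 0
flagged by n_roh = 0. QC removes call-rate failures before computing MAF
on the survivors; "MAF lower than 1%" is strict, so MAF = 0.01 is kept.
All randomness flows from a single seed through spawned generator
streams; identical seeds reproduce byte-identical exports.
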