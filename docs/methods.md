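# Methods

`poolevo` analyses Pool-Seq time series from evolve-and-resequence (E&R)
experiments in which a genetically diverse but strictly asexual population —
a pool of diploid F2 genotypes from a cross of two homozygous strains —
adapts under serial transfer. This note documents the models behind each
stage, the simulator that stands in for deposited sequencing data, the
numerical choices, and what passing tests do and do not demonstrate.

## The data model

All frequency analyses run on a polarized site-by-sample table: biallelic
sites with per-sample read counts for the two parental alleles, with allele
A defined as the allele carried by the parent-A strain. Frequencies are
`count_A / (count_A + count_B)`; zero-depth cells are explicit `NaN`
(never silently 0). Coordinates are 1-based closed throughout; BED input is
converted on read. Sites where both parents carry the same allele are kept
at parse time — the de novo detection path needs them — and removed only by
the standing-variation filter.

## Variant filters

The standing-variation set applies, in order: (1) defined in every sample;
(2) per-sample depth ≥ 25× and ≤ that sample's own 95th depth percentile,
the percentile computed over all pre-filter sites (whether the original
analysis computed it before or after the missing-data step is not
documented; pre-filter is fixed here and recorded); (3) mappability = 1;
(4) MAF < 0.05 in each haploid parent (guards against mismapping and hidden
paralogy); (5) MAF > 0.3 in every founder sample (true F2 heterozygotes).
Criteria 3–5 are per-site independent, so their order cannot change the
retained set; the removal log attributes each site to the first criterion
it fails.

De novo detection looks for an allele absent from both parents (parental
frequency < 0.05) that is not monomorphically absent in the evolved
samples. Records with founder MAF ≥ 0.3 are set aside as pre-existing
variation; the rest are `putative`, upgraded to `denovo` at an observed
frequency ≥ 0.10 at any sampled generation and to `candidate` above 0.35.
Manual inspection of alignments is not automatable; it enters as an
optional per-site boolean (`curation_pass`, default true) that demotes
failed candidates. Mutations whose frequency trajectories are nearly
identical within a replicate (Pearson r ≥ 0.95 over ≥ 3 shared
generations, a threshold chosen here since the linkage criterion is
otherwise qualitative) share a linked-group id and count once as
independent events.

## Haplotype clusters

In an asexual population descended from single-recombination F2s, linkage
is genome-wide, so SNPs riding the same background share trajectories.
Per replicate: arcsine-square-root transform of each SNP's frequency series
(variance stabilization for binomial sampling), per-site centering and unit
scaling, pairwise Pearson correlation, average-linkage hierarchical
clustering on distance d = 1 − r. The generation-0 founder time point is
part of each series. For each cutoff c in 0.30–0.90 (step 0.05, a grid
resolution chosen here) the tree is cut at height 1 − c and blocks with at
least ten SNPs are counted; the chosen cutoff maximizes that count, with
ties going to the larger (tighter) cutoff. One representative SNP per
cluster is drawn with a seeded RNG.

Distance is signed (1 − r, not 1 − |r|): a real haplotype of mixed
parental ancestry produces mirror-image trajectories, and keeping mirrors
apart (distance 2 at r = −1) displays them as two clusters rather than
collapsing them — matching how such sweeps read in trajectory plots.
Zero-variance trajectories are excluded before correlation. Clusters may
span chromosomes by design; no physical phasing is attempted, and the
linkage-equilibrium machinery of sexual-population haplotype inference is
deliberately not used, since it does not apply to asexual data.

## Fixation dynamics

A site is nearly fixed when its MAF ≤ 0.1. Proportions are computed per
time point independently, so "unfixing" (sites returning to intermediate
frequency) is representable. Each replicate's series is fit by a
3-parameter logistic y(t) = L / (1 + exp(−k(t − t0))) with bounds
L ∈ [0, 1], k ≥ 0, initialized at L₀ = max y, t0₀ = first generation with
y ≥ L₀/2, k₀ = 0.01, using bounded least squares on raw proportions with
equal weights. The plateau time is the fitted curve's 95%-of-L crossing,
t0 + ln(19)/k, clamped at 0; the 0.95 quantile is configurable. Degenerate
rule: the k → 0 limit of this family is the constant L/2, so when the
fitted curve is flat over the observed range the reported L is the fitted
constant and the plateau time is the first observed generation.
Environment comparisons use Kruskal–Wallis and exact pairwise two-sided
rank-sum tests with Bonferroni correction — standard routines, called, not
re-derived; single-replicate environments are excluded from pairwise tests.

## Windowed parallelism

Non-overlapping 10-kb windows anchored at position 1 of each chromosome;
windows need ≥ 4 member SNPs; the window statistic is the median member
frequency, and a window is fixed for A when the median ≥ 0.9 (MAF ≤ 0.1,
mirroring the site-level threshold) and for B when ≤ 0.1. The environment
parallelism index is (#replicates fixed for A − #fixed for B)/n, in
[−1, 1]. For groups of replicates, "group fixed" requires every member
fixed for the same allele (the two-replicate case is unambiguous; larger
groups are this package's generalization). The analytic chance-overlap
null for two populations each dominated by one F2 genotype is
2 × (1/4)² = 1/8 per window — homozygosity for a specific allele is 1/4
under Mendelian segregation — and ignores within-genome linkage, exactly as
the back-of-envelope does; the Monte-Carlo property test covers the
unlinked case only.

## Copy number

Per sample: mean depth in 1-kb windows (partial windows averaged over
covered positions); windows above 2× the provisional chromosome mean
dropped in a single pass (the provisional mean is the pre-removal mean, a
one-pass reading of "remove outliers, then take the mean"); chromosomes
with a "smile" artifact — window SD above 15% of the chromosome mean AND
the middle third more than 15% below the outer thirds — are summarized by
the outer-third mean excluding a 20-kb subtelomeric margin at each end.
The thirds and the 20-kb margin are explicit stand-ins; no quantitative
definition of "center", "ends" or "subtelomeric" exists for this rule, and
all are configurable. The genome baseline is the unweighted mean of
per-chromosome effective means (a length-weighted mean and a median are
config options); calls are gain at relative depth ≥ 1.25 and loss at
≤ 0.75. Chromosomes with fewer than 10 windows get no call. A local query
compares a target interval (e.g., one gene) against ~100-kb flanks on the
same chromosome with the same ±25% convention.

One numerical caveat drives a config option: a gain at population
frequency f has expected relative depth 1 + f/2 **against a euploid
baseline**, but the aneuploid chromosome itself inflates a genome *mean*,
so the f where a call fires drifts below the nominal threshold. When the
exact threshold behaviour matters (the boundary case f = 0.5, where
1 + f/2 = 1.25 exactly), the median per-chromosome baseline
(`genome_stat="median"`) keeps the arithmetic exact; the default remains
the mean.

## The simulator

The generator emulates the experiment's structure, not its sequences:

- **Parents.** Alternating tracts with exponential lengths (mean 50 kb)
  over a 16-chromosome, ~12-Mb genome; each tract is identical between
  parents with probability 0.25 (divergence is block-distributed, with
  large identical regions); SNPs (default 10,000) fall uniformly on
  divergent tracts only.
- **Founder pool.** Each of 10,000 lineages is the union of two
  independent F1 gametes; crossovers are Poisson per chromosome at
  3.5 × 10⁻⁶ per bp (≈ 0.35 cM/kb, a yeast-like map). Expected per-site
  homozygosity of a random F2 is 0.5 (one intertetrad-style mating round).
  A configurable fraction of lineages are unmated haploids (founder
  contamination), off by default.
- **Evolution.** Lineages are genotype classes with frequencies. Each
  48-h transfer spans 7 generations: fitness w = Π(1 + s_b)^(copies of the
  selected allele at block b's central driver locus) × Π(1 + s_m)^(copies
  of each de novo mutation), applied as w⁷; events (de novo mutations at
  0.002 per genome per generation with exponential beneficial effects of
  mean 0.05, LOH tracts of exponential mean 50 kb at 10⁻⁵ per lineage per
  generation, aneuploidy gains/losses) each split a one-cell class off a
  frequency-weighted parent; then the dilution bottleneck draws a
  multinomial of census × survival cells and the culture regrows
  deterministically. The printed transfer volume of the emulated protocol
  (10 µl into 5 ml) reads "0.02%" but is 0.2%; the default survival is
  1/500, configurable, with 7 generations per transfer kept as the
  calibrated estimate. The census size defaults to the lineage count and
  can be set independently. One multinomial of N_b cells per g-generation
  transfer adds allele-frequency variance ≈ pq/(2N_b), i.e., an effective
  per-generation population size of g·N_b; across transfers with varying
  bottlenecks the harmonic mean of g·N_b applies. Total loss of the
  population (all fitness zero) is reported as an extinct result, not an
  error.
- **Observation.** Site depth is Poisson around mean · (chromosome copy
  ratio) · (per-site Gamma factor of mean 1, shape = `depth_dispersion`,
  default 5). The Gamma factor is derived from (chrom, pos) and shared by
  all samples: marginally negative-binomial depth, strongly correlated
  across samples, as real Pool-Seq coverage is (local context effects).
  Reads are binomial at the true frequency. An aneuploid chromosome at
  population copy ratio r scales expected depth by r; per-base depth
  tracks use the same scaling. Defaults: depth 100× (the emulated
  experiment spans ~30–780×), nine sampled generations
  (0–1000).
- **Truth.** Per-SNP divergence-block labels, true frequencies at sampled
  generations, per-transfer fixation generations, every planted mutation's
  trajectory and fate, and chromosome copy ratios are recorded for
  parameter-recovery tests. A separate planted-haplotype scenario supplies
  k block trajectories of known membership (sweep, collapse, clonal
  interference hump, crash-and-recover) with Pool-Seq noise only, for
  clustering recovery tests with controlled between-block correlation.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level artifacts (mapping error, paralogy,
indel realignment), variant-caller behaviour, GC- or flowcell-dependent
depth trends beyond the static per-site factor, the smile artifact's
actual cause, growth-phase structure within a transfer (fitness is one
scalar per genotype per environment), mutation spectra, and interference
between more than a handful of simultaneously segregating beneficial
mutations at experiment scale. Recovery rates measured here are therefore
upper bounds on what identical thresholds achieve on real libraries.

## Problem sizes

Unit and recovery tests run at desk scale by choice: hundreds of SNPs,
pools of 40–10,000 lineages, 10–60 transfers, 5–200 Monte-Carlo
replicates; the full suite completes in well under a minute and the
acceptance script (10,000 F2 genotypes at 1,000 SNPs) in seconds. The
statistical checks are calibrated to these sizes (tolerances state the
Monte-Carlo standard error they allow).

## Known limitations

- Selection acts at one driver locus per divergence block; polygenic
  within-block architecture is not modelled.
- LOH and aneuploidy events only apply cleanly to euploid chromosomes;
  stacked events on already-aneuploid chromosomes are skipped.
- The multi-hit gene probability is a binomial placement model under
  user-supplied gene weights; reported values are model-dependent and no
  claim is made that any published multi-hit probability is reproduced.
- `summarize_environments` requires ≥ 2 environments with fitted
  replicates; heterogeneous sampling designs (replicates measured at
  different generations) are supported but compared on fitted parameters
  only.
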