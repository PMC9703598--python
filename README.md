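# poolevo

Pool-Seq time-series analysis of adaptation in **asexual, genetically
diverse populations** — the evolve-and-resequence (E&R) design in which a
pool of diploid F2 yeast genotypes (from a cross of two homozygous strains)
adapts to stressful environments under serial transfer, and whole
populations are sequenced at a series of generations.

It is written for experimental evolution groups who have allele-depth
calls (VCF with `FORMAT/AD`), per-base depth tracks and a sample sheet,
and want the standard analyses of this design as a tested, scriptable
pipeline:

- **Standing variation**: the shared high-confidence SNP set (depth,
  mappability, parental homozygosity MAF < 0.05, founder heterozygosity
  MAF > 0.3), parent-A-polarized frequencies.
- **Haplotype clusters**: arcsine-square-root–normalized SNP trajectories,
  signed Pearson correlation, average-linkage clustering with a
  per-replicate cutoff sweep over 0.3–0.9 keeping blocks of ≥ 10 SNPs — a
  rough count of haplotypes segregating per population.
- **Fixation dynamics**: per-sample proportion of nearly fixed sites
  (MAF ≤ 0.1), per-replicate logistic fits
  y(t) = L/(1 + e^(−k(t−t0))) with plateau height L and 95%-of-L plateau
  time, Kruskal–Wallis / rank-sum comparisons across environments.
- **Genomic parallelism**: 10-kb windows (≥ 4 SNPs), median frequencies,
  the signed index (#replicates fixed for one parental allele − #fixed for
  the other)/n ∈ [−1, 1], shared-window counts between replicate groups,
  and the analytic F2 chance-overlap null 2·(1/4)² = 0.125 per window.
- **Copy number**: 1-kb window depth, outlier removal, ±25% aneuploidy
  calls with "smile"-artifact correction, and local gene-vs-flank ratios.
- **Small statistics**: mating-type fixation binomial, multi-hit gene
  probabilities under weighted placement, relative fitness
  OD_adapted/mean(OD_founder).
- **A simulator** (`poolevo.simulate`) that generates the whole design —
  block-structured parental divergence, recombinant F2 founder pools,
  serial-transfer evolution with selection, de novo mutations, LOH and
  aneuploidies, overdispersed Pool-Seq counts — plus ground truth, so
  every stage is testable without any sequencing data.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

The `demo` subcommand simulates a small two-environment experiment
(2 × 150 kb genome, 360 parental SNPs, 300 founder lineages, 2 replicates
per environment, 210 generations sampled at 7 time points, 80× depth) and
runs every stage on the files it wrote:

```sh
poolevo demo --out-dir demo --seed 3
cat demo/results/summary.txt
```

```
poolevo 0.1.0 run summary (seed 3)
[read] {"n_sites": 498, "n_samples": 27, "n_multiallelic_skipped": 0}
[filter] {"n_retained": 290, "removal_log": {"missing": 138, "depth": 70, "mappability": 0, "parent_maf": 0, "founder_maf": 0}}
[denovo] {"EtOH": {"putative": 49, "denovo": 16, "candidate": 10, ...}, "NaCl": {"putative": 50, "denovo": 18, "candidate": 11, ...}}
[haplotypes] {"EtOH_R1": {"cutoff": 0.9, "n_clusters": 3}, "EtOH_R2": {"cutoff": 0.9, "n_clusters": 4}, "NaCl_R1": {"cutoff": 0.3, "n_clusters": 8}, "NaCl_R2": {"cutoff": 0.8, "n_clusters": 6}}
[fixation] {"kruskal_L": [2.4, 0.121], "kruskal_plateau": [0.0, 1.0]}
[parallelism] {"n_windows": 30, "n_dropped_windows": 0}
[cnv] {"n_samples": 24, "n_calls": 0}
```

Reading it: of 498 VCF records (360 parental SNPs + de novo sites), 290
survive the standing-variation filter — the de novo rows are removed as
"missing" because they are uncalled in other replicates, and 70 sites fall
outside the per-sample depth band. Each replicate's surviving SNP
trajectories collapse into a handful of haplotype blocks at its chosen
correlation cutoff. The logistic fits (in `fixation_fits.tsv`) put the
EtOH replicates' plateau at L ≈ 0.92–0.97 by generation ~100 — these runs
swept a nearly homozygous genotype — and the Kruskal–Wallis H on L across
the two environments is 2.4 (p = 0.12, n = 2 + 2). No aneuploidies were
planted, and none are called across 24 depth tracks.

Every stage is also a library call (`filter_standing_variants`,
`cluster_haplotypes`, `fit_sigmoid`, `make_windows`, `chromosome_summary`,
…) and a separate subcommand (`simulate`, `filter-standing`,
`detect-denovo`, `haplotypes`, `fixation`, `parallelism`, `cnv`, `stats`,
`run`).

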