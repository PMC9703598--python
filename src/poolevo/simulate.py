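"""Synthetic evolve-and-resequence data with ground truth.

The simulator emulates the structure of a yeast cross-and-evolve experiment:
two fully homozygous parental strains whose divergence is distributed in
blocks (some chromosomal regions identical between strains), a pooled diploid
F2 founder produced by one round of meiosis from the F1 heterozygote, serial
asexual transfer with selection on haplotype blocks, de novo mutations, loss
of heterozygosity (LOH), optional haploid contamination of the founder,
aneuploidy events, and Pool-Seq read sampling with overdispersed depth.

Lineages are tracked as genotype classes (arrays of allele copies per site),
so populations of 10^4 or more founders evolve in seconds at desk scale while
every quantity the analysis pipeline consumes has an exact truth value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import DepthTrack, SampleMeta, SiteTable

# S. cerevisiae R64 chromosome lengths (bp), the genome the experiment mapped to.
YEAST_CHROM_LENGTHS = (
    230218, 813184, 316620, 1531933, 576874, 270161, 1090940, 562643,
    439888, 745751, 666816, 1078177, 924431, 784333, 1091291, 948066,
)


@dataclass
class SimulationConfig:
    """Parameters of one evolve-and-resequence run.

    Defaults describe the emulated experiment: a ~12 Mb, 16-chromosome
    genome, ~10^4 parental SNPs in divergence blocks, a pool of 10^4 diploid
    F2 lineages, serial transfer with a 1/500 dilution bottleneck and ~7
    generations per transfer, and Pool-Seq sampling at the experiment's nine
    time points.
    """

    chrom_lengths: tuple[int, ...] = YEAST_CHROM_LENGTHS
    n_parental_snps: int = 10_000
    mean_block_length: float = 50_000.0
    proportion_identical: float = 0.25
    pool_size: int = 10_000
    census_size: int | None = None  # cells at transfer; defaults to pool_size
    transfer_count: int = 143
    generations_per_transfer: int = 7
    dilution_survival: float = 1.0 / 500.0
    crossover_rate_per_bp: float = 3.5e-6  # ~0.35 cM/kb, a yeast-like map
    selection: dict = field(default_factory=dict)  # env -> {block_id: s per A copy}
    environment: str = "NaCl"
    de_novo_rate: float = 0.002  # per genome per generation
    de_novo_effect_mean: float = 0.05  # exponential mean of beneficial s
    loh_rate: float = 1e-5  # per lineage per generation
    loh_tract_mean: float = 50_000.0  # bp
    haploidization_prob: float = 0.0  # unmated haploids in the founder pool
    aneuploidy_rate: float = 0.0  # per lineage per generation
    aneuploidy_gain_prob: float = 0.8
    depth_mean: float = 100.0
    depth_dispersion: float = 5.0  # NB size; var = m + m^2/size
    sampled_generations: tuple[int, ...] = (0, 30, 60, 100, 200, 300, 400, 500, 700, 1000)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_novo_rate", "loh_rate", "aneuploidy_rate", "crossover_rate_per_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dilution_survival",):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if not (0 <= self.proportion_identical < 1):
            raise ValueError("proportion_identical must be in [0, 1)")
        if not (0 <= self.haploidization_prob <= 1):
            raise ValueError("haploidization_prob must be in [0, 1]")
        if self.generations_per_transfer <= 0:
            raise ValueError("generations_per_transfer must be > 0")
        if self.pool_size < 2:
            raise ValueError("pool_size must be >= 2")

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_lengths)

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chroms)]

    @property
    def total_generations(self) -> int:
        return self.transfer_count * self.generations_per_transfer


@dataclass
class Parents:
    """Two homozygous parental haplotypes and their divergent-block structure."""

    chrom_names: list[str]
    chrom_lengths: tuple[int, ...]
    blocks: pd.DataFrame  # chrom_idx, start, end, divergent, block_id (-1 if identical)
    snp_chrom: np.ndarray  # chromosome index per SNP
    snp_pos: np.ndarray  # 1-based position per SNP
    snp_block: np.ndarray  # divergent-block id per SNP
    allele_a: np.ndarray  # parent-A base per SNP
    allele_b: np.ndarray  # parent-B base per SNP

    @property
    def n_snps(self) -> int:
        return len(self.snp_pos)

    @property
    def n_blocks(self) -> int:
        return int(self.snp_block.max()) + 1 if self.n_snps else 0


@dataclass
class F2Pool:
    """Founder pool: per lineage, two gametes of parent-A/B ancestry flags."""

    parents: Parents
    hap1: np.ndarray  # (n_lineages, n_snps) bool, True = parent-A allele
    hap2: np.ndarray
    ploidy: np.ndarray  # (n_lineages,) 1 for unmated haploids, else 2

    @property
    def n_lineages(self) -> int:
        return self.hap1.shape[0]

    def homozygosity(self) -> np.ndarray:
        """Per-lineage fraction of parental SNPs at which it is homozygous."""
        hom = self.hap1 == self.hap2
        out = hom.mean(axis=1)
        out[self.ploidy == 1] = 1.0
        return out

    def allele_frequencies(self) -> np.ndarray:
        """Pool frequency of the parent-A allele at each SNP (equal lineage weights)."""
        a = self.hap1.astype(np.int32) + self.hap2.astype(np.int32)
        n = np.full(self.n_lineages, 2, dtype=np.int32)
        hap = self.ploidy == 1
        if hap.any():
            a[hap] = self.hap1[hap].astype(np.int32)
            n[hap] = 1
        return a.sum(axis=0) / n.sum()


@dataclass
class PlantedMutation:
    chrom: str
    pos: int
    selection_coefficient: float
    birth_generation: int
    trajectory: dict[int, float] = field(default_factory=dict)  # sampled gen -> true freq
    final_fate: str = "segregating"  # fixed / lost / segregating

    @property
    def max_frequency(self) -> float:
        return max(self.trajectory.values(), default=0.0)


@dataclass
class TruthSet:
    """Ground truth of one simulated run, for parameter-recovery tests."""

    snp_block: np.ndarray
    true_freq: dict[int, np.ndarray]  # sampled generation -> freq_A per SNP
    founder_freq: np.ndarray
    mutations: list[PlantedMutation]
    chrom_copy_ratio: dict[int, np.ndarray]  # sampled generation -> ratio per chromosome
    fixation_generation: np.ndarray  # per SNP; -1 if never fixed
    extinct: bool = False
    extinction_generation: int | None = None
    achieved_generations: dict[int, int] = field(default_factory=dict)


def _rng(seed, *stream) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *stream]))


def generate_parents(config: SimulationConfig, seed: int | None = None) -> Parents:
    """Draw the divergent-block structure and place parental SNPs inside it.

    Each chromosome is segmented into alternating tracts with exponentially
    distributed lengths (mean ``mean_block_length``); a tract is identical
    between parents with probability ``proportion_identical``. SNPs fall
    uniformly on the divergent tracts only.
    """
    rng = _rng(config.rng_seed if seed is None else seed, 1)
    rows = []
    block_id = 0
    for ci, length in enumerate(config.chrom_lengths):
        pos = 1
        while pos <= length:
            seg = max(1, int(rng.exponential(config.mean_block_length)))
            end = min(length, pos + seg - 1)
            divergent = (
                True if config.proportion_identical == 0
                else rng.random() >= config.proportion_identical
            )
            rows.append((ci, pos, end, divergent, block_id if divergent else -1))
            if divergent:
                block_id += 1
            pos = end + 1
    blocks = pd.DataFrame(rows, columns=["chrom_idx", "start", "end", "divergent", "block_id"])

    div = blocks[blocks["divergent"]]
    capacity = int((div["end"] - div["start"] + 1).sum())
    if capacity < config.n_parental_snps:
        raise ValueError(
            f"divergent regions hold {capacity} bp but {config.n_parental_snps} SNPs requested"
        )
    seg_len = (div["end"] - div["start"] + 1).to_numpy()
    offsets = rng.choice(capacity, size=config.n_parental_snps, replace=False)
    offsets.sort()
    cum = np.concatenate([[0], np.cumsum(seg_len)])
    seg_idx = np.searchsorted(cum, offsets, side="right") - 1
    snp_pos = div["start"].to_numpy()[seg_idx] + (offsets - cum[seg_idx])
    snp_chrom = div["chrom_idx"].to_numpy()[seg_idx]
    snp_block = div["block_id"].to_numpy()[seg_idx]

    bases = np.array(list("ACGT"))
    ia = rng.integers(0, 4, size=config.n_parental_snps)
    ib = (ia + rng.integers(1, 4, size=config.n_parental_snps)) % 4
    return Parents(
        chrom_names=config.chrom_names,
        chrom_lengths=config.chrom_lengths,
        blocks=blocks,
        snp_chrom=snp_chrom.astype(np.int64),
        snp_pos=snp_pos.astype(np.int64),
        snp_block=snp_block.astype(np.int64),
        allele_a=bases[ia],
        allele_b=bases[ib],
    )


def _gametes(parents: Parents, n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n recombinant F1 gametes as parent-A ancestry flags per SNP."""
    out = np.empty((n, parents.n_snps), dtype=bool)
    for ci, length in enumerate(parents.chrom_lengths):
        sel = parents.snp_chrom == ci
        if not sel.any():
            continue
        pos = parents.snp_pos[sel]
        n_xo = rng.poisson(rate * length, size=n)
        start = rng.random(n) < 0.5
        for i in range(n):
            if n_xo[i] == 0:
                out[i, sel] = start[i]
            else:
                xo = np.sort(rng.integers(1, length + 1, size=n_xo[i]))
                parity = np.searchsorted(xo, pos, side="left") % 2
                out[i, sel] = np.where(parity == 0, start[i], ~start[i])
    return out


def generate_f2_pool(parents: Parents, config: SimulationConfig, seed: int | None = None) -> F2Pool:
    """Build the founder pool: each F2 is the union of two independent gametes.

    Crossovers are Poisson per chromosome (rate ``crossover_rate_per_bp`` ×
    length) with uniform positions, so the expected per-site homozygosity of
    a random F2 is 0.5 (inbreeding coefficient of one intertetrad-style
    mating round). With probability ``haploidization_prob`` a lineage is an
    unmated haploid gamete instead.
    """
    if config.pool_size < 2:
        raise ValueError("pool_size must be >= 2")
    rng = _rng(config.rng_seed if seed is None else seed, 2)
    n = config.pool_size
    h1 = _gametes(parents, n, config.crossover_rate_per_bp, rng)
    h2 = _gametes(parents, n, config.crossover_rate_per_bp, rng)
    ploidy = np.full(n, 2, dtype=np.int8)
    if config.haploidization_prob > 0:
        hap = rng.random(n) < config.haploidization_prob
        ploidy[hap] = 1
        h2[hap] = h1[hap]
    return F2Pool(parents=parents, hap1=h1, hap2=h2, ploidy=ploidy)


class PopulationExtinct(Exception):
    """Raised internally; surfaced as TruthSet.extinct rather than an error."""


class _State:
    """Mutable genotype-class state during evolution.

    ``acount`` (copies carrying the parent-A allele per site) and ``copies``
    (chromosome copy number per class) are authoritative for frequencies and
    depth; the gamete matrices ``h1``/``h2`` identify homologs for LOH and
    aneuploidy events and are kept consistent for euploid classes.
    """

    def __init__(self, pool: F2Pool, config: SimulationConfig):
        self.parents = pool.parents
        self.config = config
        n = pool.n_lineages
        self.h1 = pool.hap1.copy()
        self.h2 = pool.hap2.copy()
        self.ploidy = pool.ploidy.copy()
        self.copies = np.repeat(
            self.ploidy[:, None], len(config.chrom_lengths), axis=1
        ).astype(np.int8)
        self.acount = (pool.hap1.astype(np.int8) + pool.hap2.astype(np.int8))
        hap = self.ploidy == 1
        if hap.any():
            self.acount[hap] = pool.hap1[hap].astype(np.int8)
        self.freq = np.full(n, 1.0 / n)
        self.mut_count = np.zeros((n, 0), dtype=np.int8)
        self.mut_s: list[float] = []
        self.mut_chrom_idx: list[int] = []
        self.mutations: list[PlantedMutation] = []

    # -- derived quantities -------------------------------------------------
    def site_freq(self) -> np.ndarray:
        num = self.freq @ self.acount.astype(np.float64)
        den = self.freq @ self.copies[:, self.parents.snp_chrom].astype(np.float64)
        with np.errstate(invalid="ignore"):
            f = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        return np.clip(f, 0.0, 1.0)

    def mut_freq(self) -> np.ndarray:
        if self.mut_count.shape[1] == 0:
            return np.zeros(0)
        num = self.freq @ self.mut_count.astype(np.float64)
        den = self.freq @ self.copies[:, self.mut_chrom_idx].astype(np.float64)
        return num / np.maximum(den, 1e-300)

    def chrom_ratio(self) -> np.ndarray:
        return (self.freq @ self.copies.astype(np.float64)) / 2.0

    def fitness(self) -> np.ndarray:
        w = np.ones(self.h1.shape[0])
        sel = self.config.selection.get(self.config.environment, {})
        for block, s in sel.items():
            driver = self._driver_snp(int(block))
            w *= (1.0 + s) ** self.acount[:, driver].astype(float)
        for j, s in enumerate(self.mut_s):
            carriers = self.mut_count[:, j] > 0
            if carriers.any():
                w[carriers] *= (1.0 + s) ** self.mut_count[carriers, j].astype(float)
        return w

    def _driver_snp(self, block: int) -> int:
        idx = np.flatnonzero(self.parents.snp_block == block)
        if len(idx) == 0:
            raise ValueError(f"selection on block {block} but no SNPs in it")
        return int(idx[len(idx) // 2])

    # -- event machinery ----------------------------------------------------
    def spawn(self, parent_idx: int) -> int:
        """Clone one class into a new zero-frequency class; returns its index."""
        sl = slice(parent_idx, parent_idx + 1)
        self.h1 = np.vstack([self.h1, self.h1[sl]])
        self.h2 = np.vstack([self.h2, self.h2[sl]])
        self.acount = np.vstack([self.acount, self.acount[sl]])
        self.ploidy = np.append(self.ploidy, self.ploidy[parent_idx])
        self.copies = np.vstack([self.copies, self.copies[sl]])
        self.freq = np.append(self.freq, 0.0)
        if self.mut_count.shape[1]:
            self.mut_count = np.vstack([self.mut_count, self.mut_count[sl]])
        else:
            self.mut_count = np.zeros((len(self.freq), 0), dtype=np.int8)
        return len(self.freq) - 1

    def compact(self) -> None:
        keep = self.freq > 0
        if keep.all():
            return
        self.h1, self.h2 = self.h1[keep], self.h2[keep]
        self.acount = self.acount[keep]
        self.ploidy, self.copies = self.ploidy[keep], self.copies[keep]
        self.freq = self.freq[keep]
        self.mut_count = self.mut_count[keep]


def evolve_pool(
    pool: F2Pool, config: SimulationConfig, seed: int | None = None
) -> tuple[TruthSet, _State]:
    """Serial-transfer evolution of the founder pool; returns truth + final state.

    Each transfer applies ``generations_per_transfer`` generations of
    multiplicative selection to the lineage frequencies, plants de novo
    mutation / LOH / aneuploidy events at their per-lineage-per-generation
    rates, then passes the population through the dilution bottleneck
    (multinomial sample of ``pool_size × dilution_survival`` cells) and
    regrows it deterministically.
    """
    rng = _rng(config.rng_seed if seed is None else seed, 3)
    st = _State(pool, config)
    cfg = config
    n_census = cfg.census_size or cfg.pool_size
    g = cfg.generations_per_transfer
    chrom_of = {name: i for i, name in enumerate(cfg.chrom_names)}

    # map requested sampled generations to achieved transfer boundaries
    achieved = {}
    for r in cfg.sampled_generations:
        a = int(round(r / g)) * g
        a = min(a, cfg.total_generations)
        achieved[r] = a
    record_at = {}
    for r, a in achieved.items():
        record_at.setdefault(a, []).append(r)

    truth = TruthSet(
        snp_block=st.parents.snp_block.copy(),
        true_freq={},
        founder_freq=pool.allele_frequencies(),
        mutations=st.mutations,
        chrom_copy_ratio={},
        fixation_generation=np.full(st.parents.n_snps, -1, dtype=np.int64),
        achieved_generations=achieved,
    )

    per_transfer_freq: list[np.ndarray] = []

    def record(gen: int) -> None:
        if gen in record_at:
            f = st.site_freq()
            ratio = st.chrom_ratio()
            mf = st.mut_freq()
            for r in record_at[gen]:
                truth.true_freq[r] = f.copy()
                truth.chrom_copy_ratio[r] = ratio.copy()
                for j, m in enumerate(st.mutations):
                    m.trajectory[r] = float(mf[j]) if j < len(mf) else 0.0

    record(0)
    extinct_at = None
    for t in range(1, cfg.transfer_count + 1):
        gen = t * g
        w = st.fitness()
        sel = st.freq * w**g
        tot = sel.sum()
        if tot <= 0:
            extinct_at = gen
            break
        p = sel / tot

        # events during this transfer (rates are per lineage per generation)
        lam = n_census * g

        def split_off(parent: int) -> tuple[int, np.ndarray]:
            """Spawn a one-cell class off ``parent`` within the working vector p."""
            nonlocal p
            idx = st.spawn(parent)
            take = min(1.0 / n_census, p[parent])
            p = np.append(p, take)
            p[parent] -= take
            return idx, p

        n_mut = rng.poisson(cfg.de_novo_rate * lam)
        for _ in range(n_mut):
            parent = int(rng.choice(len(p), p=p / p.sum()))
            ci = int(rng.integers(cfg.n_chroms))
            pos = int(rng.integers(1, cfg.chrom_lengths[ci] + 1))
            s = float(rng.exponential(cfg.de_novo_effect_mean))
            idx, p = split_off(parent)
            st.mut_count = np.hstack(
                [st.mut_count, np.zeros((st.mut_count.shape[0], 1), dtype=np.int8)]
            )
            st.mut_count[idx, -1] = 1  # born heterozygous in one lineage
            st.mut_s.append(s)
            st.mut_chrom_idx.append(ci)
            st.mutations.append(
                PlantedMutation(
                    chrom=cfg.chrom_names[ci], pos=pos,
                    selection_coefficient=s, birth_generation=gen,
                )
            )

        n_loh = rng.poisson(cfg.loh_rate * lam)
        for _ in range(n_loh):
            parent = int(rng.choice(len(p), p=p / p.sum()))
            if st.ploidy[parent] == 1:
                continue
            ci = int(rng.integers(cfg.n_chroms))
            length = cfg.chrom_lengths[ci]
            start = int(rng.integers(1, length + 1))
            end = min(length, start + max(1, int(rng.exponential(cfg.loh_tract_mean))))
            idx, p = split_off(parent)
            region = (st.parents.snp_chrom == ci) & (st.parents.snp_pos >= start) & (
                st.parents.snp_pos <= end
            )
            if rng.random() < 0.5:
                st.h2[idx, region] = st.h1[idx, region]
            else:
                st.h1[idx, region] = st.h2[idx, region]
            if st.copies[idx, ci] == 2:  # keep acount authoritative for euploid chrom
                st.acount[idx, region] = (
                    st.h1[idx, region].astype(np.int8) + st.h2[idx, region].astype(np.int8)
                )
            for j, m in enumerate(st.mutations):
                if chrom_of[m.chrom] == ci and start <= m.pos <= end and st.mut_count[idx, j] == 1:
                    st.mut_count[idx, j] = 2 if rng.random() < 0.5 else 0

        n_ane = rng.poisson(cfg.aneuploidy_rate * lam)
        for _ in range(n_ane):
            parent = int(rng.choice(len(p), p=p / p.sum()))
            ci = int(rng.integers(cfg.n_chroms))
            gain = rng.random() < cfg.aneuploidy_gain_prob
            if st.copies[parent, ci] != 2:
                continue  # only euploid chromosomes gain/lose a copy here
            idx, p = split_off(parent)
            on_chrom = st.parents.snp_chrom == ci
            use_h1 = bool(rng.random() < 0.5)
            homolog = (st.h1 if use_h1 else st.h2)[idx, on_chrom].astype(np.int8)
            if gain:
                st.copies[idx, ci] = 3
                st.acount[idx, on_chrom] += homolog
            else:
                st.copies[idx, ci] = 1
                st.acount[idx, on_chrom] -= homolog
                kept = (st.h2 if use_h1 else st.h1)[idx, on_chrom]
                st.h1[idx, on_chrom] = kept
                st.h2[idx, on_chrom] = kept

        # dilution bottleneck
        n_b = max(1, int(round(n_census * cfg.dilution_survival)))
        counts = rng.multinomial(n_b, p / p.sum())
        st.freq = counts / counts.sum()
        st.compact()

        f = st.site_freq()
        per_transfer_freq.append(f)
        record(gen)

    if extinct_at is not None:
        truth.extinct = True
        truth.extinction_generation = extinct_at
        # freeze remaining sampled generations at the last recorded state
        for r, a in achieved.items():
            if a >= extinct_at and r not in truth.true_freq:
                truth.true_freq[r] = per_transfer_freq[-1] if per_transfer_freq else (
                    truth.founder_freq.copy()
                )
                truth.chrom_copy_ratio[r] = st.chrom_ratio()

    # fixation generation: first transfer boundary at which a site is at 0/1
    # and stays there for the rest of the run
    if per_transfer_freq:
        mat = np.vstack(per_transfer_freq)  # transfers × snps
        at_bound = (mat <= 1e-12) | (mat >= 1 - 1e-12)
        fixed_from = np.flip(np.logical_and.accumulate(np.flip(at_bound, 0), 0), 0)
        first = fixed_from.argmax(axis=0)
        ever = fixed_from.any(axis=0)
        truth.fixation_generation[ever] = (first[ever] + 1) * g

    # mutation fates
    final_mf = st.mut_freq()
    for j, m in enumerate(st.mutations):
        f = final_mf[j] if j < len(final_mf) else 0.0
        m.final_fate = "fixed" if f >= 1 - 1e-9 else ("lost" if f <= 1e-9 else "segregating")
    return truth, st


def negative_binomial_depth(
    mean: float, dispersion: float, size, rng: np.random.Generator
) -> np.ndarray:
    """Overdispersed Pool-Seq depth: NB with var = m + m²/dispersion."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(np.int64)


def poolseq_counts(
    true_freq: np.ndarray,
    depth_mean: float | np.ndarray,
    dispersion: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (count_A, depth): NB depth, then binomial reads at the true frequency."""
    true_freq = np.asarray(true_freq, dtype=float)
    mean = np.broadcast_to(np.asarray(depth_mean, dtype=float), true_freq.shape)
    p = dispersion / (dispersion + np.maximum(mean, 1e-300))
    depth = rng.negative_binomial(dispersion, p, size=true_freq.shape).astype(np.int64)
    depth[mean <= 0] = 0
    safe = np.nan_to_num(true_freq, nan=0.0).clip(0, 1)
    count_a = rng.binomial(depth, safe)
    return count_a, depth


def _site_depth_factors(
    chroms: Sequence[str], positions: Sequence[int], dispersion: float, seed: int
) -> np.ndarray:
    """Deterministic per-site depth multipliers shared across all samples.

    Pool-Seq coverage varies along the genome in a way that is largely
    reproducible between libraries (local GC, mappability); modelling it as
    a per-site Gamma factor (mean 1, shape = ``dispersion``) shared by every
    sample reproduces both the overdispersed marginal depth (negative
    binomial) and the strong cross-sample depth correlation real data shows.
    Factors are derived from (chrom, pos) so the same site gets the same
    factor in every replicate's table.
    """
    import zlib

    from scipy.stats import gamma

    u = np.empty(len(positions))
    base = int(seed) & 0x7FFFFFFF
    for i, (c, p) in enumerate(zip(chroms, positions)):
        rr = np.random.default_rng(
            np.random.SeedSequence([base, zlib.crc32(str(c).encode()), int(p)])
        )
        u[i] = rr.random()
    return gamma.ppf(np.clip(u, 1e-12, 1 - 1e-12), a=dispersion) / dispersion


@dataclass
class SampledData:
    """One replicate's Pool-Seq observables plus sample metadata."""

    site_table: SiteTable
    metas: list[SampleMeta]
    truth: TruthSet


def sample_poolseq(
    truth: TruthSet,
    parents: Parents,
    config: SimulationConfig,
    seed: int | None = None,
    environment: str | None = None,
    replicate: str = "R1",
    generations: Sequence[int] | None = None,
) -> SampledData:
    """Observe one evolved replicate by Pool-Seq at the sampled generations.

    Emits a polarized :class:`SiteTable` containing the parental samples
    (pure reads for their own allele), the founder pool at generation 0, and
    one evolved sample per requested generation. De novo mutation sites are
    appended as extra rows whose B allele is absent from both parents.
    Depth is Poisson around a per-site Gamma factor shared across samples
    (negative-binomial marginally, correlated between samples as in real
    Pool-Seq); expected depth on an aneuploid chromosome at population copy
    ratio r is scaled by r.
    """
    rng = _rng(config.rng_seed if seed is None else seed, 4)
    env = environment or config.environment
    gens = list(config.sampled_generations if generations is None else generations)
    for r in gens:
        if r not in truth.true_freq:
            raise ValueError(f"generation {r} was not sampled in this run")

    # site frame: parental SNPs plus planted mutation positions
    chrom_idx = {name: i for i, name in enumerate(parents.chrom_names)}
    base_sites = pd.DataFrame(
        {
            "chrom": [parents.chrom_names[c] for c in parents.snp_chrom],
            "pos": parents.snp_pos,
            "allele_A": parents.allele_a,
            "allele_B": parents.allele_b,
            "variant_class": "SNP",
        }
    )
    mut_rows = []
    kept_muts = []
    for m in truth.mutations:
        if max(m.trajectory.get(r, 0.0) for r in gens) <= 0:
            continue  # never seen at a sampled generation
        kept_muts.append(m)
        mut_rows.append((m.chrom, m.pos, "A", "T", "SNP"))
    mut_sites = pd.DataFrame(
        mut_rows, columns=["chrom", "pos", "allele_A", "allele_B", "variant_class"]
    )

    samples: list[str] = ["parentA", "parentB", "founder"]
    metas = [
        SampleMeta("parentA", "parent_A"),
        SampleMeta("parentB", "parent_B"),
        SampleMeta("founder", "founder", environment=env, replicate=replicate, generation=0),
    ]
    for r in gens:
        if r == 0:
            continue
        sid = f"{env}_{replicate}_g{r}"
        samples.append(sid)
        metas.append(SampleMeta(sid, "evolved", environment=env, replicate=replicate, generation=r))

    n_base, n_mut = len(base_sites), len(mut_sites)
    n_sites = n_base + n_mut
    count_a = np.zeros((n_sites, len(samples)), dtype=np.int64)
    count_b = np.zeros_like(count_a)

    base_factor = _site_depth_factors(
        base_sites["chrom"], base_sites["pos"], config.depth_dispersion, config.rng_seed
    )
    mut_factor = _site_depth_factors(
        mut_sites["chrom"], mut_sites["pos"], config.depth_dispersion, config.rng_seed
    ) if n_mut else np.zeros(0)

    def fill(j: int, freq_a_base: np.ndarray, freq_b_mut: np.ndarray, depth_scale: np.ndarray):
        mean_base = config.depth_mean * depth_scale[parents.snp_chrom] * base_factor
        dp = rng.poisson(mean_base)
        ca = rng.binomial(dp, np.nan_to_num(freq_a_base, nan=0.0).clip(0, 1))
        count_a[:n_base, j] = ca
        count_b[:n_base, j] = dp - ca
        if n_mut:
            mci = np.array([chrom_idx[m.chrom] for m in kept_muts])
            mean_mut = config.depth_mean * depth_scale[mci] * mut_factor
            dp = rng.poisson(mean_mut)
            cb = rng.binomial(dp, np.nan_to_num(freq_b_mut, nan=0.0).clip(0, 1))
            count_b[n_base:, j] = cb
            count_a[n_base:, j] = dp - cb

    ones = np.ones(config.n_chroms)
    fill(0, np.ones(n_base), np.zeros(n_mut), ones)   # parent A: all A alleles
    fill(1, np.zeros(n_base), np.zeros(n_mut), ones)  # parent B: all B alleles
    fill(2, truth.founder_freq, np.zeros(n_mut), ones)
    j = 3
    for r in gens:
        if r == 0:
            continue
        ratio = truth.chrom_copy_ratio.get(r, ones)
        mut_f = np.array([m.trajectory.get(r, 0.0) for m in kept_muts])
        fill(j, truth.true_freq[r], mut_f, ratio)
        j += 1

    sites = pd.concat([base_sites, mut_sites], ignore_index=True)
    order = sites.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    table = SiteTable(
        sites=sites.iloc[order].reset_index(drop=True),
        samples=samples,
        count_a=count_a[order],
        count_b=count_b[order],
    )
    return SampledData(site_table=table, metas=metas, truth=truth)


def sample_depth_track(
    truth: TruthSet,
    config: SimulationConfig,
    generation: int,
    seed: int | None = None,
) -> DepthTrack:
    """Per-base depth track for one sampled generation (desk-scale genomes).

    Expected depth per position is the configured mean scaled by the
    population chromosome copy ratio at that generation.
    """
    if generation not in truth.chrom_copy_ratio:
        raise ValueError(f"generation {generation} was not sampled in this run")
    rng = _rng(config.rng_seed if seed is None else seed, 5, generation)
    ratio = truth.chrom_copy_ratio[generation]
    frames = []
    for ci, (name, length) in enumerate(zip(config.chrom_names, config.chrom_lengths)):
        depth = negative_binomial_depth(
            config.depth_mean * ratio[ci], config.depth_dispersion, length, rng
        )
        frames.append(
            pd.DataFrame({"chrom": name, "pos": np.arange(1, length + 1), "depth": depth})
        )
    return DepthTrack(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# planted-haplotype scenario: known block trajectories + Pool-Seq noise only
# ---------------------------------------------------------------------------

def planted_block_frequencies(
    generations: Sequence[int],
    n_blocks: int = 4,
    n_snps_per_block: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted haplotype-block trajectories for clustering-recovery tests.

    Returns (freq, labels): ``freq`` is sites × generations of true parent-A
    frequencies, ``labels`` the block id per site. Block 0 is a selective
    sweep; the others lose out at different rates, one transiently rising
    before collapsing (clonal interference) and one crashing then recovering.
    Shapes are chosen so that distinct blocks are not near-perfectly
    correlated in either sign over the experiment's sampling grid.
    """
    t = np.asarray(list(generations), dtype=float)
    shapes = [
        1.0 / (1.0 + np.exp(-0.02 * (t - 250.0))),            # sweep up
        1.0 / (1.0 + np.exp(0.03 * (t - 120.0))),             # early collapse
        0.05 + 0.75 * np.exp(-(((t - 250.0) / 120.0) ** 2)),  # interference hump
        0.62 - 0.55 * np.exp(-(((t - 300.0) / 150.0) ** 2)),  # crash and recover
        0.5 + 0.45 * np.sin(t / 700.0 * np.pi),               # slow rise-fall
        0.9 - 0.0008 * t,                                     # slow decline
    ]
    if n_blocks > len(shapes):
        raise ValueError(f"at most {len(shapes)} planted blocks supported")
    rng = _rng(seed, 6)
    freq = np.vstack([
        np.clip(shapes[b] + rng.normal(0, 0.005, size=(n_snps_per_block, len(t))), 0, 1)
        for b in range(n_blocks)
    ])
    labels = np.repeat(np.arange(n_blocks), n_snps_per_block)
    return freq, labels


# ---------------------------------------------------------------------------
# fixture emission
# ---------------------------------------------------------------------------

def _write_vcf(table: SiteTable, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        for chrom in table.sites["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(table.samples) + "\n")
        for i, row in enumerate(table.sites.itertuples(index=False)):
            # REF = allele_A by construction of the emitted fixture
            cells = "\t".join(
                f"{table.count_a[i, j]},{table.count_b[i, j]}"
                for j in range(len(table.samples))
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.allele_A}\t{row.allele_B}"
                f"\t.\tPASS\t.\tAD\t{cells}\n"
            )


def emit_fixture(
    config: SimulationConfig,
    out_dir: str | Path,
    seed: int | None = None,
    environments: Sequence[str] | None = None,
    n_replicates: int = 1,
) -> dict:
    """Run the simulator end to end and write a readable fixture.

    Writes ``variants.vcf`` (FORMAT/AD), ``samples.tsv``, one
    ``depth_<sample>.tsv`` per evolved sample-generation, ``mappability.bed``
    (empty: fully mappable) and ``truth.json``. Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed if seed is None else seed
    envs = list(environments) if environments else [config.environment]

    parents = generate_parents(config, seed)
    pool = generate_f2_pool(parents, config, seed)

    tables = []
    metas_all: list[SampleMeta] = []
    truth_json: dict = {"environments": {}, "n_parental_snps": parents.n_snps}
    depth_files = []
    for ei, env in enumerate(envs):
        for rep in range(1, n_replicates + 1):
            rep_seed = (seed + 1009 * ei + 131 * rep) & 0x7FFFFFFF
            cfg = SimulationConfig(**{**config.__dict__, "environment": env})
            truth, _ = evolve_pool(pool, cfg, rep_seed)
            sampled = sample_poolseq(
                truth, parents, cfg, rep_seed, environment=env, replicate=f"R{rep}"
            )
            tables.append(sampled)
            truth_json["environments"][f"{env}_R{rep}"] = {
                "extinct": truth.extinct,
                "fixation_generation": truth.fixation_generation.tolist(),
                "snp_block": truth.snp_block.tolist(),
                "true_freq": {str(g): f.tolist() for g, f in truth.true_freq.items()},
                "mutations": [
                    {
                        "chrom": m.chrom, "pos": m.pos,
                        "s": m.selection_coefficient,
                        "birth_generation": m.birth_generation,
                        "final_fate": m.final_fate,
                        "trajectory": {str(g): f for g, f in m.trajectory.items()},
                    }
                    for m in truth.mutations
                ],
                "chrom_copy_ratio": {
                    str(g): r.tolist() for g, r in truth.chrom_copy_ratio.items()
                },
            }
            for gen in cfg.sampled_generations:
                if gen == 0:
                    continue
                track = sample_depth_track(truth, cfg, gen, rep_seed)
                fname = f"depth_{env}_R{rep}_g{gen}.tsv"
                track.records.to_csv(out / fname, sep="\t", index=False, header=False)
                depth_files.append(fname)

    # merge replicate tables on the union of sites
    merged = _merge_sampled(tables)
    metas_all = merged.metas
    _write_vcf(merged.site_table, out / "variants.vcf")
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id, "role": m.role, "environment": m.environment,
                "replicate": m.replicate, "generation": m.generation,
            }
            for m in metas_all
        ]
    ).to_csv(out / "samples.tsv", sep="\t", index=False)
    (out / "mappability.bed").write_text("")  # fully mappable genome
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_json, fh)
    manifest = {
        "out_dir": str(out),
        "n_sites": merged.site_table.n_sites,
        "n_samples": len(merged.site_table.samples),
        "depth_files": depth_files,
        "seed": seed,
    }
    return manifest


def _merge_sampled(sampled: list[SampledData]) -> SampledData:
    """Outer-join replicate site tables on (chrom, pos); shared parental sites align."""
    if len(sampled) == 1:
        return sampled[0]
    raw = sorted(
        {
            (r.chrom, r.pos, r.allele_A, r.allele_B, r.variant_class)
            for s in sampled
            for r in s.site_table.sites.itertuples(index=False)
        }
    )
    keys, seen = [], set()
    for k in raw:  # one row per (chrom, pos); positional collisions keep the first
        if k[:2] not in seen:
            seen.add(k[:2])
            keys.append(k)
    key_idx = {k[:2]: i for i, k in enumerate(keys)}
    samples: list[str] = []
    metas: list[SampleMeta] = []
    cols_a, cols_b = [], []
    for si, s in enumerate(sampled):
        tbl = s.site_table
        rows = np.array([key_idx[(r.chrom, r.pos)] for r in tbl.sites.itertuples(index=False)])
        for j, sid in enumerate(tbl.samples):
            if sid in samples:  # parents/founder shared across replicates
                continue
            samples.append(sid)
            metas.append(s.metas[j])
            ca = np.zeros(len(keys), dtype=np.int64)
            cb = np.zeros(len(keys), dtype=np.int64)
            ca[rows] = tbl.count_a[:, j]
            cb[rows] = tbl.count_b[:, j]
            cols_a.append(ca)
            cols_b.append(cb)
    sites = pd.DataFrame(keys, columns=["chrom", "pos", "allele_A", "allele_B", "variant_class"])
    table = SiteTable(
        sites=sites,
        samples=samples,
        count_a=np.column_stack(cols_a),
        count_b=np.column_stack(cols_b),
    )
    return SampledData(site_table=table, metas=metas, truth=sampled[0].truth)
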