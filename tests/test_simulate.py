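import json

import numpy as np
import pytest

from poolevo.io_formats import compute_frequencies, read_variant_table
from poolevo.simulate import (
    SimulationConfig,
    emit_fixture,
    evolve_pool,
    generate_f2_pool,
    generate_parents,
    planted_block_frequencies,
    poolseq_counts,
    sample_depth_track,
    sample_poolseq,
)


def small_config(**kw):
    base = dict(
        chrom_lengths=(200_000, 200_000, 200_000),
        n_parental_snps=200,
        mean_block_length=60_000,
        proportion_identical=0.2,
        pool_size=300,
        transfer_count=15,
        dilution_survival=0.2,
        sampled_generations=(0, 35, 70, 105),
        depth_mean=80.0,
        rng_seed=11,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenerateParents:
    def test_no_identical_blocks_when_proportion_zero(self):
        cfg = small_config(proportion_identical=0.0)
        parents = generate_parents(cfg, 1)
        assert parents.blocks["divergent"].all()
        assert parents.n_snps == cfg.n_parental_snps

    def test_no_snps_inside_identical_blocks(self):
        cfg = small_config(proportion_identical=0.3)
        parents = generate_parents(cfg, 2)
        ident = parents.blocks[~parents.blocks["divergent"]]
        for ci, start, end in ident[["chrom_idx", "start", "end"]].itertuples(index=False):
            inside = (
                (parents.snp_chrom == ci)
                & (parents.snp_pos >= start)
                & (parents.snp_pos <= end)
            )
            assert not inside.any()

    def test_deterministic_under_fixed_seed(self):
        cfg = small_config()
        p1, p2 = generate_parents(cfg, 5), generate_parents(cfg, 5)
        assert (p1.snp_pos == p2.snp_pos).all()
        assert (p1.allele_a == p2.allele_a).all()
        assert p1.blocks.equals(p2.blocks)

    def test_capacity_error_when_too_many_snps(self):
        cfg = small_config(chrom_lengths=(1000,), n_parental_snps=5000, proportion_identical=0.0)
        with pytest.raises(ValueError, match="divergent regions"):
            generate_parents(cfg, 1)

    def test_alleles_differ_at_every_snp(self):
        parents = generate_parents(small_config(), 3)
        assert (parents.allele_a != parents.allele_b).all()


class TestGenerateF2Pool:
    def test_pool_frequency_near_half(self):
        cfg = small_config(pool_size=2000)
        pool = generate_f2_pool(generate_parents(cfg, 1), cfg, 1)
        f = pool.allele_frequencies()
        # each site is a mean of 2N Bernoulli(1/2) gametes: se = 1/sqrt(4N)
        se = 1 / np.sqrt(4 * cfg.pool_size)
        assert abs(f.mean() - 0.5) < 3 * se
        assert (np.abs(f - 0.5) < 6 * se).mean() > 0.99

    def test_zero_crossovers_gives_parental_homologs(self):
        cfg = small_config(crossover_rate_per_bp=0.0)
        parents = generate_parents(cfg, 1)
        pool = generate_f2_pool(parents, cfg, 1)
        # per chromosome, each gamete is a pure parental homolog: per-lineage
        # per-chromosome homozygosity is either 0 or 1
        for ci in range(cfg.n_chroms):
            sel = parents.snp_chrom == ci
            if sel.sum() < 2:
                continue
            hom = (pool.hap1[:, sel] == pool.hap2[:, sel]).mean(axis=1)
            assert np.isin(hom, [0.0, 1.0]).all()

    def test_mean_homozygosity_near_half(self):
        """Monte-Carlo Mendelian segregation: a random F2 is homozygous at
        half its sites in expectation (inbreeding coefficient 0.5)."""
        cfg = small_config(pool_size=3000)
        pool = generate_f2_pool(generate_parents(cfg, 4), cfg, 4)
        assert pool.homozygosity().mean() == pytest.approx(0.5, abs=0.02)

    def test_haploid_contamination_marked_and_homozygous(self):
        cfg = small_config(haploidization_prob=0.5)
        pool = generate_f2_pool(generate_parents(cfg, 1), cfg, 1)
        hap = pool.ploidy == 1
        assert 0 < hap.sum() < pool.n_lineages
        assert (pool.homozygosity()[hap] == 1.0).all()

    def test_tiny_pool_rejected(self):
        cfg = small_config()
        parents = generate_parents(cfg, 1)
        object.__setattr__(cfg, "pool_size", 1)
        with pytest.raises(ValueError, match="pool_size"):
            generate_f2_pool(parents, cfg, 1)


class TestEvolvePool:
    def test_drift_only_null_at_large_census(self):
        """With no selection and a 10^6 census, ten generations move no site
        by more than 0.01 (binomial drift variance ~ pq/N per transfer)."""
        cfg = small_config(
            pool_size=1000, census_size=1_000_000, dilution_survival=1.0,
            transfer_count=1, generations_per_transfer=10,
            de_novo_rate=0.0, loh_rate=0.0,
            sampled_generations=(0, 10),
        )
        parents = generate_parents(cfg, 7)
        pool = generate_f2_pool(parents, cfg, 7)
        truth, _ = evolve_pool(pool, cfg, 7)
        delta = np.abs(truth.true_freq[10] - truth.true_freq[0])
        assert delta.max() < 0.01

    def test_selected_block_rises_monotonically_in_expectation(self):
        cfg = small_config(
            pool_size=500, census_size=200_000, dilution_survival=1.0,
            transfer_count=10, selection={"NaCl": {0: 0.5}},
            de_novo_rate=0.0, loh_rate=0.0,
            sampled_generations=(0, 14, 28, 42, 56, 70),
        )
        parents = generate_parents(cfg, 8)
        pool = generate_f2_pool(parents, cfg, 8)
        truth, st = evolve_pool(pool, cfg, 8)
        driver = st._driver_snp(0)
        traj = [truth.true_freq[g][driver] for g in cfg.sampled_generations]
        assert all(b >= a - 1e-3 for a, b in zip(traj, traj[1:]))
        assert traj[-1] > 0.9 > traj[0]

    def test_lethal_allele_gone_after_one_transfer(self):
        cfg = small_config(
            pool_size=400, selection={"NaCl": {0: -1.0}},
            de_novo_rate=0.0, loh_rate=0.0,
            sampled_generations=(0, 7),
        )
        parents = generate_parents(cfg, 9)
        pool = generate_f2_pool(parents, cfg, 9)
        truth, st = evolve_pool(pool, cfg, 9)
        driver = st._driver_snp(0)
        assert truth.true_freq[0][driver] > 0.3
        assert truth.true_freq[7][driver] == 0.0

    def test_total_extinction_reported_not_raised(self):
        # every block lethal for the A allele: any carrier dies, and with a
        # small pool some seed leaves no survivor
        parents = generate_parents(small_config(), 10)
        lethal_all = {b: -1.0 for b in range(parents.n_blocks)}
        for seed in range(30):
            cfg = small_config(pool_size=10, selection={"NaCl": lethal_all},
                               de_novo_rate=0.0, loh_rate=0.0)
            pool = generate_f2_pool(parents, cfg, seed)
            truth, _ = evolve_pool(pool, cfg, seed)
            if truth.extinct:
                assert truth.extinction_generation is not None
                break
        else:
            pytest.fail("no extinction observed across seeds")

    def test_wright_fisher_drift_variance(self):
        """Neutral allele-frequency variance after t generations matches
        p0(1-p0)[1 - (1 - 1/(2N))^t] within Monte-Carlo error."""
        n, t, reps = 100, 5, 300
        cfg = small_config(
            n_parental_snps=60, pool_size=n, dilution_survival=1.0,
            generations_per_transfer=1, transfer_count=t,
            de_novo_rate=0.0, loh_rate=0.0,
            sampled_generations=(0, t),
        )
        parents = generate_parents(cfg, 21)
        pool = generate_f2_pool(parents, cfg, 21)
        p0 = pool.allele_frequencies()
        final = np.array([evolve_pool(pool, cfg, 1000 + r)[0].true_freq[t] for r in range(reps)])
        emp_var = final.var(axis=0).mean()
        expected = (p0 * (1 - p0)).mean() * (1 - (1 - 1 / (2 * n)) ** t)
        # variance of a variance estimate: se ~ var * sqrt(2/(reps-1)); allow 3 se
        assert emp_var == pytest.approx(expected, rel=3 * np.sqrt(2 / (reps - 1)))

    def test_frequency_conservation_and_truth_bounds(self):
        cfg = small_config(selection={"NaCl": {0: 0.3}}, de_novo_rate=0.01, loh_rate=1e-4)
        parents = generate_parents(cfg, 12)
        pool = generate_f2_pool(parents, cfg, 12)
        truth, st = evolve_pool(pool, cfg, 12)
        assert st.freq.sum() == pytest.approx(1.0)
        for f in truth.true_freq.values():
            assert np.nanmin(f) >= 0.0 and np.nanmax(f) <= 1.0
        for m in truth.mutations:
            assert 0 < m.birth_generation <= cfg.total_generations

    def test_fixed_single_genotype_matches_its_homozygosity(self):
        """When one diploid genotype sweeps to fixation (no LOH/haploids),
        the fraction of parental SNPs at frequency 0 or 1 equals that
        genotype's homozygosity."""
        cfg = small_config(
            pool_size=40, transfer_count=60, dilution_survival=0.1,
            selection={"NaCl": {0: 1.0}}, de_novo_rate=0.0, loh_rate=0.0,
            sampled_generations=(0, 420),
        )
        parents = generate_parents(cfg, 13)
        pool = generate_f2_pool(parents, cfg, 13)
        truth, st = evolve_pool(pool, cfg, 13)
        assert len(st.freq) == 1, "population should have fixed a single genotype"
        f = truth.true_freq[420]
        frac_fixed = ((f <= 1e-12) | (f >= 1 - 1e-12)).mean()
        hom = (st.acount[0] != 1).mean()  # dosage 0 or 2 = homozygous
        assert frac_fixed == pytest.approx(hom, abs=1e-12)

    def test_fixation_generation_truth_consistent(self):
        cfg = small_config(
            pool_size=40, transfer_count=60, dilution_survival=0.1,
            selection={"NaCl": {0: 1.0}}, de_novo_rate=0.0, loh_rate=0.0,
            sampled_generations=(0, 420),
        )
        parents = generate_parents(cfg, 13)
        pool = generate_f2_pool(parents, cfg, 13)
        truth, _ = evolve_pool(pool, cfg, 13)
        fixed = truth.fixation_generation >= 0
        f = truth.true_freq[420]
        at_bound = (f <= 1e-12) | (f >= 1 - 1e-12)
        assert (fixed == at_bound).all()


class TestSamplePoolseq:
    def test_true_frequency_one_yields_no_b_reads(self):
        cfg = small_config(de_novo_rate=0.0, loh_rate=0.0)
        parents = generate_parents(cfg, 14)
        pool = generate_f2_pool(parents, cfg, 14)
        truth, _ = evolve_pool(pool, cfg, 14)
        truth.true_freq[105] = np.ones(parents.n_snps)
        data = sample_poolseq(truth, parents, cfg, 14)
        j = data.site_table.samples.index("NaCl_R1_g105")
        assert (data.site_table.count_b[:, j] == 0).all()

    def test_binomial_sampling_unbiased_at_half(self):
        rng = np.random.default_rng(0)
        ca, dp = poolseq_counts(np.full(10_000, 0.5), 100.0, 5.0, rng)
        freq = ca[dp > 0] / dp[dp > 0]
        assert freq.mean() == pytest.approx(0.5, abs=0.005)

    def test_fixed_trisomy_scales_depth_by_1_5(self):
        cfg = small_config(de_novo_rate=0.0, loh_rate=0.0)
        parents = generate_parents(cfg, 15)
        pool = generate_f2_pool(parents, cfg, 15)
        truth, _ = evolve_pool(pool, cfg, 15)
        truth.chrom_copy_ratio[105] = np.array([1.5, 1.0, 1.0])
        track = sample_depth_track(truth, cfg, 105, 15)
        means = track.records.groupby("chrom")["depth"].mean()
        assert means["chr01"] / means[["chr02", "chr03"]].mean() == pytest.approx(1.5, rel=0.02)

    def test_unsampled_generation_rejected(self):
        cfg = small_config()
        parents = generate_parents(cfg, 16)
        pool = generate_f2_pool(parents, cfg, 16)
        truth, _ = evolve_pool(pool, cfg, 16)
        with pytest.raises(ValueError, match="generation"):
            sample_poolseq(truth, parents, cfg, 16, generations=[33])
        with pytest.raises(ValueError, match="generation"):
            sample_depth_track(truth, cfg, 33, 16)


class TestPlantedBlocks:
    def test_blocks_are_distinguishable_on_sampling_grid(self):
        gens = [0, 30, 60, 100, 200, 300, 400, 500]
        freq, labels = planted_block_frequencies(gens, n_blocks=4, n_snps_per_block=5, seed=0)
        assert freq.shape == (20, len(gens))
        assert ((freq >= 0) & (freq <= 1)).all()
        means = np.array([freq[labels == b].mean(axis=0) for b in range(4)])
        z = (means - means.mean(axis=1, keepdims=True)) / means.std(axis=1, keepdims=True)
        corr = z @ z.T / len(gens)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.9


class TestEmitFixture:
    def test_fixture_round_trips_and_is_deterministic(self, tmp_path):
        cfg = small_config(sampled_generations=(0, 35, 70), transfer_count=10)
        m1 = emit_fixture(cfg, tmp_path / "a", seed=3)
        m2 = emit_fixture(cfg, tmp_path / "b", seed=3)
        for name in ("variants.vcf", "samples.tsv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
        table, metas = read_variant_table(tmp_path / "a" / "variants.vcf",
                                          tmp_path / "a" / "samples.tsv")
        assert table.n_sites == m1["n_sites"]
        # parental SNP rows of the VCF match the truth site count
        truth = json.loads((tmp_path / "a" / "truth.json").read_text())
        n_mut = sum(
            len(env["mutations"]) > 0 for env in truth["environments"].values()
        )
        assert table.n_sites >= truth["n_parental_snps"]
        fm = compute_frequencies(table)
        founder = fm.column("founder")[: truth["n_parental_snps"]]
        assert np.nanmean(founder) == pytest.approx(0.5, abs=0.05)
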