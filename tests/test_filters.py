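import numpy as np
import pytest

from poolevo.filters import (
    FilterParams,
    classification_counts,
    detect_denovo,
    filter_standing_variants,
    group_linked_mutations,
    n_independent_events,
)
from poolevo.io_formats import SampleMeta

from conftest import make_site_table


class TestFilterStandingVariants:
    def test_toy_table_two_planted_violations(self, filter_toy):
        table, metas = filter_toy
        filtered, log = filter_standing_variants(table, metas, None)
        assert filtered.n_sites == 4
        assert log == {
            "missing": 0, "depth": 1, "mappability": 0, "parent_maf": 0, "founder_maf": 1,
        }
        assert filtered.sites["pos"].tolist() == [100, 200, 400, 600]

    def test_heterozygous_parent_removed(self):
        samples = ["pA", "pB", "F"]
        metas = [
            SampleMeta("pA", "parent_A"), SampleMeta("pB", "parent_B"),
            SampleMeta("F", "founder", generation=0),
        ]
        table = make_site_table(
            [("chr1", 100, "A", "G", [(18, 12), (0, 30), (15, 15)])], samples
        )  # parent A MAF 0.4
        filtered, log = filter_standing_variants(table, metas, None)
        assert filtered.n_sites == 0
        assert log["parent_maf"] == 1

    def test_all_sites_pass_is_identity(self, filter_toy):
        _, metas = filter_toy
        ok = [(30, 0), (0, 28), (15, 15), (20, 10)]
        clean = make_site_table(
            [("chr1", p, "A", "G", ok) for p in (100, 200, 300, 400)],
            ["pA", "pB", "F", "E1"],
        )
        filtered, log = filter_standing_variants(clean, metas, None)
        assert filtered.n_sites == clean.n_sites
        assert sum(log.values()) == 0
        assert (filtered.count_a == clean.count_a).all()

    def test_no_founder_sample_is_hard_error(self, filter_toy):
        table, metas = filter_toy
        metas = [m for m in metas if m.role != "founder"]
        table = table.select_samples([m.sample_id for m in metas])
        with pytest.raises(ValueError, match="founder"):
            filter_standing_variants(table, metas, None)

    def test_per_site_criteria_are_order_insensitive(self, filter_toy):
        """The retained set equals the intersection of the per-criterion masks
        (criteria 3-5 are per-site independent, so order cannot matter)."""
        table, metas = filter_toy
        filtered, _ = filter_standing_variants(table, metas, None)
        # recompute each mask independently
        depth = table.depth()
        p95 = np.percentile(depth, 95, axis=0)
        maf = np.minimum(
            table.count_a / depth, 1 - table.count_a / depth
        )
        m_missing = (depth > 0).all(axis=1)
        m_depth = ((depth >= 25) & (depth <= p95[None, :])).all(axis=1)
        m_parent = (maf[:, :2] < 0.05).all(axis=1)
        m_founder = maf[:, 2] > 0.3
        expect = m_missing & m_depth & m_parent & m_founder
        assert filtered.n_sites == int(expect.sum())
        assert filtered.sites["pos"].tolist() == table.sites["pos"][expect].tolist()


def denovo_table(founder_counts, evolved_freqs, parent_b_has_allele=False, depth=100):
    """One candidate site plus one parental standing site, 4 evolved gens."""
    samples = ["pA", "pB", "F"] + [f"E{g}" for g in range(len(evolved_freqs))]
    metas = [
        SampleMeta("pA", "parent_A"), SampleMeta("pB", "parent_B"),
        SampleMeta("F", "founder", environment="NaCl", replicate="1", generation=0),
    ] + [
        SampleMeta(f"E{i}", "evolved", environment="NaCl", replicate="1", generation=100 * (i + 1))
        for i in range(len(evolved_freqs))
    ]
    pb = (depth // 2, depth // 2) if parent_b_has_allele else (depth, 0)
    mut_row = (
        "chr1", 500, "A", "T",
        [(depth, 0), pb, founder_counts]
        + [(int(depth * (1 - f)), int(depth * f)) for f in evolved_freqs],
    )
    standing_row = (
        "chr1", 100, "A", "G",
        [(depth, 0), (0, depth), (depth // 2, depth // 2)]
        + [(depth, 0) for _ in evolved_freqs],
    )
    return make_site_table([standing_row, mut_row], samples), metas


class TestDetectDenovo:
    @pytest.mark.parametrize(
        "traj,expected",
        [
            ([0.0, 0.02, 0.12, 0.40], "candidate"),   # crosses 0.10 and 0.35
            ([0.0, 0.02, 0.12, 0.20], "denovo"),      # crosses 0.10 only
            ([0.0, 0.02, 0.08, 0.05], "putative"),    # stays below 0.10
        ],
    )
    def test_threshold_classification(self, traj, expected):
        table, metas = denovo_table((100, 0), traj)
        records = detect_denovo(table, metas)
        assert len(records) == 1
        assert records[0].classification == expected
        assert records[0].pos == 500
        assert records[0].max_freq == pytest.approx(max(traj))

    def test_allele_present_in_parent_is_not_a_mutation(self):
        table, metas = denovo_table((100, 0), [0.0, 0.1, 0.4, 0.6], parent_b_has_allele=True)
        assert detect_denovo(table, metas) == []

    def test_intermediate_founder_frequency_excluded_as_preexisting(self):
        table, metas = denovo_table((60, 40), [0.3, 0.4, 0.5, 0.6])
        records = detect_denovo(table, metas)
        assert records[0].classification == "preexisting_excluded"

    def test_monomorphic_nonparental_allele_dropped(self):
        table, metas = denovo_table((100, 0), [0.0, 0.0, 0.0, 0.0])
        assert detect_denovo(table, metas) == []

    def test_missing_parents_is_hard_error(self):
        table, metas = denovo_table((100, 0), [0.0, 0.1, 0.2, 0.3])
        keep = [m for m in metas if m.role != "parent_B"]
        with pytest.raises(ValueError, match="parental"):
            detect_denovo(table.select_samples([m.sample_id for m in keep]), keep)

    def test_failed_curation_discards_candidate(self):
        table, metas = denovo_table((100, 0), [0.0, 0.02, 0.12, 0.40])
        records = detect_denovo(table, metas, curation={("chr1", 500): False})
        assert records[0].classification == "discarded_curation"

    def test_classification_lattice_on_mixed_fixture(self):
        """#candidate <= #denovo <= #putative in the cumulative tallies."""
        rng = np.random.default_rng(7)
        all_records = []
        for i in range(20):
            peak = rng.uniform(0, 0.8)
            traj = list(np.clip(np.linspace(0, peak, 4), 0, 1))
            table, metas = denovo_table((100, 0), traj)
            all_records += detect_denovo(table, metas)
        counts = classification_counts(all_records)
        assert counts["candidate"] <= counts["denovo"] <= counts["putative"]


def _record(env, rep, traj_values, gens=(100, 200, 300, 400)):
    from poolevo.filters import MutationRecord

    traj = {rep: dict(zip(gens, traj_values))}
    return MutationRecord(
        chrom="chr1", pos=int(1000 * sum(traj_values) + 1), allele="T", environment=env,
        trajectory=traj, classification="candidate", max_freq=max(traj_values),
    )


class TestGroupLinkedMutations:
    def test_identical_trajectories_form_one_group(self):
        a = _record("NaCl", "1", [0.1, 0.3, 0.5, 0.9])
        b = _record("NaCl", "1", [0.1, 0.3, 0.5, 0.9])
        grouped = group_linked_mutations([a, b])
        assert a.linked_group_id == b.linked_group_id
        assert n_independent_events(grouped) == 1

    def test_orthogonal_trajectories_stay_separate(self):
        # constructed orthogonal vectors: Pearson r = 0 exactly
        a = _record("NaCl", "1", [1.0, 0.0, 1.0, 0.0])
        b = _record("NaCl", "1", [0.0, 0.0, 1.0, 1.0])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        assert abs(np.corrcoef(x, y)[0, 1]) < 1e-12
        grouped = group_linked_mutations([a, b])
        assert a.linked_group_id != b.linked_group_id
        assert n_independent_events(grouped) == 2

    def test_different_replicates_never_grouped(self):
        a = _record("NaCl", "1", [0.1, 0.3, 0.5, 0.9])
        b = _record("NaCl", "2", [0.1, 0.3, 0.5, 0.9])
        group_linked_mutations([a, b])
        assert a.linked_group_id != b.linked_group_id

    def test_short_trajectories_flagged_and_ungrouped(self):
        a = _record("NaCl", "1", [0.2, 0.9], gens=(100, 200))
        b = _record("NaCl", "1", [0.2, 0.9], gens=(100, 200))
        group_linked_mutations([a, b])
        assert a.group_flagged and b.group_flagged
        assert a.linked_group_id != b.linked_group_id


def test_filter_params_validation():
    with pytest.raises(ValueError):
        FilterParams(min_depth=0)
    with pytest.raises(ValueError):
        FilterParams(founder_min_maf=0.7)
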