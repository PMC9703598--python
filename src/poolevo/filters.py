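"""The two variant-filtering strategies.

Strategy one recovers the shared standing-variation SNP set used by every
downstream frequency analysis: sites defined in all samples, with adequate
and not excessive coverage, fully mappable, homozygous in both haploid
parents and clearly heterozygous in the founder pool. Strategy two detects
de novo mutations per environment and classifies them by the maximum
frequency their non-parental allele reaches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import FrequencyMatrix, MappabilityTrack, SampleMeta, SiteTable

FILTER_CRITERIA = ("missing", "depth", "mappability", "parent_maf", "founder_maf")


@dataclass
class FilterParams:
    """Thresholds for both filtering strategies (values from the study design)."""

    min_depth: int = 25
    max_depth_percentile: float = 95.0
    min_mappability: float = 1.0
    parental_max_maf: float = 0.05
    founder_min_maf: float = 0.3
    denovo_founder_max_maf: float = 0.3
    denovo_min_freq: float = 0.10
    candidate_min_freq: float = 0.35
    linked_correlation_min: float = 0.95

    def __post_init__(self) -> None:
        if self.min_depth <= 0:
            raise ValueError("min_depth must be > 0")
        for name in ("parental_max_maf", "founder_min_maf", "denovo_founder_max_maf"):
            if not (0 <= getattr(self, name) <= 0.5):
                raise ValueError(f"{name} must be in [0, 0.5]")
        for name in ("denovo_min_freq", "candidate_min_freq"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


def _maf(count_a: np.ndarray, count_b: np.ndarray) -> np.ndarray:
    """Minor allele frequency from allele depths; NaN where depth is zero."""
    depth = (count_a + count_b).astype(float)
    with np.errstate(invalid="ignore"):
        f = np.where(depth > 0, count_a / np.where(depth > 0, depth, 1.0), np.nan)
    return np.minimum(f, 1.0 - f)


def filter_standing_variants(
    table: SiteTable,
    metas: Sequence[SampleMeta],
    mappability: MappabilityTrack | None,
    params: FilterParams | None = None,
) -> tuple[SiteTable, dict[str, int]]:
    """Apply the standing-variation filters in order; returns (table, removal log).

    Criteria, applied in order with each removal attributed to the first
    criterion a site fails:

    1. ``missing`` — defined (depth > 0) in every sample;
    2. ``depth`` — every sample's depth ≥ ``min_depth`` and ≤ that sample's
       own 95th depth percentile, the percentile being computed over all
       pre-filter sites;
    3. ``mappability`` — overlapping mappability ≥ ``min_mappability``;
    4. ``parent_maf`` — MAF < ``parental_max_maf`` in each parent
       (homozygous parental calls);
    5. ``founder_maf`` — MAF > ``founder_min_maf`` in every founder sample
       (clearly heterozygous in the F2 pool).
    """
    params = params or FilterParams()
    meta_by_id = {m.sample_id: m for m in metas}
    founders = [s for s in table.samples if meta_by_id[s].role == "founder"]
    if not founders:
        raise ValueError("no founder sample in table")
    parents = [s for s in table.samples if meta_by_id[s].role in ("parent_A", "parent_B")]

    depth = table.depth()
    n = table.n_sites
    ok = np.ones(n, dtype=bool)
    log = dict.fromkeys(FILTER_CRITERIA, 0)

    def apply(name: str, passes: np.ndarray) -> None:
        newly = ok & ~passes
        log[name] = int(newly.sum())
        ok[newly] = False

    apply("missing", (depth > 0).all(axis=1))

    # per-sample 95th percentile over the pre-filter call set
    p95 = np.percentile(depth, params.max_depth_percentile, axis=0)
    apply("depth", ((depth >= params.min_depth) & (depth <= p95[None, :])).all(axis=1))

    if mappability is not None:
        mapp = np.ones(n)
        for chrom, grp in table.sites.groupby("chrom", sort=False):
            mapp[grp.index] = mappability.values_at(chrom, grp["pos"].to_numpy())
        apply("mappability", mapp >= params.min_mappability)
    else:
        log["mappability"] = 0

    maf = _maf(table.count_a, table.count_b)
    pidx = [table.sample_index(s) for s in parents]
    parent_maf = maf[:, pidx]
    apply("parent_maf", np.nan_to_num(parent_maf, nan=1.0).max(axis=1) < params.parental_max_maf)

    fidx = [table.sample_index(s) for s in founders]
    founder_maf = maf[:, fidx]
    apply("founder_maf", np.nan_to_num(founder_maf, nan=-1.0).min(axis=1) > params.founder_min_maf)

    return table.subset_sites(ok), log


CLASSIFICATIONS = ("putative", "denovo", "candidate", "preexisting_excluded", "discarded_curation")


@dataclass
class MutationRecord:
    """One putative de novo mutation in one environment."""

    chrom: str
    pos: int
    allele: str  # the non-parental allele
    environment: str
    trajectory: dict[str, dict[int, float]]  # replicate -> generation -> frequency
    classification: str
    max_freq: float
    curation_pass: bool = True
    effect_label: str = ""
    linked_group_id: int | None = None
    group_flagged: bool = False

    @property
    def primary_replicate(self) -> str:
        """Replicate in which the mutation reaches its maximum frequency."""
        best, best_f = "", -1.0
        for rep, traj in self.trajectory.items():
            m = max(traj.values(), default=-1.0)
            if m > best_f:
                best, best_f = rep, m
        return best


def detect_denovo(
    table: SiteTable,
    metas: Sequence[SampleMeta],
    params: FilterParams | None = None,
    environment: str | None = None,
    curation: dict[tuple[str, int], bool] | None = None,
) -> list[MutationRecord]:
    """Detect and classify de novo mutations in one environment's table.

    A site yields a record when one of its alleles is found in neither
    parental strain (parental frequency of that allele < ``parental_max_maf``
    in both parents) and that allele is not monomorphically absent across
    the evolved samples. Records with founder MAF ≥ ``denovo_founder_max_maf``
    are labelled ``preexisting_excluded`` (already segregating at the start);
    the rest are ``putative``, upgraded to ``denovo`` when the allele reaches
    ``denovo_min_freq`` at any sampled generation and to ``candidate`` above
    ``candidate_min_freq``. ``curation`` maps (chrom, pos) to a manual
    curation verdict; failures become ``discarded_curation``.
    """
    params = params or FilterParams()
    meta_by_id = {m.sample_id: m for m in metas}
    parents = [s for s in table.samples if meta_by_id[s].role in ("parent_A", "parent_B")]
    if len(parents) < 2:
        raise ValueError("both parental samples are required")
    founders = [s for s in table.samples if meta_by_id[s].role == "founder"]
    evolved = [s for s in table.samples if meta_by_id[s].role == "evolved"]
    if environment is not None:
        evolved = [s for s in evolved if meta_by_id[s].environment == environment]
    env = environment or (meta_by_id[evolved[0]].environment if evolved else "")

    depth = table.depth().astype(float)
    with np.errstate(invalid="ignore"):
        freq_b = np.where(depth > 0, table.count_b / np.where(depth > 0, depth, 1.0), np.nan)

    pidx = [table.sample_index(s) for s in parents]
    fidx = [table.sample_index(s) for s in founders]
    eidx = [table.sample_index(s) for s in evolved]

    # the B allele is non-parental when neither parent shows it above noise
    parent_b = np.nan_to_num(freq_b[:, pidx], nan=0.0)
    nonparental = (parent_b < params.parental_max_maf).all(axis=1)
    # drop monomorphic sites: allele-depth frequency 0 across the environment
    seen = np.nan_to_num(freq_b[:, eidx], nan=0.0).max(axis=1) > 0 if eidx else np.zeros(
        table.n_sites, dtype=bool
    )

    records: list[MutationRecord] = []
    for i in np.flatnonzero(nonparental & seen):
        row = table.sites.iloc[i]
        founder_maf = np.nan_to_num(freq_b[i, fidx], nan=0.0)
        traj: dict[str, dict[int, float]] = {}
        for j, s in zip(eidx, evolved):
            m = meta_by_id[s]
            if not np.isnan(freq_b[i, j]):
                traj.setdefault(str(m.replicate), {})[m.generation] = float(freq_b[i, j])
        max_freq = max((f for d in traj.values() for f in d.values()), default=0.0)
        if founders and (founder_maf >= params.denovo_founder_max_maf).any():
            classification = "preexisting_excluded"
        else:
            classification = "putative"
            if max_freq >= params.denovo_min_freq:
                classification = "denovo"
            if max_freq > params.candidate_min_freq:
                classification = "candidate"
        passed = True if curation is None else curation.get((row.chrom, int(row.pos)), True)
        if not passed and classification == "candidate":
            classification = "discarded_curation"
        records.append(
            MutationRecord(
                chrom=row.chrom,
                pos=int(row.pos),
                allele=row.allele_B,
                environment=env,
                trajectory=traj,
                classification=classification,
                max_freq=max_freq,
                curation_pass=passed,
            )
        )
    return records


def classification_counts(records: Sequence[MutationRecord]) -> dict[str, int]:
    """Cumulative tallies respecting the classification lattice.

    ``candidate ⇒ denovo ⇒ putative``: every candidate is also counted as a
    de novo mutation and every de novo mutation as putative.
    """
    n_candidate = sum(r.classification == "candidate" for r in records)
    n_denovo = n_candidate + sum(r.classification == "denovo" for r in records)
    n_putative = n_denovo + sum(r.classification == "putative" for r in records)
    return {
        "putative": n_putative,
        "denovo": n_denovo,
        "candidate": n_candidate,
        "preexisting_excluded": sum(r.classification == "preexisting_excluded" for r in records),
        "discarded_curation": sum(r.classification == "discarded_curation" for r in records),
    }


def group_linked_mutations(
    records: Sequence[MutationRecord], correlation_min: float | None = None
) -> list[MutationRecord]:
    """Assign shared ``linked_group_id`` to trajectory-linked mutations.

    Two records are linked when they sit in the same environment, reach their
    maximum in the same replicate, and their frequency trajectories in that
    replicate have Pearson r ≥ ``correlation_min`` over shared generations.
    Records with fewer than 3 defined points stay ungrouped and are flagged.
    Linkage is transitive (union of pairs). Linked mutations are counted once
    when tallying independent events.
    """
    if correlation_min is None:
        correlation_min = FilterParams().linked_correlation_min
    records = list(records)
    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    vectors: list[tuple[str, str, dict[int, float]] | None] = []
    for r in records:
        rep = r.primary_replicate
        traj = r.trajectory.get(rep, {})
        if len(traj) < 3:
            r.group_flagged = True
            vectors.append(None)
        else:
            vectors.append((r.environment, rep, traj))

    for i in range(n):
        if vectors[i] is None:
            continue
        for j in range(i + 1, n):
            if vectors[j] is None:
                continue
            env_i, rep_i, ti = vectors[i]
            env_j, rep_j, tj = vectors[j]
            if env_i != env_j or rep_i != rep_j:
                continue  # mutations in different replicates are never grouped
            gens = sorted(set(ti) & set(tj))
            if len(gens) < 3:
                continue
            x = np.array([ti[g] for g in gens])
            y = np.array([tj[g] for g in gens])
            if x.std() == 0 or y.std() == 0:
                continue
            r_xy = float(np.corrcoef(x, y)[0, 1])
            if r_xy >= correlation_min:
                union(i, j)

    roots: dict[int, int] = {}
    for i, r in enumerate(records):
        root = find(i)
        gid = roots.setdefault(root, len(roots))
        r.linked_group_id = gid
    return records


def n_independent_events(records: Sequence[MutationRecord]) -> int:
    """Number of distinct linked groups (linked trajectories count once)."""
    return len({r.linked_group_id for r in records})
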