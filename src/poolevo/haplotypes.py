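"""Haplotype-cluster reconstruction from SNP-frequency trajectories.

In a strictly asexual population descended from F2 genotypes, SNPs that ride
on the same genetic background share frequency trajectories. Clustering
trajectories therefore approximates the segregating haplotypes: frequencies
are variance-stabilized (arcsine square root), z-scored per site, correlated
across time points, and grouped by average-linkage hierarchical clustering
at a minimum merge correlation chosen per replicate to maximize the number
of blocks with at least ten SNPs.

Correlation is signed and distance is 1 − r, so a haplotype of mixed
parental ancestry appears as two mirror-image clusters rather than one; this
matches how such sweeps display in trajectory plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class NormalizedTrajectories:
    """Z-scored arcsine-square-root trajectories of one replicate."""

    site_keys: list  # keys of retained sites, aligned with rows of ``vectors``
    vectors: np.ndarray  # retained sites × generations
    raw: np.ndarray  # raw frequencies of retained sites
    generations: list[int]
    excluded_zero_variance: list = field(default_factory=list)


@dataclass
class HaplotypeClusterSet:
    """Partition of SNPs into haplotype blocks at the chosen cutoff."""

    replicate: str
    chosen_cutoff: float
    clusters: list[list]  # each a list of site keys, size >= min_size
    representatives: list  # one seeded-random site key per cluster
    unassigned: list
    cutoff_counts: dict[float, int]
    rng_seed: int

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self, site_keys: list) -> np.ndarray:
        """Cluster index per site key; −1 for unassigned sites."""
        lab = {k: i for i, members in enumerate(self.clusters) for k in members}
        return np.array([lab.get(k, -1) for k in site_keys])


def normalize_trajectories(
    freq: np.ndarray,
    generations: list[int] | None = None,
    site_keys: list | None = None,
) -> NormalizedTrajectories:
    """Arcsine-square-root transform then per-site centering and unit scaling.

    ``freq`` is sites × time points with no missing values (the shared
    filtered set guarantees this). Constant (zero-variance) trajectories
    carry no correlation signal and are excluded, listed in
    ``excluded_zero_variance``.
    """
    freq = np.asarray(freq, dtype=float)
    if freq.ndim != 2:
        raise ValueError("freq must be sites × generations")
    n_sites, n_gens = freq.shape
    if n_gens < 3:
        raise ValueError("need at least 3 time points for trajectory correlation")
    if np.isnan(freq).any():
        raise ValueError("missing frequencies; use the shared filtered site set")
    generations = list(generations) if generations is not None else list(range(n_gens))
    site_keys = list(site_keys) if site_keys is not None else list(range(n_sites))

    y = np.arcsin(np.sqrt(np.clip(freq, 0.0, 1.0)))
    sd = y.std(axis=1, ddof=0)
    keep = sd > 0
    z = (y[keep] - y[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return NormalizedTrajectories(
        site_keys=[k for k, ok in zip(site_keys, keep) if ok],
        vectors=z,
        raw=freq[keep],
        generations=generations,
        excluded_zero_variance=[k for k, ok in zip(site_keys, keep) if not ok],
    )


DEFAULT_CUTOFF_GRID = tuple(np.round(np.arange(0.30, 0.9001, 0.05), 2))


def cluster_haplotypes(
    traj: NormalizedTrajectories,
    cutoff_grid: tuple[float, ...] = DEFAULT_CUTOFF_GRID,
    min_size: int = 10,
    seed: int = 0,
    replicate: str = "",
) -> HaplotypeClusterSet:
    """Average-linkage clustering with a per-replicate correlation-cutoff sweep.

    Pairwise Pearson correlation r on the normalized vectors gives distance
    d = 1 − r (signed; mirrored trajectories are distance 2 apart and never
    merge). For each cutoff c on the grid the tree is cut at height 1 − c and
    clusters of at least ``min_size`` SNPs are counted; the chosen cutoff
    maximizes that count, ties resolved toward the larger (tighter) cutoff.
    One representative SNP per cluster is drawn with a seeded RNG.
    """
    n = traj.vectors.shape[0]
    if n < min_size:
        raise ValueError(f"need at least min_size={min_size} trajectories, have {n}")
    corr = np.corrcoef(traj.vectors)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    tree = linkage(squareform(dist, checks=False), method="average")

    best_cutoff, best_count, best_labels = None, -1, None
    counts: dict[float, int] = {}
    for c in cutoff_grid:
        labels = fcluster(tree, t=1.0 - c, criterion="distance")
        sizes = np.bincount(labels)
        count = int((sizes >= min_size).sum())
        counts[float(c)] = count
        if count > best_count or (count == best_count and (best_cutoff or -1) < c):
            best_cutoff, best_count, best_labels = float(c), count, labels

    if best_count == 0:
        warnings.warn("no haplotype block reached the minimum size at any cutoff")
        return HaplotypeClusterSet(
            replicate=replicate, chosen_cutoff=best_cutoff or float(cutoff_grid[-1]),
            clusters=[], representatives=[], unassigned=list(traj.site_keys),
            cutoff_counts=counts, rng_seed=seed,
        )

    rng = np.random.default_rng(seed)
    clusters, reps, assigned = [], [], set()
    for lab in np.unique(best_labels):
        members = np.flatnonzero(best_labels == lab)
        if len(members) < min_size:
            continue
        keys = [traj.site_keys[i] for i in members]
        clusters.append(keys)
        reps.append(keys[int(rng.integers(len(keys)))])
        assigned.update(members)
    unassigned = [traj.site_keys[i] for i in range(n) if i not in assigned]
    return HaplotypeClusterSet(
        replicate=replicate, chosen_cutoff=best_cutoff, clusters=clusters,
        representatives=reps, unassigned=unassigned, cutoff_counts=counts,
        rng_seed=seed,
    )


def cluster_recovery(result: HaplotypeClusterSet, truth_labels: dict | list | np.ndarray) -> float:
    """Chance-adjusted agreement (adjusted Rand index) with the true blocks.

    Restricted to SNPs assigned to a retained cluster. ``truth_labels`` maps
    site key → true haplotype-block label (or is an array indexed by integer
    site keys). Returns a score in [−1, 1]; 1 is exact recovery, 0 chance.
    """
    from sklearn.metrics import adjusted_rand_score

    inferred, truth = [], []
    for i, members in enumerate(result.clusters):
        for k in members:
            inferred.append(i)
            truth.append(truth_labels[k])
    if not inferred:
        return 0.0
    return float(adjusted_rand_score(truth, inferred))


def representative_trajectories(
    result: HaplotypeClusterSet, traj: NormalizedTrajectories
) -> np.ndarray:
    """Raw frequency trajectory of each cluster's representative SNP."""
    index = {k: i for i, k in enumerate(traj.site_keys)}
    return np.array([traj.raw[index[k]] for k in result.representatives])
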