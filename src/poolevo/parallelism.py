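"""Windowed genomic parallelism between replicate populations.

The genome is tiled into non-overlapping 10-kb windows anchored at position
1 of each chromosome; windows with at least four SNPs get the median
parent-A frequency of their member SNPs per sample. A window is nearly
fixed for the A allele when its median frequency is ≥ 0.9 (MAF ≤ 0.1) and
for the B allele when ≤ 0.1. The signed parallelism index of an environment
is the replicate-scaled count of windows fixed for A (+1 each) versus B
(−1 each), ranging from −1 to +1.

The chance-overlap null for two populations each dominated by a single F2
genotype is analytic: a random F2 is homozygous for a *given* parental
allele with probability (1/2)(1/2) = 1/4, so two F2s are fixed for the same
allele with probability 2 × (1/4)² = 1/8 = 0.125.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import FrequencyMatrix

STATE_A, STATE_B, STATE_UNFIXED = "A_fixed", "B_fixed", "unfixed"

# Mendelian F2 null: probability of homozygosity for one specific parental allele
F2_HOM_SPECIFIC_ALLELE = 0.25
# probability a random F2 is homozygous at a site (either allele)
F2_HOM_ANY_ALLELE = 0.5
# probability two independent F2s are homozygous for the same allele
F2_SHARED_FIXATION = 2 * F2_HOM_SPECIFIC_ALLELE**2  # = 0.125


@dataclass
class GenomicWindowTrack:
    """Tiled windows with per-sample median frequencies and fixation states."""

    windows: pd.DataFrame  # chrom, start, end, n_snps
    samples: list[str]
    median_freq: np.ndarray  # windows × samples
    maf_threshold: float = 0.1
    n_dropped_windows: int = 0

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def states(self) -> np.ndarray:
        """Fixation state per window per sample."""
        out = np.full(self.median_freq.shape, STATE_UNFIXED, dtype=object)
        out[self.median_freq >= 1.0 - self.maf_threshold] = STATE_A
        out[self.median_freq <= self.maf_threshold] = STATE_B
        return out


def make_windows(
    fm: FrequencyMatrix,
    window_size: int = 10_000,
    min_snps: int = 4,
    maf_threshold: float = 0.1,
) -> GenomicWindowTrack:
    """Tile chromosomes into windows and take median member-SNP frequencies.

    Windows are 1-based closed intervals anchored at position 1
    ([1, window_size], [window_size+1, 2·window_size], ...). Windows with
    fewer than ``min_snps`` member SNPs are dropped and counted. Medians are
    invariant to SNP order within a window.
    """
    if fm.n_sites == 0:
        raise ValueError("empty site set")
    sites = fm.sites
    widx = (sites["pos"].to_numpy() - 1) // window_size
    key = pd.DataFrame({"chrom": sites["chrom"].to_numpy(), "widx": widx})
    rows, med = [], []
    n_dropped = 0
    for (chrom, wi), grp in key.groupby(["chrom", "widx"], sort=True):
        if len(grp) < min_snps:
            n_dropped += 1
            continue
        rows.append(
            {
                "chrom": chrom,
                "start": int(wi) * window_size + 1,
                "end": (int(wi) + 1) * window_size,
                "n_snps": len(grp),
            }
        )
        med.append(np.nanmedian(fm.freq[grp.index.to_numpy()], axis=0))
    if not rows:
        return GenomicWindowTrack(
            windows=pd.DataFrame(columns=["chrom", "start", "end", "n_snps"]),
            samples=list(fm.samples),
            median_freq=np.empty((0, len(fm.samples))),
            maf_threshold=maf_threshold,
            n_dropped_windows=n_dropped,
        )
    return GenomicWindowTrack(
        windows=pd.DataFrame(rows),
        samples=list(fm.samples),
        median_freq=np.vstack(med),
        maf_threshold=maf_threshold,
        n_dropped_windows=n_dropped,
    )


def parallelism_index(states: Sequence[str]) -> float:
    """Signed replicate-scaled fixation count for one window.

    index = (#A_fixed − #B_fixed) / n_replicates ∈ [−1, 1]; the numerator is
    an integer in [−n, n]. Swapping parental labels negates the index.
    """
    states = list(states)
    if not states:
        raise ValueError("need at least one replicate state")
    n_a = sum(s == STATE_A for s in states)
    n_b = sum(s == STATE_B for s in states)
    return (n_a - n_b) / len(states)


def parallelism_index_track(track: GenomicWindowTrack, replicate_samples: Sequence[str]) -> np.ndarray:
    """Per-window signed index over the given replicate sample columns."""
    idx = [track.samples.index(s) for s in replicate_samples]
    states = track.states()[:, idx]
    return np.array([parallelism_index(row) for row in states])


def _group_fixed_allele(states_row: np.ndarray) -> str | None:
    """Allele ('A'/'B') a replicate group is fixed for, or None.

    A group counts as fixed only when every member replicate is fixed for
    the same parental allele.
    """
    if (states_row == STATE_A).all():
        return "A"
    if (states_row == STATE_B).all():
        return "B"
    return None


def shared_fixed_windows(
    states_group1: np.ndarray, states_group2: np.ndarray
) -> tuple[int, int]:
    """Count windows where both replicate groups fixed the same parental allele.

    Inputs are windows × replicates state arrays on the same window set.
    Returns (n_same_allele, n_analyzed).
    """
    s1 = np.atleast_2d(np.asarray(states_group1, dtype=object))
    s2 = np.atleast_2d(np.asarray(states_group2, dtype=object))
    if s1.ndim != 2 or s2.ndim != 2 or s1.shape[0] != s2.shape[0]:
        raise ValueError("window sets of the two groups do not match")
    n_same = 0
    for row1, row2 in zip(s1, s2):
        a1, a2 = _group_fixed_allele(row1), _group_fixed_allele(row2)
        if a1 is not None and a1 == a2:
            n_same += 1
    return n_same, s1.shape[0]


def expected_shared_windows(n_windows: int, p_hom: float = F2_HOM_SPECIFIC_ALLELE) -> float:
    """Analytic chance-overlap: expected windows fixed for the same allele.

    ``p_hom`` is the probability that one F2 is homozygous for a specific
    parental allele (1/4 under Mendelian segregation); sharing either allele
    gives 2·p_hom² = 0.125, and the expectation scales linearly with the
    number of analyzed windows (63 for 504). Within-genome linkage is
    ignored, as in the back-of-envelope null.
    """
    if n_windows < 0:
        raise ValueError("n_windows must be >= 0")
    return 2.0 * p_hom * p_hom * n_windows


def simulate_shared_fixation(n_pairs: int, rng: np.random.Generator) -> float:
    """Monte-Carlo check of the F2 chance-overlap null at unlinked windows.

    Draws genotype dosages for pairs of independent F2s (0/1/2 copies of the
    A allele with probabilities 1/4, 1/2, 1/4) and returns the fraction of
    pairs homozygous for the same allele. Converges to 0.125.
    """
    d1 = rng.choice([0, 1, 2], size=n_pairs, p=[0.25, 0.5, 0.25])
    d2 = rng.choice([0, 1, 2], size=n_pairs, p=[0.25, 0.5, 0.25])
    same = ((d1 == 0) & (d2 == 0)) | ((d1 == 2) & (d2 == 2))
    return float(same.mean())
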