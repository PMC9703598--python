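"""Small self-contained statistics: mating-type fixation, multi-hit genes,
relative fitness ratios."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


def mating_type_binomial(n_fixed: int, n_total: int, p: float = 0.5) -> float:
    """Probability of exactly ``n_fixed`` of ``n_total`` replicates fixing one
    mating type by chance: the binomial pmf C(n, k) p^k (1−p)^(n−k).

    Fixing one allele in 4 of 5 replicates at p = 1/2 gives 0.15625.
    """
    if not (0 <= p <= 1):
        raise ValueError("p must be in [0, 1]")
    if not (0 <= n_fixed <= n_total):
        raise ValueError("need 0 <= n_fixed <= n_total")
    return float(sps.binom.pmf(n_fixed, n_total, p))


def multi_hit_probability(n_mutations: int, gene_weight: float, k: int) -> float:
    """P(gene hit by ≥ k of M independent mutations) under weighted placement.

    Mutations land on a gene independently with probability equal to its
    weight (e.g., its share of total coding length); the tail is binomial,
    P(X ≥ k) with X ~ Binomial(M, w). A low value flags more parallel hits
    than chance placement explains. The result depends on the chosen weights
    (gene universe and lengths), so probabilities are model-dependent.
    """
    if k < 0 or n_mutations < k:
        raise ValueError("need 0 <= k <= n_mutations")
    if not (0 < gene_weight < 1):
        raise ValueError("gene_weight must be in (0, 1)")
    if k == 0:
        return 1.0
    return float(sps.binom.sf(k - 1, n_mutations, gene_weight))


def gene_weights_from_lengths(lengths: dict[str, float]) -> dict[str, float]:
    """Coding-length share per gene (weights sum to 1)."""
    total = float(sum(lengths.values()))
    if total <= 0:
        raise ValueError("total coding length must be positive")
    return {g: length / total for g, length in lengths.items()}


@dataclass
class FitnessRatio:
    od_adapted: float
    mean_od_founder: float

    @property
    def ratio(self) -> float:
        return self.od_adapted / self.mean_od_founder


def relative_fitness(
    od_adapted: Sequence[float], od_founder: Sequence[float]
) -> list[FitnessRatio]:
    """Relative yield OD_adapted / mean(OD_founder), one ratio per measurement.

    A value > 1 means higher fitness than the founder mean. Homogeneous of
    degree 0 under a common rescaling of both OD vectors.
    """
    founder = np.asarray(list(od_founder), dtype=float)
    if founder.size == 0:
        raise ValueError("founder vector is empty")
    mean_founder = float(founder.mean())
    if mean_founder <= 0:
        raise ValueError("founder mean must be positive")
    return [FitnessRatio(float(a), mean_founder) for a in od_adapted]
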