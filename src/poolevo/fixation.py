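"""Fixation dynamics of standing variation.

Tracks the per-sample proportion of sites near fixation (MAF ≤ 0.1), fits a
three-parameter logistic to each replicate's time series, and compares
plateau heights and timings between environments with rank-based tests.
Proportions are computed per time point independently, so "unfixing" —
sites returning to intermediate frequency — is representable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


def proportion_nearly_fixed(freqs: np.ndarray, maf_threshold: float = 0.1) -> float:
    """Proportion of sites with minor allele frequency ≤ ``maf_threshold``.

    Symmetric in the A/B polarization. NaN (undefined) cells are not
    accepted: columns come from the shared filtered set.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("no sites")
    if np.isnan(freqs).any():
        raise ValueError("undefined frequencies; use the filtered shared site set")
    maf = np.minimum(freqs, 1.0 - freqs)
    return float((maf <= maf_threshold).mean())


@dataclass
class FixationSeries:
    """Per-replicate proportion of nearly fixed sites over generations."""

    replicate: str
    environment: str
    generations: np.ndarray
    proportions: np.ndarray
    maf_threshold: float = 0.1

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if not (np.diff(self.generations) > 0).all():
            raise ValueError("generations must be strictly increasing")
        if ((self.proportions < 0) | (self.proportions > 1)).any():
            raise ValueError("proportions must be in [0, 1]")


@dataclass
class SigmoidFit:
    """Fitted logistic y(t) = L / (1 + exp(−k (t − t0))).

    ``plateau_time`` is the first generation at which the fitted curve
    reaches ``plateau_q``·L (the 95%-of-maximum crossing by default),
    clamped to be non-negative.
    """

    L: float
    k: float
    t0: float
    rss: float
    plateau_time: float
    converged: bool
    plateau_q: float = 0.95


def _logistic(t: np.ndarray, L: float, k: float, t0: float) -> np.ndarray:
    return L / (1.0 + np.exp(-k * (t - t0)))


def fit_sigmoid(series: FixationSeries, plateau_q: float = 0.95) -> SigmoidFit:
    """Least-squares logistic fit of one replicate's fixation series.

    Bounds L ∈ [0, 1], k ≥ 0; initialization L₀ = max observed proportion,
    t0₀ = first generation with y ≥ L₀/2, k₀ = 0.01. Degenerate flat series
    (the k → 0 limit, where the curve is the constant L/2) are reported with
    L equal to the fitted constant and plateau_time at the first generation.
    """
    t, y = series.generations, series.proportions
    if len(t) < 4:
        raise ValueError("need at least 4 time points for a sigmoid fit")
    L0 = max(float(y.max()), 1e-6)
    above = np.flatnonzero(y >= L0 / 2.0)
    t00 = float(t[above[0]]) if len(above) else float(t[0])
    x0 = np.array([L0, 0.01, t00])

    def residuals(p: np.ndarray) -> np.ndarray:
        return _logistic(t, *p) - y

    res = optimize.least_squares(
        residuals,
        x0,
        bounds=([0.0, 0.0, -np.inf], [1.0, np.inf, np.inf]),
        max_nfev=10_000,
    )
    L, k, t0 = (float(v) for v in res.x)
    rss = float((res.fun**2).sum())
    fitted = _logistic(t, L, k, t0)

    if fitted.max() - fitted.min() < 1e-9:  # flat: constant-curve limit
        return SigmoidFit(
            L=float(fitted.mean()), k=k, t0=t0, rss=rss,
            plateau_time=float(t[0]), converged=bool(res.success), plateau_q=plateau_q,
        )
    if k <= 0:
        crossing = np.inf
    else:
        crossing = t0 + np.log(plateau_q / (1.0 - plateau_q)) / k
    return SigmoidFit(
        L=L, k=k, t0=t0, rss=rss,
        plateau_time=float(max(0.0, crossing)),
        converged=bool(res.success), plateau_q=plateau_q,
    )


def fixation_series_from_frequencies(
    freq: np.ndarray,
    generations: Sequence[int],
    replicate: str = "",
    environment: str = "",
    maf_threshold: float = 0.1,
) -> FixationSeries:
    """Build a series from a sites × generations frequency matrix."""
    props = [proportion_nearly_fixed(freq[:, j], maf_threshold) for j in range(freq.shape[1])]
    return FixationSeries(
        replicate=replicate, environment=environment,
        generations=np.asarray(list(generations), dtype=float),
        proportions=np.asarray(props), maf_threshold=maf_threshold,
    )


@dataclass
class EnvironmentSummary:
    """Environment-level comparison of plateau heights and timings."""

    table: pd.DataFrame  # per replicate: environment, L, plateau_time
    kruskal_L: tuple[float, float]  # (H, p) across environments on L
    kruskal_plateau: tuple[float, float]
    pairwise: pd.DataFrame  # env pair, variable, statistic, p, p_bonferroni


def summarize_environments(
    fits: dict[str, list[SigmoidFit]],
) -> EnvironmentSummary:
    """Kruskal–Wallis across environments and Bonferroni-corrected pairwise
    rank-sum tests on the fitted maxima (L) and plateau timings.

    Environments with a single replicate are excluded from pairwise tests
    with a warning. The rank tests are standard routines, not re-derived.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 environments")
    rows = [
        {"environment": env, "L": f.L, "plateau_time": f.plateau_time}
        for env, fs in fits.items()
        for f in fs
    ]
    table = pd.DataFrame(rows)

    def kruskal(col: str) -> tuple[float, float]:
        groups = [g[col].to_numpy() for _, g in table.groupby("environment")]
        if np.ptp(np.concatenate(groups)) == 0:
            return 0.0, 1.0  # identical values everywhere: no between-group variation
        h, p = stats.kruskal(*groups)
        return float(h), float(p)

    pair_rows = []
    eligible = [env for env, fs in fits.items() if len(fs) >= 2]
    for env in fits:
        if env not in eligible:
            warnings.warn(f"environment {env!r} has a single replicate; excluded from pairwise tests")
    pairs = list(combinations(sorted(eligible), 2))
    n_tests = max(1, len(pairs))
    for a, b in pairs:
        for col in ("L", "plateau_time"):
            xa = table.loc[table["environment"] == a, col].to_numpy()
            xb = table.loc[table["environment"] == b, col].to_numpy()
            stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="exact")
            pair_rows.append(
                {
                    "env_a": a, "env_b": b, "variable": col,
                    "statistic": float(stat), "p": float(p),
                    "p_bonferroni": float(min(1.0, p * n_tests)),
                }
            )
    return EnvironmentSummary(
        table=table,
        kruskal_L=kruskal("L"),
        kruskal_plateau=kruskal("plateau_time"),
        pairwise=pd.DataFrame(pair_rows),
    )
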