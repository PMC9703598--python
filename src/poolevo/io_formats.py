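"""Readers, writers and the polarized site-by-sample data model.

The backbone container is :class:`SiteTable`: biallelic sites with per-sample
read counts for the two parental alleles, polarized so that allele A is the
allele carried by the homozygous parent-A strain (SK1 in the original cross).
All genomic coordinates are 1-based and intervals are closed; BED input is
converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLES = ("parent_A", "parent_B", "founder", "evolved")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequenced pool or parental strain."""

    sample_id: str
    role: str
    environment: str = ""
    replicate: str = ""
    generation: int = 0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for sample {self.sample_id!r}")
        if self.generation < 0:
            raise ValueError(f"negative generation for sample {self.sample_id!r}")


def validate_sample_metas(metas: Sequence[SampleMeta]) -> None:
    """Enforce the dataset-level invariants on a sample sheet."""
    for role in ("parent_A", "parent_B"):
        n = sum(m.role == role for m in metas)
        if n != 1:
            raise ValueError(f"expected exactly one {role} sample, found {n}")
    seen = set()
    for m in metas:
        if m.role == "evolved":
            key = (m.environment, str(m.replicate), m.generation)
            if key in seen:
                raise ValueError(f"duplicate evolved sample key {key}")
            seen.add(key)
        if m.role == "founder" and m.generation != 0:
            raise ValueError(f"founder sample {m.sample_id!r} must have generation 0")


@dataclass
class SiteTable:
    """Polarized biallelic sites × samples with allele read counts.

    ``sites`` has columns chrom, pos, allele_A, allele_B, variant_class; rows
    are sorted by (chrom, pos) with positions strictly increasing within a
    chromosome. ``count_a[i, j]`` is the number of reads supporting allele A
    of site i in sample j.
    """

    sites: pd.DataFrame
    samples: list[str]
    count_a: np.ndarray
    count_b: np.ndarray
    n_multiallelic_skipped: int = 0

    def __post_init__(self) -> None:
        n, m = len(self.sites), len(self.samples)
        if self.count_a.shape != (n, m) or self.count_b.shape != (n, m):
            raise ValueError("count matrices do not match sites × samples")
        if (self.count_a < 0).any() or (self.count_b < 0).any():
            raise ValueError("negative read counts")
        for _, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing within a chromosome")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def depth(self) -> np.ndarray:
        return self.count_a + self.count_b

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in table") from None

    def subset_sites(self, mask: np.ndarray) -> "SiteTable":
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            sites=self.sites.loc[mask].reset_index(drop=True),
            count_a=self.count_a[mask],
            count_b=self.count_b[mask],
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "SiteTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return replace(
            self,
            samples=list(sample_ids),
            count_a=self.count_a[:, idx],
            count_b=self.count_b[:, idx],
        )

    def swap_polarization(self) -> "SiteTable":
        """Swap the parent-A/parent-B allele labels (freq_A ↦ 1 − freq_A)."""
        sites = self.sites.copy()
        sites[["allele_A", "allele_B"]] = sites[["allele_B", "allele_A"]].to_numpy()
        return replace(self, sites=sites, count_a=self.count_b.copy(), count_b=self.count_a.copy())


@dataclass
class FrequencyMatrix:
    """Sites × samples matrix of parent-A allele frequencies.

    Cells with zero depth are undefined and stored as NaN; they are never
    silently treated as 0.
    """

    sites: pd.DataFrame
    samples: list[str]
    freq: np.ndarray
    depth: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.freq)

    def column(self, sample_id: str) -> np.ndarray:
        return self.freq[:, self.samples.index(sample_id)]


@dataclass
class MappabilityTrack:
    """Non-overlapping intervals (1-based, closed) with mappability values.

    Positions not covered by any interval are taken to be fully mappable
    (value 1.0), matching tracks that list only the problematic regions.
    """

    intervals: pd.DataFrame  # chrom, start, end, value

    def __post_init__(self) -> None:
        df = self.intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
        for _, grp in df.groupby("chrom", sort=False):
            if (grp["start"].to_numpy()[1:] <= grp["end"].to_numpy()[:-1]).any():
                raise ValueError("overlapping mappability intervals")
        if ((df["value"] <= 0) | (df["value"] > 1)).any():
            raise ValueError("mappability values must be in (0, 1]")
        self.intervals = df

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions)
        out = np.ones(len(positions), dtype=float)
        sub = self.intervals[self.intervals["chrom"] == chrom]
        for start, end, value in sub[["start", "end", "value"]].itertuples(index=False):
            out[(positions >= start) & (positions <= end)] = value
        return out


@dataclass
class DepthTrack:
    """Per-position mean depth records, sorted by (chrom, pos)."""

    records: pd.DataFrame  # chrom, pos, depth

    def __post_init__(self) -> None:
        df = self.records
        if (df["depth"] < 0).any() or not np.isfinite(df["depth"]).all():
            raise ValueError("depths must be finite and non-negative")
        self.records = df.sort_values(["chrom", "pos"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read a TSV sample sheet (sample_id, role, environment, replicate, generation)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "replicate": str})
    required = {"sample_id", "role", "environment", "replicate", "generation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    metas = [
        SampleMeta(
            sample_id=row.sample_id,
            role=row.role,
            environment="" if pd.isna(row.environment) else str(row.environment),
            replicate="" if pd.isna(row.replicate) else str(row.replicate),
            generation=int(row.generation),
        )
        for row in df.itertuples(index=False)
    ]
    validate_sample_metas(metas)
    return metas


def _major_allele_index(ad: np.ndarray) -> int:
    """Index (0=ref, 1=alt) of the majority allele in one sample's AD pair."""
    return int(ad[1] > ad[0])


def read_variant_table(
    vcf_path: str | Path, sample_sheet_path: str | Path
) -> tuple[SiteTable, list[SampleMeta]]:
    """Parse a VCF with FORMAT/AD into a polarized :class:`SiteTable`.

    Multiallelic records are skipped (counted in ``n_multiallelic_skipped``).
    Polarization sets allele A to the allele called in the parent-A sample
    (its majority allele by read count); sites where parent A has no
    coverage keep the reference allele as allele A.
    """
    from cyvcf2 import VCF

    metas = read_sample_sheet(sample_sheet_path)
    meta_by_id = {m.sample_id: m for m in metas}

    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    for s in vcf_samples:
        if s not in meta_by_id:
            raise ValueError(f"sample {s!r} present in VCF but absent from sample sheet")
    parent_a_id = next(m.sample_id for m in metas if m.role == "parent_A")
    if parent_a_id not in vcf_samples:
        raise ValueError(f"parent_A sample {parent_a_id!r} not in VCF")
    ia = vcf_samples.index(parent_a_id)

    rows = []
    counts_a, counts_b = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        ad = var.format("AD")
        if ad is None:
            raise ValueError(f"record {var.CHROM}:{var.POS} has no FORMAT/AD field")
        ad = np.asarray(ad, dtype=np.int64)
        ad[ad < 0] = 0  # cyvcf2 encodes missing AD as negative sentinels
        ref, alt = var.REF, var.ALT[0]
        variant_class = "SNP" if len(ref) == 1 and len(alt) == 1 else "INDEL"
        a_idx = _major_allele_index(ad[ia]) if ad[ia].sum() > 0 else 0
        allele_a, allele_b = (ref, alt) if a_idx == 0 else (alt, ref)
        rows.append((var.CHROM, var.POS, allele_a, allele_b, variant_class))
        counts_a.append(ad[:, a_idx])
        counts_b.append(ad[:, 1 - a_idx])
    if n_skipped:
        logger.info("skipped %d multiallelic records", n_skipped)

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "allele_A", "allele_B", "variant_class"])
    table = SiteTable(
        sites=sites,
        samples=vcf_samples,
        count_a=np.array(counts_a, dtype=np.int64).reshape(len(sites), len(vcf_samples)),
        count_b=np.array(counts_b, dtype=np.int64).reshape(len(sites), len(vcf_samples)),
        n_multiallelic_skipped=n_skipped,
    )
    return table, metas


def compute_frequencies(table: SiteTable) -> FrequencyMatrix:
    """Parent-A allele frequencies; zero-depth cells are NaN (undefined)."""
    depth = table.depth().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth > 0, table.count_a / np.where(depth > 0, depth, 1.0), np.nan)
    return FrequencyMatrix(
        sites=table.sites.copy(), samples=list(table.samples), freq=freq, depth=depth
    )


def read_depth_track(path: str | Path) -> DepthTrack:
    """Read a samtools-depth style TSV (chrom, pos, depth), 1-based positions."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: malformed row at line {lineno}")
            try:
                chrom, pos, depth = parts[0], int(parts[1]), float(parts[2])
            except ValueError:
                raise ValueError(f"{path}: malformed row at line {lineno}") from None
            if depth < 0:
                raise ValueError(f"{path}: negative depth at line {lineno}")
            rows.append((chrom, pos, depth))
    return DepthTrack(pd.DataFrame(rows, columns=["chrom", "pos", "depth"]))


def read_mappability_bed(path: str | Path) -> MappabilityTrack:
    """Read a mappability BED (0-based half-open) into 1-based closed intervals."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        usecols=[0, 1, 2, 3],
    )
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return MappabilityTrack(df)


def write_frequency_table(fm: FrequencyMatrix, path: str | Path, precision: int = 6) -> None:
    """Write a frequency matrix as TSV; undefined cells become ``NA``."""
    out = fm.sites[["chrom", "pos"]].copy()
    for j, s in enumerate(fm.samples):
        out[s] = np.round(fm.freq[:, j], precision)
        out[f"{s}.depth"] = fm.depth[:, j].astype(int)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=f"%.{precision}f")


def read_frequency_table(path: str | Path) -> FrequencyMatrix:
    """Read a TSV written by :func:`write_frequency_table`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    samples = [c for c in df.columns if c not in ("chrom", "pos") and not c.endswith(".depth")]
    freq = df[samples].to_numpy(dtype=float)
    depth = df[[f"{s}.depth" for s in samples]].to_numpy(dtype=float)
    sites = df[["chrom", "pos"]].copy()
    return FrequencyMatrix(sites=sites, samples=samples, freq=freq, depth=depth)
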