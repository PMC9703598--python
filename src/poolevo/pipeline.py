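"""End-to-end orchestration: filter → haplotypes → fixation → parallelism → CNV.

One flat config drives every stage; all randomness flows from a single
global seed through per-stage derived seeds, and a manifest records the
parameters and per-stage input/output counts so each stage can be rerun
from the previous stage's on-disk outputs with identical results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .copynumber import CnvParams, chromosome_summary, summaries_to_frame, window_depth_means
from .filters import FilterParams, classification_counts, detect_denovo, filter_standing_variants, group_linked_mutations
from .fixation import FixationSeries, fit_sigmoid, fixation_series_from_frequencies, summarize_environments
from .haplotypes import cluster_haplotypes, normalize_trajectories, representative_trajectories
from .io_formats import (
    FrequencyMatrix,
    SampleMeta,
    compute_frequencies,
    read_depth_track,
    read_mappability_bed,
    read_variant_table,
    write_frequency_table,
)
from .parallelism import make_windows, parallelism_index_track

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str = ""
    sample_sheet: str = ""
    depth_dir: str = ""
    mappability: str = ""
    out_dir: str = "poolevo_out"
    filter_params: FilterParams = field(default_factory=FilterParams)
    cluster_min_size: int = 10
    fixation_maf: float = 0.1
    plateau_q: float = 0.95
    window_size: int = 10_000
    window_min_snps: int = 4
    cnv_params: CnvParams = field(default_factory=CnvParams)
    seed: int = 0


def stage_seed(config_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the single global seed."""
    import zlib

    ss = np.random.SeedSequence([config_seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def replicate_frequency_matrix(
    fm: FrequencyMatrix, metas: list[SampleMeta], environment: str, replicate: str
) -> tuple[np.ndarray, list[int]]:
    """Sites × generations frequencies for one replicate, founder at gen 0."""
    meta_by_id = {m.sample_id: m for m in metas}
    cols: list[tuple[int, int]] = []
    for j, s in enumerate(fm.samples):
        m = meta_by_id[s]
        if m.role == "founder":
            cols.append((0, j))
        elif (
            m.role == "evolved"
            and m.environment == environment
            and str(m.replicate) == str(replicate)
        ):
            cols.append((m.generation, j))
    cols.sort()
    gens = [g for g, _ in cols]
    return fm.freq[:, [j for _, j in cols]], gens


def evolved_groups(metas: list[SampleMeta]) -> dict[str, list[str]]:
    """environment -> sorted replicate ids among evolved samples."""
    groups: dict[str, set[str]] = {}
    for m in metas:
        if m.role == "evolved":
            groups.setdefault(m.environment, set()).add(str(m.replicate))
    return {env: sorted(reps) for env, reps in sorted(groups.items())}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("poolevo")
    root.addHandler(fh)
    root.setLevel(logging.INFO)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    logger.info("pipeline start, seed=%d", config.seed)

    try:
        stage = "read"
        for path in (config.vcf, config.sample_sheet):
            if not Path(path).exists():
                raise FileNotFoundError(f"input file not found: {path}")
        table, metas = read_variant_table(config.vcf, config.sample_sheet)
        manifest["stages"]["read"] = {
            "n_sites": table.n_sites,
            "n_samples": len(table.samples),
            "n_multiallelic_skipped": table.n_multiallelic_skipped,
        }

        stage = "filter"
        mapp = None
        if config.mappability:
            if not Path(config.mappability).exists():
                raise FileNotFoundError(f"mappability file not found: {config.mappability}")
            mapp = read_mappability_bed(config.mappability)
        filtered, removal_log = filter_standing_variants(
            table, metas, mapp, config.filter_params
        )
        fm = compute_frequencies(filtered)
        write_frequency_table(fm, out / "standing_frequencies.tsv")
        manifest["stages"]["filter"] = {
            "n_retained": filtered.n_sites,
            "removal_log": removal_log,
        }

        stage = "denovo"
        denovo_rows = []
        for env in evolved_groups(metas):
            records = group_linked_mutations(
                detect_denovo(table, metas, config.filter_params, environment=env)
            )
            for r in records:
                denovo_rows.append(
                    {
                        "chrom": r.chrom, "pos": r.pos, "allele": r.allele,
                        "environment": r.environment, "classification": r.classification,
                        "max_freq": r.max_freq, "linked_group_id": r.linked_group_id,
                    }
                )
            manifest["stages"].setdefault("denovo", {})[env] = classification_counts(records)
        pd.DataFrame(
            denovo_rows,
            columns=[
                "chrom", "pos", "allele", "environment", "classification",
                "max_freq", "linked_group_id",
            ],
        ).to_csv(out / "denovo_mutations.tsv", sep="\t", index=False)

        stage = "haplotypes"
        hap_counts = {}
        membership_rows = []
        for env, reps in evolved_groups(metas).items():
            for rep in reps:
                freq, gens = replicate_frequency_matrix(fm, metas, env, rep)
                if freq.shape[1] < 3 or freq.shape[0] < config.cluster_min_size:
                    continue
                traj = normalize_trajectories(freq, gens, site_keys=list(range(fm.n_sites)))
                clusters = cluster_haplotypes(
                    traj,
                    min_size=config.cluster_min_size,
                    seed=stage_seed(config.seed, f"haplotypes/{env}/{rep}"),
                    replicate=f"{env}_{rep}",
                )
                hap_counts[f"{env}_{rep}"] = {
                    "cutoff": clusters.chosen_cutoff,
                    "n_clusters": clusters.n_clusters,
                }
                for ci, members in enumerate(clusters.clusters):
                    for k in members:
                        membership_rows.append(
                            {
                                "environment": env, "replicate": rep, "cluster": ci,
                                "chrom": fm.sites["chrom"].iloc[k],
                                "pos": int(fm.sites["pos"].iloc[k]),
                                "representative": k == clusters.representatives[ci],
                            }
                        )
        pd.DataFrame(
            membership_rows,
            columns=["environment", "replicate", "cluster", "chrom", "pos", "representative"],
        ).to_csv(out / "haplotype_clusters.tsv", sep="\t", index=False)
        manifest["stages"]["haplotypes"] = hap_counts

        stage = "fixation"
        fits_by_env: dict[str, list] = {}
        fit_rows = []
        for env, reps in evolved_groups(metas).items():
            for rep in reps:
                freq, gens = replicate_frequency_matrix(fm, metas, env, rep)
                if freq.shape[1] < 4:
                    continue
                series = fixation_series_from_frequencies(
                    freq, gens, replicate=rep, environment=env,
                    maf_threshold=config.fixation_maf,
                )
                fit = fit_sigmoid(series, plateau_q=config.plateau_q)
                fits_by_env.setdefault(env, []).append(fit)
                fit_rows.append(
                    {
                        "environment": env, "replicate": rep, "L": fit.L, "k": fit.k,
                        "t0": fit.t0, "plateau_time": fit.plateau_time,
                        "converged": fit.converged,
                    }
                )
        pd.DataFrame(
            fit_rows,
            columns=["environment", "replicate", "L", "k", "t0", "plateau_time", "converged"],
        ).to_csv(out / "fixation_fits.tsv", sep="\t", index=False)
        if len(fits_by_env) >= 2:
            summary = summarize_environments(fits_by_env)
            summary.table.to_csv(out / "environment_summary.tsv", sep="\t", index=False)
            summary.pairwise.to_csv(out / "environment_pairwise.tsv", sep="\t", index=False)
            manifest["stages"]["fixation"] = {
                "kruskal_L": summary.kruskal_L,
                "kruskal_plateau": summary.kruskal_plateau,
            }
        else:
            manifest["stages"]["fixation"] = {"n_fits": len(fit_rows)}

        stage = "parallelism"
        track = make_windows(
            fm, window_size=config.window_size, min_snps=config.window_min_snps,
            maf_threshold=config.fixation_maf,
        )
        index_rows = []
        meta_by_id = {m.sample_id: m for m in metas}
        gens_by_env: dict[str, set[int]] = {}
        for m in metas:
            if m.role == "evolved":
                gens_by_env.setdefault(m.environment, set()).add(m.generation)
        for env, gens in gens_by_env.items():
            for gen in sorted(gens):
                cols = [
                    s
                    for s in track.samples
                    if meta_by_id[s].role == "evolved"
                    and meta_by_id[s].environment == env
                    and meta_by_id[s].generation == gen
                ]
                if not cols:
                    continue
                idx = parallelism_index_track(track, cols)
                for w, v in zip(track.windows.itertuples(index=False), idx):
                    index_rows.append(
                        {
                            "chrom": w.chrom, "start": w.start, "end": w.end,
                            "environment": env, "generation": gen,
                            "index": v, "n_replicates": len(cols),
                        }
                    )
        pd.DataFrame(
            index_rows,
            columns=["chrom", "start", "end", "environment", "generation", "index", "n_replicates"],
        ).to_csv(out / "parallelism_index.tsv", sep="\t", index=False)
        manifest["stages"]["parallelism"] = {
            "n_windows": track.n_windows,
            "n_dropped_windows": track.n_dropped_windows,
        }

        stage = "cnv"
        cnv_frames = []
        if config.depth_dir and Path(config.depth_dir).exists():
            for path in sorted(Path(config.depth_dir).glob("depth_*.tsv")):
                sample = path.stem.replace("depth_", "")
                dt = read_depth_track(path)
                wm = window_depth_means(dt, config.cnv_params.bin_size)
                cnv_frames.append(
                    summaries_to_frame(chromosome_summary(wm, sample, config.cnv_params))
                )
        if cnv_frames:
            cnv = pd.concat(cnv_frames, ignore_index=True)
            cnv.to_csv(out / "cnv_summary.tsv", sep="\t", index=False)
            manifest["stages"]["cnv"] = {
                "n_samples": len(cnv_frames),
                "n_calls": int((cnv["call"].isin(["gain", "loss"])).sum()),
            }
        else:
            manifest["stages"]["cnv"] = {"n_samples": 0}
    except Exception as exc:
        logger.exception("stage %s failed", stage)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(fh)
        fh.close()

    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    _write_summary(out, manifest)
    return manifest


def _write_summary(out: Path, manifest: dict) -> None:
    lines = [f"poolevo {manifest['version']} run summary (seed {manifest['seed']})"]
    for stage, info in manifest["stages"].items():
        lines.append(f"[{stage}] {json.dumps(info, default=str)}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")


def demo_config() -> "PipelineConfig":
    """Built-in desk-scale demo configuration (used with a simulated fixture)."""
    return PipelineConfig()
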