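"""One-config orchestration of the full scan pipeline.

A run config (YAML or dict) names either an input VCF + manifest or a
synthetic scenario (exactly one of the two), an output directory, a seed,
and one parameter block per stage to execute:

    seed: 1
    out_dir: out/
    scenario: {pop_sizes: {popA: 25, popB: 25}, fst: 0.1, ...}
    # or: vcf: calls.vcf, manifest: samples.tsv [, reference: ref.fa]
    windows: {size: 40000, step: 20000, min_snps: 20, stat: theta_pi, pop: popA}
    heterozygosity: {window_size: 500000, z_contigs: [chrZ], test: t_two_tailed}
    sweep: {target: popA, reference: popB, quantile: 0.95 [, genes: genes.bed]}
    dstat: {p1: popA, p2: popB, p3: popC, block_size: 1000000}
    isochore: {window_size: auto}          # needs a reference
    afd: {group_a: popA, group_b: popB, hi: 0.8, lo: 0.2, p_max: 0.001}
    ld: {pop: popA, max_dist: 40000, bin_width: 1000}

Stages run in dependency order; every output TSV carries the seed and the
stage parameters as ``# key=value`` comment lines, so reruns of the same
config + seed are byte-identical.  Any stage error aborts the run with the
stage name attached.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import afd_screen, introgression, isochores, ld_decay, sweep_scan, windowed_stats
from .core_io import (
    GenotypeMatrix,
    PopscanError,
    PopulationManifest,
    read_reference,
    read_variants,
    write_json,
    write_regions_bed,
    write_table,
)
from .synthetic_data import (
    IntrogressionSpec,
    ScenarioConfig,
    SimulatedCohort,
    SweepSpec,
    simulate_cohort,
)

STAGE_ORDER = ("simulate", "windows", "heterozygosity", "sweep", "dstat", "isochore", "afd", "ld")


class StageError(PopscanError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PopscanError("run config must be a mapping")
    return cfg


def scenario_from_dict(d: Mapping[str, Any], seed: int) -> ScenarioConfig:
    d = dict(d)
    sweeps = [SweepSpec(**s) for s in d.pop("sweeps", [])]
    intro = [IntrogressionSpec(**s) for s in d.pop("introgressions", [])]
    contigs = [tuple(c) for c in d.pop("contigs", [("chr1", 10_000_000)])]
    z_contigs = tuple(d.pop("z_contigs", ()))
    return ScenarioConfig(
        contigs=contigs, z_contigs=z_contigs, sweeps=sweeps, introgressions=intro,
        seed=seed, **d,
    )


def run(config: Mapping[str, Any] | str | Path) -> dict:
    """Execute the configured stages; returns the machine-readable summary."""
    if not isinstance(config, Mapping):
        config = load_config(config)
    cfg = dict(config)
    if "seed" not in cfg:
        raise PopscanError("run config requires a seed")
    seed = int(cfg["seed"])
    out_dir = Path(cfg.get("out_dir", "popscan_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    has_vcf = "vcf" in cfg
    has_scenario = "scenario" in cfg
    if has_vcf == has_scenario:
        raise PopscanError("config must name exactly one of 'vcf' or 'scenario'")

    meta_base = {"seed": seed, "popscan_config": "inline"}
    summary: dict[str, Any] = {"seed": seed, "out_dir": str(out_dir), "stages": {}}
    produced: list[str] = []

    cohort: SimulatedCohort | None = None
    reference = None
    try:
        if has_scenario:
            scen = scenario_from_dict(cfg["scenario"], seed)
            cohort = simulate_cohort(scen)
            paths = cohort.write(out_dir)
            produced += [str(p) for p in paths.values()]
            matrix, manifest = cohort.matrix, cohort.manifest
            summary["stages"]["simulate"] = {
                "n_sites": matrix.n_sites,
                "n_samples": matrix.n_samples,
                "n_sweeps": len(cohort.truth["sweeps"]),
                "n_introgression_tracts": len(cohort.truth["introgression_tracts"]),
            }
        else:
            matrix, manifest = read_variants(cfg["vcf"], cfg.get("manifest"))
            if manifest is None:
                raise PopscanError("a manifest is required alongside the VCF")
        if "reference" in cfg:
            reference = read_reference(cfg["reference"])
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError("input", exc) from exc

    def _stage(name: str):
        block = cfg.get(name)
        return dict(block) if isinstance(block, Mapping) else None

    def _samples(pop: str) -> list[str]:
        return manifest.samples_of(pop)

    # -- windowed statistics ------------------------------------------------
    block = _stage("windows")
    window_frames: dict[tuple, pd.DataFrame] = {}
    if block is not None:
        try:
            spec = windowed_stats.WindowSpec(
                size=int(block.get("size", 40_000)),
                step=int(block.get("step", 20_000)),
                min_snps=int(block.get("min_snps", 20)),
            )
            frame = windowed_stats.make_windows(matrix.contigs, spec)
            stat = block.get("stat", "theta_pi")
            pop = block["pop"]
            table = windowed_stats.window_diversity(
                matrix, _samples(pop), frame, stat, min_snps=spec.min_snps
            )
            p = out_dir / f"windows_{stat}_{pop}.tsv"
            write_table(table, p, {**meta_base, "stage": "windows", **block})
            produced.append(str(p))
            summary["stages"]["windows"] = {
                "n_windows": len(table),
                "stat": stat,
                "pop": pop,
                "mean_value": float(np.nanmean(table[stat].to_numpy(dtype=float)))
                if table[stat].notna().any() else None,
            }
        except Exception as exc:
            raise StageError("windows", exc) from exc

    # -- heterozygosity scan -------------------------------------------------
    block = _stage("heterozygosity")
    if block is not None:
        try:
            size = int(block.get("window_size", 500_000))
            spec = windowed_stats.WindowSpec(size=size, step=size, min_snps=0)
            frame = windowed_stats.make_windows(matrix.contigs, spec)
            samples = (
                _samples(block["pop"]) if "pop" in block else list(manifest.populations)
            )
            het = windowed_stats.window_diversity(
                matrix, samples, frame, "het_count", min_snps=0
            )
            p = out_dir / "heterozygosity_windows.tsv"
            write_table(het, p, {**meta_base, "stage": "heterozygosity", **block})
            produced.append(str(p))
            info: dict[str, Any] = {"n_windows": len(het)}
            if block.get("z_contigs"):
                tests = windowed_stats.compare_chromosome_groups(
                    het, block["z_contigs"], block.get("test", "t_two_tailed")
                )
                p2 = out_dir / "z_vs_autosome_tests.tsv"
                write_table(tests, p2, {**meta_base, "stage": "heterozygosity"})
                produced.append(str(p2))
                pooled = tests[tests["autosome"] == "all_autosomes"].iloc[0]
                info["pooled_p_value"] = float(pooled["p_value"])
            summary["stages"]["heterozygosity"] = info
        except Exception as exc:
            raise StageError("heterozygosity", exc) from exc

    # -- sweep scan -----------------------------------------------------------
    block = _stage("sweep")
    if block is not None:
        try:
            spec = windowed_stats.WindowSpec(
                size=int(block.get("size", 40_000)),
                step=int(block.get("step", 20_000)),
                min_snps=int(block.get("min_snps", 20)),
            )
            frame = windowed_stats.make_windows(matrix.contigs, spec)
            target, ref_pop = block["target"], block["reference"]
            z_contigs = tuple(block.get("z_contigs", ()))
            # the SNP-count gate lives on the cross-population FST table;
            # per-population pi is computed ungated so sweep-fixed windows
            # (monomorphic in the target alone) stay comparable
            _, fst_tab = sweep_scan.weir_cockerham_fst(
                matrix, _samples(target), _samples(ref_pop), frame,
                min_snps=spec.min_snps,
            )
            pi_t = windowed_stats.window_diversity(
                matrix, _samples(target), frame, "theta_pi", min_snps=0
            )
            pi_r = windowed_stats.window_diversity(
                matrix, _samples(ref_pop), frame, "theta_pi", min_snps=0
            )
            ratio = sweep_scan.log2_pi_ratio(pi_r, pi_t)
            d_t = windowed_stats.window_diversity(
                matrix, _samples(target), frame, "tajimas_d", min_snps=0
            )
            d_r = windowed_stats.window_diversity(
                matrix, _samples(ref_pop), frame, "tajimas_d", min_snps=0
            )
            regions = sweep_scan.call_sweep_regions(
                fst_tab, ratio, d_t, d_r,
                quantile=float(block.get("quantile", 0.95)),
                z_contigs=z_contigs,
            )
            if "genes" in block:
                from .core_io import read_gene_intervals

                regions = sweep_scan.annotate_regions(
                    regions, read_gene_intervals(block["genes"])
                )
            meta = {**meta_base, "stage": "sweep", **{k: v for k, v in block.items()}}
            for name, df in (
                ("sweep_windows_fst", fst_tab),
                ("sweep_windows_pi_ratio", ratio),
                ("sweep_regions", regions),
            ):
                p = out_dir / f"{name}.tsv"
                write_table(df, p, meta)
                produced.append(str(p))
            bed = out_dir / "sweep_regions.bed"
            write_regions_bed(regions, bed)
            produced.append(str(bed))
            contrast = None
            if len(regions):
                contrast = sweep_scan.background_contrast(
                    regions, fst_tab, ratio, z_contigs
                )
                p = out_dir / "sweep_background_contrast.tsv"
                write_table(contrast, p, meta)
                produced.append(str(p))
            summary["stages"]["sweep"] = {
                "n_regions": len(regions),
                "total_region_bp": int((regions["end"] - regions["start"]).sum())
                if len(regions) else 0,
                "max_fst": float(regions["fst_max"].max()) if len(regions) else None,
            }
        except Exception as exc:
            raise StageError("sweep", exc) from exc

    # -- D-statistic ----------------------------------------------------------
    block = _stage("dstat")
    if block is not None:
        try:
            outgroup_pop = block.get("outgroup", "outgroup")
            res, report = introgression.d_statistic_from_matrix(
                matrix,
                _samples(block["p1"]),
                _samples(block["p2"]),
                _samples(block["p3"]),
                _samples(outgroup_pop),
                block_size=int(block.get("block_size", 1_000_000)),
            )
            df = pd.DataFrame([dataclasses.asdict(res)])
            p = out_dir / "dstat.tsv"
            write_table(df, p, {**meta_base, "stage": "dstat", **block})
            produced.append(str(p))
            summary["stages"]["dstat"] = {**dataclasses.asdict(res), **report}
        except Exception as exc:
            raise StageError("dstat", exc) from exc

    # -- isochores ------------------------------------------------------------
    block = _stage("isochore")
    if block is not None:
        try:
            if reference is None:
                raise PopscanError("isochore stage requires a reference FASTA")
            wanted = block.get("window_size", "auto")
            if wanted == "auto":
                sizes = block.get("candidate_sizes", (10_000, 20_000, 50_000, 100_000))
                window_size, sd_table = isochores.choose_gc_window(reference, sizes)
                p = out_dir / "isochore_gc_sd.tsv"
                write_table(sd_table, p, {**meta_base, "stage": "isochore"})
                produced.append(str(p))
            else:
                window_size = int(wanted)
            segments = isochores.segment_isochores(reference, window_size)
            p = out_dir / "isochore_segments.tsv"
            write_table(segments, p, {**meta_base, "stage": "isochore",
                                      "window_size": window_size})
            produced.append(str(p))
            info = {"window_size": window_size, "n_segments": len(segments)}
            if block.get("correlate", True) and matrix.n_sites:
                classified = segments[segments["family"] != isochores.GAP]
                if len(classified) >= 3:
                    rep = isochores.variant_gc_correlation(
                        segments, matrix, block.get("variant_class", "snp")
                    )
                    info["pearson_r"] = rep["pearson_r"]
                    info["p_value"] = rep["p_value"]
                    p = out_dir / "isochore_variant_density.tsv"
                    write_table(rep["segments"], p, {**meta_base, "stage": "isochore"})
                    produced.append(str(p))
            summary["stages"]["isochore"] = info
        except Exception as exc:
            raise StageError("isochore", exc) from exc

    # -- AFD screen -----------------------------------------------------------
    block = _stage("afd")
    if block is not None:
        try:
            ga = (
                manifest.samples_with_role("groupA")
                if block.get("group_a") is None
                else _samples(block["group_a"])
            )
            gb = (
                manifest.samples_with_role("groupB")
                if block.get("group_b") is None
                else _samples(block["group_b"])
            )
            hits = afd_screen.screen_differential(
                matrix, ga, gb,
                hi=float(block.get("hi", 0.8)),
                lo=float(block.get("lo", 0.2)),
                p_max=float(block.get("p_max", 0.001)),
            )
            if "annotations" in block:
                ann = afd_screen.read_annotations(block["annotations"])
                hits, _ = afd_screen.join_consequences(
                    hits, ann, block.get("keep_classes", ())
                )
            p = out_dir / "afd_hits.tsv"
            write_table(hits, p, {**meta_base, "stage": "afd", **block})
            produced.append(str(p))
            summary["stages"]["afd"] = {"n_hits": len(hits)}
        except Exception as exc:
            raise StageError("afd", exc) from exc

    # -- LD decay -------------------------------------------------------------
    block = _stage("ld")
    if block is not None:
        try:
            pop = block["pop"]
            max_dist = int(block.get("max_dist", 40_000))
            maf_min = float(block.get("maf_min", 0.05))
            if cohort is not None:
                cols = cohort.haplotype_columns(pop)
                pairs = ld_decay.pairwise_r2(
                    cohort.haplotypes[:, cols],
                    cohort.sites["pos"].to_numpy(),
                    cohort.sites["contig"].to_numpy(),
                    phased=True, max_dist=max_dist, maf_min=maf_min,
                )
            else:
                idx = matrix.sample_indices(_samples(pop))
                pairs = ld_decay.pairwise_r2(
                    matrix.dosages[:, idx],
                    matrix.sites["pos"].to_numpy(),
                    matrix.sites["contig"].to_numpy(),
                    phased=False, max_dist=max_dist, maf_min=maf_min,
                )
            curve = ld_decay.decay_curve(
                pairs, bin_width=int(block.get("bin_width", 1_000)), max_dist=max_dist
            )
            p = out_dir / f"ld_curve_{pop}.tsv"
            write_table(curve, p, {**meta_base, "stage": "ld", **block})
            produced.append(str(p))
            means = curve["mean_r2"].dropna()
            summary["stages"]["ld"] = {
                "n_pairs": int(pairs.shape[0]),
                "first_bin_mean_r2": float(means.iloc[0]) if len(means) else None,
                "last_bin_mean_r2": float(means.iloc[-1]) if len(means) else None,
            }
        except Exception as exc:
            raise StageError("ld", exc) from exc

    summary["files"] = sorted(produced)
    write_json(summary, out_dir / "summary.json")
    with open(out_dir / "report.txt", "w") as fh:
        fh.write(format_report(summary))
    return summary


def format_report(summary: Mapping[str, Any]) -> str:
    lines = [
        "popscan run report",
        f"seed: {summary['seed']}",
        f"output directory: {summary['out_dir']}",
        "",
    ]
    for stage, info in summary["stages"].items():
        lines.append(f"[{stage}]")
        for k, v in info.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
    lines.append(f"files written: {len(summary.get('files', []))}")
    return "\n".join(lines) + "\n"
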