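"""End-to-end orchestration: simulate -> call peaks -> haplotype ->
profile -> deconvolve -> compare, from one YAML config.

Stage seeds are derived deterministically from the global seed as
``seed + 100 * stage_index``, so a rerun with the same config produces
byte-identical outputs (verified by the SHA-256 manifest the run
emits).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict
from typing import Any

import yaml

from . import compare as compare_mod
from . import deconv, haplotype, io_formats, peaks, profiles, synthetic_data

_STAGE_SEED_STEP = 100

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "protein": "RPA",
    "genotypes": ["WT", "DMC1KO"],
    "genome": {
        "n_chroms": 2,
        "chrom_len": 2_000_000,
        "snp_spacing": 200,
        "n_hotspots": 100,
        "x_frac": 0.1,
    },
    "simulate": {
        "n_signal_fragments": 200_000,
        "background_rate": 1e-4,
    },
    "f_source": "h3k4me3",  # or "fragments"
    "h3k4me3": {"n_signal_fragments": 100_000, "background_rate": 1e-5},
    "peaks": {"window": 1000, "merge_gap": 500, "q_max": 0.01, "min_count": 5},
    "haplotype": {"epsilon": 0.0, "n_min": 10},
    "profile": {"binsize": 40, "half_width": 2500},
    "deconv": {"ridge": 1e-2},
    "compare": {"n_boot": 2000},
}


def _merged(config: dict[str, Any] | None) -> dict[str, Any]:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def load_config(path: str) -> dict[str, Any]:
    with open(path) as fh:
        return _merged(yaml.safe_load(fh) or {})


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict[str, Any], outdir: str) -> dict[str, Any]:
    """Run every stage; returns the manifest (also written to disk).

    The manifest maps artifact names to SHA-256 digests and carries a
    summary block (peak counts, class comparisons, template-signal
    checks per genotype).
    """
    cfg = _merged(config)
    os.makedirs(outdir, exist_ok=True)
    seed = int(cfg["seed"])
    produced: dict[str, str] = {}
    summary: dict[str, Any] = {}

    def emit(name: str, writer, *args) -> None:
        path = os.path.join(outdir, name)
        writer(*args, path)
        produced[name] = _sha256(path)

    # stage 0: genome
    genome, hotspots = synthetic_data.simulate_genome(
        seed=seed + 0 * _STAGE_SEED_STEP, **cfg["genome"]
    )
    emit("genome.tsv", io_formats.write_genome_tsv, genome)
    emit("snps.tsv", io_formats.write_snps_tsv, genome.snps)
    emit("hotspots.bed", io_formats.write_hotspots_bed, hotspots)

    # stage 1: H3K4me3-like PRDM9 surrogate for f (if configured)
    protein = cfg["protein"]
    f_fragments = None
    if cfg["f_source"] == "h3k4me3":
        f_fragments = synthetic_data.simulate_h3k4me3(
            genome, hotspots, seed=seed + 1 * _STAGE_SEED_STEP, **cfg["h3k4me3"]
        )
        emit("h3k4me3.fragments.bed", io_formats.write_fragments_bed, f_fragments)

    signal_tables: dict[str, Any] = {}
    symmetry_frames: dict[str, Any] = {}
    per_genotype: dict[str, Any] = {}
    for g_i, genotype in enumerate(cfg["genotypes"]):
        sim_cfg = synthetic_data.preset_config(
            genotype,
            protein,
            seed=seed + (2 + g_i) * _STAGE_SEED_STEP,
            **cfg["simulate"],
        )
        fragments, sim_log = synthetic_data.simulate_fragments(genome, hotspots, sim_cfg)
        tag = genotype.lower()
        emit(f"{tag}.fragments.bed", io_formats.write_fragments_bed, fragments)

        # peaks: bootstrap rho from a provisional whole-genome rate, then
        # re-estimate outside the called peaks
        rho0 = len(fragments) / genome.total_length
        pk = peaks.call_peaks(
            fragments, genome.chrom_sizes, rho0, **cfg["peaks"]
        )
        rho = peaks.estimate_background(
            fragments, peaks.hotspot_mask_from_peaks(pk), genome
        )
        if rho > 0:
            pk = peaks.call_peaks(fragments, genome.chrom_sizes, rho, **cfg["peaks"])
        emit(f"{tag}.peaks.tsv", lambda p, _pk=pk: io_formats.write_signal_table(
            peaks.peaks_to_frame(_pk), p))
        summary[f"{tag}_n_peaks"] = len(pk)
        summary[f"{tag}_rho"] = rho

        calls = haplotype.assign_haplotypes(
            fragments,
            genome,
            epsilon=cfg["haplotype"]["epsilon"],
            seed=seed + (10 + g_i) * _STAGE_SEED_STEP,
        )
        emit(f"{tag}.haplotype.tsv", lambda p, _c=calls: io_formats.write_signal_table(
            haplotype.calls_to_frame(_c), p))

        if cfg["f_source"] == "h3k4me3":
            f_calls = haplotype.assign_haplotypes(
                f_fragments, genome, epsilon=cfg["haplotype"]["epsilon"],
                seed=seed + 20 * _STAGE_SEED_STEP,
            )
            sym, sym_frame = haplotype.symmetry_table(
                hotspots, f_fragments, f_calls, n_min=cfg["haplotype"]["n_min"]
            )
        else:
            sym, sym_frame = haplotype.symmetry_table(
                hotspots, fragments, calls, n_min=cfg["haplotype"]["n_min"]
            )
        emit(f"{tag}.symmetry.tsv", lambda p, _f=sym_frame: io_formats.write_signal_table(_f, p))
        symmetry_frames[genotype] = sym_frame

        profile = profiles.aggregate_profile(
            fragments, calls, hotspots, sym, **cfg["profile"]
        )
        emit(f"{tag}.profile.tsv", io_formats.write_profile_tsv, profile)
        summary[f"{tag}_template_check"] = profiles.template_enrichment(profile)

        kernel = deconv.DsbLocationKernel.gaussian(
            sim_cfg.dsb_sd, cfg["profile"]["binsize"]
        )
        results = deconv.footprint_pipeline(
            profile, kernel, ridge=cfg["deconv"]["ridge"]
        )
        emit(f"{tag}.footprint.tsv", io_formats.write_footprint_tsv, results)

        table = peaks.hotspot_signal_table(hotspots, fragments, rho)
        emit(f"{tag}.signal.tsv", lambda p, _t=table: io_formats.write_signal_table(_t, p))
        signal_tables[genotype] = table
        per_genotype[genotype] = {"sym": sym, "log": sim_log}
        summary[f"{tag}_sim_log"] = sim_log

    if {"WT", "DMC1KO"} <= set(cfg["genotypes"]):
        wt_t = signal_tables["WT"].set_index("hotspot_id")
        ko_t = signal_tables["DMC1KO"].set_index("hotspot_id")
        labels = {
            s.hotspot_id: s.label for s in per_genotype["WT"]["sym"]
        }
        flags = {h.hotspot_id: h.on_x_nonpar for h in hotspots}
        comparisons = compare_mod.compare_classes(
            wt_t["corrected_intensity"],
            ko_t["corrected_intensity"],
            labels,
            flags,
            n_boot=cfg["compare"]["n_boot"],
            seed=seed + 30 * _STAGE_SEED_STEP,
        )
        emit("comparison.tsv", lambda p: io_formats.write_signal_table(
            compare_mod.comparisons_to_frame(comparisons), p))
        summary["class_comparison"] = [asdict(c) for c in comparisons]
        summary["wt_ko_pearson_r"] = compare_mod.correlate_signals(
            wt_t["corrected_intensity"], ko_t["corrected_intensity"]
        )
        ko_check = summary["dmc1ko_template_check"]
        summary["ko_template_flat"] = bool(ko_check["p_uniform"] > 0.01)

    manifest = {"config": cfg, "files": produced, "summary": summary}
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return manifest
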