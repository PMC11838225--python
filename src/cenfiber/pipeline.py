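"""End-to-end pipeline driver: simulate -> call -> occupancy -> report.

Each stage writes its artifacts under the output directory and records them
in a manifest (parameters, seed, SHA-256 content digests). Output bytes are a
pure function of (config, seed): rerunning with the same config reproduces
identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import io as cio
from .config import PipelineConfig
from .errors import PipelineError
from .footprints import call_footprints_all
from .geometry import DistanceSample, consistency_report, distance_summary
from .occupancy import (
    CentromereWindow,
    average_profiles,
    centromeric_footprint_sizes,
    classify_fibers,
    compare_footprint_sizes,
    extract_centromeric_fibers,
    nucleosome_density_profile,
)
from .simulate import (
    build_genome,
    layout_chromatin,
    simulate_distances,
    simulate_fibers,
    simulate_rupture_events,
)
from .survival import bimodality, km_survival, logrank, survival_median
from .errors import MedianUndefinedError

log = logging.getLogger("cenfiber.pipeline")

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all enabled stages; return (and write) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    manifest: dict = {"seed": config.seed, "stages": list(config.stages), "species": {}}

    state: dict = {}
    stage_fns = {
        "simulate": _stage_simulate,
        "call": _stage_call,
        "occupancy": _stage_occupancy,
        "rupture": _stage_rupture,
        "geometry": _stage_geometry,
    }
    for stage in config.stages:
        log.info("stage %s: starting", stage)
        try:
            stage_fns[stage](config, outdir, state, manifest, artifacts)
        except Exception as exc:  # halt with stage name; keep partial outputs
            _finalize(manifest, artifacts, outdir, failed=stage)
            raise PipelineError(stage, exc) from exc
        log.info("stage %s: done", stage)
    _finalize(manifest, artifacts, outdir, failed=None)
    return manifest


def _finalize(manifest, artifacts, outdir, failed):
    manifest["failed_stage"] = failed
    manifest["files"] = {
        str(p.relative_to(outdir)): _sha256(p) for p in sorted(artifacts)
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _stage_simulate(config, outdir, state, manifest, artifacts):
    state["species"] = {}
    for k, sp in enumerate(config.species):
        log.info("simulate: species %s (protected_width=%s, n_fibers=%d)",
                 sp.name, sp.protected_width, sp.n_fibers)
        seed = config.seed * 1009 + 13 * k
        cens = sp.centromere_specs()
        genome = build_genome(sp.n_chrom, sp.chrom_length, sp.at_fraction, cens, seed=seed)
        layout = layout_chromatin(
            genome, config.nuc_len, (config.linker_mean, config.linker_sd), seed=seed + 1
        )
        fibers = simulate_fibers(
            genome,
            layout,
            sp.n_fibers,
            (sp.fiber_len_mean, sp.fiber_len_sd),
            sp.methylation_params(),
            seed=seed + 2,
        )
        state["species"][sp.name] = {"genome": genome, "layout": layout, "fibers": fibers}
        fiber_path = outdir / f"fibers_{sp.name}.tsv"
        cio.write_fiber_table(fibers, fiber_path)
        cen_path = outdir / f"centromeres_{sp.name}.bed"
        cio.write_bed6(
            [(c.chrom, c.start, c.end, f"CEN{i+1}", 0, "+") for i, c in enumerate(cens)],
            cen_path,
        )
        truth_path = outdir / f"protected_truth_{sp.name}.bed"
        cio.write_bed6(
            [
                (chrom, int(s), int(e), "protected", 0, "+")
                for chrom, iv in layout.intervals.items()
                for s, e in iv
            ],
            truth_path,
        )
        artifacts.extend([fiber_path, cen_path, truth_path])
    state["ruptures"] = {}
    for params in config.rupture_conditions:
        events = simulate_rupture_events(params)
        state["ruptures"][params.condition] = events
        path = outdir / f"events_{params.condition}.csv"
        cio.write_events_csv(events, path)
        artifacts.append(path)
    state["distances"] = {}
    for kind, params in config.distance_blocks:
        values = simulate_distances(params)
        state["distances"][kind] = DistanceSample(values=values, kind=kind)
    if state["distances"]:
        path = outdir / "distances.csv"
        cio.write_distances_csv(state["distances"].values(), path)
        artifacts.append(path)


def _stage_call(config, outdir, state, manifest, artifacts):
    for name, sp_state in state.get("species", {}).items():
        table = call_footprints_all(sp_state["fibers"], config.calling)
        sp_state["footprints"] = table
        path = outdir / f"footprints_{name}.bed"
        cio.write_footprint_bed(table, path)
        artifacts.append(path)
        log.info("call: species %s -> %d footprints", name, len(table))


def _stage_occupancy(config, outdir, state, manifest, artifacts):
    size_samples = {}
    for name, sp_state in state.get("species", {}).items():
        genome = sp_state["genome"]
        fibers = sp_state["fibers"]
        table = sp_state["footprints"]
        profiles = []
        all_sizes = []
        calls_frames = []
        fps = cio.footprints_from_frame(table)
        for cen in genome.centromeres:
            window = CentromereWindow.from_centromere(cen, config.flank)
            sub = extract_centromeric_fibers(fibers, window)
            sub_ids = {f.fiber_id for f in sub}
            sub_table = table[table["fiber_id"].isin(sub_ids)]
            profiles.append(nucleosome_density_profile(sub_table, sub, window))
            sample = centromeric_footprint_sizes(
                table, (cen.chrom, cen.start, cen.end), config.max_size, species=name
            )
            all_sizes.append(sample)
            calls_frames.append(
                classify_fibers(sub, fps, (cen.chrom, cen.start, cen.end), config.classify)
            )
        for i, profile in enumerate(profiles):
            path = outdir / f"density_{name}_cen{i+1}.bedgraph"
            cio.write_bedgraph(profile, path)
            artifacts.append(path)
        avg = average_profiles(profiles)
        avg_path = outdir / f"density_{name}_averaged.tsv"
        _write_tsv(
            avg_path,
            ["offset", "density", "n_contributing"],
            (
                (o, f"{d:.6g}" if np.isfinite(d) else "NA", n)
                for o, d, n in zip(avg.offsets(), avg.density, avg.n_contributing)
            ),
        )
        artifacts.append(avg_path)
        sizes = np.sort(np.concatenate([s.sizes for s in all_sizes]))
        merged = type(all_sizes[0])(
            species=name,
            sizes=sizes,
            n_raw=sum(s.n_raw for s in all_sizes),
            n_filtered=sum(s.n_filtered for s in all_sizes),
            max_size=config.max_size,
        )
        size_samples[name] = merged
        sizes_path = outdir / f"footprint_sizes_{name}.tsv"
        _write_tsv(sizes_path, ["size_bp"], ((int(s),) for s in sizes))
        artifacts.append(sizes_path)
        import pandas as pd

        calls = pd.concat(calls_frames, ignore_index=True)
        calls_path = outdir / f"model_calls_{name}.tsv"
        calls.to_csv(calls_path, sep="\t", index=False)
        artifacts.append(calls_path)
        informative = calls[calls["call"] != "uninformative"]
        counts = informative["call"].value_counts().to_dict()
        manifest["species"][name] = {
            "n_fibers": len(fibers),
            "n_footprints": len(table),
            "median_centromeric_footprint_bp": float(np.median(sizes)) if sizes.size else None,
            "model_calls": counts,
        }
        log.info("occupancy: species %s median footprint %.1f bp (n=%d), calls %s",
                 name, float(np.median(sizes)) if sizes.size else float("nan"),
                 sizes.size, counts)
    state["size_samples"] = size_samples
    names = list(size_samples)
    if len(names) >= 2:
        cmp_result = compare_footprint_sizes(size_samples[names[0]], size_samples[names[1]])
        path = outdir / "size_comparison.tsv"
        _write_tsv(
            path,
            ["species_a", "species_b", "median_a", "median_b", "t", "p", "n_a", "n_b"],
            [(
                names[0], names[1],
                cmp_result.median_a, cmp_result.median_b,
                f"{cmp_result.t_statistic:.6g}", f"{cmp_result.p_value:.6g}",
                cmp_result.n_a, cmp_result.n_b,
            )],
        )
        artifacts.append(path)
        manifest["size_comparison"] = {
            "median_a": cmp_result.median_a,
            "median_b": cmp_result.median_b,
            "t": cmp_result.t_statistic,
            "p": cmp_result.p_value,
        }


def _stage_rupture(config, outdir, state, manifest, artifacts):
    curves = {}
    manifest["rupture"] = {}
    for condition, events in state.get("ruptures", {}).items():
        curve = km_survival(events)
        curves[condition] = curve
        path = outdir / f"survival_{condition}.tsv"
        _write_tsv(
            path,
            ["force_pN", "survival", "lo95", "hi95"],
            (
                (f"{f:.6g}", f"{s:.6g}", f"{lo:.6g}", f"{hi:.6g}")
                for f, s, lo, hi in zip(
                    curve.breakpoints, curve.survival, curve.ci_lower, curve.ci_upper
                )
            ),
        )
        artifacts.append(path)
        try:
            med = survival_median(curve)
        except MedianUndefinedError:
            med = None
        rupture_forces = [e.force for e in events if e.outcome == "rupture"]
        entry = {"median_pN": med, "n": len(events)}
        if len(rupture_forces) >= 20:
            bim = bimodality(rupture_forces, seed=config.seed)
            entry["modality"] = bim.preferred
        manifest["rupture"][condition] = entry
        log.info("rupture: %s median %s pN (n=%d)", condition, med, len(events))
    if config.rupture_compare and all(c in state.get("ruptures", {}) for c in config.rupture_compare):
        a_name, b_name = config.rupture_compare
        result = logrank(state["ruptures"][a_name], state["ruptures"][b_name])
        manifest["rupture"]["logrank"] = {
            "groups": [a_name, b_name],
            "chi_square": result.chi_square,
            "p": result.p_value,
        }
        log.info("rupture: log-rank %s vs %s chi2=%.3f p=%.4g",
                 a_name, b_name, result.chi_square, result.p_value)


def _stage_geometry(config, outdir, state, manifest, artifacts):
    distances = state.get("distances", {})
    manifest["geometry"] = {}
    for kind, sample in distances.items():
        median, (q1, q3), n = distance_summary(sample)
        manifest["geometry"][kind] = {"median_nm": median, "q1": q1, "q3": q3, "n": n}
    if "inter_kt" in distances and "doublet_length" in distances:
        report = consistency_report(
            distances["doublet_length"], distances["inter_kt"], tol=config.geometry_tol
        )
        path = outdir / "consistency_report.tsv"
        _write_tsv(
            path,
            [
                "median_inter_kt_nm", "median_doublet_nm",
                "fraction_within_range", "fraction_within_tol", "tol_nm",
            ],
            [(
                f"{report.median_inter_kt:.6g}", f"{report.median_doublet:.6g}",
                f"{report.fraction_within_range:.6g}", f"{report.fraction_within_tol:.6g}",
                f"{report.tol:.6g}",
            )],
        )
        hist_path = outdir / "consistency_histogram.tsv"
        _write_tsv(
            hist_path,
            ["bin_start_nm", "bin_end_nm", "n_doublet", "n_inter_kt"],
            (
                (f"{s:.6g}", f"{e:.6g}", int(d), int(k))
                for s, e, d, k in zip(
                    report.bin_edges[:-1], report.bin_edges[1:],
                    report.hist_doublet, report.hist_inter_kt,
                )
            ),
        )
        artifacts.extend([path, hist_path])
        manifest["geometry"]["consistency"] = {
            "fraction_within_range": report.fraction_within_range,
            "fraction_within_tol": report.fraction_within_tol,
            "tol_nm": report.tol,
        }
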