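"""Stage runners wiring simulation, calling, annotation and burden analysis.

Each stage reads/writes the package's TSV formats and records a JSON run
manifest (config hash, seed, inputs, package version, timestamp) next to
its outputs, so every file can be traced to the run that produced it.
The CLI and the numbered analysis scripts are both thin wrappers over
these functions.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import io as cio
from .annotation import ControlCNVMap, annotate_calls, rarity_filter
from .burden import (
    de_novo_test,
    large_cnv_burden_test,
    largest_cnv_per_sample,
    rare_carrier_test,
    survivor_curve,
    two_hit_test,
    cohort_summary,
)
from .config import AnalysisConfig
from .core import ProbeDesign, calls_to_frame, validate_sample_meta
from .segmentation import (
    HMMParams,
    assemble_segments,
    bridge_segments,
    qc_filter_calls,
    sample_qc,
    viterbi_decode,
    zscore_transform,
)
from .synthetic import (
    DEFAULT_COHORTS,
    CohortSpec,
    NoiseModel,
    make_layout,
    make_probe_design,
    simulate_cohorts,
    simulate_control_map,
    simulate_disorder_regions,
    simulate_gene_table,
    simulate_intensities,
)

__all__ = [
    "write_manifest",
    "run_simulate",
    "run_call",
    "run_annotate",
    "run_burden",
    "DEFAULT_COMPARISONS",
]


def write_manifest(outdir: Path, stage: str, seed: Optional[int], config: AnalysisConfig,
                   inputs: dict) -> None:
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": seed,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _cohort_specs_from_config(block: dict) -> list[CohortSpec]:
    return [CohortSpec(**row) for row in block]


def run_simulate(outdir: str | Path, seed: int, config: Optional[AnalysisConfig] = None,
                 sim_config: Optional[dict] = None) -> dict[str, Path]:
    """Generate all pipeline inputs on disk; returns the artifact paths.

    ``sim_config`` may override generator blocks: ``layout`` (kwargs of
    :func:`make_layout`), ``design``, ``noise``, ``control_map``,
    ``cohorts`` (list of CohortSpec kwargs).
    """
    if seed is None:
        raise ValueError("seed is mandatory for simulation")
    config = config or AnalysisConfig()
    sim = sim_config or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()

    layout = make_layout(seed, **sim.get("layout", {}))
    design = make_probe_design(layout, seed=seed, **sim.get("design", {}))
    cmap_events, n_controls = simulate_control_map(layout, seed=seed, **sim.get("control_map", {}))
    specs = (
        _cohort_specs_from_config(sim["cohorts"]) if "cohorts" in sim else DEFAULT_COHORTS
    )
    meta, truth = simulate_cohorts(layout, specs, seed=seed, control_map=cmap_events)
    noise = NoiseModel(**sim.get("noise", {}))
    all_ids = meta["sample_id"].astype(str).tolist()
    tracks = simulate_intensities(design, truth, noise, seed=seed, sample_ids=all_ids)
    genes = simulate_gene_table(layout, seed=seed, **sim.get("genes", {}))
    disorders = simulate_disorder_regions(layout, seed=seed, **sim.get("disorders", {}))

    paths = {
        "layout": outdir / "layout.tsv",
        "design": outdir / "probes.bed",
        "matrix": outdir / "log2_ratios.tsv",
        "truth": outdir / "truth.tsv",
        "meta": outdir / "samples.tsv",
        "control_map": outdir / "control_map.tsv",
        "genes": outdir / "genes.bed",
        "disorders": outdir / "disorders.bed",
    }
    cio.write_layout(layout, paths["layout"], h, seed)
    cio.write_probe_design(design, paths["design"], h, seed)
    cio.write_log_ratio_matrix(tracks, design, paths["matrix"], h, seed)
    truth_rows = [
        {
            "sample_id": sid,
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "type": c.type,
            "inheritance": c.inheritance,
            "rare": c.rare,
        }
        for sid in sorted(truth.events)
        for c in truth.events[sid]
    ]
    cio.write_intervals(
        pd.DataFrame(truth_rows, columns=["sample_id", "chrom", "start", "end", "type",
                                          "inheritance", "rare"])
        if truth_rows
        else pd.DataFrame(columns=["sample_id", "chrom", "start", "end", "type",
                                   "inheritance", "rare"]),
        paths["truth"], h, seed,
    )
    cio.write_sample_meta(meta, paths["meta"], h, seed)
    cio.write_control_map(cmap_events, n_controls, paths["control_map"], h, seed)
    cio.write_intervals(genes, paths["genes"], h, seed)
    cio.write_intervals(disorders, paths["disorders"], h, seed)
    write_manifest(outdir, "simulate", seed, config, {})
    return paths


def run_call(
    design_path: str | Path,
    matrix_path: str | Path,
    layout_path: str | Path,
    outdir: str | Path,
    config: Optional[AnalysisConfig] = None,
    meta_path: Optional[str | Path] = None,
    hmm: Optional[HMMParams] = None,
    seed: Optional[int] = None,
) -> Path:
    """Call CNVs for every sample in a log2-ratio matrix; write the table.

    The output keeps rejected variants (qc_pass False with a reason code)
    and a per-sample QC table derived from track noise and raw call counts.
    """
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = cio.read_probe_design(design_path)
    layout = cio.read_layout(layout_path)
    tracks = cio.read_log_ratio_matrix(matrix_path, design)

    all_calls = []
    raw_counts = {}
    for track in tracks:
        z = zscore_transform(track, design, robust=config.robust_zscore)
        states = viterbi_decode(z, design, hmm)
        segments = assemble_segments(states, z, design, config.segment_gap_bp)
        variants = bridge_segments(segments, z, design,
                                   config.bridge_max_probes, config.bridge_max_gap_bp)
        calls = qc_filter_calls(variants, track.sample_id, config, layout)
        raw_counts[track.sample_id] = len(variants)
        all_calls.extend(calls)
    call_frame = calls_to_frame(all_calls)

    median_raw = float(np.median(list(raw_counts.values()))) if raw_counts else 0.0
    qc_rows = []
    for track in tracks:
        status, reason = sample_qc(track, raw_counts[track.sample_id], config, median_raw)
        qc_rows.append({"sample_id": track.sample_id, "qc_status": status, "reason": reason})
    qc_frame = pd.DataFrame(qc_rows)

    h = config.config_hash()
    calls_path = outdir / "calls.tsv"
    cio.write_cnv_calls(call_frame, calls_path, h, seed)
    cio.write_sample_meta(qc_frame, outdir / "sample_qc.tsv", h, seed)
    write_manifest(outdir, "call", seed, config,
                   {"design": design_path, "matrix": matrix_path, "layout": layout_path})
    return calls_path


def run_annotate(
    calls_path: str | Path,
    control_map_path: str | Path,
    outdir: str | Path,
    genes_path: Optional[str | Path] = None,
    disorders_path: Optional[str | Path] = None,
    meta_path: Optional[str | Path] = None,
    layout_path: Optional[str | Path] = None,
    config: Optional[AnalysisConfig] = None,
    seed: Optional[int] = None,
) -> Path:
    """Annotate QC-passed calls; write the annotated table."""
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calls = cio.read_cnv_calls(calls_path)
    calls = calls[calls["qc_pass"].astype(bool)].reset_index(drop=True)
    events, n_controls = cio.read_control_map(control_map_path)
    cmap = ControlCNVMap(events, n_controls)
    genes = cio.read_intervals(genes_path) if genes_path else None
    disorders = cio.read_intervals(disorders_path) if disorders_path else None
    meta = cio.read_sample_meta(meta_path) if meta_path else None
    layout = cio.read_layout(layout_path) if layout_path else None
    annotated = annotate_calls(calls, cmap, genes, disorders, meta, layout, config)
    out_path = Path(outdir) / "annotated_calls.tsv"
    cio.write_cnv_calls(annotated, out_path, config.config_hash(), seed)
    write_manifest(outdir, "annotate", seed, config,
                   {"calls": calls_path, "control_map": control_map_path})
    return out_path


DEFAULT_COMPARISONS: tuple[dict, ...] = (
    {"kind": "large", "a": "ID", "b": "control"},
    {"kind": "large", "a": "ID_MCA", "b": "ID"},
    {"kind": "large", "a": "dyslexia", "b": "control"},
    {"kind": "rare_carrier", "a": "ID", "b": "dyslexia"},
    {"kind": "rare_carrier", "a": "autism_no_ID", "b": "dyslexia"},
    {"kind": "de_novo", "a": "ID", "b": "autism_no_ID"},
    {"kind": "two_hit", "a": "ID_MCA", "b": "ID"},
)


def run_burden(
    annotated_path: str | Path,
    meta_path: str | Path,
    outdir: str | Path,
    comparisons: Optional[Sequence[dict]] = None,
    config: Optional[AnalysisConfig] = None,
    grid_bp: Sequence[int] = (0, 50_000, 100_000, 250_000, 500_000, 1_000_000,
                              2_000_000, 5_000_000),
    seed: Optional[int] = None,
) -> Path:
    """Run the requested cohort comparisons; write report, curves, summary."""
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotated = cio.read_cnv_calls(annotated_path)
    meta = cio.read_sample_meta(meta_path)
    cohorts = sorted(meta["cohort"].unique())
    if len(cohorts) < 2:
        raise ValueError("burden analysis needs at least two cohorts")
    if comparisons is None:
        # default: the standard comparison set, restricted to present cohorts,
        # plus a large-CNV comparison for every cohort pair not covered
        comparisons = [c for c in DEFAULT_COMPARISONS
                       if c["a"] in cohorts and c["b"] in cohorts]
        if not comparisons:
            comparisons = [
                {"kind": "large", "a": a, "b": b}
                for i, a in enumerate(cohorts) for b in cohorts[i + 1:]
            ]

    probands = meta[meta.get("role", "proband") == "proband"] if "role" in meta.columns else meta
    maxima = {
        cohort: largest_cnv_per_sample(
            annotated, probands.loc[probands["cohort"] == cohort, "sample_id"].astype(str)
        )
        for cohort in cohorts
    }
    rows = []
    for comp in comparisons:
        kind, a, b = comp["kind"], comp["a"], comp["b"]
        for cohort in (a, b):
            if cohort not in cohorts:
                raise ValueError(f"unknown cohort label {cohort!r}")
        if kind == "large":
            res = large_cnv_burden_test(maxima[a], maxima[b], config.large_cnv_bp,
                                        label=f"large:{a}_vs_{b}")
        elif kind == "rare_carrier":
            res = rare_carrier_test(annotated, meta, a, b)
        elif kind == "de_novo":
            res = de_novo_test(annotated, meta, a, b)
        elif kind == "two_hit":
            res = two_hit_test(annotated, meta, a, b)
        else:
            raise ValueError(f"unknown comparison kind {kind!r}")
        t = res.table
        rows.append({
            "comparison": res.label, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "odds_ratio": res.odds_ratio, "p_value": res.p_value, "test": res.test,
        })
    report = pd.DataFrame(rows)

    curve = survivor_curve(maxima, grid_bp)
    curve_frame = pd.DataFrame({"size_bp": curve.grid, **curve.fractions})
    summary = cohort_summary(annotated, meta)

    h = config.config_hash()
    report_path = outdir / "burden_report.tsv"
    cio._write_frame(report, report_path, cio.provenance_line(h, seed))
    cio._write_frame(curve_frame, outdir / "survivor_curves.tsv", cio.provenance_line(h, seed))
    cio._write_frame(summary, outdir / "cohort_summary.tsv", cio.provenance_line(h, seed))
    write_manifest(outdir, "burden", seed, config,
                   {"annotated": annotated_path, "meta": meta_path})
    return report_path
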