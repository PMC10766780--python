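"""Configuration, orchestration and reporting for the full analysis pipeline.

A single YAML config selects stages (``simulate``, ``screen``, ``chip``,
``cbf``) and sets per-stage parameter blocks. Stages communicate through
files under the output directory, so each stage is independently runnable
and resumable; a stage failure stops the run with earlier outputs intact.
Every stage writes a JSON metadata sidecar (parameters, seed, input
checksums) and the run ends with a ``report.json`` of headline numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io as aio
from .cbf import batch_cbf
from .chip import (classify_peak_regions, compare_peak_depth,
                   scan_peaks_for_motif, select_candidate_genes,
                   tss_density_profile)
from .errors import StageError, ValidationError
from .motif import MotifModel
from .screen import ScreenParams, run_screen
from .simulate import (GenomeSimConfig, ScreenSimConfig, TraceSimConfig,
                       simulate_genome_inputs, simulate_screen_inputs,
                       simulate_trace)

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "screen", "chip", "cbf")


def _check_block(name: str, block: dict, allowed: dict[str, type | tuple]) -> dict:
    """Type-check a config block against allowed keys; reject unknown keys."""
    if not isinstance(block, dict):
        raise ValidationError(f"{name}: expected a mapping, got {type(block).__name__}")
    out = {}
    for key, value in block.items():
        if key not in allowed:
            raise ValidationError(f"{name}.{key}: unknown key")
        expected = allowed[key]
        if value is not None and not isinstance(value, expected):
            raise ValidationError(
                f"{name}.{key}: expected {expected}, got {type(value).__name__}"
            )
        out[key] = value
    return out

_NUM = (int, float)
_SIM_SCREEN_KEYS = {f.name: _NUM if f.type in ("float", "int") else object
                    for f in dataclasses.fields(ScreenSimConfig)}
_SIM_GENOME_KEYS = {f.name: object for f in dataclasses.fields(GenomeSimConfig)}
_SIM_TRACE_KEYS = {f.name: object for f in dataclasses.fields(TraceSimConfig)}


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration."""

    stages: list[str]
    seed: int
    outdir: Path
    log_level: str = "INFO"
    simulate: dict = dataclasses.field(default_factory=dict)
    screen: dict = dataclasses.field(default_factory=dict)
    chip: dict = dataclasses.field(default_factory=dict)
    cbf: dict = dataclasses.field(default_factory=dict)


_SCREEN_KEYS = {
    "matrix": str, "annotation": str, "network": str, "basal_label": str,
    "term": str, "k": int, "cap": int, "min_confidence": _NUM,
    "pseudocount": _NUM, "n_perm": int, "alternative": str,
    "aggregation": str, "restrict_universe_positive": bool,
}
_CHIP_KEYS = {
    "peaks": str, "gtf": str, "fasta": str, "motif": str,
    "motif_consensus": str, "p_threshold": _NUM, "precision": _NUM,
    "window": list, "strand_aware": bool, "promoter_window": list,
    "profile_window": int, "profile_bin": int, "smooth_bins": int,
    "control_coverage": str, "treated_coverage": str, "depth_pseudocount": _NUM,
}
_CBF_KEYS = {
    "traces_dir": str, "traces": list, "fs": _NUM, "band": list,
    "detrend": str, "window": str,
}
_SIM_KEYS = {"screen": dict, "genome": dict, "traces": dict, "n_traces": int}


def validate_config(cfg: dict | str | Path) -> RunConfig:
    """Parse and validate a pipeline config (YAML path or dict).

    Unknown keys are rejected; stage parameters are range-checked by the
    stage dataclasses at run time. Defaults: seed 0, outdir ``airscreen_out``.
    """
    if not isinstance(cfg, dict):
        with open(cfg) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ValidationError("config: top level must be a mapping")
    top = _check_block(
        "config", cfg,
        {"stages": list, "seed": int, "outdir": str, "log_level": str,
         "simulate": dict, "screen": dict, "chip": dict, "cbf": dict},
    )
    stages = top.get("stages")
    if not stages:
        raise ValidationError("stages: at least one stage must be selected")
    for s in stages:
        if s not in STAGE_ORDER:
            raise ValidationError(f"stages: unknown stage {s!r}")
    stages = [s for s in STAGE_ORDER if s in stages]

    sim = _check_block("simulate", top.get("simulate") or {}, _SIM_KEYS)
    _check_block("simulate.screen", sim.get("screen") or {}, _SIM_SCREEN_KEYS)
    _check_block("simulate.genome", sim.get("genome") or {}, _SIM_GENOME_KEYS)
    _check_block("simulate.traces", sim.get("traces") or {}, _SIM_TRACE_KEYS)
    screen = _check_block("screen", top.get("screen") or {}, _SCREEN_KEYS)
    chip = _check_block("chip", top.get("chip") or {}, _CHIP_KEYS)
    cbf = _check_block("cbf", top.get("cbf") or {}, _CBF_KEYS)

    # fail early on out-of-range stage parameters
    sp = ScreenParams(**{k: v for k, v in screen.items()
                         if k in {f.name for f in dataclasses.fields(ScreenParams)}})
    sp.validate()

    return RunConfig(
        stages=stages,
        seed=int(top.get("seed", 0)),
        outdir=Path(top.get("outdir", "airscreen_out")),
        log_level=top.get("log_level", "INFO"),
        simulate=sim,
        screen=screen,
        chip=chip,
        cbf=cbf,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_meta(outdir: Path, stage: str, params: dict, seed: int,
                inputs: dict[str, Path] | None = None) -> None:
    meta = {
        "stage": stage,
        "seed": seed,
        "parameters": {k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()},
        "input_checksums": {k: _sha256(Path(p)) for k, p in (inputs or {}).items()},
    }
    aio.write_json(meta, outdir / f"{stage}_metadata.json")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: RunConfig) -> dict:
    out = cfg.outdir / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    block = cfg.simulate
    # sub-seeds derive from the run seed unless a block pins its own
    scr_cfg = ScreenSimConfig(**{"seed": cfg.seed, **(block.get("screen") or {})})
    gen_cfg = GenomeSimConfig(**{"seed": cfg.seed + 1, **(block.get("genome") or {})})
    trace_kwargs = dict(block.get("traces") or {})
    n_traces = int(block.get("n_traces") or 32)

    matrix, ann, net, truth = simulate_screen_inputs(scr_cfg)
    aio.write_matrix_mtx(matrix, out / "expression")
    aio.write_annotation_tsv(ann, out / "annotation.tsv")
    aio.write_network_tsv(net, out / "network.tsv")
    aio.write_json(truth, out / "screen_ground_truth.json")

    genome, tx, peaks, gtruth = simulate_genome_inputs(gen_cfg)
    aio.write_fasta(genome, out / "genome.fa")
    aio.write_gtf(tx, out / "genes.gtf")
    aio.write_peaks_bed(peaks, out / "peaks.narrowPeak", narrowpeak=True)
    aio.write_json(gtruth, out / "genome_ground_truth.json")

    tdir = out / "traces"
    tdir.mkdir(exist_ok=True)
    for i in range(n_traces):
        tcfg = TraceSimConfig(**{**trace_kwargs,
                                 "seed": cfg.seed + 2 + i,
                                 "bead_id": f"bead{i:03d}"})
        aio.write_trace_csv(simulate_trace(tcfg), tdir / f"bead{i:03d}.csv")

    _write_meta(out, "simulate",
                {"screen": dataclasses.asdict(scr_cfg),
                 "genome": dataclasses.asdict(gen_cfg),
                 "traces": {**trace_kwargs, "n_traces": n_traces}},
                cfg.seed)
    return {
        "planted_tf": truth["planted_tf"],
        "n_cells": matrix.n_cells,
        "n_genes": matrix.n_genes,
        "n_edges": truth["n_edges"],
        "n_peaks": len(peaks),
        "n_traces": n_traces,
    }


def _stage_screen(cfg: RunConfig) -> dict:
    out = cfg.outdir / "screen"
    out.mkdir(parents=True, exist_ok=True)
    block = dict(cfg.screen)
    sim = cfg.outdir / "simulate"
    matrix_path = Path(block.pop("matrix", None) or sim / "expression")
    ann_path = Path(block.pop("annotation", None) or sim / "annotation.tsv")
    net_path = Path(block.pop("network", None) or sim / "network.tsv")
    basal = block.pop("basal_label", None)

    matrix = aio.read_matrix_mtx(matrix_path, basal_label=basal)
    ann = aio.read_annotation_tsv(ann_path)
    net = aio.read_network_tsv(net_path)
    params = ScreenParams(**{"seed": cfg.seed, **block})
    result = run_screen(matrix, ann, net, params)
    result.to_csv(out / "screen_results.tsv", sep="\t", index=False, float_format="%.10g")
    _write_meta(out, "screen", dataclasses.asdict(params), cfg.seed,
                inputs={"annotation": ann_path, "network": net_path})
    top = result.dropna(subset=["p_combined"]).head(5)
    return {
        "n_tested": int(len(result)),
        "top_tfs": top["tf_id"].tolist(),
        "top_p_combined": [float(p) for p in top["p_combined"]],
    }


def _stage_chip(cfg: RunConfig) -> dict:
    out = cfg.outdir / "chip"
    out.mkdir(parents=True, exist_ok=True)
    block = dict(cfg.chip)
    sim = cfg.outdir / "simulate"
    peaks_path = Path(block.get("peaks") or sim / "peaks.narrowPeak")
    gtf_path = Path(block.get("gtf") or sim / "genes.gtf")
    fasta_path = Path(block.get("fasta") or sim / "genome.fa")

    peaks = aio.read_peaks_bed(peaks_path)
    tx = aio.read_gtf(gtf_path)
    genome = aio.read_fasta(fasta_path)
    if block.get("motif"):
        m = aio.read_motif_jaspar(block["motif"])
    elif block.get("motif_consensus"):
        m = MotifModel.from_consensus(block["motif_consensus"])
    else:
        raise ValidationError("chip: one of 'motif' (JASPAR file) or 'motif_consensus' required")

    profile = tss_density_profile(
        peaks, tx,
        window=int(block.get("profile_window") or 20_000),
        bin_size=int(block.get("profile_bin") or 200),
        smooth_bins=int(block.get("smooth_bins") or 5),
    )
    profile.to_csv(out / "tss_profile.tsv", sep="\t", index=False, float_format="%.10g")

    promoter_window = tuple(block.get("promoter_window") or (2000, 500))
    labels, fractions = classify_peak_regions(peaks, tx, promoter_window)
    fractions.rename_axis("region").to_frame().to_csv(out / "region_fractions.tsv", sep="\t",
                                                      float_format="%.10g")

    p_threshold = float(block.get("p_threshold") or 1e-4)
    hits, fraction = scan_peaks_for_motif(
        peaks, genome, m, p_threshold=p_threshold,
        precision=float(block.get("precision") or 0.01),
    )
    hits.to_csv(out / "motif_hits.tsv", sep="\t", index=False, float_format="%.10g")

    window = tuple(block.get("window") or (-20_000, 500))
    strand_aware = bool(block.get("strand_aware", True))
    candidates = select_candidate_genes(peaks, hits, tx, window=window,
                                        strand_aware=strand_aware)
    candidates.to_csv(out / "candidate_genes.tsv", sep="\t", index=False,
                      float_format="%.10g")

    depth_summary = None
    if block.get("control_coverage") and block.get("treated_coverage"):
        per_peak, hist, depth_summary = compare_peak_depth(
            aio.read_bedgraph(block["control_coverage"]),
            aio.read_bedgraph(block["treated_coverage"]),
            peaks,
            pseudocount=float(block.get("depth_pseudocount") or 0.5),
        )
        per_peak.to_csv(out / "peak_depth.tsv", sep="\t", index=False, float_format="%.10g")
        hist.to_csv(out / "depth_histogram.tsv", sep="\t", index=False, float_format="%.10g")

    _write_meta(
        out, "chip",
        {"p_threshold": p_threshold, "window": list(window),
         "strand_aware": strand_aware,
         "offset_sign_convention": "negative = upstream of TSS in transcription orientation"
                                   if strand_aware else "negative = left of TSS genomically",
         "promoter_window": list(promoter_window), "motif": m.name},
        cfg.seed, inputs={"peaks": peaks_path, "gtf": gtf_path},
    )
    return {
        "n_peaks": len(peaks),
        "motif_fraction": fraction,
        "region_fractions": fractions.to_dict(),
        "n_candidate_genes": int(len(candidates)),
        "depth": depth_summary,
    }


def _stage_cbf(cfg: RunConfig) -> dict:
    out = cfg.outdir / "cbf"
    out.mkdir(parents=True, exist_ok=True)
    block = cfg.cbf
    fs = block.get("fs")
    if block.get("traces"):
        paths = [Path(p) for p in block["traces"]]
    else:
        tdir = Path(block.get("traces_dir") or cfg.outdir / "simulate" / "traces")
        paths = sorted(tdir.glob("*.csv"))
    if not paths:
        raise ValidationError("cbf: no trace files found")
    traces = [aio.read_trace_csv(p, fs=fs) for p in paths]
    band = tuple(block.get("band") or (2.0, 40.0))
    estimates, failures, summary = batch_cbf(
        traces, band=band,
        detrend=block.get("detrend") or "linear",
        window=block.get("window") or "hann",
    )
    import pandas as pd

    pd.DataFrame(
        [(e.bead_id, e.frequency, e.power_fraction, e.resolution, e.harmonic_flag)
         for e in estimates],
        columns=["bead_id", "frequency_hz", "power_fraction", "resolution_hz",
                 "harmonic_flag"],
    ).to_csv(out / "cbf_estimates.tsv", sep="\t", index=False, float_format="%.10g")
    aio.write_json({"summary": summary,
                    "failures": [list(f) for f in failures]}, out / "cbf_summary.json")
    _write_meta(out, "cbf", {"band": list(band), "n_traces": len(traces)}, cfg.seed)
    return summary


_STAGES = {
    "simulate": _stage_simulate,
    "screen": _stage_screen,
    "chip": _stage_chip,
    "cbf": _stage_cbf,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the selected stages in order and return the run report.

    The report echoes parameters and headline outputs per stage and is also
    written to ``<outdir>/report.json``. A stage failure raises
    :class:`StageError` naming the stage; outputs of earlier stages remain
    on disk.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": cfg.seed, "stages": {}}
    for stage in cfg.stages:
        logger.info("running stage %s", stage)
        try:
            headline = _STAGES[stage](cfg)
        except Exception as exc:
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            aio.write_json(report, cfg.outdir / "report.json")
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        report["stages"][stage] = {"status": "ok", "headline": headline}
    aio.write_json(report, cfg.outdir / "report.json")
    return report
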