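"""End-to-end orchestration from a single plain-text (YAML) config.

Stages run in dependency order — simulate (optional) → union → normalise →
differential → heatmap matrices → motif scores → priming → expression —
and every output file lands under ``<outdir>/<stage>/``.  A manifest
records each output with its SHA-256 content hash plus a structured log of
the parameters used and the peak/gene counts surviving each step, so a
rerun with the same config and seed is byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import diffacc, expression, motifs, priming, simulate
from .intervals import (
    GeneAnnotation,
    PeakSet,
    filter_blacklist,
    read_peaks,
    write_peaks,
)
from .tracks import TagTrack, read_bedgraph, write_bedgraph

logger = logging.getLogger("chromprime")

__all__ = ["RunConfig", "run_pipeline", "load_config"]

DEFAULT_PARAMETERS: dict[str, Any] = {
    "summit_distance": 400,
    "promoter_window": 1500,
    "fold": 2.0,
    "window": 400,
    "heatmap_window": 2000,
    "bin": 10,
    "n_resamples": 1000,
}


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    parameters: dict[str, Any] = field(default_factory=dict)
    simulate: dict[str, Any] | None = None
    inputs: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_PARAMETERS)
        unknown = set(self.parameters) - set(DEFAULT_PARAMETERS)
        if unknown:
            raise ValueError(f"unknown parameters {sorted(unknown)}")
        merged.update(self.parameters)
        self.parameters = merged

    def param(self, key: str):
        return self.parameters[key]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "outdir" not in raw:
        raise ValueError("config must set outdir")
    return RunConfig(
        outdir=raw["outdir"],
        seed=int(raw.get("seed", 0)),
        parameters=raw.get("parameters", {}) or {},
        simulate=raw.get("simulate"),
        inputs=raw.get("inputs", {}) or {},
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


class _Run:
    def __init__(self, cfg: RunConfig) -> None:
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.outputs: dict[str, str] = {}
        self.log: dict[str, Any] = {"parameters": cfg.parameters, "seed": cfg.seed}

    def emit(self, stage: str, name: str, writer) -> Path:
        d = self.outdir / stage
        d.mkdir(parents=True, exist_ok=True)
        path = d / name
        writer(path)
        self.outputs[f"{stage}/{name}"] = _sha256(path)
        logger.info("wrote %s", path)
        return path


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run all configured stages; return (and write) the manifest."""
    run = _Run(config)
    params = config.parameters
    inputs = dict(config.inputs)
    atlas_result = None

    missing = [
        str(v) for k, v in inputs.items()
        if k.endswith(("peaks_minus", "peaks_plus", "track_minus", "track_plus",
                       "genes", "blacklist", "motif_counts"))
        and isinstance(v, str) and not Path(v).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing}")

    # --- simulate -----------------------------------------------------
    if config.simulate is not None:
        atlas_spec = simulate.AtlasSpec(**(config.simulate.get("atlas") or {}))
        exp_spec = simulate.ExperimentSpec(**(config.simulate.get("experiment") or {}))
        atlas_result = simulate.simulate_atlas(atlas_spec, seed=config.seed)
        exp = simulate.simulate_experiment(exp_spec, atlas_result, seed=config.seed + 1)
        run.emit("simulate", "truth_atlas.tsv",
                 lambda p: atlas_result.truth.to_csv(p, sep="\t", index=False))
        run.emit("simulate", "truth_experiment.tsv",
                 lambda p: exp.truth.to_csv(p, sep="\t", index=False))
        run.emit("simulate", "peaks_minus.narrowPeak",
                 lambda p: write_peaks(exp.peaks_minus, p, "narrowPeak"))
        run.emit("simulate", "peaks_plus.narrowPeak",
                 lambda p: write_peaks(exp.peaks_plus, p, "narrowPeak"))
        run.emit("simulate", "track_minus.bedGraph",
                 lambda p: write_bedgraph(exp.track_minus, p))
        run.emit("simulate", "track_plus.bedGraph",
                 lambda p: write_bedgraph(exp.track_plus, p))
        peaks_minus, peaks_plus = exp.peaks_minus, exp.peaks_plus
        track_minus, track_plus = exp.track_minus, exp.track_plus
    else:
        fmt = inputs.get("format", "narrowPeak")
        peaks_minus = read_peaks(inputs["peaks_minus"], fmt, label="minus")
        peaks_plus = read_peaks(inputs["peaks_plus"], fmt, label="plus")
        track_minus = read_bedgraph(inputs["track_minus"])
        track_plus = read_bedgraph(inputs["track_plus"])

    genes = None
    if inputs.get("genes"):
        genes = GeneAnnotation.read_tsv(inputs["genes"])
    if inputs.get("blacklist"):
        blk = read_peaks(inputs["blacklist"], "bed", label="blacklist")
        before = len(peaks_minus) + len(peaks_plus)
        peaks_minus = filter_blacklist(peaks_minus, blk)
        peaks_plus = filter_blacklist(peaks_plus, blk)
        run.log["blacklist_removed"] = before - len(peaks_minus) - len(peaks_plus)
    run.log["n_peaks_minus"] = len(peaks_minus)
    run.log["n_peaks_plus"] = len(peaks_plus)

    # --- union + differential ----------------------------------------
    union = diffacc.build_peak_union(
        peaks_minus, peaks_plus, summit_distance=int(params["summit_distance"])
    )
    run.log["n_union_peaks"] = len(union)
    table = diffacc.differential_table(
        union,
        track_minus,
        track_plus,
        genes=genes,
        width=int(params["window"]),
        promoter_window=int(params["promoter_window"]),
        fold_threshold=float(params["fold"]),
    )
    counts = table.groupby(["element", "class"]).size()
    run.log["differential_counts"] = {
        f"{e}:{c}": int(v) for (e, c), v in counts.items()
    }
    logger.info("differential class counts: %s", run.log["differential_counts"])
    run.emit("differential", "differential.tsv",
             lambda p: diffacc.write_differential_table(table, p))

    # --- ranked heatmap matrices -------------------------------------
    mats = diffacc.ranked_density_matrix(
        table,
        {"minus": track_minus, "plus": track_plus},
        window=int(params["heatmap_window"]),
        bin=int(params["bin"]),
    )
    for name, mat in mats.items():
        run.emit("heatmaps", f"density_{name}.tsv",
                 lambda p, m=mat: m.to_csv(p, sep="\t", index_label="peak"))
    corr, order = diffacc.correlation_cluster(
        pd.DataFrame(
            {"minus": table["log2_minus"], "plus": table["log2_plus"]}
        ).T
    )
    run.emit("heatmaps", "sample_correlation.tsv",
             lambda p: corr.to_csv(p, sep="\t", index_label="sample"))
    run.log["sample_order"] = order

    # --- motifs -------------------------------------------------------
    motif_counts = None
    if inputs.get("motif_counts"):
        motif_counts = motifs.read_motif_counts(inputs["motif_counts"])
    elif config.simulate is not None and config.simulate.get("motifs"):
        mcfg = config.simulate["motifs"]
        gained = diffacc.differential_peakset(table, "gained", "gained")
        lost = diffacc.differential_peakset(table, "lost", "lost")
        shared = diffacc.differential_peakset(table, "shared", "shared")
        motif_counts, _ = simulate.simulate_motifs(
            {"gained": gained, "lost": lost, "shared": shared},
            mcfg.get("rates", {}),
            seed=config.seed + 2,
        )
    if motif_counts is not None and len(motif_counts.n):
        S = motifs.enrichment_scores(motif_counts)
        run.emit("motifs", "scores.tsv",
                 lambda p: motifs.write_score_matrix(S, p))
        if S.shape[0] >= 2:
            row_order, col_order = motifs.cluster_scores(S)
            run.log["motif_order"] = row_order

    # --- priming ------------------------------------------------------
    atlas = None
    if inputs.get("signatures"):
        atlas = priming.SignatureAtlas(
            signatures={
                ct: read_peaks(path, inputs.get("signature_format", "bed"), label=ct)
                for ct, path in sorted(inputs["signatures"].items())
            }
        )
    elif atlas_result is not None:
        atlas = priming.derive_signatures(atlas_result.replicates)
        for ct, sig in sorted(atlas.signatures.items()):
            run.emit("signatures", f"{ct}.summit-bed",
                     lambda p, s=sig: write_peaks(s, p, "summit-bed"))
    if atlas is not None:
        panel = priming.priming_panel(
            table,
            atlas,
            n_resamples=int(params["n_resamples"]),
            seed=config.seed,
            condition=inputs.get("condition", "experiment"),
        )
        run.emit("priming", "priming.tsv",
                 lambda p: panel.to_csv(p, sep="\t", index=False))
        run.log["degenerate_priming_tests"] = int(
            panel.get("degenerate", pd.Series(dtype=bool)).fillna(False).sum()
        )

    # --- expression ---------------------------------------------------
    de_paths = inputs.get("de_tables") or []
    if de_paths:
        tables = {Path(p).stem: expression.read_de_table(p) for p in de_paths}
        sets = {k: expression.deregulated_sets(t, float(params["fold"]))
                for k, t in tables.items()}
        run.log["deregulated_counts"] = {
            k: {"up": len(u), "down": len(d)} for k, (u, d) in sets.items()
        }
        if len(tables) >= 2:
            conc, opp, flags = expression.pairwise_overlap(sets)
            run.emit("expression", "concordant.tsv",
                     lambda p: conc.to_csv(p, sep="\t", index_label="contrast"))
            run.emit("expression", "opposing.tsv",
                     lambda p: opp.to_csv(p, sep="\t", index_label="contrast"))
            try:
                ecorr, eorder = expression.fold_change_correlation(
                    tables, float(params["fold"])
                )
                run.emit("expression", "fold_change_correlation.tsv",
                         lambda p: ecorr.to_csv(p, sep="\t", index_label="contrast"))
                run.log["expression_order"] = eorder
            except ValueError as exc:
                run.log["expression_correlation_skipped"] = str(exc)

    manifest = {
        "outputs": dict(sorted(run.outputs.items())),
        "log": run.log,
    }
    run.outdir.mkdir(parents=True, exist_ok=True)
    with open(run.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
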