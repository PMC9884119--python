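"""End-to-end orchestration of the quantification pipeline.

For every embryo in a cohort manifest: read the stack (and optional
region-of-interest mask), segment the DNA channel into a 3D label volume,
measure every nucleus, restrict to the embryonic region, apply QC, and
export the per-object table. Cohort-level stages then run the statistics
battery per marker channel, apply any configured gates, and write
per-embryo summaries, together with a machine-readable run log (config
hash, per-stage object counts, package versions). The pipeline is fully
deterministic given inputs and config; per-embryo failures are logged and
skipped, and are reported in the run summary.
"""

from __future__ import annotations

import json
import logging
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .gating import (PolygonGate, ThresholdGate, gate_select, per_embryo_summary,
                     size_intensity_correlation)
from .io import (PipelineConfig, read_manifest, read_roi, read_stack,
                 write_labels)
from .quantify import apply_region, export_table, measure_nuclei, qc_filter
from .segmentation import segment_stack
from .stats import compare_stages, results_to_frame

logger = logging.getLogger(__name__)


def gate_from_dict(raw: dict):
    kind = raw.get("kind")
    if kind == "threshold":
        return ThresholdGate(raw["channel"], float(raw["min_intden"]))
    if kind == "polygon":
        return PolygonGate(raw["x_channel"], raw["y_channel"],
                           tuple(map(tuple, raw["vertices"])))
    raise ValueError(f"unknown gate kind {raw.get('kind')!r}")


def process_embryo(row, config: PipelineConfig, out_dir: Path) -> pd.DataFrame:
    """Segment, measure, region-restrict and QC one embryo; returns its table."""
    stack = read_stack(row["stack_path"])
    labels, tracks = segment_stack(stack, config.segmentation, config.dna_channel)
    table = measure_nuclei(
        labels, stack,
        embryo_id=str(row["embryo_id"]),
        stage=str(row["stage"]),
        genotype=str(row.get("genotype", "WT")),
        dna_channel=config.dna_channel,
    )
    roi_path = row.get("roi_path")
    if isinstance(roi_path, str) and roi_path:
        roi = read_roi(roi_path)
        table = apply_region(table, roi, stack.calibration)
    table = qc_filter(table, config.qc)
    write_labels(labels, out_dir / f"{row['embryo_id']}_labels.tif")
    export_table(table, out_dir / f"{row['embryo_id']}_nuclei.csv",
                 channel_names=stack.channel_names)
    return table


def run_pipeline(manifest, config: PipelineConfig, out_dir) -> dict:
    """Run the full pipeline over a cohort manifest.

    ``manifest`` is a path or DataFrame with columns embryo_id, stage,
    genotype, stack_path, roi_path, seed. Returns a summary dict (also
    written as run_log.json) with per-embryo status and cohort outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)

    tables, failures, counts = [], {}, {}
    for _, row in manifest.iterrows():
        embryo_id = str(row["embryo_id"])
        try:
            table = process_embryo(row, config, out_dir)
            tables.append(table)
            counts[embryo_id] = int(len(table))
        except Exception as exc:  # noqa: BLE001 - failures must not stop the cohort
            logger.error("embryo %s failed: %s", embryo_id, exc)
            failures[embryo_id] = f"{type(exc).__name__}: {exc}"
            logger.debug("%s", traceback.format_exc())

    outputs = {}
    if tables:
        cohort = pd.concat(tables, ignore_index=True)
        export_table(cohort, out_dir / "cohort_nuclei.csv")

        n_stages = cohort.loc[cohort["in_region"].astype(bool), "stage"].nunique()
        if n_stages >= 2:
            frames = []
            for channel in config.stats.channels:
                col = f"intden_{channel}"
                if col not in cohort.columns:
                    continue
                results, summary = compare_stages(
                    cohort, channel,
                    adjust=config.stats.adjust,
                    per_embryo=config.stats.per_embryo,
                )
                frame = results_to_frame(results)
                frame.insert(0, "channel", channel)
                frames.append(frame)
                summary.insert(0, "channel", channel)
                summary.to_csv(out_dir / f"violin_{channel}.csv", index=False)
            if frames:
                pd.concat(frames, ignore_index=True).to_csv(
                    out_dir / "stats.csv", index=False)
                outputs["stats"] = "stats.csv"

        for g_idx, raw_gate in enumerate(config.gates):
            gate = gate_from_dict(raw_gate)
            selection = gate_select(cohort, gate)
            pd.DataFrame(selection, columns=["embryo_id", "nucleus_id"]).to_csv(
                out_dir / f"gate_{g_idx}_selection.csv", index=False)

        summary = per_embryo_summary(cohort)
        summary.to_csv(out_dir / "per_embryo_summary.csv", index=False)
        outputs["per_embryo_summary"] = "per_embryo_summary.csv"
        for channel in config.stats.channels:
            if (f"mean_intden_{channel}" in summary.columns and len(summary) > 2
                    and summary["n_cells"].nunique() > 1):
                rho, p = size_intensity_correlation(summary, channel)
                outputs[f"size_intensity_{channel}"] = {"rho": rho, "p": p}

    run_log = {
        "config_hash": config.content_hash(),
        "embryoquant_version": __version__,
        "numpy_version": np.__version__,
        "n_embryos": int(len(manifest)),
        "n_failed": len(failures),
        "failures": failures,
        "nuclei_per_embryo": counts,
        "outputs": outputs,
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return run_log
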