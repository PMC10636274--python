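"""End-to-end batch processing.

Per file: read -> match characteristic ions -> warp RT -> extract isotopic
clusters -> locate and bound peaks -> integrate -> MID -> natural-abundance
correction -> record. Per-file failures are logged and skipped so a single
corrupt file never aborts a batch. A JSON-lines run log captures versions,
seed and parameters for reproducibility.
"""

from __future__ import annotations

import glob as globlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .chromatography import (
    extract_cluster,
    find_bounds,
    match_peak,
    prepare_cluster,
    warp_rt,
)
from .correction import CorrectionError, correct_mid
from .errors import MidquantError, PeakNotFoundError
from .io_raw import read_run
from .method import Method, load_method
from .quantify import (
    FLAG_CORRECTION_FAILED,
    FLAG_LOW_SIGNAL,
    FLAG_OK,
    FLAG_PEAK_NOT_FOUND,
    MIDRecord,
    compute_ape,
    compute_ape_dual,
    compute_mid,
    integrate_cluster,
    low_signal,
)
from .reporting import (
    compare_groups,
    export_workbook,
    load_sample_meta,
    summarize_groups,
)
from .synthetic import target_matrix

logger = logging.getLogger(__name__)


@dataclass
class BatchConfig:
    method_path: str
    data_paths: list[str]
    output_dir: str
    meta_path: str | None = None
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    correction_enabled: bool | None = None  # None = follow the method file
    plots: bool = False
    seed: int = 0
    workbook_name: str = "results.xlsx"

    def resolve_data_paths(self) -> list[str]:
        paths = []
        for entry in self.data_paths:
            expanded = sorted(globlib.glob(entry))
            paths.extend(expanded if expanded else [entry])
        return paths


def process_file(
    path: str,
    method: Method,
    sample_id: str | None = None,
    correction_enabled: bool | None = None,
) -> list[MIDRecord]:
    """Process one raw file against a method; returns one record per target."""
    run = read_run(path)
    sample_id = sample_id or Path(path).stem
    correct = (
        method.correction_enabled if correction_enabled is None
        else correction_enabled
    )
    isotope_table = method.isotope_table()
    k = method.noise_multiplier_k

    # pass 1: characteristic ions with the identity warp -> RT anchors
    anchors = []
    characteristic_rts: dict[str, list[float]] = {}
    for target in method.targets:
        if not target.is_characteristic:
            continue
        try:
            cluster = prepare_cluster(extract_cluster(run, target, method), method)
            apex = match_peak(cluster, target.expected_rt, target.rt_window, k=k)
            observed = float(cluster.composite.rt[apex])
            anchors.append((target.expected_rt, observed))
            characteristic_rts.setdefault(target.compound_name, []).append(observed)
        except (PeakNotFoundError, MidquantError) as exc:
            logger.warning("characteristic ion %s not anchored: %s",
                           target.ion_name, exc)
    warp = warp_rt(anchors)

    records = []
    for target in method.targets:
        cluster = None
        try:
            cluster = prepare_cluster(extract_cluster(run, target, method), method)
            sibling_rts = [
                rt for rt in characteristic_rts.get(target.compound_name, [])
            ]
            apex = match_peak(
                cluster,
                warp(target.expected_rt),
                target.rt_window,
                characteristic_apex_rts=sibling_rts or None,
                k=k,
            )
            cluster.bounds = find_bounds(
                cluster, apex, k=k, asymmetry_cap=method.asymmetry_cap
            )
        except PeakNotFoundError as exc:
            logger.info("%s: %s", sample_id, exc)
            n = len(target.quantified_isotopologues)
            records.append(MIDRecord(
                target=target, sample_id=sample_id, areas=np.zeros(n),
                flags=[FLAG_PEAK_NOT_FOUND],
            ))
            continue

        areas = integrate_cluster(cluster)
        record = MIDRecord(target=target, sample_id=sample_id, areas=areas)
        record.raw_mid = compute_mid(areas)
        flags = []
        if record.raw_mid is None:
            flags.append(FLAG_LOW_SIGNAL)
        elif low_signal(areas, cluster.noise_level, cluster.bounds):
            flags.append(FLAG_LOW_SIGNAL)
        if record.raw_mid is not None and correct:
            try:
                m = target_matrix(target, method.correction_mode, isotope_table)
                record.corrected_mid = correct_mid(record.raw_mid, m).fractions
            except CorrectionError as exc:
                logger.warning("%s/%s: correction failed: %s",
                               sample_id, target.ion_name, exc)
                flags.append(FLAG_CORRECTION_FAILED)
        elif record.raw_mid is not None:
            record.corrected_mid = record.raw_mid.copy()
        if record.corrected_mid is not None:
            if target.is_dual_tracer:
                record.ape_percent = list(compute_ape_dual(
                    record.corrected_mid,
                    [tuple(c) for c in target.quantified_isotopologues],
                    (target.tracers[0].n_labeled_positions,
                     target.tracers[1].n_labeled_positions),
                ))
            else:
                record.ape_percent = [compute_ape(
                    record.corrected_mid, target.tracers[0].n_labeled_positions
                )]
        record.flags = flags or [FLAG_OK]
        records.append(record)
    return records


def run_batch(config: BatchConfig) -> int:
    """Run a full batch; returns the number of successfully processed files.

    Outputs under ``config.output_dir``: the workbook, its CSV mirror and
    ``run_log.jsonl``. A file that fails to parse is logged and skipped.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    method = load_method(config.method_path)
    meta = load_sample_meta(config.meta_path) if config.meta_path else None

    log_path = out_dir / "run_log.jsonl"
    records = []
    processed = 0
    with open(log_path, "w") as log:
        log.write(json.dumps({
            "event": "start", "version": __version__, "seed": config.seed,
            "method": str(config.method_path),
            "correction_enabled": config.correction_enabled,
        }) + "\n")
        for path in config.resolve_data_paths():
            sample_id = Path(path).stem
            try:
                file_records = process_file(
                    path, method, sample_id=sample_id,
                    correction_enabled=config.correction_enabled,
                )
            except (MidquantError, FileNotFoundError, OSError) as exc:
                logger.warning("skipping %s: %s", path, exc)
                log.write(json.dumps({
                    "event": "file_failed", "file": str(path), "error": str(exc),
                }) + "\n")
                continue
            processed += 1
            records.extend(file_records)
            log.write(json.dumps({
                "event": "file_done", "file": str(path),
                "n_records": len(file_records),
            }) + "\n")
        log.write(json.dumps({"event": "end", "files_processed": processed}) + "\n")

    if processed == 0:
        return 0
    summaries = summarize_groups(records, meta) if meta else None
    comparisons = (
        compare_groups(records, meta, config.comparisons)
        if meta and config.comparisons else None
    )
    export_workbook(
        records,
        out_dir / config.workbook_name,
        summaries=summaries,
        comparisons=comparisons,
        meta=meta,
        isotope_table=method.isotope_table(),
        mode=method.correction_mode,
    )
    if config.plots:
        _write_plots(config, method, out_dir)
    return processed


def _write_plots(config: BatchConfig, method: Method, out_dir: Path) -> None:
    """Diagnostic EIC + bounds overlays, one PNG per file x target."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir = out_dir / "plots"
    plot_dir.mkdir(exist_ok=True)
    for path in config.resolve_data_paths():
        try:
            run = read_run(path)
        except (MidquantError, OSError):
            continue
        for target in method.targets:
            try:
                cluster = prepare_cluster(
                    extract_cluster(run, target, method), method)
                apex = match_peak(cluster, target.expected_rt,
                                  target.rt_window, k=method.noise_multiplier_k)
                bounds = find_bounds(cluster, apex, k=method.noise_multiplier_k,
                                     asymmetry_cap=method.asymmetry_cap)
            except MidquantError:
                continue
            fig, ax = plt.subplots(figsize=(6, 3))
            for eic, lc in zip(cluster.channel_eics,
                               target.quantified_isotopologues):
                ax.plot(eic.rt, eic.intensity, lw=0.8, label=f"M+{lc}")
            ax.plot(cluster.composite.rt, cluster.smoothed_composite.intensity,
                    "k--", lw=1, label="composite (SG)")
            for idx in (bounds.left_index, bounds.right_index):
                ax.axvline(cluster.composite.rt[idx], color="r", lw=0.8)
            ax.set_xlabel("RT / s")
            ax.set_ylabel("intensity")
            ax.legend(fontsize=6)
            stem = Path(path).stem
            safe = target.ion_name.replace("/", "_").replace(" ", "_")
            fig.savefig(plot_dir / f"{stem}_{safe}.png", dpi=100,
                        bbox_inches="tight")
            plt.close(fig)
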