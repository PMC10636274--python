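"""Batch aggregation: spreadsheets, group statistics and QC diagnostics.

Outputs are a single .xlsx workbook (sheets: MIDs, APEs, Abundances,
GroupStats when metadata is given, QC) mirrored as plain CSV files. Group
comparisons use Welch's two-sample t-test per mass-isotopomer channel and
per APE, with Benjamini-Hochberg adjustment across the channels of each
target; the test is a pluggable default, not a claim that it is the only
sensible choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .quantify import MIDRecord

HEADER_VERSION = "midquant-report-v1"


@dataclass
class SampleMeta:
    sample_id: str
    file_path: str = ""
    time_point: str | float | None = None
    group: str | None = None
    is_unlabeled_control: bool = False


@dataclass
class GroupSummary:
    target_ion: str
    group: str | None
    time_point: str | float | None
    mean_mid: np.ndarray
    sd_mid: np.ndarray | None
    n: int
    mean_ape: float | None
    sd_ape: float | None


def load_sample_meta(path) -> dict[str, SampleMeta]:
    """Read sample metadata CSV (sample_id, file, group, time_point,
    is_unlabeled_control) into a sample_id-keyed dict."""
    df = pd.read_csv(path)
    meta = {}
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        if sid in meta:
            raise ValueError(f"duplicate sample_id {sid!r} in metadata")
        meta[sid] = SampleMeta(
            sample_id=sid,
            file_path=str(row.get("file", "")),
            time_point=row.get("time_point"),
            group=(str(row["group"]) if "group" in row and pd.notna(row["group"])
                   else None),
            is_unlabeled_control=bool(row.get("is_unlabeled_control", False)),
        )
    return meta


def _channel_labels(record: MIDRecord) -> list[str]:
    out = []
    for lc in record.target.quantified_isotopologues:
        if isinstance(lc, (tuple, list)):
            out.append(f"M+{lc[0]},{lc[1]}")
        else:
            out.append(f"M+{lc}")
    return out


def rmse_vs_theoretical(
    record: MIDRecord,
    isotope_table=None,
    mode: str = "low_res_ms1",
) -> float | None:
    """RMSE of an unlabeled control's *raw* MID against its theoretical value.

    The uncorrected MID is compared (correction would zero the comparison
    by construction). The theoretical unlabeled MID on the tracked
    channels is the natural isotopologue distribution of the ion formula
    as observed in the given instrument mode — i.e. the zero-label column
    of the target's correction matrix — truncated to the tracked channels
    and renormalized. ``None`` when the record carries no raw MID.
    """
    if record.raw_mid is None:
        return None
    from .synthetic import target_matrix

    theoretical = target_matrix(record.target, mode, isotope_table).matrix[:, 0]
    theoretical = theoretical / theoretical.sum()
    diff = record.raw_mid - theoretical
    return float(np.sqrt(np.mean(diff**2)))


def summarize_groups(
    records: list[MIDRecord],
    meta: dict[str, SampleMeta],
) -> list[GroupSummary]:
    """Mean and sample SD of corrected MIDs and APEs per
    (target, group, time point); missing records are excluded."""
    buckets: dict[tuple, list[MIDRecord]] = {}
    for rec in records:
        if rec.sample_id not in meta:
            raise KeyError(f"sample {rec.sample_id!r} missing from metadata")
        if rec.corrected_mid is None:
            continue
        m = meta[rec.sample_id]
        key = (rec.target.ion_name, m.group, m.time_point)
        buckets.setdefault(key, []).append(rec)
    summaries = []
    for (ion, group, tp), recs in sorted(
        buckets.items(), key=lambda kv: tuple(str(x) for x in kv[0])
    ):
        mids = np.vstack([r.corrected_mid for r in recs])
        apes = [r.ape_percent[0] for r in recs if r.ape_percent]
        n = len(recs)
        summaries.append(
            GroupSummary(
                target_ion=ion,
                group=group,
                time_point=tp,
                mean_mid=mids.mean(axis=0),
                sd_mid=mids.std(axis=0, ddof=1) if n >= 2 else None,
                n=n,
                mean_ape=float(np.mean(apes)) if apes else None,
                sd_ape=float(np.std(apes, ddof=1)) if len(apes) >= 2 else None,
            )
        )
    return summaries


def compare_groups(
    records: list[MIDRecord],
    meta: dict[str, SampleMeta],
    group_pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Welch t-test per channel and per APE between the requested groups.

    p-values are Benjamini-Hochberg adjusted across the mass-isotopomer
    channels within each (target, pair); comparisons with fewer than two
    replicates on either side are skipped with a note.
    """
    rows = []
    by_target: dict[str, list[MIDRecord]] = {}
    for rec in records:
        if rec.corrected_mid is not None:
            by_target.setdefault(rec.target.ion_name, []).append(rec)
    for ion, recs in sorted(by_target.items()):
        labels = _channel_labels(recs[0])
        for ga, gb in group_pairs:
            a = [r for r in recs if meta[r.sample_id].group == ga]
            b = [r for r in recs if meta[r.sample_id].group == gb]
            if len(a) < 2 or len(b) < 2:
                rows.append({
                    "target_ion": ion, "group_a": ga, "group_b": gb,
                    "channel": "(all)", "t": np.nan, "p": np.nan,
                    "p_adj": np.nan,
                    "note": f"skipped: n_a={len(a)}, n_b={len(b)} (need >= 2)",
                })
                continue
            mids_a = np.vstack([r.corrected_mid for r in a])
            mids_b = np.vstack([r.corrected_mid for r in b])
            channel_rows = []
            pvals = []
            for c, label in enumerate(labels):
                t, p = scipy.stats.ttest_ind(
                    mids_a[:, c], mids_b[:, c], equal_var=False
                )
                if math.isnan(p):  # zero variance in both groups
                    t, p = 0.0, 1.0
                channel_rows.append({
                    "target_ion": ion, "group_a": ga, "group_b": gb,
                    "channel": label, "t": float(t), "p": float(p), "note": "",
                })
                pvals.append(p)
            adj = multipletests(pvals, method="fdr_bh")[1]
            for row, p_adj in zip(channel_rows, adj):
                row["p_adj"] = float(p_adj)
                rows.append(row)
            apes_a = [r.ape_percent[0] for r in a if r.ape_percent]
            apes_b = [r.ape_percent[0] for r in b if r.ape_percent]
            if len(apes_a) >= 2 and len(apes_b) >= 2:
                t, p = scipy.stats.ttest_ind(apes_a, apes_b, equal_var=False)
                if math.isnan(p):
                    t, p = 0.0, 1.0
                rows.append({
                    "target_ion": ion, "group_a": ga, "group_b": gb,
                    "channel": "APE", "t": float(t), "p": float(p),
                    "p_adj": float(p), "note": "",
                })
    return pd.DataFrame(
        rows, columns=["target_ion", "group_a", "group_b", "channel",
                       "t", "p", "p_adj", "note"]
    )


def _records_frames(records, meta=None, isotope_table=None,
                    mode="low_res_ms1"):
    mid_rows, ape_rows, abundance_rows, qc_rows = [], [], [], []
    for rec in records:
        labels = _channel_labels(rec)
        for c, label in enumerate(labels):
            mid_rows.append({
                "sample_id": rec.sample_id,
                "compound": rec.target.compound_name,
                "target_ion": rec.target.ion_name,
                "channel": label,
                "area": float(rec.areas[c]),
                "raw_mid": (float(rec.raw_mid[c]) if rec.raw_mid is not None
                            else np.nan),
                "corrected_mid": (
                    float(rec.corrected_mid[c])
                    if rec.corrected_mid is not None else np.nan
                ),
            })
        ape_entry = {
            "sample_id": rec.sample_id,
            "compound": rec.target.compound_name,
            "target_ion": rec.target.ion_name,
        }
        for i, tracer in enumerate(rec.target.tracers):
            ape_entry[f"ape_{tracer.isotope_mass_number}{tracer.element}"] = (
                rec.ape_percent[i]
                if rec.ape_percent and i < len(rec.ape_percent)
                else np.nan
            )
        ape_rows.append(ape_entry)
        abundance_rows.append({
            "sample_id": rec.sample_id,
            "compound": rec.target.compound_name,
            "target_ion": rec.target.ion_name,
            "total_abundance": rec.total_abundance,
            "flags": ";".join(rec.flags),
        })
        is_control = bool(
            meta and rec.sample_id in meta
            and meta[rec.sample_id].is_unlabeled_control
        )
        if is_control:
            qc_rows.append({
                "sample_id": rec.sample_id,
                "target_ion": rec.target.ion_name,
                "rmse_vs_theoretical": rmse_vs_theoretical(rec, isotope_table,
                                                           mode),
                "flags": ";".join(rec.flags),
            })
    return (
        pd.DataFrame(mid_rows),
        pd.DataFrame(ape_rows),
        pd.DataFrame(abundance_rows),
        pd.DataFrame(qc_rows, columns=["sample_id", "target_ion",
                                       "rmse_vs_theoretical", "flags"]),
    )


def _summaries_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for c in range(s.mean_mid.size):
            rows.append({
                "target_ion": s.target_ion,
                "group": s.group,
                "time_point": s.time_point,
                "channel": c,
                "mean_mid": float(s.mean_mid[c]),
                "sd_mid": float(s.sd_mid[c]) if s.sd_mid is not None else np.nan,
                "n": s.n,
                "mean_ape": s.mean_ape if s.mean_ape is not None else np.nan,
                "sd_ape": s.sd_ape if s.sd_ape is not None else np.nan,
            })
    return pd.DataFrame(rows)


def export_workbook(
    records: list[MIDRecord],
    path,
    summaries: list[GroupSummary] | None = None,
    comparisons: pd.DataFrame | None = None,
    meta: dict[str, SampleMeta] | None = None,
    csv_dir=None,
    isotope_table=None,
    mode: str = "low_res_ms1",
) -> Path:
    """Write the batch workbook (.xlsx) and its CSV mirror.

    Sheets: MIDs, APEs, Abundances, GroupStats (only when summaries are
    given), Comparisons (only when requested) and QC. Numeric cells are
    written at full float precision so a re-read reproduces them exactly.
    """
    if not records:
        raise ValueError("no records to export")
    path = Path(path)
    mids, apes, abundances, qc = _records_frames(records, meta, isotope_table,
                                                 mode)
    sheets = {"MIDs": mids, "APEs": apes, "Abundances": abundances}
    if summaries is not None:
        sheets["GroupStats"] = _summaries_frame(summaries)
    if comparisons is not None and not comparisons.empty:
        sheets["Comparisons"] = comparisons
    sheets["QC"] = qc
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for name, df in sheets.items():
            df.to_excel(writer, sheet_name=name, index=False)
    if csv_dir is None:
        csv_dir = path.parent / (path.stem + "_csv")
    csv_dir = Path(csv_dir)
    csv_dir.mkdir(parents=True, exist_ok=True)
    for name, df in sheets.items():
        df.to_csv(csv_dir / f"{name}.csv", index=False,
                  float_format="%.15g", lineterminator="\n")
    return path
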