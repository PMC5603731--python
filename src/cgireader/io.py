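"""Plain-text interchange: TSV tables, BED intervals, bedGraph tracks."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .binding import TitrationSeries, combined_csp
from .calibration import ReadSummary, SignalTrack
from .frap import FrapTrace

__all__ = [
    "write_frap_trace", "read_frap_trace",
    "write_titration", "read_titration_fluorescence", "read_titration_csp",
    "write_bed", "read_bed", "write_tss", "read_tss",
    "write_read_summaries", "read_read_summaries",
]


def write_frap_trace(trace: FrapTrace, path) -> None:
    bg = np.broadcast_to(np.asarray(trace.background, dtype=float), trace.time.shape)
    pd.DataFrame(
        {"time": trace.time, "roi": trace.roi_intensity,
         "cell": trace.cell_intensity, "background": bg}
    ).to_csv(path, sep="\t", index=False)


def read_frap_trace(path, bleach_index: int) -> FrapTrace:
    df = pd.read_csv(path, sep="\t")
    bg = df["background"].to_numpy() if "background" in df.columns else 0.0
    return FrapTrace(
        time=df["time"].to_numpy(),
        roi_intensity=df["roi"].to_numpy(),
        cell_intensity=df["cell"].to_numpy(),
        background=bg,
        bleach_index=bleach_index,
    )


def write_titration(series: TitrationSeries, path) -> None:
    if series.mode == "fluorescence":
        pd.DataFrame(
            {"ligand_uM": series.ligand_totals, "intensity": series.response}
        ).to_csv(path, sep="\t", index=False)
    else:
        labels = series.residues or [
            f"res{i + 1}" for i in range(series.response.shape[0])
        ]
        rows = []
        for label, row in zip(labels, series.response):
            for lig, csp in zip(series.ligand_totals, row):
                rows.append({"residue": label, "ligand_uM": lig, "csp_ppm": csp})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_titration_fluorescence(path, protein_total: float) -> TitrationSeries:
    df = pd.read_csv(path, sep="\t")
    return TitrationSeries(
        protein_total=protein_total,
        ligand_totals=df["ligand_uM"].to_numpy(),
        response=df["intensity"].to_numpy(),
        mode="fluorescence",
    )


def read_titration_csp(
    path, protein_total: float, nitrogen_weight: float = 5.0
) -> TitrationSeries:
    """Read a per-residue CSP table.

    Accepts either raw shift changes (columns residue, ligand_uM, d_h_ppm,
    d_n_ppm), combined on the fly, or pre-combined magnitudes (columns
    residue, ligand_uM, csp_ppm).
    """
    df = pd.read_csv(path, sep="\t")
    if "csp_ppm" not in df.columns:
        df = df.assign(
            csp_ppm=combined_csp(
                df["d_h_ppm"].to_numpy(), df["d_n_ppm"].to_numpy(),
                nitrogen_weight,
            )
        )
    wide = df.pivot_table(
        index="residue", columns="ligand_uM", values="csp_ppm", sort=True
    )
    return TitrationSeries(
        protein_total=protein_total,
        ligand_totals=wide.columns.to_numpy(dtype=float),
        response=wide.to_numpy(),
        mode="nmr_csp",
        residues=list(wide.index),
    )


_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(intervals: pd.DataFrame, path) -> None:
    cols = [c for c in _BED_COLS if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = _BED_COLS[: df.shape[1]]
    return df


def write_tss(tss: pd.DataFrame, path) -> None:
    """TSS point set as single-base BED (name '.', score 0)."""
    out = pd.DataFrame(
        {"chrom": tss["chrom"], "start": tss["pos"], "end": tss["pos"] + 1,
         "name": ".", "score": 0, "strand": tss["strand"]}
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_tss(path) -> pd.DataFrame:
    bed = read_bed(path)
    return pd.DataFrame(
        {"chrom": bed["chrom"], "pos": bed["start"],
         "strand": bed.get("strand", pd.Series(["+"] * len(bed)))}
    )


def write_read_summaries(summaries: pd.DataFrame, path) -> None:
    summaries.to_csv(path, sep="\t", index=False)


def read_read_summaries(path) -> list[ReadSummary]:
    df = pd.read_csv(path, sep="\t")
    return [
        ReadSummary(
            sample_id=str(r.sample_id), role=str(r.role),
            target_reads=int(r.target_reads), spike_reads=int(r.spike_reads),
        )
        for r in df.itertuples()
    ]
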