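"""Spike-in calibration of ChIP-seq / nuclear RNA-seq signal.

When every sample receives a fixed amount of foreign-genome material (e.g.
a constant number of Drosophila cells per fixed number of experimental
cells), the reads mapping to the spike genome measure the per-sample
recovery efficiency, and scaling each sample "per million spike-in reads"
puts all samples on a common absolute axis.  Plain sequencing-depth
normalization cannot do this: a genuine global loss of signal changes
target and normalizer together and silently cancels out.

Tracks use bedGraph semantics: fixed-width, 0-based, half-open bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "ReadSummary",
    "CalibrationFactor",
    "SignalTrack",
    "compute_spike_factor",
    "calibrate_track",
    "quantify_intervals",
    "log2_change",
]


@dataclass
class ReadSummary:
    """Per-sample mapped-read totals for target and spike genomes."""

    sample_id: str
    target_reads: int
    spike_reads: int
    role: str = "ip"   # {"ip", "input", "rna", "gdna"}

    def __post_init__(self):
        if self.target_reads < 0 or self.spike_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.role not in ("ip", "input", "rna", "gdna"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class CalibrationFactor:
    sample_id: str
    alpha: float

    def __post_init__(self):
        if not (self.alpha > 0):
            raise ValueError("alpha must be > 0")


@dataclass
class SignalTrack:
    """Fixed-width binned genome signal (bedGraph semantics).

    ``data`` has columns chrom, start, end, value with uniform bin width,
    sorted and non-overlapping within each chromosome.  ``factor_applied``
    records any calibration multiplier already baked into the values.
    """

    data: pd.DataFrame
    bin_size: int
    factor_applied: float = 1.0

    def __post_init__(self):
        required = {"chrom", "start", "end", "value"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"track needs columns {sorted(required)}")
        widths = self.data["end"] - self.data["start"]
        if len(self.data) and not np.all(widths == self.bin_size):
            raise ValueError("all bins must have width == bin_size")
        for _, sub in self.data.groupby("chrom", sort=False):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            if np.any(np.diff(s) <= 0) or np.any(s[1:] < e[:-1]):
                raise ValueError("bins must be sorted and non-overlapping")

    def to_bedgraph(self, path) -> None:
        self.data.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bedgraph(cls, path, bin_size: int | None = None) -> "SignalTrack":
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "value"],
        )
        if bin_size is None:
            if df.empty:
                raise ValueError("cannot infer bin size from an empty bedGraph")
            bin_size = int(df["end"].iloc[0] - df["start"].iloc[0])
        return cls(data=df, bin_size=bin_size)


def compute_spike_factor(
    summary: ReadSummary, input_summary: ReadSummary | None = None
) -> CalibrationFactor:
    """Per-million-spike-reads calibration factor.

    alpha = 10⁶ / spike_reads; samples with equal spike recovery get equal
    factors regardless of target depth.  With ``input_summary`` given, the
    factor is additionally multiplied by the paired input's
    spike_reads/target_reads ratio (input-corrected mode), which cancels
    differences in input material composition between samples.
    """
    if summary.spike_reads <= 0:
        raise ValueError("spike_reads must be > 0 for calibration")
    total = summary.spike_reads + summary.target_reads
    if total > 0 and summary.spike_reads / total > 0.5:
        warnings.warn(
            f"sample {summary.sample_id}: spike reads exceed 50% of the "
            "library; calibration factor dominated by spike material",
            stacklevel=2,
        )
    alpha = 1e6 / summary.spike_reads
    if input_summary is not None:
        if input_summary.spike_reads <= 0 or input_summary.target_reads <= 0:
            raise ValueError("input summary needs positive spike and target reads")
        alpha *= input_summary.spike_reads / input_summary.target_reads
    return CalibrationFactor(sample_id=summary.sample_id, alpha=alpha)


def calibrate_track(track: SignalTrack, factor: CalibrationFactor) -> SignalTrack:
    """Multiply every bin by the calibration factor; record it in metadata."""
    data = track.data.copy()
    data["value"] = data["value"] * factor.alpha
    return replace(
        track, data=data, factor_applied=track.factor_applied * factor.alpha
    )


@dataclass
class IntervalQuantification:
    """Overlap-weighted mean signal per interval, in input order."""

    mean_signal: np.ndarray
    covered_fraction: np.ndarray
    flags: list[str] = field(default_factory=list)


def quantify_intervals(
    track: SignalTrack, intervals: pd.DataFrame, extend: int = 0
) -> IntervalQuantification:
    """Mean track value over each interval, weighted by overlap length.

    Intervals (columns chrom, start, end) are optionally extended by
    ``extend`` bp on both sides and clipped at 0.  The mean is taken over
    the covered bases only; intervals with no covered base quantify to 0
    and are flagged (``covered_fraction`` 0).

    Raises
    ------
    KeyError
        For intervals on chromosomes absent from the track.
    """
    per_chrom = {}
    for chrom, sub in track.data.groupby("chrom", sort=False):
        per_chrom[chrom] = (
            sub["start"].to_numpy(dtype=np.int64),
            sub["end"].to_numpy(dtype=np.int64),
            sub["value"].to_numpy(dtype=float),
        )
    unknown = sorted(set(intervals["chrom"]) - set(per_chrom))
    if unknown:
        raise KeyError(f"intervals on chromosomes absent from track: {unknown}")

    n = len(intervals)
    means = np.zeros(n)
    covered = np.zeros(n)
    flags: list[str] = []
    rows = zip(
        intervals["chrom"].to_numpy(),
        intervals["start"].to_numpy(dtype=np.int64),
        intervals["end"].to_numpy(dtype=np.int64),
    )
    for i, (chrom, s, e) in enumerate(rows):
        s = max(int(s) - extend, 0)
        e = int(e) + extend
        if e <= s:
            flags.append(f"interval {i}: empty after extension")
            continue
        starts, ends, values = per_chrom[chrom]
        j0 = np.searchsorted(ends, s, side="right")
        j1 = np.searchsorted(starts, e, side="left")
        if j1 <= j0:
            flags.append(f"interval {i}: no track coverage")
            continue
        ov = np.minimum(ends[j0:j1], e) - np.maximum(starts[j0:j1], s)
        ov = np.clip(ov, 0, None).astype(float)
        w = float(ov.sum())
        if w == 0:
            flags.append(f"interval {i}: no track coverage")
            continue
        means[i] = float(ov @ values[j0:j1]) / w
        covered[i] = w / (e - s)
    return IntervalQuantification(
        mean_signal=means, covered_fraction=covered, flags=flags
    )


def log2_change(quant_a, quant_b, pseudocount: float = 1.0) -> np.ndarray:
    """Per-interval log2((a + pc) / (b + pc)) over matched interval sets."""
    a = np.asarray(
        quant_a.mean_signal if hasattr(quant_a, "mean_signal") else quant_a,
        dtype=float,
    )
    b = np.asarray(
        quant_b.mean_signal if hasattr(quant_b, "mean_signal") else quant_b,
        dtype=float,
    )
    if a.shape != b.shape:
        raise ValueError("interval quantifications differ in length")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log2((a + pseudocount) / (b + pseudocount))
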