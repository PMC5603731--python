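"""CpG-island / non-methylated-island (NMI) interval analytics.

Quantitative genomics of a multivalent chromatin reader: overlap of binding
peaks with NMIs, TSS annotation, metaprofiles around anchors, percentile
binning of NMIs by H3K4me3, and a divergence-from-linearity multivalence
index.  The index captures the contrast between a monovalent reader (whose
occupancy scales linearly with non-methylated DNA irrespective of H3K4me3)
and a multivalent one (whose occupancy per unit of non-methylated DNA rises
with H3K4me3): per H3K4me3-percentile bin the ratio
mean(signal)/mean(reference DNA signal) is computed, and the index is the
Spearman correlation of that ratio with bin rank, judged against a
permutation null that shuffles the signal among NMIs with matched reference
signal.

Coordinates are BED dialect throughout: 0-based, half-open, sorted within
chromosome; overlap means >= 1 bp intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import SignalTrack, quantify_intervals

__all__ = [
    "OverlapVenn",
    "TssAnnotation",
    "MultivalenceResult",
    "overlap_venn",
    "annotate_tss",
    "metaprofile",
    "percentile_bins",
    "enrichment_matrix",
    "multivalence_index",
    "rank_correlation",
    "classify_de",
    "classify_expression",
    "group_difference_test",
    "call_nmis",
]


# ---------------------------------------------------------------- overlap

def _as_chrom_arrays(df: pd.DataFrame) -> dict:
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        s = sub["start"].to_numpy(dtype=np.int64)
        e = sub["end"].to_numpy(dtype=np.int64)
        if np.any(e <= s):
            raise ValueError("intervals must satisfy start < end")
        if np.any(np.diff(s) < 0):
            raise ValueError("intervals must be sorted by start within chrom")
        out[chrom] = (s, e)
    return out


def _overlaps_any(df: pd.DataFrame, other: dict) -> np.ndarray:
    """Boolean per row of df: >= 1 bp intersection with any interval in other.

    ``other`` maps chrom -> (starts, ends) sorted by start.  Among other-
    intervals starting before a query's end, the one reaching furthest
    right (running max of ends) decides overlap, so intervals within a set
    may themselves nest or overlap.
    """
    hit = np.zeros(len(df), dtype=bool)
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in other:
            continue
        os, oe = other[chrom]
        reach = np.maximum.accumulate(oe)
        s = sub["start"].to_numpy(dtype=np.int64)
        e = sub["end"].to_numpy(dtype=np.int64)
        idx = np.searchsorted(os, e, side="left") - 1
        ok = idx >= 0
        ok[ok] = reach[idx[ok]] > s[ok]
        hit[df.index.get_indexer(sub.index)] = ok
    return hit


@dataclass
class OverlapVenn:
    peaks_total: int
    nmis_total: int
    peaks_overlapping: int
    nmis_overlapped: int
    peaks_only: int
    nmis_only: int
    frac_peaks_at_nmis: float   # nan when no peaks
    frac_nmis_occupied: float   # nan when no NMIs


def overlap_venn(peaks: pd.DataFrame, nmis: pd.DataFrame) -> OverlapVenn:
    """Two-way overlap census between peaks and NMIs.

    Fractions are relative to each set's own total and reported as nan
    (undefined, not zero) for an empty input set.
    """
    nmi_idx = _as_chrom_arrays(nmis)
    peak_idx = _as_chrom_arrays(peaks)
    p_hit = _overlaps_any(peaks, nmi_idx) if len(peaks) else np.zeros(0, bool)
    n_hit = _overlaps_any(nmis, peak_idx) if len(nmis) else np.zeros(0, bool)
    np_, nn = len(peaks), len(nmis)
    return OverlapVenn(
        peaks_total=np_,
        nmis_total=nn,
        peaks_overlapping=int(p_hit.sum()),
        nmis_overlapped=int(n_hit.sum()),
        peaks_only=int(np_ - p_hit.sum()),
        nmis_only=int(nn - n_hit.sum()),
        frac_peaks_at_nmis=float(p_hit.mean()) if np_ else float("nan"),
        frac_nmis_occupied=float(n_hit.mean()) if nn else float("nan"),
    )


# ------------------------------------------------------------ TSS overlap

@dataclass
class TssAnnotation:
    """2x2 census of NMIs by (bound, overlaps a TSS)."""

    table: pd.DataFrame          # index bound/unbound, columns tss/no_tss
    pct_tss_bound: float
    pct_tss_unbound: float
    has_tss: np.ndarray          # per-NMI, input order


def annotate_tss(
    nmis: pd.DataFrame, tss: pd.DataFrame, bound: np.ndarray, window: int = 0
) -> TssAnnotation:
    """Cross NMI binding status with TSS overlap.

    An NMI overlaps a TSS when a TSS point lies in [start − window,
    end + window), clipped at 0; the default window 0 is containment in the
    half-open NMI itself.  ``bound`` is a boolean per NMI (e.g. from
    ``overlap_venn`` against reader peaks).
    """
    bound = np.asarray(bound, dtype=bool)
    if bound.size != len(nmis):
        raise ValueError("bound flag length must match NMIs")
    pos_by_chrom = {
        c: np.sort(sub["pos"].to_numpy(dtype=np.int64))
        for c, sub in tss.groupby("chrom", sort=False)
    }
    has = np.zeros(len(nmis), dtype=bool)
    for chrom, sub in nmis.groupby("chrom", sort=False):
        pos = pos_by_chrom.get(chrom)
        if pos is None:
            continue
        s = np.maximum(sub["start"].to_numpy(dtype=np.int64) - window, 0)
        e = sub["end"].to_numpy(dtype=np.int64) + window
        cnt = np.searchsorted(pos, e, "left") - np.searchsorted(pos, s, "left")
        has[nmis.index.get_indexer(sub.index)] = cnt > 0
    table = pd.DataFrame(
        {
            "tss": [int((bound & has).sum()), int((~bound & has).sum())],
            "no_tss": [int((bound & ~has).sum()), int((~bound & ~has).sum())],
        },
        index=["bound", "unbound"],
    )

    def _pct(mask):
        return float(100.0 * has[mask].mean()) if mask.any() else float("nan")

    return TssAnnotation(
        table=table,
        pct_tss_bound=_pct(bound),
        pct_tss_unbound=_pct(~bound),
        has_tss=has,
    )


# ------------------------------------------------------------ metaprofile

def metaprofile(
    track: SignalTrack, anchors: pd.DataFrame, flank: int, n_bins: int
) -> pd.DataFrame:
    """Average signal in ``n_bins`` bins across [anchor − flank, anchor + flank).

    ``anchors`` needs columns chrom, pos, strand; minus-strand windows are
    reversed before averaging so bin 0 is always "upstream".  Anchors whose
    window has no track coverage at all are excluded and counted in the
    ``n_anchors`` column.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    width = 2.0 * flank / n_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    excluded = 0
    per_chrom = {
        c: (
            sub["start"].to_numpy(dtype=np.int64),
            sub["end"].to_numpy(dtype=np.int64),
            sub["value"].to_numpy(dtype=float),
        )
        for c, sub in track.data.groupby("chrom", sort=False)
    }
    for chrom, pos, strand in zip(
        anchors["chrom"], anchors["pos"].astype(np.int64), anchors["strand"]
    ):
        cov = per_chrom.get(chrom)
        if cov is None:
            excluded += 1
            continue
        starts, ends, values = cov
        edges = pos - flank + width * np.arange(n_bins + 1)
        vals = np.full(n_bins, np.nan)
        for b in range(n_bins):
            s, e = edges[b], edges[b + 1]
            j0 = np.searchsorted(ends, s, side="right")
            j1 = np.searchsorted(starts, e, side="left")
            if j1 <= j0:
                continue
            ov = np.minimum(ends[j0:j1], e) - np.maximum(starts[j0:j1], s)
            ov = np.clip(ov, 0, None).astype(float)
            if ov.sum() > 0:
                vals[b] = float(ov @ values[j0:j1]) / float(ov.sum())
        if np.all(np.isnan(vals)):
            excluded += 1
            continue
        if strand == "-":
            vals = vals[::-1]
        ok = ~np.isnan(vals)
        sums[ok] += vals[ok]
        counts[ok] += 1
    centers = -flank + width * (np.arange(n_bins) + 0.5)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out = pd.DataFrame(
        {"bin": np.arange(n_bins), "offset": centers, "mean": mean,
         "n_anchors": counts}
    )
    out.attrs["excluded_anchors"] = excluded
    return out


# ------------------------------------------------- percentile multivalence

def percentile_bins(values, n_bins: int) -> np.ndarray:
    """Assign equal-population percentile bins (0 .. n_bins−1) by rank.

    Ranking is by value with ties kept in stable input order, so bin
    populations differ by at most 1.  Rank-based, hence invariant to any
    monotone transform of the values.  All-equal values are an error:
    percentiles are undefined.
    """
    v = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if v.size < n_bins:
        raise ValueError("fewer intervals than bins")
    if np.ptp(v) == 0:
        raise ValueError("all key values equal: percentile bins undefined")
    order = np.argsort(v, kind="stable")
    bins = np.empty(v.size, dtype=int)
    bins[order] = (np.arange(v.size) * n_bins) // v.size
    return bins


def enrichment_matrix(
    tracks: dict, intervals: pd.DataFrame, extend: int = 0
) -> pd.DataFrame:
    """Mean signal per interval for each named track (rows = input order)."""
    cols = {}
    for name, track in tracks.items():
        cols[name] = quantify_intervals(track, intervals, extend=extend).mean_signal
    out = pd.DataFrame(cols)
    out.index = intervals.index
    return out


@dataclass
class MultivalenceResult:
    """Percentile-binned enrichment and a divergence-from-linearity index.

    ``relative_enrichment`` holds per-bin mean signal normalized to each
    signal's maximum bin mean (values in [0, 1], max exactly 1).  ``index``
    is the Spearman correlation between H3K4me3-bin rank and the per-bin
    signal/reference ratio; ``null_band`` brackets the central mass of the
    index under permutation of the signal among reference-matched NMIs.
    """

    bin_edges: np.ndarray
    ratio: np.ndarray
    relative_enrichment: pd.DataFrame
    index: float
    null_band: tuple[float, float]
    null_indices: np.ndarray
    p_value: float
    is_multivalent: bool
    signal: str = ""


def _ratio_index(bins, n_bins, sig, ref):
    ratio = np.empty(n_bins)
    for b in range(n_bins):
        m = bins == b
        mref = ref[m].mean()
        if mref == 0:
            raise ValueError(f"bin {b}: mean reference signal is 0")
        ratio[b] = sig[m].mean() / mref
    spread = np.ptp(ratio)
    scale = max(abs(ratio).max(), 1e-300)
    if spread <= 1e-9 * scale:
        return ratio, 0.0
    rho, _ = stats.spearmanr(np.arange(n_bins), ratio)
    return ratio, float(rho)


def multivalence_index(
    matrix: pd.DataFrame,
    signal: str,
    reference: str = "biocap",
    k4: str = "h3k4me3",
    n_bins: int = 20,
    n_permutations: int = 200,
    n_strata: int = 10,
    band_level: float = 0.99,
    rng=None,
) -> MultivalenceResult:
    """Test whether a reader's occupancy is super-linear in H3K4me3.

    NMIs are binned into ``n_bins`` equal-population bins by H3K4me3
    percentile; per bin the ratio mean(signal)/mean(reference) is computed.
    For a purely monovalent (DNA-only) reader the ratio is flat and the
    Spearman correlation of ratio against bin rank — the index — is 0; for
    a multivalent reader the ratio rises with H3K4me3 and the index
    approaches 1.  The null distribution permutes the signal column among
    NMIs within ``n_strata`` reference-signal strata (preserving the
    signal/reference coupling while destroying any H3K4me3 relation).
    Multivalence is flagged by the exact two-sided permutation p value
    ``(1 + #{|null| ≥ |index|}) / (n_permutations + 1)`` at
    α = 1 − band_level (default 0.01); unlike a finite-sample percentile
    band, this test is valid however few permutations are drawn.  The
    reported ``null_band`` (central ``band_level`` mass of the null) is
    descriptive.
    """
    for col in (signal, reference, k4):
        if col not in matrix.columns:
            raise KeyError(f"column {col!r} missing from enrichment matrix")
    if len(matrix) < 5 * n_bins:
        raise ValueError("need at least 5 intervals per percentile bin")
    rng = np.random.default_rng(rng)
    sig = matrix[signal].to_numpy(dtype=float)
    ref = matrix[reference].to_numpy(dtype=float)
    k4v = matrix[k4].to_numpy(dtype=float)

    bins = percentile_bins(k4v, n_bins)
    ratio, index = _ratio_index(bins, n_bins, sig, ref)

    strata = percentile_bins(ref, n_strata)
    stratum_members = [np.flatnonzero(strata == s) for s in range(n_strata)]
    null = np.empty(n_permutations)
    perm_sig = sig.copy()
    for p in range(n_permutations):
        for members in stratum_members:
            perm_sig[members] = sig[members[rng.permutation(members.size)]]
        _, null[p] = _ratio_index(bins, n_bins, perm_sig, ref)
    if not (0 < band_level < 1):
        raise ValueError("band_level must be in (0, 1)")
    tail = 100.0 * (1.0 - band_level) / 2.0
    lo, hi = np.percentile(null, [tail, 100.0 - tail])
    p_value = (1.0 + np.sum(np.abs(null) >= abs(index) - 1e-12)) / (
        n_permutations + 1.0
    )

    rel = {}
    for col in matrix.columns:
        v = matrix[col].to_numpy(dtype=float)
        bm = np.array([v[bins == b].mean() for b in range(n_bins)])
        top = bm.max()
        rel[col] = bm / top if top > 0 else bm
    edges = np.linspace(0, 100, n_bins + 1)

    return MultivalenceResult(
        bin_edges=edges,
        ratio=ratio,
        relative_enrichment=pd.DataFrame(rel, index=pd.RangeIndex(n_bins)),
        index=index,
        null_band=(float(lo), float(hi)),
        null_indices=null,
        p_value=float(p_value),
        is_multivalent=bool(p_value <= 1.0 - band_level),
        signal=signal,
    )


# ------------------------------------------------------------- statistics

def rank_correlation(x, y) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def classify_de(
    table: pd.DataFrame,
    fdr_threshold: float = 0.01,
    fold_change: float = 1.5,
) -> pd.DataFrame:
    """Classify genes as down / up / not_significant.

    Down: FDR ≤ ``fdr_threshold`` and log2FC ≤ −log2(fold_change); up:
    FDR ≤ threshold and log2FC ≥ +log2(fold_change); otherwise not
    significant.  Rows with missing log2fc or fdr are classed ``flagged``
    and excluded from the three substantive counts.  Class counts are in
    ``result.attrs['counts']``.
    """
    needed = {"gene", "log2fc", "fdr"}
    if not needed.issubset(table.columns):
        raise ValueError(f"table needs columns {sorted(needed)}")
    lfc_cut = np.log2(fold_change)
    out = table.copy()
    lfc = out["log2fc"].to_numpy(dtype=float)
    fdr = out["fdr"].to_numpy(dtype=float)
    valid_fdr = fdr[np.isfinite(fdr)]
    if valid_fdr.size and (valid_fdr.min() < 0 or valid_fdr.max() > 1):
        raise ValueError("fdr values must lie in [0, 1]")
    bad = ~(np.isfinite(lfc) & np.isfinite(fdr))
    cls = np.full(len(out), "not_significant", dtype=object)
    sig = fdr <= fdr_threshold
    cls[sig & (lfc <= -lfc_cut)] = "down"
    cls[sig & (lfc >= lfc_cut)] = "up"
    cls[bad] = "flagged"
    out["class"] = cls
    out.attrs["counts"] = {
        k: int((cls == k).sum())
        for k in ("down", "up", "not_significant", "flagged")
    }
    return out


def classify_expression(log2_fpkm, threshold: float = -2.5):
    """Label genes lowly_expressed (strictly below threshold) or expressed."""
    v = np.asarray(log2_fpkm, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite expression value")
    labels = np.where(v < threshold, "lowly_expressed", "expressed")
    return labels.item() if np.ndim(log2_fpkm) == 0 else labels


def group_difference_test(a, b, mode: str = "mann_whitney") -> float:
    """Two-sided nonparametric group comparison p value.

    ``mann_whitney`` for independent samples (rank ties averaged);
    ``wilcoxon_signed_rank`` for paired samples of equal length.  Paired
    samples with all-zero differences are an error — the signed-rank
    statistic is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mode == "mann_whitney":
        if a.size < 2 or b.size < 2:
            raise ValueError("each sample needs n >= 2")
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif mode == "wilcoxon_signed_rank":
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        if np.all(a == b):
            raise ValueError("all paired differences are zero")
        _, p = stats.wilcoxon(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(p)


# ----------------------------------------------------------- NMI calling

def call_nmis(
    track: SignalTrack,
    threshold: float,
    gap_max: int = 0,
    min_width: int = 1,
) -> pd.DataFrame:
    """Threshold-and-merge island caller for synthetic Bio-CAP-like tracks.

    Bins with value > threshold are kept, runs separated by gaps smaller
    than ``gap_max`` bp merged, and islands shorter than ``min_width``
    dropped.  A convenience for synthetic data; real NMI/CGI calls should
    come from dedicated callers and be supplied as BED.
    """
    records = []
    for chrom, sub in track.data.groupby("chrom", sort=False):
        sel = sub[sub["value"] > threshold]
        cur = None
        for s, e in zip(sel["start"], sel["end"]):
            gap = s - cur[1] if cur is not None else None
            if cur is not None and (gap == 0 or gap < gap_max):
                cur = (cur[0], e)
            else:
                if cur is not None:
                    records.append((chrom, *cur))
                cur = (s, e)
        if cur is not None:
            records.append((chrom, *cur))
    df = pd.DataFrame(records, columns=["chrom", "start", "end"])
    if len(df):
        df = df[df["end"] - df["start"] >= min_width].reset_index(drop=True)
        df["name"] = [f"island_{i}" for i in range(len(df))]
    return df
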