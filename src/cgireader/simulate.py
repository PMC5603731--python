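"""Synthetic data generators for every analysis stage.

Three generators emulate the statistical structure of the study designs the
package analyses, so the full chain is testable without imaging or
sequencing data:

* FRAP traces: biexponential recovery with an instantaneous bleach,
  multiplicative acquisition photobleaching shared by the spot and the
  whole-cell channel, and homoscedastic Gaussian shot noise.
* Titrations: 1:1 binding isotherms with ligand depletion, read out either
  as a single fluorescence response or as per-residue fast-exchange CSP
  amplitudes sharing one Kd.
* A toy genome: non-overlapping NMIs with graded non-methylated-DNA
  (Bio-CAP) intensity and rank-assigned H3K4me3; reader IP read counts are
  Poisson with mean proportional to Bio-CAP alone (monovalent reader) or to
  Bio-CAP times an increasing function of the H3K4me3 percentile
  (multivalent reader), plus spike-genome read totals for calibration.

All randomness flows through a seed field; a fixed seed reproduces output
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import fraction_bound
from .calibration import SignalTrack
from .frap import FrapTrace
from .binding import TitrationSeries

__all__ = [
    "FrapSimParams",
    "TitrationSimParams",
    "GenomeSimParams",
    "SyntheticGenome",
    "simulate_frap_trace",
    "simulate_titration",
    "simulate_genome",
    "frap_params_for_half_time",
]


# ------------------------------------------------------------------ FRAP

@dataclass
class FrapSimParams:
    """Generator settings for one FRAP trace.

    Defaults mirror a spinning-disk acquisition of a fast nuclear protein:
    8 frames/s, 50 pre-bleach and 1000 post-bleach frames, a bleach to 30%
    of the pre-bleach level, mild acquisition photobleaching and 2% noise.
    ``amplitude_fast + amplitude_slow ≤ 1``; the remainder is the immobile
    fraction.
    """

    amplitude_fast: float = 0.5
    rate_fast: float = 2.0          # 1/s
    amplitude_slow: float = 0.3
    rate_slow: float = 0.2          # 1/s
    bleach_depth: float = 0.3       # fraction of pre-bleach level, in (0, 1]
    acquisition_bleach_rate: float = 0.002   # 1/s
    noise_sd: float = 0.02          # in units of the pre-bleach mean
    frame_rate: float = 8.0         # frames/s
    n_prebleach: int = 50
    n_postbleach: int = 1000
    seed: int = 0

    def validate(self) -> None:
        a1, a2 = self.amplitude_fast, self.amplitude_slow
        vals = [a1, a2, self.bleach_depth, self.rate_fast, self.rate_slow,
                self.acquisition_bleach_rate, self.noise_sd, self.frame_rate]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite FRAP simulation parameter")
        if not (0 <= a1 <= 1 and 0 <= a2 <= 1 and a1 + a2 <= 1 + 1e-12):
            raise ValueError("amplitudes and immobile fraction must be in [0,1]")
        if (a1 > 0 and self.rate_fast <= 0) or (a2 > 0 and self.rate_slow <= 0):
            raise ValueError("rates must be > 0")
        if not (0 < self.bleach_depth <= 1):
            raise ValueError("bleach_depth must be in (0, 1]")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.acquisition_bleach_rate < 0 or self.noise_sd < 0:
            raise ValueError("bleach rate and noise must be >= 0")
        if self.n_prebleach < 2 or self.n_postbleach < 1:
            raise ValueError("need >= 2 pre-bleach and >= 1 post-bleach frames")


def simulate_frap_trace(params: FrapSimParams) -> FrapTrace:
    """Simulate one bleach-spot / whole-cell trace pair.

    Pre-bleach spot intensity fluctuates around 1; at the bleach frame it
    drops to ``bleach_depth`` and recovers biexponentially toward
    ``bleach_depth + (1−bleach_depth)(a1+a2)``.  Both channels are
    multiplied by the shared acquisition-photobleaching decay
    ``exp(−acquisition_bleach_rate · t)`` and carry additive Gaussian noise.
    """
    params.validate()
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_prebleach + p.n_postbleach
    time = np.arange(n) / p.frame_rate
    t_bleach = time[p.n_prebleach]
    tau = time[p.n_prebleach:] - t_bleach

    roi = np.ones(n)
    rec = p.amplitude_fast * (1.0 - np.exp(-p.rate_fast * tau)) \
        + p.amplitude_slow * (1.0 - np.exp(-p.rate_slow * tau))
    roi[p.n_prebleach:] = p.bleach_depth + (1.0 - p.bleach_depth) * rec
    decay = np.exp(-p.acquisition_bleach_rate * time)
    roi = roi * decay
    cell = decay.copy()
    roi = roi + rng.normal(0.0, p.noise_sd, n)
    cell = cell + rng.normal(0.0, p.noise_sd, n)
    return FrapTrace(
        time=time, roi_intensity=roi, cell_intensity=cell,
        bleach_index=p.n_prebleach,
    )


def _analytic_half_time(a1, k1, a2, k2):
    from .frap import half_time_params
    return half_time_params(a1, k1, a2, k2)


def frap_params_for_half_time(
    t_half: float,
    amplitude_fast: float = 0.5,
    amplitude_slow: float = 0.3,
    rate_ratio: float = 10.0,
    **kwargs,
) -> FrapSimParams:
    """Build FrapSimParams whose analytic recovery half-time equals ``t_half``.

    Holds the amplitude structure fixed (default 0.5 fast + 0.3 slow, 0.2
    immobile) and the fast/slow rate ratio fixed, then scales both rates so
    the biexponential half-point lands exactly on the requested value.
    The half-time of a biexponential scales as 1/k at fixed amplitudes and
    rate ratio, so a single reference evaluation suffices.
    """
    if t_half <= 0:
        raise ValueError("t_half must be > 0")
    ref = _analytic_half_time(
        amplitude_fast, 1.0, amplitude_slow, 1.0 / rate_ratio
    )
    k_fast = ref / t_half
    return FrapSimParams(
        amplitude_fast=amplitude_fast,
        rate_fast=k_fast,
        amplitude_slow=amplitude_slow,
        rate_slow=k_fast / rate_ratio,
        **kwargs,
    )


# ------------------------------------------------------------- titration

@dataclass
class TitrationSimParams:
    """Generator settings for one titration series."""

    protein_total: float            # μM
    ligand_points: np.ndarray       # μM, strictly increasing
    kd_true: float                  # μM
    response_free: float = 1.0
    response_sat: float = 0.0       # quench by default
    noise_sd: float = 0.0
    readout_mode: str = "fluorescence"   # {"fluorescence", "nmr_csp"}
    n_residues: int = 5
    csp_amplitude_range: tuple = (0.02, 0.12)   # ppm, CSP mode
    seed: int = 0

    def validate(self) -> None:
        lig = np.asarray(self.ligand_points, dtype=float)
        if lig.size == 0:
            raise ValueError("empty ligand_points")
        if np.any(lig < 0) or np.any(np.diff(lig) <= 0):
            raise ValueError("ligand_points must be non-negative, strictly increasing")
        if self.protein_total <= 0 or self.kd_true <= 0:
            raise ValueError("protein_total and kd_true must be > 0")
        if self.readout_mode not in ("fluorescence", "nmr_csp"):
            raise ValueError(f"unknown readout_mode {self.readout_mode!r}")
        if self.readout_mode == "nmr_csp" and self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")


def simulate_titration(params: TitrationSimParams) -> TitrationSeries:
    """Simulate a titration under the quadratic 1:1 depletion isotherm.

    Fluorescence mode interpolates between ``response_free`` and
    ``response_sat`` with the bound fraction; CSP mode emits ``n_residues``
    response rows sharing ``kd_true`` with per-residue saturation
    amplitudes drawn once from ``csp_amplitude_range``.  Gaussian noise of
    ``noise_sd`` is added per point.
    """
    params.validate()
    p = params
    rng = np.random.default_rng(p.seed)
    lig = np.asarray(p.ligand_points, dtype=float)
    f = fraction_bound(p.protein_total, lig, p.kd_true)
    if p.readout_mode == "fluorescence":
        resp = p.response_free + (p.response_sat - p.response_free) * f
        resp = resp + rng.normal(0.0, p.noise_sd, resp.shape)
        return TitrationSeries(
            protein_total=p.protein_total, ligand_totals=lig,
            response=resp, mode="fluorescence",
        )
    lo, hi = p.csp_amplitude_range
    amps = rng.uniform(lo, hi, p.n_residues)
    resp = amps[:, None] * f[None, :]
    resp = resp + rng.normal(0.0, p.noise_sd, resp.shape)
    return TitrationSeries(
        protein_total=p.protein_total, ligand_totals=lig,
        response=resp, mode="nmr_csp",
        residues=[f"res{i + 1}" for i in range(p.n_residues)],
    )


# ---------------------------------------------------------------- genome

@dataclass
class GenomeSimParams:
    """Generator settings for a toy genome with NMIs and signal tracks.

    NMIs get a Bio-CAP intensity (uniform in ``biocap_intensity_range``)
    and an H3K4me3 level assigned by transcription rank so that the
    H3K4me3 percentile of every NMI is unambiguous.  Expected reader IP
    signal per NMI is ``c·biocap`` under the monovalent model and
    ``c·biocap·(1 + multivalence_strength · pct/100)`` under the
    multivalent model, where pct is the NMI's H3K4me3 percentile midpoint.
    Read counts are Poisson around these means; spike-genome reads are
    totals only.  ``global_signal_scale`` rescales all IP means while
    leaving the spike expectation untouched (a global gain/loss of signal
    with fixed spike recovery); ``count_noise=False`` emits the noiseless
    expectations instead of Poisson draws.
    """

    n_nmis: int = 500
    n_background_regions: int = 200
    chrom_length: int = 10_000_000
    bin_size: int = 200
    biocap_intensity_range: tuple = (1.0, 10.0)
    k4_gradient: float = 1.0
    occupancy_model: str = "monovalent"     # {"monovalent", "multivalent"}
    multivalence_strength: float = 0.0
    reads_per_sample: int = 1_000_000
    spike_reads_per_sample: int = 50_000
    background_level: float = 0.02   # background bin mean, fraction of mean NMI bin mean
    global_signal_scale: float = 1.0
    count_noise: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.occupancy_model not in ("monovalent", "multivalent"):
            raise ValueError(f"unknown occupancy_model {self.occupancy_model!r}")
        if self.occupancy_model == "monovalent" and self.multivalence_strength != 0:
            raise ValueError("monovalent model forces multivalence_strength = 0")
        if self.multivalence_strength < 0:
            raise ValueError("multivalence_strength must be >= 0")
        if self.bin_size > self.chrom_length:
            raise ValueError("bin_size exceeds chrom_length")
        if self.n_nmis < 1 or self.bin_size < 1:
            raise ValueError("need n_nmis >= 1 and bin_size >= 1")
        lo, hi = self.biocap_intensity_range
        if not (0 < lo < hi):
            raise ValueError("biocap_intensity_range must be 0 < low < high")
        if self.global_signal_scale <= 0:
            raise ValueError("global_signal_scale must be > 0")


@dataclass
class SyntheticGenome:
    """Everything the downstream interval analytics consume."""

    nmis: pd.DataFrame            # chrom start end name biocap h3k4me3 k4_percentile
    background: pd.DataFrame      # chrom start end
    tss: pd.DataFrame             # chrom pos strand
    tracks: dict                  # name -> SignalTrack (biocap, h3k4me3, ip, input)
    read_summaries: pd.DataFrame  # sample_id role target_reads spike_reads
    params: GenomeSimParams = field(repr=False, default=None)


def _place_intervals(rng, n, chrom_length, bin_size, width_bins=(3, 10)):
    """Sorted, non-overlapping, bin-aligned intervals on one chromosome."""
    widths = rng.integers(width_bins[0], width_bins[1] + 1, n) * bin_size
    total = int(widths.sum())
    free = chrom_length - total
    if free < n:
        raise ValueError("chromosome too short for requested intervals")
    cuts = np.sort(rng.choice(free // bin_size, size=n, replace=False)) * bin_size
    starts = cuts + np.concatenate([[0], np.cumsum(widths[:-1])])
    ends = starts + widths
    return starts.astype(np.int64), ends.astype(np.int64)


def simulate_genome(params: GenomeSimParams) -> SyntheticGenome:
    params.validate()
    p = params
    rng = np.random.default_rng(p.seed)
    chrom = "chrS"

    n_total = p.n_nmis + p.n_background_regions
    starts, ends = _place_intervals(rng, n_total, p.chrom_length, p.bin_size)
    which = rng.permutation(n_total) < p.n_nmis
    nmi_s, nmi_e = starts[which], ends[which]
    bg_s, bg_e = starts[~which], ends[~which]

    lo, hi = p.biocap_intensity_range
    biocap = rng.uniform(lo, hi, p.n_nmis)
    # transcription rank drives H3K4me3: a random permutation of ranks,
    # independent of Bio-CAP, so DNA signal and H3K4me3 are decoupled
    rank = rng.permutation(p.n_nmis)
    pct = 100.0 * (rank + 0.5) / p.n_nmis
    k4 = p.k4_gradient * (rank + 1.0) / p.n_nmis

    if p.occupancy_model == "multivalent":
        occupancy = biocap * (1.0 + p.multivalence_strength * pct / 100.0)
    else:
        occupancy = biocap.copy()

    n_bins = p.chrom_length // p.bin_size
    bin_starts = np.arange(n_bins, dtype=np.int64) * p.bin_size

    def mean_track(nmi_values, total_reads):
        """Per-bin Poisson means: NMI bins carry the NMI value, background
        regions and the rest of the genome a low uniform floor; scaled so
        the expected genome-wide total equals total_reads."""
        m = np.full(n_bins, np.nan)
        floor = p.background_level * float(np.mean(nmi_values))
        m[:] = floor
        for s, e, v in zip(nmi_s, nmi_e, nmi_values):
            m[s // p.bin_size: e // p.bin_size] = v
        scale = total_reads / m.sum()
        return m * scale

    ip_mean = mean_track(occupancy, p.reads_per_sample * p.global_signal_scale)
    biocap_mean = mean_track(biocap, p.reads_per_sample)
    k4_mean = mean_track(k4, p.reads_per_sample)
    input_mean = np.full(n_bins, p.reads_per_sample / n_bins)

    def draw(mean):
        return rng.poisson(mean).astype(float) if p.count_noise else mean.copy()

    track_values = {
        "biocap": draw(biocap_mean),
        "h3k4me3": draw(k4_mean),
        "ip": draw(ip_mean),
        "input": draw(input_mean),
    }
    tracks = {}
    for name, vals in track_values.items():
        df = pd.DataFrame(
            {"chrom": chrom, "start": bin_starts,
             "end": bin_starts + p.bin_size, "value": vals}
        )
        tracks[name] = SignalTrack(data=df, bin_size=p.bin_size)

    def spike():
        if p.count_noise:
            return int(rng.poisson(p.spike_reads_per_sample))
        return int(p.spike_reads_per_sample)

    summaries = pd.DataFrame(
        [
            {"sample_id": name, "role": "ip" if name != "input" else "input",
             "target_reads": int(track_values[name].sum()),
             "spike_reads": spike()}
            for name in track_values
        ]
    )

    order = np.argsort(nmi_s)
    nmis = pd.DataFrame(
        {
            "chrom": chrom,
            "start": nmi_s[order],
            "end": nmi_e[order],
            "name": [f"nmi_{i}" for i in range(p.n_nmis)],
            "biocap": biocap[order],
            "h3k4me3": k4[order],
            "k4_percentile": pct[order],
            "occupancy": occupancy[order],
        }
    )
    background = pd.DataFrame(
        {"chrom": chrom, "start": np.sort(bg_s), "end": bg_e[np.argsort(bg_s)]}
    )
    tss = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": ((nmis["start"] + nmis["end"]) // 2).astype(np.int64),
            "strand": rng.choice(["+", "-"], p.n_nmis),
        }
    )
    return SyntheticGenome(
        nmis=nmis, background=background, tss=tss, tracks=tracks,
        read_summaries=summaries, params=p,
    )
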