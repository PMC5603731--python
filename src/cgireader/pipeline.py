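"""End-to-end synthetic runs: simulate → analyze → report.

A run is declared in a YAML config listing stages with parameter blocks
mirroring the generator/analysis dataclasses, plus a global seed.  Each
stage derives its own seed from (global seed, fixed stage id), so adding a
stage never perturbs the random streams of earlier ones.  Every run writes
a manifest recording the config, package version, per-stage outputs and
their content hashes; deterministic stages are byte-reproducible under a
fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as cgio
from .binding import fit_kd_fluorescence
from .calibration import compute_spike_factor
from .frap import compare_cohorts, fit_biexponential, normalize_trace
from .intervals import enrichment_matrix, multivalence_index
from .simulate import (
    FrapSimParams,
    GenomeSimParams,
    TitrationSimParams,
    simulate_frap_trace,
    simulate_genome,
    simulate_titration,
)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "stage_seed"]

log = logging.getLogger("cgireader.pipeline")

# fixed ids so per-stage streams never shift when stages are added
_STAGE_IDS = {
    "simulate_frap": 1,
    "simulate_titration": 2,
    "simulate_genome": 3,
    "frap_fit": 4,
    "binding_fit": 5,
    "multivalence": 6,
    "multivalence_demo": 7,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Counter-derived per-stage seed, stable across config edits."""
    ss = np.random.SeedSequence((int(global_seed), _STAGE_IDS[stage]))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclasses.dataclass
class RunConfig:
    stages: list
    seed: int = 0
    outdir: str = "run_output"
    log_level: str = "INFO"

    _KNOWN = {"stages", "seed", "outdir", "log_level"}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        stages = d.get("stages", [])
        for st in stages:
            if "stage" not in st:
                raise ValueError("each stage block needs a 'stage' key")
            if st["stage"] not in _STAGE_IDS:
                raise ValueError(f"unknown stage {st['stage']!r}")
        return cls(
            stages=stages, seed=int(d.get("seed", 0)),
            outdir=str(d.get("outdir", "run_output")),
            log_level=str(d.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"stages": self.stages, "seed": self.seed,
                 "outdir": self.outdir, "log_level": self.log_level},
                fh, sort_keys=False,
            )


@dataclasses.dataclass
class RunManifest:
    seed: int
    version: str
    stages: list
    outputs: dict          # path -> sha256
    started: float
    finished: float = 0.0
    failed_stage: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params_from_block(cls, block: dict, seed: int):
    kwargs = {k: v for k, v in block.items() if k != "stage"}
    kwargs.setdefault("seed", seed)
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(kwargs) - fields
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    for key in ("ligand_points", "biocap_intensity_range", "csp_amplitude_range"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key]) if "range" in key else np.asarray(kwargs[key])
    return cls(**kwargs)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages in order; write outputs and a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest = RunManifest(
        seed=config.seed, version=__version__, stages=[], outputs={},
        started=time.time(),
    )
    manifest_path = outdir / "manifest.json"
    try:
        for block in config.stages:
            name = block["stage"]
            seed = stage_seed(config.seed, name)
            t0 = time.time()
            log.info("stage %s (seed %d)", name, seed)
            outputs = _STAGE_RUNNERS[name](block, seed, outdir)
            for p in outputs:
                manifest.outputs[str(p.relative_to(outdir))] = _sha256(p)
            manifest.stages.append(
                {"stage": name, "seed": seed,
                 "duration_s": round(time.time() - t0, 3)}
            )
    except Exception:
        manifest.failed_stage = name
        manifest.finished = time.time()
        manifest.to_json(outdir / "manifest.failed.json")
        raise RuntimeError(f"pipeline stage {name!r} failed") from None
    manifest.finished = time.time()
    manifest.to_json(manifest_path)
    return manifest


# ---------------------------------------------------------------- stages

def _run_simulate_frap(block, seed, outdir):
    n_cells = int(block.get("n_cells", 1))
    block = {k: v for k, v in block.items() if k != "n_cells"}
    paths = []
    for i in range(n_cells):
        params = _params_from_block(FrapSimParams, block, seed + i)
        params.seed = seed + i
        trace = simulate_frap_trace(params)
        p = outdir / f"frap_trace_{i:03d}.tsv"
        cgio.write_frap_trace(trace, p)
        paths.append(p)
    return paths


def _run_simulate_titration(block, seed, outdir):
    params = _params_from_block(TitrationSimParams, block, seed)
    series = simulate_titration(params)
    p = outdir / "titration.tsv"
    cgio.write_titration(series, p)
    return [p]


def _write_genome(genome, outdir, tag=""):
    paths = []
    p = outdir / f"nmis{tag}.bed"
    cgio.write_bed(genome.nmis, p)
    paths.append(p)
    p = outdir / f"tss{tag}.bed"
    cgio.write_tss(genome.tss, p)
    paths.append(p)
    for name, track in genome.tracks.items():
        p = outdir / f"track_{name}{tag}.bedgraph"
        track.to_bedgraph(p)
        paths.append(p)
    p = outdir / f"read_summaries{tag}.tsv"
    cgio.write_read_summaries(genome.read_summaries, p)
    paths.append(p)
    return paths


def _run_simulate_genome(block, seed, outdir):
    params = _params_from_block(GenomeSimParams, block, seed)
    genome = simulate_genome(params)
    return _write_genome(genome, outdir)


def _run_frap_fit(block, seed, outdir):
    import pandas as pd

    bleach_index = int(block.get("bleach_index", 50))
    rows = []
    for path in sorted(outdir.glob("frap_trace_*.tsv")):
        trace = cgio.read_frap_trace(path, bleach_index=bleach_index)
        fit = fit_biexponential(normalize_trace(trace))
        rows.append(
            {"trace": path.name, "a1": fit.a1, "a2": fit.a2, "k1": fit.k1,
             "k2": fit.k2, "bleach_depth": fit.bleach_depth_fitted,
             "t_half": fit.t_half, "mobile_fraction": fit.mobile_fraction,
             "rss": fit.rss, "flags": ";".join(fit.flags)}
        )
    p = outdir / "frap_fits.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    return [p]


def _run_binding_fit(block, seed, outdir):
    series = cgio.read_titration_fluorescence(
        outdir / "titration.tsv", protein_total=float(block["protein_total"])
    )
    fit = fit_kd_fluorescence(series)
    p = outdir / "binding_fit.json"
    with open(p, "w") as fh:
        json.dump(
            {"kd_uM": fit.kd, "se_kd_uM": fit.standard_error_kd,
             "response_free": fit.response_free,
             "response_sat": fit.response_sat, "rss": fit.rss,
             "flags": fit.flags},
            fh, indent=2,
        )
    return [p]


def _multivalence_report(genome, seed, block):
    matrix = enrichment_matrix(genome.tracks, genome.nmis)
    matrix["h3k4me3_level"] = genome.nmis["h3k4me3"].to_numpy()
    res = multivalence_index(
        matrix, signal="ip", reference="biocap", k4="h3k4me3",
        n_bins=int(block.get("n_bins", 20)),
        n_permutations=int(block.get("n_permutations", 200)),
        rng=seed,
    )
    return {
        "index": res.index, "null_band": list(res.null_band),
        "is_multivalent": res.is_multivalent,
        "ratio_per_bin": res.ratio.tolist(),
    }


def _run_multivalence(block, seed, outdir):
    from .calibration import SignalTrack
    import pandas as pd

    tracks = {
        name: SignalTrack.from_bedgraph(outdir / f"track_{name}.bedgraph")
        for name in ("biocap", "h3k4me3", "ip")
    }
    nmis = cgio.read_bed(outdir / "nmis.bed")
    matrix = enrichment_matrix(tracks, nmis)
    res = multivalence_index(
        matrix, signal="ip", reference="biocap", k4="h3k4me3",
        n_bins=int(block.get("n_bins", 20)),
        n_permutations=int(block.get("n_permutations", 200)),
        rng=seed,
    )
    p = outdir / "multivalence.json"
    with open(p, "w") as fh:
        json.dump(
            {"index": res.index, "null_band": list(res.null_band),
             "is_multivalent": res.is_multivalent}, fh, indent=2,
        )
    return [p]


def _run_multivalence_demo(block, seed, outdir):
    """Simulate both occupancy models and contrast their indices."""
    base = {k: v for k, v in block.items()
            if k not in ("stage", "n_bins", "n_permutations")}
    mono = _params_from_block(
        GenomeSimParams,
        dict(base, occupancy_model="monovalent", multivalence_strength=0.0),
        seed,
    )
    multi = _params_from_block(
        GenomeSimParams,
        dict(base, occupancy_model="multivalent",
             multivalence_strength=float(block.get("multivalence_strength", 2.0))),
        seed + 1,
    )
    report = {}
    for tag, params in (("monovalent", mono), ("multivalent", multi)):
        genome = simulate_genome(params)
        report[tag] = _multivalence_report(genome, seed, block)
    p = outdir / "multivalence_demo.json"
    with open(p, "w") as fh:
        json.dump(report, fh, indent=2)
    return [p]


_STAGE_RUNNERS = {
    "simulate_frap": _run_simulate_frap,
    "simulate_titration": _run_simulate_titration,
    "simulate_genome": _run_simulate_genome,
    "frap_fit": _run_frap_fit,
    "binding_fit": _run_binding_fit,
    "multivalence": _run_multivalence,
    "multivalence_demo": _run_multivalence_demo,
}
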