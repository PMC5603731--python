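# cgireader

Quantitative analytics for studies of **multivalent CpG-island chromatin
readers** — proteins such as SET1-complex subunits that select their genomic
targets by simultaneously recognising non-methylated CpG DNA and histone
H3K4 trimethylation (H3K4me3). The package implements the four quantitative
workhorses such a study needs, plus synthetic-data generators so every stage
can be exercised and validated without imaging or sequencing data:

1. **FRAP kinetics** (`cgireader.frap`) — double normalization of
   bleach-spot/whole-cell traces (which also removes acquisition
   photobleaching), biexponential recovery fits
   `r(t) = b + a₁(1−e^(−k₁t)) + a₂(1−e^(−k₂t))`, half recovery times t½,
   and Student's-t cohort comparisons of per-cell t½.
2. **Binding affinity** (`cgireader.binding`) — Kd estimation from
   intrinsic-fluorescence and NMR chemical-shift-perturbation titrations
   under the exact 1:1 isotherm with ligand depletion,
   `f = [(P+L+K_d) − √((P+L+K_d)² − 4PL)] / 2P`,
   with a global shared-Kd fit across residues in CSP mode.
3. **Spike-in calibration** (`cgireader.calibration`) — per-million-spike-read
   factors (α = 10⁶/spike reads, optional input correction), calibrated
   bedGraph tracks, overlap-weighted interval quantification and log₂
   changes. Spike calibration detects genuine global signal changes that
   plain sequencing-depth normalization silently cancels.
4. **Interval analytics** (`cgireader.intervals`) — peak/NMI overlap census,
   TSS annotation, stranded metaprofiles, H3K4me3 percentile binning, and a
   **multivalence index**: the Spearman correlation between H3K4me3
   percentile bin and the per-bin ratio mean(reader)/mean(non-methylated
   DNA), tested against a stratified permutation null. A monovalent
   DNA-only reader scores ≈ 0; a multivalent reader scores ≈ 1 with an
   exact permutation p value ≤ 0.01. Threshold classifiers for
   differential expression (FDR ≤ 0.01, ≥ 1.5-fold) and expression level
   (lowly expressed below −2.5 log₂ FPKM) are included.

`cgireader.simulate` provides the generators (biexponential FRAP traces
with acquisition photobleaching, depletion isotherms under fluorescence or
CSP readout, and a toy genome whose reader occupancy follows either a
monovalent or a multivalent model with Poisson counts and spike-in reads);
`cgireader.pipeline` and the `cgireader` command line orchestrate
simulate → analyze → report runs with per-stage seeds and hashed manifests.

## Worked example

Simulate one genome under each occupancy model and contrast the
multivalence index:

```python
from cgireader.simulate import GenomeSimParams, simulate_genome
from cgireader.intervals import enrichment_matrix, multivalence_index

for model, strength in (("monovalent", 0.0), ("multivalent", 2.0)):
    genome = simulate_genome(GenomeSimParams(
        n_nmis=500, occupancy_model=model,
        multivalence_strength=strength, seed=1,
    ))
    matrix = enrichment_matrix(genome.tracks, genome.nmis)
    res = multivalence_index(matrix, signal="ip", rng=1)
    print(f"{model:12s} index {res.index:+.3f}  p {res.p_value:.3f}  "
          f"flagged {res.is_multivalent}")
```

```
monovalent   index +0.304  p 0.184  flagged False
multivalent  index +1.000  p 0.005  flagged True
```

The monovalent reader's occupancy per unit of non-methylated DNA is flat
across H3K4me3 percentiles (index indistinguishable from the permutation
null), while the multivalent reader's rises monotonically (index 1.0 at
the smallest attainable permutation p, 1/201).

Fit a Kd from a simulated fluorescence titration:

```python
import numpy as np
from cgireader.simulate import TitrationSimParams, simulate_titration
from cgireader.binding import fit_kd_fluorescence

series = simulate_titration(TitrationSimParams(
    protein_total=5.0, ligand_points=np.linspace(0, 52, 10),
    kd_true=1.3, noise_sd=0.02, seed=0,
))
fit = fit_kd_fluorescence(series)
print(f"Kd = {fit.kd:.2f} ± {fit.standard_error_kd:.2f} uM")
```

```
Kd = 1.34 ± 0.17 uM
```

The same operations are available from the shell, e.g.
`cgireader simulate genome --seed 1 --outdir demo/`,
`cgireader binding fit-fluor --table titr.tsv --protein-um 5 --out fit.json`,
or a whole YAML-configured run via `cgireader run --config run.yaml`.

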