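# Methods

This note records the models implemented in `cgireader`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical and design decisions a maintainer should know
about.

## FRAP kinetics

**Normalization.** A trace consists of a bleach-spot (ROI) channel, a
whole-cell channel, an optional background, and the index of the first
post-bleach frame. After background subtraction the ROI is divided frame by
frame by the whole-cell signal and the ratio rescaled by its pre-bleach
mean, so pre-bleach recovery is 1 by construction. Dividing by the
whole-cell channel *is* the acquisition-photobleaching correction: both
channels share the illumination decay, which cancels in the ratio. We
preferred this measurement-based correction over fitting an exponential to
the whole-cell channel because it needs no extra model and remains correct
when the acquisition decay is not a single exponential. Frames acquired
during the bleach pulse (between `prebleach_end` and `bleach_index`) are
excluded from both the pre-bleach reference and the fit; in the synthetic
traces the bleach is instantaneous and there are none.

**Biexponential fit.** Post-bleach recovery is fitted as
`r(t) = b + a₁(1−e^(−k₁t)) + a₂(1−e^(−k₂t))` by bounded least squares.
Biexponential fits are initialization-sensitive, so rates are multi-started
on the grid {10, 1, 0.1}/t_range (all ordered pairs), amplitudes seeded by
linear projection at fixed rates, the best residual sum of squares wins and
ties go to the smaller k₁/k₂ ratio (the less stiff solution). Components
are reported with k₁ ≥ k₂. A fitted plateau b + a₁ + a₂ exceeding 1 by more
than three residual standard deviations raises an `over_recovery` flag; a
mobile amplitude below 10⁻³ flags `immobile` and leaves t½ undefined.

**Half recovery time.** t½ solves
`a₁(1−e^(−k₁t)) + a₂(1−e^(−k₂t)) = (a₁+a₂)/2`, i.e. the half-point of the
*fitted mobile amplitude above the fitted bleach depth*. The reference
level matters: anchoring at the mobile amplitude makes t½ invariant to the
immobile fraction and to amplitude rescaling, the standard FRAP convention.
The left side is strictly increasing, so the root is unique and bracketed
in (0, ln2/min(k₁,k₂)]; it is found by Brent's method to 10⁻¹² relative
tolerance.

**Cohorts.** Fits are per cell; cohort statistics (two-sided Student's t
test, medians, interquartile ranges) operate on per-cell t½ values. An
error is raised only when *both* groups have zero variance (the t statistic
is then undefined); identical non-degenerate groups correctly give p = 1.

**Accuracy under the default acquisition** (8 frames/s, 50 + 1000 frames,
bleach to 0.3, 2% per-frame noise in both channels, 0.002/s acquisition
bleaching): per-cell t½ estimates are unbiased with ≈ 9% standard
deviation at the 2% noise ceiling; a 42-cell cohort median is therefore
reproducible to ~2%. The parameter-recovery test pools a grid of noise
levels ≤ 2% and checks a ≤ 5% median relative error across the grid.

## Binding affinity

**Model.** The bound fraction under 1:1 stoichiometry with ligand
depletion is the exact quadratic solution
`f = [(P+L+K_d) − √((P+L+K_d)² − 4PL)] / 2P`. Protein and peptide
concentrations in these titrations are comparable (micromolar protein,
micromolar-range Kd), so the hyperbolic Langmuir form is biased; it is
available as the analytic P → 0 limit. Two numerical details: the
discriminant is computed as `(P−L)² + K² + 2K(P+L)` (non-negative by
construction, no cancellation near stoichiometric saturation), and the
root is evaluated in the co-root form `2L/(P+L+K+√disc)`, which avoids the
catastrophic cancellation of the textbook form when P ≪ L + K.

**Fluorescence fit.** `R(L) = R_free + (R_sat − R_free)·f(P, L, K_d)` by
nonlinear least squares over (log₁₀Kd, R_free, R_sat), Kd bounded to
(10⁻⁶, 10⁴] μM, multi-started at Kd ∈ {0.1, 1, 10, 100} μM. Quench
titrations (R_sat < R_free) are permitted. The Kd standard error comes
from the fit covariance by the delta method. A fit is declared
*unidentifiable* (an error) when the fitted Kd sits at a bound or the
fitted amplitude is below three residual standard deviations; a standard
error exceeding the estimate raises a `weak_identifiability` warning — the
signature of a ligand range too narrow relative to Kd, where amplitude and
Kd trade off freely.

**CSP fit.** Combined shift changes `√(Δδ_H² + (Δδ_N/5)²)` (the
conventional ¹⁵N down-weighting; the weight is configurable) are fitted
globally across residues assuming fast exchange:
`Δδ_r(L) = Δδ_r,max · f(P, L, K_d)` with one shared Kd. For a trial Kd the
per-residue amplitudes are linear and profiled out analytically, reducing
the global fit to a one-dimensional search over log Kd (grid bracket +
bounded minimization) — exact, fast, and free of amplitude initialization
issues. A global fit uses all residues' information at once and is
standard practice for HSQC titrations; per-residue Kds followed by
averaging wastes the shared-Kd constraint. Residues whose largest CSP
never exceeds a noise floor (default 0.005 ppm) are excluded; a root-mean-
square residual above 1.5× the floor flags `model_misfit` (e.g. residues
that do not share one Kd).

**Validated operating range.** Simulated recovery with the default design
(fixed protein 5 μM, 10 ligand points spanning 0–40×Kd, 2% amplitude
noise) recovers median Kds within a few percent across 1.3–373 μM and
preserves the rank order of the four-state methylation ladder in every
replicate set (see `scripts/acceptance.py`).

## Spike-in calibration

Each sample's factor is α = 10⁶ / spike-genome reads ("per million
spike-in reads"). Samples receiving the same amount of spike material and
recovering it equally get equal factors regardless of target depth, which
is the property that makes a genuine global signal change visible:
depth normalization rescales every sample to the same total and cancels
any global shift, while spike scaling preserves it. An optional
input-corrected mode multiplies by the paired input's spike/target ratio,
cancelling compositional differences in input material. Factors are
reference-free (no designated reference sample); cross-condition
statements are made on ratios of calibrated values with a pseudocount
(default 1 calibrated unit). Nuclear-RNA calibration reuses the same
machinery on gene-level counts, with genomic-DNA "input" libraries in the
`gdna` role enabling input correction.

Tracks are fixed-width, 0-based, half-open bins (bedGraph semantics).
Interval quantification is the overlap-length-weighted mean over covered
bases; uncovered intervals report 0 with a coverage flag rather than NaN
so downstream log-ratio arithmetic stays finite. Quantification is
invariant to bin refinement that preserves values.

## Interval analytics and the multivalence index

Coordinates are BED dialect throughout (0-based, half-open, ≥ 1 bp
intersection = overlap). The overlap census uses a sorted sweep with a
running maximum of interval ends, so nested or overlapping intervals
within a set are handled; it is validated against a brute-force all-pairs
oracle. Overlap fractions of an empty set are reported as NaN (undefined),
never 0.

**Percentile binning.** Intervals are ranked by the key signal (ties in
stable input order) and assigned to equal-population bins differing by at
most one member. Rank-based binning makes "percentile" unambiguous and the
assignment invariant to monotone transforms of the key.

**Relative enrichment.** Per-bin mean signal normalized to that signal's
maximum bin mean, putting signals with different dynamic ranges on a
common [0, 1] axis with max = 1. Normalizing to the total or to a z-scale
were alternatives; the maximum-bin convention keeps the curve
interpretable as "fraction of peak enrichment".

**Multivalence index.** Per H3K4me3-percentile bin the ratio
r_b = mean(signal)/mean(reference DNA signal) is computed; the index is
the Spearman correlation of r_b with bin rank. Exact proportionality
(ratio spread below 10⁻⁹ relative) is defined as index 0, since a rank
correlation of a constant is otherwise undefined. Significance comes from
permuting the signal among intervals within reference-signal strata
(default 10 deciles), which preserves the signal/reference coupling while
destroying any H3K4me3 relation. The flag uses the exact two-sided
permutation p value `(1 + #{|null| ≥ |index|})/(n_perm + 1)` at α = 0.01;
an empirical percentile band of the null is reported for description only,
because extreme percentiles of a few hundred permutation draws are
unstable order statistics and not a valid test (measured false-flag rate
6% versus the nominal 1% before this was fixed). With 500 intervals,
20 bins and 200 permutations, a monovalent generator is flagged in ≈ 1%
of runs and a multivalent generator (strength ≥ 1) in ≈ 100%.

**Classifiers.** Differential expression: down/up require FDR ≤ 0.01
*and* |fold change| ≥ 1.5 (both gates inclusive at the boundary); rows
with missing values are flagged and excluded from counts. Expression:
lowly expressed strictly below −2.5 log₂ FPKM. Group tests are two-sided
Mann-Whitney (independent samples) and Wilcoxon signed-rank (paired;
all-zero differences are an error), both with average-rank ties.

## Synthetic-data generators

The generators produce the statistical structure the analyses assume — no
more. What they deliberately do not emulate bounds what passing tests
prove about real data.

**FRAP traces.** Pre-bleach ROI fluctuates around 1; at the bleach frame
it drops to `bleach_depth` and recovers biexponentially; both channels are
multiplied by a shared exponential acquisition decay and carry additive
homoscedastic Gaussian noise (default 2% of the pre-bleach mean, both
channels). Defaults mirror a spinning-disk acquisition of a fast nuclear
protein: 8 frames/s, 50 pre-bleach + 1000 post-bleach frames, bleach to
0.3, 0.002/s acquisition bleaching. `frap_params_for_half_time` solves the
generator rates (amplitudes 0.5 fast + 0.3 slow, rate ratio 10) so the
analytic half-time equals a requested value, exploiting the 1/k scaling of
the half-point at fixed amplitude structure. Not emulated: camera physics
(shot-noise heteroscedasticity), diffusion-reaction recovery shapes,
bleach-spot geometry, drift. Conclusions about normalization and fitting
transfer to real traces; conclusions about the biexponential being the
*correct* physical model do not.

**Titrations.** Noiseless responses follow the quadratic depletion
isotherm exactly; CSP mode emits per-residue rows sharing one Kd with
amplitudes drawn once from 0.02–0.12 ppm. Gaussian noise per point.
Not emulated: baseline drift, pipetting error correlated across points,
intermediate exchange.

**Toy genome.** One chromosome (default 10 Mb, 200 bp bins) with
non-overlapping, bin-aligned NMIs (default 500) and background regions.
Each NMI gets a Bio-CAP intensity uniform on (1, 10) and an H3K4me3 level
assigned by a random transcription rank — independent of Bio-CAP, so DNA
signal and H3K4me3 are decoupled and the multivalence contrast is
attributable. Expected reader occupancy is `c·biocap` (monovalent) or
`c·biocap·(1 + strength·pct/100)` (multivalent, pct the H3K4me3 percentile
midpoint). Per-bin read counts are Poisson with these means scaled to the
configured library size (default 10⁶ target reads), background bins at 2%
of the mean NMI level; spike-genome reads are Poisson totals only (default
5×10⁴), since calibration needs only totals. `global_signal_scale`
rescales all IP means while leaving the spike expectation fixed — the
scenario of a genuine global signal loss with constant spike recovery
used to validate calibration. Poisson was chosen as the simplest count
model adequate for testing normalization linearity; real ChIP-seq
overdispersion, mappability structure, fragment-length effects and
peak-shape are not emulated. One TSS is placed at each NMI midpoint with
random strand.

All generators are deterministic under a fixed seed (byte-identical
outputs) and validated empirically: replicate means converge to the
noiseless expectations (law of large numbers at 1000 replicates).

## Pipeline and reproducibility

A YAML config declares stages and a global seed; unknown keys are
rejected. Each stage's seed derives from `SeedSequence((global_seed,
stage_id))` with fixed per-stage ids, so adding a stage never shifts the
streams of existing ones. Runs write a manifest with SHA-256 hashes of
every output; identical config + seed reproduces identical hashes. The
reference studies in `scripts/acceptance.py` use sizes chosen as typical
desk-scale designs: 500 titration replicates per affinity and a 42-cell
FRAP cohort; the test suite runs scaled-down versions of the heavier
property checks (e.g. 20 repeats of the two-cohort discrimination study at
10 cells per cohort) and full-scale versions of the acceptance studies.

## Known limitations

* FRAP analysis is purely phenomenological; it cannot distinguish
  reaction-dominant from diffusion-dominant recovery, and t½ comparisons
  across proteins with different bleach geometries are not meaningful.
* The binding fits assume a single class of non-cooperative sites; 2:1 or
  cooperative binding will surface only as `model_misfit`/residual flags.
* The spike factor presumes equal spike material per sample and equal
  recovery efficiency; violations bias all calibrated comparisons and are
  not detectable from read totals alone (the > 50% spike-fraction warning
  catches only gross imbalance).
* The multivalence index is a rank statistic: it detects monotone
  divergence from proportionality but does not estimate its functional
  form or magnitude.
* NMI calling from continuous signal (`call_nmis`) is a
  threshold-and-merge convenience for synthetic tracks; real NMI/CGI sets
  should come from dedicated callers as BED.
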