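"""Dissociation-constant estimation from titration experiments.

Implements the single-site 1:1 binding model with ligand depletion (the
"quadratic" isotherm) and fits it to two readouts used to characterise
histone-tail recognition by reader domains:

* intrinsic tryptophan fluorescence quench titrations, where one global
  response per ligand point is recorded, and
* NMR chemical-shift-perturbation (CSP) titrations in the fast-exchange
  regime, where every assigned residue reports the same fractional
  saturation scaled by its own maximal shift change.

Because protein and peptide concentrations in such experiments are
comparable (low micromolar protein against micromolar-range Kd), free and
total ligand cannot be identified, so the hyperbolic Langmuir form is a
biased approximation; the depletion-corrected quadratic form is exact for
1:1 stoichiometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "UnidentifiableFitError",
    "fraction_bound",
    "combined_csp",
    "fit_kd_fluorescence",
    "fit_kd_nmr",
]

KD_LOWER = 1e-6  # μM, numerical floor
KD_UPPER = 1e4   # μM, identifiability ceiling


class UnidentifiableFitError(RuntimeError):
    """The titration carries no usable information about Kd."""


def fraction_bound(protein_total, ligand_total, kd):
    """Fraction of protein bound at equilibrium for 1:1 binding with depletion.

    Solves ``P·f² − (P + L + Kd)·f + L = 0`` for the physical root

        f = [(P + L + Kd) − sqrt((P + L + Kd)² − 4·P·L)] / (2·P)

    Parameters
    ----------
    protein_total : float
        Total protein concentration (μM), > 0.  ``P → 0`` degenerates to the
        hyperbolic limit ``L / (L + Kd)``.
    ligand_total : float or array_like
        Total ligand concentration(s) (μM), ≥ 0.
    kd : float
        Dissociation constant (μM), > 0.

    Returns
    -------
    float or ndarray
        Bound fraction in [0, 1]; monotone non-decreasing in ``ligand_total``
        and non-increasing in ``kd``.
    """
    P = float(protein_total)
    K = float(kd)
    L = np.asarray(ligand_total, dtype=float)
    if K <= 0:
        raise ValueError("kd must be > 0")
    if P < 0 or np.any(L < 0):
        raise ValueError("concentrations must be non-negative")
    if P == 0.0:
        f = L / (L + K)
    else:
        s = P + L + K
        # (P+L+K)^2 - 4PL rewritten as a sum of non-negative terms: exact
        # non-negativity, no cancellation near stoichiometric saturation.
        disc = (P - L) ** 2 + K * K + 2.0 * K * (P + L)
        # co-root form 2L/(s + sqrt(disc)) avoids the catastrophic
        # cancellation of (s - sqrt(disc))/(2P) when P << L + K
        f = 2.0 * L / (s + np.sqrt(disc))
    f = np.clip(f, 0.0, 1.0)
    return float(f) if np.ndim(ligand_total) == 0 else f


def combined_csp(delta_h, delta_n, nitrogen_weight: float = 5.0):
    """Combine ¹H and ¹⁵N shift changes into a single CSP magnitude (ppm).

    Uses the conventional Euclidean combination with the ¹⁵N axis
    down-weighted by ``nitrogen_weight`` (default 5) to account for the
    wider ¹⁵N chemical-shift dispersion:

        Δδ = sqrt(Δδ_H² + (Δδ_N / w)²)
    """
    if nitrogen_weight <= 0:
        raise ValueError("nitrogen_weight must be > 0")
    dh = np.asarray(delta_h, dtype=float)
    dn = np.asarray(delta_n, dtype=float)
    if not (np.all(np.isfinite(dh)) and np.all(np.isfinite(dn))):
        raise ValueError("non-finite chemical shift change")
    out = np.sqrt(dh ** 2 + (dn / nitrogen_weight) ** 2)
    return float(out) if out.ndim == 0 else out


@dataclass
class TitrationSeries:
    """One titration at fixed protein concentration.

    ``response`` is 1-D (one value per ligand point) in fluorescence mode
    and 2-D ``(n_residues, n_points)`` of combined CSP magnitudes in
    ``nmr_csp`` mode.
    """

    protein_total: float          # μM
    ligand_totals: np.ndarray     # μM, strictly increasing
    response: np.ndarray
    mode: str = "fluorescence"    # {"fluorescence", "nmr_csp"}
    residues: list | None = None  # CSP mode labels, optional

    def __post_init__(self):
        self.ligand_totals = np.asarray(self.ligand_totals, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.mode not in ("fluorescence", "nmr_csp"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.ligand_totals.size == 0:
            raise ValueError("empty ligand_totals")
        if np.any(np.diff(self.ligand_totals) <= 0):
            raise ValueError("ligand_totals must be strictly increasing")
        if np.any(self.ligand_totals < 0):
            raise ValueError("ligand_totals must be non-negative")
        if self.protein_total <= 0:
            raise ValueError("protein_total must be > 0")
        expected = (self.ligand_totals.size,)
        if self.mode == "nmr_csp":
            if self.response.ndim == 1:
                self.response = self.response[None, :]
            if self.response.shape[1:] != expected:
                raise ValueError("response/ligand length mismatch")
        elif self.response.shape != expected:
            raise ValueError("response/ligand length mismatch")

    @property
    def n_points(self) -> int:
        return self.ligand_totals.size


@dataclass
class BindingFit:
    """Result of a Kd fit."""

    kd: float                     # μM
    response_free: float
    response_sat: np.ndarray | float  # per residue in CSP mode
    standard_error_kd: float      # μM
    rss: float
    n_points: int
    flags: list[str] = field(default_factory=list)
    residues: list | None = None


def _check_min_points(series: TitrationSeries, n_params: int) -> None:
    if series.n_points < 5:
        raise ValueError("need at least 5 titration points to fit")
    if series.n_points <= n_params:
        raise ValueError("more parameters than titration points")


def fit_kd_fluorescence(
    series: TitrationSeries, model: str = "depletion"
) -> BindingFit:
    """Fit (Kd, R_free, R_sat) to a fluorescence titration.

    Nonlinear least squares of

        R(L) = R_free + (R_sat − R_free) · f_bound(P, L, Kd)

    with Kd log-parameterised and bounded to (0, 10⁴ μM]; multi-start at
    Kd ∈ {0.1, 1, 10, 100} μM, best residual sum of squares wins.  A signal
    decrease on binding (quench, R_sat < R_free) is permitted.

    ``model`` selects the bound-fraction form: ``"depletion"`` (default,
    the exact quadratic) or ``"hyperbolic"`` (L/(L+Kd), valid only when
    protein is far below Kd).

    Raises
    ------
    UnidentifiableFitError
        If the fitted Kd sits at a bound or the fitted amplitude is below
        three times the residual noise level.
    """
    if series.mode != "fluorescence":
        raise ValueError("series.mode must be 'fluorescence'")
    if model not in ("depletion", "hyperbolic"):
        raise ValueError(f"unknown model {model!r}")
    _check_min_points(series, 3)
    L = series.ligand_totals
    y = series.response
    P = series.protein_total if model == "depletion" else 0.0
    scale = max(np.ptp(y), abs(np.mean(y)), 1e-12)

    def resid(theta):
        logkd, rf, rs = theta
        f = fraction_bound(P, L, 10.0 ** logkd)
        return rf + (rs - rf) * f - y

    lo = [np.log10(KD_LOWER), -np.inf, -np.inf]
    hi = [np.log10(KD_UPPER), np.inf, np.inf]
    best = None
    for kd0 in (0.1, 1.0, 10.0, 100.0):
        x0 = [np.log10(kd0), y[0], y[-1]]
        try:
            sol = optimize.least_squares(
                resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fit starts failed")

    logkd, rf, rs = best.x
    kd = 10.0 ** logkd
    rss = float(2.0 * best.cost)
    dof = max(series.n_points - 3, 1)
    noise = np.sqrt(rss / dof)

    amplitude = abs(rs - rf)
    if amplitude < max(3.0 * noise, 1e-9 * scale):
        raise UnidentifiableFitError(
            f"fitted amplitude {amplitude:.3g} below noise level {noise:.3g}"
        )
    if kd >= 0.99 * KD_UPPER or kd <= 1.01 * KD_LOWER:
        raise UnidentifiableFitError(f"fitted Kd {kd:.3g} μM at parameter bound")

    se_kd, flags = _kd_standard_error(best, noise, kd)
    return BindingFit(
        kd=float(kd), response_free=float(rf), response_sat=float(rs),
        standard_error_kd=se_kd, rss=rss, n_points=series.n_points, flags=flags,
    )


def _kd_standard_error(sol, noise: float, kd: float) -> tuple[float, list[str]]:
    """Delta-method SE of Kd from the log10-Kd fit covariance."""
    flags: list[str] = []
    J = sol.jac
    try:
        cov = np.linalg.inv(J.T @ J) * noise ** 2
        se_log = np.sqrt(max(cov[0, 0], 0.0))
        se_kd = float(se_log * np.log(10.0) * kd)
    except np.linalg.LinAlgError:
        se_kd = float("inf")
    if not np.isfinite(se_kd) or se_kd > kd:
        flags.append("weak_identifiability")
        warnings.warn(
            "Kd poorly identified: standard error exceeds the estimate "
            "(ligand range likely too narrow relative to Kd)",
            stacklevel=3,
        )
    return se_kd, flags


def fit_kd_nmr(series: TitrationSeries, noise_floor: float = 0.005) -> BindingFit:
    """Global CSP fit: one shared Kd, per-residue saturation amplitudes.

    Assumes fast exchange, so each residue's combined CSP tracks the bound
    fraction:  Δδ_r(L) = Δδ_r,max · f_bound(P, L, Kd).  For a trial Kd the
    amplitudes are linear and profiled out analytically; the residual sum of
    squares is then minimised over log Kd alone (grid bracket + golden
    search), which makes the global fit exact and fast.

    Residues whose largest CSP never exceeds ``noise_floor`` (ppm) carry no
    binding information and are excluded; if none remain an error is raised.
    """
    if series.mode != "nmr_csp":
        raise ValueError("series.mode must be 'nmr_csp'")
    _check_min_points(series, 2)
    Y = series.response                      # (n_res, n_points)
    keep = np.max(np.abs(Y), axis=1) >= noise_floor
    labels = series.residues
    if not np.any(keep):
        raise UnidentifiableFitError(
            f"no residue with CSP above the noise floor ({noise_floor} ppm)"
        )
    Y = Y[keep]
    if labels is not None:
        labels = [r for r, k in zip(labels, keep) if k]
    L = series.ligand_totals
    P = series.protein_total

    def rss_of(logkd: float) -> tuple[float, np.ndarray]:
        f = fraction_bound(P, L, 10.0 ** logkd)
        ff = float(f @ f)
        if ff <= 0:
            return float(np.sum(Y ** 2)), np.zeros(Y.shape[0])
        amps = (Y @ f) / ff
        r = Y - amps[:, None] * f[None, :]
        return float(np.sum(r * r)), amps

    grid = np.linspace(np.log10(KD_LOWER), np.log10(KD_UPPER), 81)
    costs = np.array([rss_of(g)[0] for g in grid])
    i = int(np.argmin(costs))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda g: rss_of(g)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    logkd = float(res.x)
    rss, amps = rss_of(logkd)
    kd = 10.0 ** logkd

    n_obs = Y.size
    n_par = 1 + Y.shape[0]
    dof = max(n_obs - n_par, 1)
    noise = np.sqrt(rss / dof)

    flags: list[str] = []
    if np.sqrt(rss / n_obs) > 1.5 * noise_floor:
        flags.append("model_misfit")
    if kd >= 0.99 * KD_UPPER or kd <= 1.01 * KD_LOWER:
        raise UnidentifiableFitError(f"fitted Kd {kd:.3g} μM at parameter bound")

    # profile-likelihood curvature in log10 Kd -> delta-method SE on Kd
    h = 1e-4
    d2 = (rss_of(logkd + h)[0] - 2 * rss + rss_of(logkd - h)[0]) / h ** 2
    if d2 > 0:
        se_log = noise * np.sqrt(2.0 / d2)
        se_kd = float(se_log * np.log(10.0) * kd)
    else:
        se_kd = float("inf")
    if not np.isfinite(se_kd) or se_kd > kd:
        flags.append("weak_identifiability")

    return BindingFit(
        kd=float(kd), response_free=0.0, response_sat=amps,
        standard_error_kd=se_kd, rss=rss, n_points=series.n_points,
        flags=flags, residues=labels,
    )
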