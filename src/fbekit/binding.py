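"""Quantitative binding models: ITC one-set-of-sites, EMSA, FRET, thermodynamics.

The ITC forward model is the one-set-of-sites (Wiseman) isotherm for a
titrant X injected into a cell containing macromolecule M with N
equivalent independent sites per molecule.  With association constant
K = 1/Kd and total concentrations Mt (cell) and Xt (titrant) after
dilution, the cumulative heat after reaching (Mt, Xt) is

    Q = (N Mt dH V0 / 2) [ A - sqrt(A^2 - 4 Xt/(N Mt)) ],
    A = 1 + Xt/(N Mt) + 1/(N K Mt),

and the heat of injection i is the difference of successive Q with the
half-displaced-volume correction

    dQ_i = Q_i - Q_{i-1} + (dV_i/V0) (Q_i + Q_{i-1}) / 2.

Dilution follows the perfusion-cell convention: with v = cumulative
injected volume / V0,  Mt = M0 (1 - v/2)/(1 + v/2)  and
Xt = X0 v/(1 + v/2), shared by generator and fitter.  Vendor software
uses closely related but not always identical conventions; comparisons
at the third significant figure should keep this dialect in mind.

EMSA binding curves use the one-site specific binding model
f(x) = Bmax x / (Kd + x) with the trace-RNA approximation (free protein
= total protein; RNA is 5 nM against micromolar protein); an exact
ligand-depletion solver is available as an option.  FRET efficiency is
the acceptor intensity fraction I_668/(I_668 + I_564).

Units: molar and liters internally; heats in microjoules; energies
kJ/mol; default temperature 293.15 K (20 degC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

GAS_CONSTANT = 8.314  # J/(mol K)


@dataclass(frozen=True)
class BindingParams:
    """One-set-of-sites parameters: stoichiometry N, Kd (molar), dH (kJ/mol)."""

    n_sites: float
    kd: float
    delta_h: float

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("n_sites must be > 0")
        if self.kd <= 0:
            raise ValueError("kd must be > 0")


@dataclass(frozen=True)
class ThermoConditions:
    temperature: float = 293.15  # kelvin

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")


@dataclass(frozen=True)
class TitrationSeries:
    """An ITC injection schedule with per-injection heats.

    ``heats`` are integrated per-injection heats in microjoules (the
    raw-instrument dialect); ``heats_per_mole`` flags the alternative
    kJ/mol-of-injectant dialect.  Volumes in liters, concentrations molar.
    """

    cell_volume: float
    cell_conc0: float
    syringe_conc: float
    injection_volumes: tuple[float, ...]
    heats: Optional[tuple[float, ...]] = None
    heats_per_mole: bool = False

    def __post_init__(self) -> None:
        if self.cell_volume <= 0:
            raise ValueError("cell_volume must be > 0")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be > 0")
        if self.heats is not None and len(self.heats) != len(self.injection_volumes):
            raise ValueError("heats and injection_volumes must have equal length")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


def standard_schedule(
    n_injections: int = 19,
    injection_volume: float = 2e-6,
    cell_volume: float = 200e-6,
    cell_conc0: float = 20e-6,
    syringe_conc: float = 300e-6,
) -> TitrationSeries:
    """The routine titration layout: 2-ul injections from a 40-ul syringe
    into a 200-ul cell (defaults: 19 x 2 ul of 300 uM titrant into 20 uM
    cell material)."""
    return TitrationSeries(
        cell_volume,
        cell_conc0,
        syringe_conc,
        (injection_volume,) * n_injections,
    )


@dataclass
class FitResult:
    """Nonlinear least-squares fit outcome.

    ``params`` maps parameter name to (estimate, standard error); the
    standard errors come from the least-squares covariance and are
    labeled as such.  Parameters are meaningful only when ``converged``.
    """

    params: dict[str, tuple[float, float]] = field(default_factory=dict)
    residual_norm: float = math.nan
    converged: bool = False
    message: str = ""
    kd_above_range: bool = False

    def value(self, name: str) -> float:
        if not self.converged:
            raise ValueError(f"fit did not converge: {self.message}")
        return self.params[name][0]

    def stderr(self, name: str) -> float:
        if not self.converged:
            raise ValueError(f"fit did not converge: {self.message}")
        return self.params[name][1]


def _diluted_totals(
    series: TitrationSeries,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-injection (Mt, Xt, dV) after perfusion dilution."""
    d_v = np.asarray(series.injection_volumes, dtype=float)
    v = np.cumsum(d_v) / series.cell_volume
    mt = series.cell_conc0 * (1 - v / 2) / (1 + v / 2)
    xt = series.syringe_conc * v / (1 + v / 2)
    return mt, xt, d_v


def _cumulative_q(params: BindingParams, mt: np.ndarray, xt: np.ndarray,
                  cell_volume: float) -> np.ndarray:
    """Cumulative heat (joules) at each post-injection composition."""
    n, kd = params.n_sites, params.kd
    dh = params.delta_h * 1e3  # kJ/mol -> J/mol
    xr = xt / (n * mt)
    a = 1.0 + xr + kd / (n * mt)
    disc = a * a - 4.0 * xr
    if np.any(disc < 0):
        raise ValueError("negative discriminant in binding isotherm")
    return (n * mt * dh * cell_volume / 2.0) * (a - np.sqrt(disc))


def one_site_heats(
    params: BindingParams,
    series: TitrationSeries,
    conditions: ThermoConditions | None = None,
) -> np.ndarray:
    """Predicted per-injection heats (microjoules) for a titration.

    ``conditions`` is accepted for interface symmetry; the isotherm
    itself is parameterized by Kd at the experiment's temperature.
    """
    mt, xt, d_v = _diluted_totals(series)
    q = _cumulative_q(params, mt, xt, series.cell_volume)
    q_prev = np.concatenate(([0.0], q[:-1]))
    dq = q - q_prev + (d_v / series.cell_volume) * (q + q_prev) / 2.0
    return dq * 1e6  # J -> uJ


def bound_titrant(params: BindingParams, series: TitrationSeries) -> np.ndarray:
    """Equilibrium bound-titrant concentration after each injection (molar)."""
    mt, xt, _ = _diluted_totals(series)
    sites = params.n_sites * mt
    s = sites + xt + params.kd
    return (s - np.sqrt(s * s - 4.0 * sites * xt)) / 2.0


def fit_itc(
    series: TitrationSeries,
    conditions: ThermoConditions | None = None,
    init: BindingParams | None = None,
    *,
    discard_first: bool = True,
) -> FitResult:
    """Least-squares fit of (N, Kd, dH) to a titration's heats.

    The first injection is discarded by default (syringe-tip diffusion
    during equilibration); default initialization is N = 1, dH from the
    first retained injection scaled to per-mole-of-injectant, and Kd at
    half the cell concentration.
    """
    if series.heats is None:
        raise ValueError("series has no measured heats to fit")
    heats = np.asarray(series.heats, dtype=float)
    if series.heats_per_mole:
        # convert kJ/mol-of-injectant -> uJ
        d_v = np.asarray(series.injection_volumes)
        heats = heats * 1e3 * series.syringe_conc * d_v * 1e6
    keep = np.arange(1 if discard_first else 0, series.n_injections)
    if keep.size < 6:
        raise ValueError("need >= 6 usable injections")
    y = heats[keep]

    if np.allclose(y, 0.0):
        return FitResult(converged=False, message="all-zero heats: degenerate")

    if init is None:
        moles_first = series.syringe_conc * series.injection_volumes[keep[0]]
        dh0 = (y[0] * 1e-6) / moles_first / 1e3  # uJ -> kJ/mol injectant
        init = BindingParams(1.0, series.cell_conc0 / 2.0, dh0 if dh0 != 0 else -1.0)

    def model(_x: np.ndarray, n: float, log10_kd: float, dh: float) -> np.ndarray:
        p = BindingParams(n, 10.0 ** log10_kd, dh)
        return one_site_heats(p, series)[keep]

    p0 = (init.n_sites, math.log10(init.kd), init.delta_h)
    try:
        popt, pcov = curve_fit(
            model,
            np.zeros_like(y),
            y,
            p0=p0,
            bounds=([1e-3, -12.0, -1e5], [1e3, 0.0, 1e5]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return FitResult(converged=False, message=str(exc))

    perr = np.sqrt(np.abs(np.diag(pcov)))
    n_hat, log_kd_hat, dh_hat = popt
    kd_hat = 10.0 ** log_kd_hat
    # delta-method stderr for kd from log10(kd)
    kd_err = kd_hat * math.log(10) * perr[1]
    resid = model(np.zeros_like(y), *popt) - y
    return FitResult(
        params={
            "n_sites": (float(n_hat), float(perr[0])),
            "kd": (float(kd_hat), float(kd_err)),
            "delta_h": (float(dh_hat), float(perr[2])),
        },
        residual_norm=float(np.linalg.norm(resid)),
        converged=True,
    )


def delta_g(kd: float, conditions: ThermoConditions | None = None) -> float:
    """Binding free energy dG = R T ln(Kd) in kJ/mol (Kd molar)."""
    if kd <= 0:
        raise ValueError("kd must be > 0")
    t = (conditions or ThermoConditions()).temperature
    return GAS_CONSTANT * t * math.log(kd) / 1e3


def minus_t_delta_s(delta_g_kj: float, delta_h_kj: float) -> float:
    """Entropic term -T dS = dG - dH (kJ/mol)."""
    return delta_g_kj - delta_h_kj


def fraction_bound(intensity_bound: float, intensity_unbound: float) -> float:
    """Fraction of RNA bound from gel band intensities."""
    if intensity_bound < 0 or intensity_unbound < 0:
        raise ValueError("intensities must be nonnegative")
    total = intensity_bound + intensity_unbound
    if total == 0:
        raise ValueError("both band intensities are zero")
    return intensity_bound / total


def one_site_specific(bmax: float, kd: float, x) -> "float | np.ndarray":
    """One-site specific binding: Bmax x / (Kd + x), free ligand = total."""
    if kd <= 0:
        raise ValueError("kd must be > 0")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentrations must be >= 0")
    out = bmax * x / (kd + x)
    return float(out) if out.ndim == 0 else out


def one_site_exact(bmax: float, kd: float, protein_total, rna_total: float):
    """Ligand-depletion form: bound fraction from the binding quadratic.

    Solves [PR] from P_t, R_t and Kd exactly instead of assuming free
    protein = total protein; relevant only when protein and RNA
    concentrations are comparable.
    """
    p = np.asarray(protein_total, dtype=float)
    s = p + rna_total + kd
    bound = (s - np.sqrt(s * s - 4.0 * p * rna_total)) / 2.0
    out = bmax * bound / rna_total
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EMSACurve:
    """Protein titration vs fraction of trace RNA bound (concs molar)."""

    protein_concs: tuple[float, ...]
    fraction_bound: tuple[float, ...]
    rna_conc: float = 5e-9

    def __post_init__(self) -> None:
        if len(self.protein_concs) != len(self.fraction_bound):
            raise ValueError("protein_concs and fraction_bound lengths differ")
        arr = np.asarray(self.protein_concs)
        if np.any(arr < 0):
            raise ValueError("concentrations must be nonnegative")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("protein_concs must be strictly increasing")
        fb = np.asarray(self.fraction_bound)
        if np.any((fb < 0) | (fb > 1)):
            raise ValueError("fractions bound must lie in [0, 1]")


def fit_emsa(curve: EMSACurve, *, exact_depletion: bool = False) -> FitResult:
    """Fit (Bmax, Kd) to an EMSA binding curve by least squares.

    A fitted Kd above the highest tested protein concentration is
    reported with ``kd_above_range`` set, mirroring the '>' convention
    for affinities beyond the titration range.
    """
    x = np.asarray(curve.protein_concs, dtype=float)
    y = np.asarray(curve.fraction_bound, dtype=float)
    if x.size < 4:
        raise ValueError("need >= 4 concentration points")
    if np.allclose(y, 0.0):
        return FitResult(converged=False, message="flat zero curve")

    half = y.max() / 2.0
    kd0 = float(x[np.argmin(np.abs(y - half))]) or float(np.median(x[x > 0]))

    if exact_depletion:
        def model(xx, bmax, log10_kd):
            return one_site_exact(bmax, 10.0 ** log10_kd, xx, curve.rna_conc)
    else:
        def model(xx, bmax, log10_kd):
            return one_site_specific(bmax, 10.0 ** log10_kd, xx)

    try:
        popt, pcov = curve_fit(
            model, x, y,
            p0=(float(y.max()), math.log10(kd0)),
            bounds=([0.0, -12.0], [2.0, 0.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return FitResult(converged=False, message=str(exc))

    perr = np.sqrt(np.abs(np.diag(pcov)))
    bmax_hat, log_kd_hat = popt
    kd_hat = 10.0 ** log_kd_hat
    kd_err = kd_hat * math.log(10) * perr[1]
    resid = model(x, *popt) - y
    return FitResult(
        params={
            "bmax": (float(bmax_hat), float(perr[0])),
            "kd": (float(kd_hat), float(kd_err)),
        },
        residual_norm=float(np.linalg.norm(resid)),
        converged=True,
        kd_above_range=bool(kd_hat > x.max()),
    )


def replicate_summary(kds: Sequence[float]) -> tuple[float, float]:
    """Mean Kd and SEM over technical replicates.

    SEM = sample standard deviation / sqrt(n); with a single replicate
    the SEM is reported as nan.
    """
    arr = np.asarray(kds, dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate Kd values")
    if arr.size == 1:
        return float(arr[0]), math.nan
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))


def fret_efficiency(i_564: float, i_668: float) -> float:
    """Relative FRET efficiency I_668 / (I_668 + I_564).

    I_564 is the donor (Cy3) emission peak, I_668 the acceptor (Cy5).
    """
    if i_564 < 0 or i_668 < 0:
        raise ValueError("intensities must be nonnegative")
    total = i_564 + i_668
    if total == 0:
        raise ValueError("both intensities are zero")
    return i_668 / total


def fold_change(kd_reference: float, kd_test: float) -> float:
    """Affinity fold change: reference Kd / test Kd (> 1 means tighter)."""
    if kd_reference <= 0 or kd_test <= 0:
        raise ValueError("Kd values must be > 0")
    return kd_reference / kd_test
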