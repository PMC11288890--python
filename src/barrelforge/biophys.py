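"""Circular-dichroism normalisation and quadratic ligand-binding fits.

Mean residue ellipticity converts raw CD signal (mdeg) to a per-amide-bond
quantity:

    MRE = theta * 10^6 / (c * l * n)      [deg cm^2 dmol^-1 res^-1]

with c the compound concentration in uM, l the path length in mm and n the
number of amide bonds.

Dye-binding titrations (constant ligand at concentration c, protein varied
over x) follow the single-site quadratic tight-binding isotherm

    y = Bmax * [(c + x + Kd) - sqrt((c + x + Kd)^2 - 4 c x)] / (2 c),

the root of the exact mass-action quadratic that stays bounded by Bmax and
saturates as x -> inf (the '+' root is unphysical).  Kd and Bmax are fitted
by bounded nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CDSpectrum",
    "ThermalRamp",
    "BindingTitration",
    "BindingFit",
    "mre",
    "spectrum_mre",
    "binding_isotherm",
    "fit_binding",
    "simulate_binding",
    "read_titration_csv",
    "read_cd_csv",
    "plot_spectrum",
    "plot_thermal_response",
]


class BiophysError(ValueError):
    pass


class FitError(RuntimeError):
    pass


@dataclass
class CDSpectrum:
    """Far-UV CD spectrum with the metadata needed for MRE conversion."""

    wavelengths_nm: np.ndarray
    theta_mdeg: np.ndarray
    conc_uM: float
    path_mm: float
    n_amide: int

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, float)
        self.theta_mdeg = np.asarray(self.theta_mdeg, float)
        if self.conc_uM <= 0 or self.path_mm <= 0 or self.n_amide <= 0:
            raise BiophysError("concentration, path length and amide count must be > 0")
        d = np.diff(self.wavelengths_nm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise BiophysError("wavelengths must be strictly ordered")
        if self.wavelengths_nm.shape != self.theta_mdeg.shape:
            raise BiophysError("wavelength and signal arrays must match")


@dataclass
class ThermalRamp:
    """CD signal at one wavelength (typically 222 nm) over a temperature ramp.

    Stored and plotted only: hyperstable helical designs show no cooperative
    transition over 5-95 C, so no melting model is fitted.
    """

    temperature_C: np.ndarray
    theta_mdeg: np.ndarray
    wavelength_nm: float = 222.0


@dataclass
class BindingTitration:
    """Constant ligand (c), varied binder (x), fluorescence readout (y)."""

    x_uM: np.ndarray
    y: np.ndarray
    c_uM: float

    def __post_init__(self) -> None:
        self.x_uM = np.asarray(self.x_uM, float)
        self.y = np.asarray(self.y, float)
        if self.c_uM <= 0:
            raise BiophysError("constant-component concentration must be > 0")
        if np.any(self.x_uM < 0):
            raise BiophysError("concentrations must be nonnegative")
        if self.x_uM.shape != self.y.shape:
            raise BiophysError("x and y must have equal length")


@dataclass
class BindingFit:
    kd_uM: float
    bmax: float
    kd_se: float
    bmax_se: float
    residuals: np.ndarray
    covariance: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# MRE
# ---------------------------------------------------------------------------

def mre(theta_mdeg, conc_uM: float, path_mm: float, n_amide: int):
    """Mean residue ellipticity: theta x 10^6 / (c * l * n)."""
    if conc_uM <= 0 or path_mm <= 0 or n_amide <= 0:
        raise BiophysError("c, l and n must all be positive")
    return np.asarray(theta_mdeg, float) * 1.0e6 / (conc_uM * path_mm * n_amide)


def spectrum_mre(spec: CDSpectrum) -> np.ndarray:
    return mre(spec.theta_mdeg, spec.conc_uM, spec.path_mm, spec.n_amide)


# ---------------------------------------------------------------------------
# Binding
# ---------------------------------------------------------------------------

def binding_isotherm(x, c: float, kd: float, bmax: float):
    """Quadratic tight-binding isotherm (bounded '-' root)."""
    x = np.asarray(x, float)
    s = c + x + kd
    return bmax * (s - np.sqrt(s * s - 4.0 * c * x)) / (2.0 * c)


def fit_binding(titration: BindingTitration, init: tuple | None = None) -> BindingFit:
    """Bounded least-squares fit of (Kd, Bmax) to a titration.

    Initialises at Kd0 = median of the nonzero x values and Bmax0 = max(y)
    unless *init* is given, retrying from scaled starts on non-convergence.
    Standard errors come from the fit covariance.
    """
    x, y, c = titration.x_uM, titration.y, titration.c_uM
    nonzero = x[x > 0]
    if len(np.unique(x)) < 5:
        raise FitError("need at least 5 distinct concentrations to fit")
    if len(nonzero) == 0:
        raise FitError("all concentrations zero: titration carries no information")
    if init is None:
        init = (float(np.median(nonzero)), float(np.max(y)))

    def f(xv, kd, bmax):
        return binding_isotherm(xv, c, kd, bmax)

    last_err = None
    for scale in (1.0, 0.1, 10.0):
        p0 = (max(init[0] * scale, 1e-6), max(init[1], 1e-6))
        try:
            popt, pcov = curve_fit(f, x, y, p0=p0,
                                   bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                                   maxfev=20000)
            perr = np.sqrt(np.diag(pcov))
            resid = y - f(x, *popt)
            return BindingFit(float(popt[0]), float(popt[1]),
                              float(perr[0]), float(perr[1]), resid, pcov)
        except RuntimeError as err:  # non-convergence; retry from another start
            last_err = err
    raise FitError(f"binding fit did not converge from any start: {last_err}")


def simulate_binding(kd_uM: float, bmax: float, c_uM: float, x_grid,
                     noise_sd: float = 0.0, seed: int = 0,
                     n_replicates: int = 1) -> BindingTitration:
    """Synthetic titration from the isotherm plus Gaussian noise.

    Replicates repeat the concentration grid (quadruplicate pipetting is
    n_replicates=4); points are fitted jointly, not averaged.
    """
    if kd_uM <= 0 or bmax <= 0 or c_uM <= 0:
        raise BiophysError("Kd, Bmax and c must be positive")
    x = np.tile(np.asarray(x_grid, float), n_replicates)
    y = binding_isotherm(x, c_uM, kd_uM, bmax)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return BindingTitration(x, y, c_uM)


# ---------------------------------------------------------------------------
# I/O and plotting
# ---------------------------------------------------------------------------

def read_titration_csv(path, c_uM: float | None = None) -> BindingTitration:
    """CSV with columns x_uM, y and optionally replicate and c_uM."""
    df = pd.read_csv(path)
    for col in ("x_uM", "y"):
        if col not in df.columns:
            raise BiophysError(f"titration CSV lacks required column {col!r}")
    if c_uM is None:
        if "c_uM" not in df.columns:
            raise BiophysError("supply c_uM or include a c_uM column")
        c_uM = float(df["c_uM"].iloc[0])
    return BindingTitration(df["x_uM"].to_numpy(), df["y"].to_numpy(), c_uM)


def read_cd_csv(path, conc_uM: float, path_mm: float, n_amide: int) -> CDSpectrum:
    """CSV with columns wavelength_nm, theta_mdeg."""
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "theta_mdeg"):
        if col not in df.columns:
            raise BiophysError(f"CD CSV lacks required column {col!r}")
    return CDSpectrum(df["wavelength_nm"].to_numpy(), df["theta_mdeg"].to_numpy(),
                      conc_uM, path_mm, n_amide)


def plot_spectrum(spec: CDSpectrum, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(spec.wavelengths_nm, spectrum_mre(spec))
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel(r"MRE (deg cm$^2$ dmol$^{-1}$ res$^{-1}$)")
    ax.axhline(0.0, color="0.7", lw=0.5)
    return ax


def plot_thermal_response(ramp: ThermalRamp, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(ramp.temperature_C, ramp.theta_mdeg)
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel(f"ellipticity at {ramp.wavelength_nm:.0f} nm (mdeg)")
    return ax
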