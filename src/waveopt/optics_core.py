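"""Wavelength grids, absorber bases, and tissue optical coefficients.

Conventions used throughout the package:

* wavelengths are in nanometres, concentrations in micromolar (µM),
  molar extinction coefficients in cm^-1 M^-1 (decadic), and both the
  absorption coefficient µa and the reduced scattering coefficient µs'
  in cm^-1;
* µa(λ) = ln(10) · Σ_i ε_i(λ) · c_i with c_i converted to molar, i.e.
  extinction tables are decadic and the natural-log conversion is applied
  here, in one place;
* ⟨µs'⟩ denotes the arithmetic mean of µs'(λ) over 450–600 nm, the scalar
  scattering summary used for tissue contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

LN10 = float(np.log(10.0))

#: Spectral band over which scalar summaries (⟨µs'⟩, mean µa) are taken.
SUMMARY_BAND_NM = (450.0, 600.0)

#: Dense evaluation grid used for band-averaged summaries.
SUMMARY_STEP_NM = 1.0


# ---------------------------------------------------------------------------
# wavelength grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavelengthGrid:
    """An inclusive, evenly spaced wavelength grid.

    The grid is defined by its endpoints and increment; the number of
    points is ``(stop - start)/step + 1``.  Index arithmetic is done in
    integers scaled by the step so that fractional steps (2.5 nm) do not
    accumulate floating-point drift.
    """

    start_nm: float
    stop_nm: float
    step_nm: float

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be positive, got {self.step_nm}")
        if self.stop_nm <= self.start_nm:
            raise ValueError(
                f"stop_nm ({self.stop_nm}) must exceed start_nm ({self.start_nm})"
            )
        span = self.stop_nm - self.start_nm
        n_steps = span / self.step_nm
        if abs(n_steps - round(n_steps)) > 1e-6 * max(1.0, abs(n_steps)):
            raise ValueError(
                f"grid span {span} nm is not an integer multiple of step "
                f"{self.step_nm} nm"
            )

    @property
    def count(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.count)

    def snap(self, value_nm: float) -> float:
        """Nearest grid point to ``value_nm`` (clamped to the grid range)."""
        idx = int(round((value_nm - self.start_nm) / self.step_nm))
        idx = min(max(idx, 0), self.count - 1)
        return float(self.start_nm + self.step_nm * idx)

    def __contains__(self, value_nm: float) -> bool:
        idx = (value_nm - self.start_nm) / self.step_nm
        return (
            -1e-9 <= idx <= self.count - 1 + 1e-9
            and abs(idx - round(idx)) < 1e-6
        )


#: The full-spectrum acquisition grid: 450–600 nm in 2.5 nm steps, 61 points.
FULL_GRID = WavelengthGrid(450.0, 600.0, 2.5)


def grid_wavelengths(grid: WavelengthGrid) -> np.ndarray:
    """Return the inclusive, ascending wavelength array of ``grid``."""
    return grid.wavelengths()


# ---------------------------------------------------------------------------
# absorber bases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbsorberSpectrum:
    """Tabulated molar extinction of one absorber.

    ``molar_extinction`` is decadic, in cm^-1 M^-1, on strictly increasing
    ``wavelengths_nm``.  Interpolation is linear and restricted to the
    tabulated support; requests outside it raise.
    """

    name: str
    wavelengths_nm: np.ndarray
    molar_extinction: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        ext = np.asarray(self.molar_extinction, dtype=float)
        if wl.shape != ext.shape or wl.ndim != 1:
            raise ValueError("wavelengths and extinction must be equal-length 1-D")
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing (>= 2 points)")
        if np.any(ext < 0):
            raise ValueError(f"negative extinction values in absorber {self.name!r}")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "molar_extinction", ext)

    def at(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        wl = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if wl.min() < lo - 1e-9 or wl.max() > hi + 1e-9:
            raise ValueError(
                f"wavelengths outside tabulated support [{lo}, {hi}] nm of "
                f"absorber {self.name!r}"
            )
        return np.interp(wl, self.wavelengths_nm, self.molar_extinction)


def _gaussian_band(wl: np.ndarray, center: float, sigma: float,
                   peak: float) -> np.ndarray:
    return peak * np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def surrogate_basis(start_nm: float = 400.0, stop_nm: float = 650.0,
                    step_nm: float = 1.0) -> dict[str, AbsorberSpectrum]:
    """Synthetic absorber basis for download-free operation.

    A smooth, fully synthetic stand-in for the literature extinction
    curves of the visible-band breast absorbers, built from Gaussian
    bands with the qualitative features that drive the inverse problem:
    an oxyhemoglobin α/β doublet near 542/577 nm riding on a Soret tail,
    a single deoxyhemoglobin band near 555 nm, a broad β-carotene band
    below 520 nm, and a slightly blue-shifted crocin band (the carotenoid
    dye used as a β-carotene surrogate in liquid phantoms).  Magnitudes
    are order-of-magnitude realistic (1e4–1e5 cm^-1 M^-1) so that tissue
    concentrations in µM produce µa of a few cm^-1.
    """
    wl = np.arange(start_nm, stop_nm + step_nm / 2, step_nm, dtype=float)
    hbo2 = (
        _gaussian_band(wl, 415.0, 16.0, 5.0e5)
        + _gaussian_band(wl, 542.0, 11.0, 3.5e4)
        + _gaussian_band(wl, 577.0, 9.0, 3.2e4)
        + 2.0e3
    )
    dhb = (
        _gaussian_band(wl, 430.0, 18.0, 5.5e5)
        + _gaussian_band(wl, 555.0, 17.0, 4.2e4)
        + 1.5e3
    )
    bcar = _gaussian_band(wl, 462.0, 32.0, 1.3e5) + 5.0e2
    crocin = _gaussian_band(wl, 440.0, 30.0, 8.0e4) + 4.0e2
    return {
        "hbo2": AbsorberSpectrum("hbo2", wl, hbo2),
        "dhb": AbsorberSpectrum("dhb", wl, dhb),
        "bcar": AbsorberSpectrum("bcar", wl, bcar),
        "crocin": AbsorberSpectrum("crocin", wl, crocin),
    }


# ---------------------------------------------------------------------------
# scattering models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScatteringModel:
    """Wavelength dependence of the reduced scattering coefficient.

    ``power_law``: µs'(λ) = a · (λ/λ0)^(−b), the standard empirical tissue
    model (a in cm^-1 at the reference wavelength, b dimensionless).

    ``mie_sphere``: monodisperse spheres; µs'(λ) = ρ · C_sca(λ) · (1 − g(λ))
    with the scattering cross-section and asymmetry factor from the
    Bohren–Huffman Mie series (non-absorbing spheres), ρ the number density
    per mL.  Refractive indices are taken wavelength-independent.
    """

    kind: str = "power_law"
    amplitude_a: float = 10.0
    exponent_b: float = 1.2
    lambda0_nm: float = 525.0
    sphere_diameter_um: float = 1.0
    number_density_per_ml: float = 1.0e9
    n_sphere: float = 1.59
    n_medium: float = 1.33

    def __post_init__(self) -> None:
        if self.kind not in ("power_law", "mie_sphere"):
            raise ValueError(f"unsupported scattering kind {self.kind!r}")
        if self.kind == "power_law" and self.amplitude_a <= 0:
            raise ValueError("amplitude_a must be positive")
        if self.kind == "mie_sphere":
            if self.sphere_diameter_um <= 0 or self.number_density_per_ml <= 0:
                raise ValueError("sphere diameter and number density must be positive")
            if self.n_sphere <= 0 or self.n_medium <= 0:
                raise ValueError("refractive indices must be positive")


def mie_efficiencies(size_parameter: float, m_relative: float) -> tuple[float, float]:
    """Scattering efficiency Q_sca and asymmetry factor g for one sphere.

    Bohren–Huffman series with the logarithmic-derivative computed by
    downward recurrence and Riccati–Bessel functions by upward recurrence;
    the series is truncated at the Wiscombe order x + 4 x^(1/3) + 2.
    """
    x = float(size_parameter)
    m = float(m_relative)
    if x <= 0:
        raise ValueError("size parameter must be positive")
    nmax = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    nmx = max(nmax, int(np.ceil(abs(m * x)))) + 16

    # log-derivative D_n(mx) by downward recurrence
    mx = m * x
    d = np.zeros(nmx + 1)
    for n in range(nmx, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)

    # Riccati-Bessel psi (regular) and chi (irregular) by upward recurrence
    psi_nm1, psi_n = np.cos(x), np.sin(x)        # psi_{-1}, psi_0
    chi_nm1, chi_n = -np.sin(x), np.cos(x)       # chi_{-1}, chi_0
    a = np.zeros(nmax + 1, dtype=complex)
    b = np.zeros(nmax + 1, dtype=complex)
    for n in range(1, nmax + 1):
        psi = (2 * n - 1) / x * psi_n - psi_nm1
        chi = (2 * n - 1) / x * chi_n - chi_nm1
        xi = psi - 1j * chi
        xi_prev = psi_n - 1j * chi_n
        da = d[n] / m + n / x
        db = d[n] * m + n / x
        a[n] = (da * psi - psi_n) / (da * xi - xi_prev)
        b[n] = (db * psi - psi_n) / (db * xi - xi_prev)
        psi_nm1, psi_n = psi_n, psi
        chi_nm1, chi_n = chi_n, chi

    n_arr = np.arange(1, nmax + 1)
    an, bn = a[1:], b[1:]
    qsca = (2.0 / x ** 2) * np.sum(
        (2 * n_arr + 1) * (np.abs(an) ** 2 + np.abs(bn) ** 2)
    )
    cross = np.sum(
        (2 * n_arr + 1) / (n_arr * (n_arr + 1)) * np.real(an * np.conj(bn))
    )
    seq = np.sum(
        n_arr[:-1] * (n_arr[:-1] + 2) / (n_arr[:-1] + 1)
        * np.real(an[:-1] * np.conj(an[1:]) + bn[:-1] * np.conj(bn[1:]))
    )
    g = (4.0 / (x ** 2 * qsca)) * (seq + cross)
    return float(qsca), float(g)


def build_musp(scattering: ScatteringModel, grid: WavelengthGrid) -> np.ndarray:
    """Reduced scattering coefficient µs'(λ) in cm^-1 on ``grid``."""
    wl = grid.wavelengths()
    if scattering.kind == "power_law":
        return scattering.amplitude_a * (wl / scattering.lambda0_nm) ** (
            -scattering.exponent_b
        )
    # mie_sphere
    radius_cm = scattering.sphere_diameter_um * 1e-4 / 2.0
    m = scattering.n_sphere / scattering.n_medium
    musp = np.empty(wl.shape)
    for i, lam in enumerate(wl):
        lam_cm = lam * 1e-7
        x = 2.0 * np.pi * radius_cm * scattering.n_medium / lam_cm
        qsca, g = mie_efficiencies(x, m)
        csca = qsca * np.pi * radius_cm ** 2
        musp[i] = scattering.number_density_per_ml * csca * (1.0 - g)
    return musp


def mean_musp(musp: np.ndarray, grid: WavelengthGrid,
              lo_nm: float = SUMMARY_BAND_NM[0],
              hi_nm: float = SUMMARY_BAND_NM[1]) -> float:
    """Arithmetic mean of µs' samples with lo ≤ λ ≤ hi."""
    wl = grid.wavelengths()
    mask = (wl >= lo_nm - 1e-9) & (wl <= hi_nm + 1e-9)
    if not mask.any():
        raise ValueError(f"no grid samples inside [{lo_nm}, {hi_nm}] nm")
    return float(np.mean(np.asarray(musp)[mask]))


# ---------------------------------------------------------------------------
# tissue parameters and µa construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueParameters:
    """The unknowns of the inverse problem.

    Absorber concentrations in µM (oxy-Hb, deoxy-Hb, β-carotene) plus the
    scattering model.  [THb] = c_hbo2 + c_dhb and ⟨µs'⟩ (450–600 nm mean)
    are the derived summaries compared between full- and reduced-wavelength
    extractions.
    """

    c_hbo2: float
    c_dhb: float
    c_bc: float
    scattering: ScatteringModel = field(default_factory=ScatteringModel)

    def __post_init__(self) -> None:
        for name in ("c_hbo2", "c_dhb", "c_bc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def thb(self) -> float:
        return self.c_hbo2 + self.c_dhb

    def mean_musp(self, lo_nm: float = SUMMARY_BAND_NM[0],
                  hi_nm: float = SUMMARY_BAND_NM[1]) -> float:
        grid = WavelengthGrid(lo_nm, hi_nm, SUMMARY_STEP_NM)
        return mean_musp(build_musp(self.scattering, grid), grid, lo_nm, hi_nm)

    def concentrations(self) -> dict[str, float]:
        return {"hbo2": self.c_hbo2, "dhb": self.c_dhb, "bcar": self.c_bc}


def mua_from_concentrations(conc_um: Mapping[str, float],
                            basis: Mapping[str, AbsorberSpectrum],
                            grid: WavelengthGrid) -> np.ndarray:
    """µa(λ) = ln(10) Σ_i ε_i(λ) c_i, concentrations in µM."""
    wl = grid.wavelengths()
    mua = np.zeros(wl.shape)
    for name, c in conc_um.items():
        if c < 0:
            raise ValueError(f"negative concentration for absorber {name!r}")
        if c == 0:
            continue
        if name not in basis:
            raise KeyError(f"absorber {name!r} missing from basis")
        mua += LN10 * basis[name].at(wl) * (c * 1e-6)
    return mua


def build_mua(params: TissueParameters,
              basis: Mapping[str, AbsorberSpectrum],
              grid: WavelengthGrid) -> np.ndarray:
    """Absorption coefficient of a tissue parameter set on ``grid`` (cm^-1)."""
    return mua_from_concentrations(params.concentrations(), basis, grid)


@dataclass(frozen=True)
class OpticalProperties:
    """µa(λ) and µs'(λ) on a common grid — the forward model's input."""

    grid: WavelengthGrid
    mua: np.ndarray
    musp: np.ndarray

    def __post_init__(self) -> None:
        mua = np.asarray(self.mua, dtype=float)
        musp = np.asarray(self.musp, dtype=float)
        if mua.shape != (self.grid.count,) or musp.shape != (self.grid.count,):
            raise ValueError("coefficient arrays must match the grid length")
        if np.any(mua < 0) or np.any(musp < 0):
            raise ValueError("optical coefficients must be non-negative")
        object.__setattr__(self, "mua", mua)
        object.__setattr__(self, "musp", musp)

    @classmethod
    def from_tissue(cls, params: TissueParameters,
                    basis: Mapping[str, AbsorberSpectrum],
                    grid: WavelengthGrid) -> "OpticalProperties":
        return cls(grid, build_mua(params, basis, grid),
                   build_musp(params.scattering, grid))


def calibrate_power_law_amplitude(target_mean_musp: float,
                                  exponent_b: float = 1.2,
                                  lambda0_nm: float = 525.0,
                                  lo_nm: float = SUMMARY_BAND_NM[0],
                                  hi_nm: float = SUMMARY_BAND_NM[1]) -> ScatteringModel:
    """Power-law model whose 450–600 nm mean µs' equals ``target_mean_musp``.

    The band mean is linear in the amplitude, so the calibration is exact.
    """
    if target_mean_musp <= 0:
        raise ValueError("target mean µs' must be positive")
    grid = WavelengthGrid(lo_nm, hi_nm, SUMMARY_STEP_NM)
    shape = (grid.wavelengths() / lambda0_nm) ** (-exponent_b)
    a = target_mean_musp / float(np.mean(shape))
    return ScatteringModel(kind="power_law", amplitude_a=a,
                           exponent_b=exponent_b, lambda0_nm=lambda0_nm)
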