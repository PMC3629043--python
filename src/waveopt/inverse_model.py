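"""Extraction of tissue optical properties from reduced-wavelength spectra.

The inverse problem: given calibrated reflectance observed at a subset of
center wavelengths, find the absorber concentrations and scattering
parameters whose forward-model reflectance best matches it in the
least-squares sense.  The fit is bound-constrained, multi-start (Latin
hypercube initialization) nonlinear least squares; the quantities compared
downstream are the derived summaries [THb], [βc], and ⟨µs'⟩ (450–600 nm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .forward_model import (
    DEFAULT_GEOMETRY,
    GeometryConfig,
    PhotonRecordSet,
    ReflectanceSpectrum,
    diffusion_reflectance,
    scaled_mc_reflectance,
)
from .optics_core import (
    LN10,
    AbsorberSpectrum,
    ScatteringModel,
    TissueParameters,
    WavelengthGrid,
    build_musp,
)

#: At least this many center wavelengths are required to extract the
#: oxy-Hb / deoxy-Hb / β-carotene / scattering parameter set.
MIN_WAVELENGTHS = 5

#: Default fit bounds: concentrations up to 3× the observed tissue maxima,
#: power-law amplitude in (0, 30] cm^-1, exponent in [0.1, 3].
DEFAULT_BOUNDS = {
    "hbo2": (0.0, 3.0 * 97.9),
    "dhb": (0.0, 3.0 * 97.9),
    "bcar": (0.0, 3.0 * 37.6),
    "amplitude_a": (1e-3, 30.0),
    "exponent_b": (0.1, 3.0),
}

#: Fallback bound for absorbers without an entry in the bounds mapping.
FALLBACK_CONC_BOUND = (0.0, 1000.0)


@dataclass(frozen=True)
class WavelengthSet:
    """A candidate solution: ordered unique center wavelengths on a grid."""

    wavelengths: tuple[float, ...]
    increment_grid: WavelengthGrid

    def __post_init__(self) -> None:
        wl = tuple(float(w) for w in self.wavelengths)
        if len(wl) < 1:
            raise ValueError("a wavelength set needs at least one member")
        if len(set(wl)) != len(wl):
            raise ValueError(f"duplicate wavelengths in {wl}")
        if sorted(wl) != list(wl):
            raise ValueError("wavelengths must be ascending")
        for w in wl:
            if w not in self.increment_grid:
                raise ValueError(f"{w} nm is not on the increment grid")
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return len(self.wavelengths)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.wavelengths)

    @classmethod
    def full(cls, grid: WavelengthGrid) -> "WavelengthSet":
        return cls(tuple(grid.wavelengths()), grid)


class UnderdeterminedError(ValueError):
    """Raised when a wavelength subset cannot constrain the free parameters."""


@dataclass(frozen=True)
class ExtractionResult:
    """Fitted parameters plus fit diagnostics for one spectrum."""

    params: TissueParameters
    residual_norm: float
    converged: bool
    n_wavelengths_used: int
    concentrations: dict[str, float] | None = None  # per-absorber, µM

    @property
    def thb(self) -> float:
        return self.params.thb

    @property
    def bc(self) -> float:
        return self.params.c_bc

    @property
    def mean_musp(self) -> float:
        return self.params.mean_musp()

    def summaries(self) -> np.ndarray:
        """(THb, βc, ⟨µs'⟩) — the triplet compared between extractions."""
        return np.array([self.thb, self.bc, self.mean_musp])


def _match_subset(spectrum: ReflectanceSpectrum,
                  subset: WavelengthSet) -> np.ndarray:
    """Indices of the spectrum grid samples nearest each subset wavelength.

    A subset wavelength must fall within half a grid step of a sample.
    """
    grid = spectrum.grid
    idx = np.round((subset.as_array() - grid.start_nm) / grid.step_nm).astype(int)
    if np.any(idx < 0) or np.any(idx >= grid.count):
        raise ValueError("subset extends beyond the spectrum grid")
    matched = grid.start_nm + grid.step_nm * idx
    if np.any(np.abs(matched - subset.as_array()) > grid.step_nm / 2 + 1e-9):
        raise ValueError("subset wavelength more than half a step from any sample")
    return idx


def extract_properties(spectrum: ReflectanceSpectrum,
                       subset: WavelengthSet,
                       basis: Mapping[str, AbsorberSpectrum],
                       model: str = "diffusion",
                       geometry: GeometryConfig = DEFAULT_GEOMETRY,
                       records: PhotonRecordSet | None = None,
                       bounds: Mapping[str, tuple[float, float]] | None = None,
                       n_starts: int = 5,
                       seed: int = 0,
                       min_wavelengths: int = MIN_WAVELENGTHS,
                       absorber_names: tuple[str, ...] = ("hbo2", "dhb", "bcar"),
                       fit_scattering: bool = True,
                       fixed_scattering: ScatteringModel | None = None,
                       ) -> ExtractionResult:
    """Bound-constrained least-squares extraction at a wavelength subset.

    Free parameters are the concentrations of ``absorber_names`` (µM) plus,
    when ``fit_scattering``, the power-law scattering amplitude and
    exponent.  ``n_starts`` Latin-hypercube starting points are refined
    with trust-region-reflective least squares; the best residual wins,
    ties broken by the lowest total hemoglobin.  Non-convergence of every
    start is flagged on the result, not raised.
    """
    if len(subset) < min_wavelengths:
        raise UnderdeterminedError(
            f"{len(subset)} wavelengths given; at least {min_wavelengths} "
            "center wavelengths are needed to constrain the parameters"
        )
    idx = _match_subset(spectrum, subset)
    wl = spectrum.grid.wavelengths()[idx]
    r_obs = spectrum.values[idx]

    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)

    ext_matrix = np.column_stack([basis[name].at(wl) for name in absorber_names])
    n_conc = len(absorber_names)
    if fit_scattering:
        names = list(absorber_names) + ["amplitude_a", "exponent_b"]
        lambda0 = ScatteringModel().lambda0_nm
        shape = lambda theta: theta[n_conc] * (wl / lambda0) ** (-theta[n_conc + 1])
    else:
        if fixed_scattering is None:
            raise ValueError("fixed_scattering required when fit_scattering=False")
        names = list(absorber_names)
        grid_sub = wl
        musp_fixed = (
            fixed_scattering.amplitude_a
            * (grid_sub / fixed_scattering.lambda0_nm) ** (-fixed_scattering.exponent_b)
            if fixed_scattering.kind == "power_law"
            else None
        )
        if musp_fixed is None:
            # evaluate the Mie model once on the subset wavelengths
            tmp_grid = spectrum.grid
            musp_full = build_musp(fixed_scattering, tmp_grid)
            musp_fixed = musp_full[idx]
        shape = lambda theta: musp_fixed

    lo = np.array([bnds.get(n, FALLBACK_CONC_BOUND)[0] for n in names])
    hi = np.array([bnds.get(n, FALLBACK_CONC_BOUND)[1] for n in names])
    scale_r = max(float(np.mean(r_obs)), 1e-30)

    if model == "scaled_mc" and records is None:
        raise ValueError("scaled_mc extraction requires a PhotonRecordSet")

    def residuals(theta: np.ndarray) -> np.ndarray:
        mua = LN10 * (ext_matrix @ (theta[:n_conc] * 1e-6))
        musp = shape(theta)
        if model == "diffusion":
            r_model = diffusion_reflectance(mua, musp, geometry.separation_cm,
                                            geometry.n_relative)
        else:
            r_model = scaled_mc_reflectance(records, mua, musp)
        return (r_model - r_obs) / scale_r

    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    starts = qmc.scale(sampler.random(n_starts), lo + 1e-6 * (hi - lo),
                       hi - 1e-6 * (hi - lo))

    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for x0 in starts:
            try:
                sol = least_squares(residuals, x0, bounds=(lo, hi),
                                    method="trf", x_scale="jac",
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                    max_nfev=400)
            except Exception:
                continue
            thb = sol.x[0] + (sol.x[1] if n_conc > 1 else 0.0)
            key = (sol.cost, thb)
            if best is None or key < best[0]:
                best = (key, sol)

    if best is None:
        # every start failed: report the bounds midpoint, flagged unconverged
        mid = (lo + hi) / 2
        params = _theta_to_params(mid, names, n_conc, fixed_scattering)
        conc = dict(zip(names[:n_conc], (float(v) for v in mid)))
        return ExtractionResult(params, float("inf"), False, len(subset), conc)

    sol = best[1]
    params = _theta_to_params(sol.x, names, n_conc, fixed_scattering)
    residual_norm = float(np.sqrt(2.0 * sol.cost) * scale_r)
    conc = dict(zip(names[:n_conc], (float(v) for v in sol.x)))
    return ExtractionResult(params, residual_norm, bool(sol.success),
                            len(subset), conc)


def _theta_to_params(theta: np.ndarray, names: list[str], n_conc: int,
                     fixed_scattering: ScatteringModel | None) -> TissueParameters:
    conc = {name: float(max(v, 0.0)) for name, v in zip(names[:n_conc], theta)}
    if "amplitude_a" in names:
        scattering = ScatteringModel(
            kind="power_law",
            amplitude_a=float(theta[names.index("amplitude_a")]),
            exponent_b=float(theta[names.index("exponent_b")]),
        )
    else:
        scattering = fixed_scattering
    if not ({"hbo2", "dhb", "bcar"} & set(names[:n_conc])):
        # non-standard absorber names (e.g. toy bases): map positionally
        vals = list(conc.values()) + [0.0, 0.0, 0.0]
        return TissueParameters(c_hbo2=vals[0], c_dhb=vals[1], c_bc=vals[2],
                                scattering=scattering)
    return TissueParameters(
        c_hbo2=conc.get("hbo2", 0.0),
        c_dhb=conc.get("dhb", 0.0),
        c_bc=conc.get("bcar", 0.0),
        scattering=scattering,
    )


def extraction_errors(reduced: ExtractionResult,
                      reference: ExtractionResult) -> np.ndarray:
    """Signed percent errors (THb, βc, ⟨µs'⟩): 100·(reduced − reference)/reference.

    Positive = over-estimation by the reduced-wavelength extraction.
    """
    ref = reference.summaries()
    red = reduced.summaries()
    if np.any(ref == 0):
        raise ZeroDivisionError("reference summary of 0 — percent error undefined")
    return 100.0 * (red - ref) / ref
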