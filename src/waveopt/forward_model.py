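"""Forward reflectance models and spectral bandpass degradation.

Two interchangeable forward models map optical properties to a calibrated
diffuse reflectance spectrum for a single source–detector separation:

* ``diffusion`` — the closed-form steady-state extrapolated-boundary
  dipole solution for a semi-infinite medium, evaluated per wavelength;
* ``scaled_mc`` — Beer–Lambert rescaling of a baseline photon-transport
  simulation's exit weights and path lengths (scaled Monte Carlo), so one
  absorption-free random walk serves every (µa, µs') pair.

Both return reflectance per unit detector area (cm^-2), so they are
directly comparable.  Higher modules treat the forward model as a
contract and are agnostic to which implementation stands behind it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .optics_core import (
    AbsorberSpectrum,
    OpticalProperties,
    TissueParameters,
    WavelengthGrid,
)

#: FWHM-to-sigma conversion for a Gaussian bandpass.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class GeometryConfig:
    """Probe geometry for the forward models.

    ``separation_cm`` is the source–detector separation (default 0.75 mm,
    the annular-detector inner radius of the target probe).  The collection
    annulus spans ``annulus_fraction`` × separation on either side; photon
    records are normalized per unit annulus area.  ``n_relative`` is the
    tissue/ambient refractive-index ratio entering the diffusion boundary
    condition (1.0 = index matched, as in the built-in transport baseline).
    """

    separation_cm: float = 0.075
    annulus_fraction: float = 0.4
    n_relative: float = 1.0

    def annulus_radii_cm(self) -> tuple[float, float]:
        r_in = self.separation_cm * (1.0 - self.annulus_fraction)
        r_out = self.separation_cm * (1.0 + self.annulus_fraction)
        return r_in, r_out

    def annulus_area_cm2(self) -> float:
        r_in, r_out = self.annulus_radii_cm()
        return float(np.pi * (r_out ** 2 - r_in ** 2))


DEFAULT_GEOMETRY = GeometryConfig()


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Calibrated diffuse reflectance on a wavelength grid.

    ``fwhm_nm`` tags the source bandpass the values correspond to
    (0 = ideal monochromatic sampling).
    """

    grid: WavelengthGrid
    values: np.ndarray
    provenance: str = "simulated"
    fwhm_nm: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.grid.count,):
            raise ValueError("values must match the grid length")
        if np.any(values < 0):
            raise ValueError("reflectance values must be non-negative")
        if self.provenance not in ("measured", "simulated"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        object.__setattr__(self, "values", values)


# ---------------------------------------------------------------------------
# diffusion forward model
# ---------------------------------------------------------------------------

def _boundary_parameter(n_relative: float) -> float:
    """Internal-reflection parameter A of the extrapolated boundary.

    Uses the Groenhuis/Egan–Hilgeman polynomial fit for the effective
    reflection coefficient; A = (1 + R_eff)/(1 - R_eff), A = 1 for an
    index-matched boundary.
    """
    n = n_relative
    if abs(n - 1.0) < 1e-12:
        return 1.0
    r_eff = -1.440 / n ** 2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_eff) / (1.0 - r_eff)


def diffusion_reflectance(mua: np.ndarray, musp: np.ndarray,
                          separation_cm: float,
                          n_relative: float = 1.0) -> np.ndarray:
    """Steady-state dipole reflectance R(ρ) (cm^-2), semi-infinite medium.

    Extrapolated-boundary dipole: isotropic point source at depth
    z0 = 1/(µa + µs') with a negative image source above the boundary at
    z = −(z0 + 2·zb), zb = 2AD.  The detected reflectance combines the
    fluence and normal-flux terms, R = φ/4 + F/2, which tracks transport
    solutions at short source–detector separations much better than the
    flux-only form; the index mismatch enters through the extrapolated
    boundary (A) only.
    """
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    if np.any(musp <= 0):
        raise ValueError("µs' must be strictly positive for the diffusion model")
    mut = mua + musp
    z0 = 1.0 / mut
    d = 1.0 / (3.0 * mut)
    mueff = np.sqrt(3.0 * mua * mut)
    zb = 2.0 * _boundary_parameter(n_relative) * d
    rho = separation_cm
    if np.any(rho < 1.0 / np.max(mut)):
        warnings.warn(
            "source-detector separation is below one transport mean free "
            "path; diffusion approximation is marginal there",
            stacklevel=2,
        )
    r1 = np.sqrt(z0 ** 2 + rho ** 2)
    r2 = np.sqrt((z0 + 2.0 * zb) ** 2 + rho ** 2)
    flux = (z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1 ** 2
            + (z0 + 2.0 * zb) * (mueff + 1.0 / r2)
            * np.exp(-mueff * r2) / r2 ** 2) / (4.0 * np.pi)
    fluence = (np.exp(-mueff * r1) / r1
               - np.exp(-mueff * r2) / r2) / (4.0 * np.pi * d)
    return 0.25 * fluence + 0.5 * flux


def diffusion_reflectance_annulus(mua: np.ndarray, musp: np.ndarray,
                                  geometry: GeometryConfig,
                                  n_radial: int = 64) -> np.ndarray:
    """Area-averaged dipole reflectance over the collection annulus."""
    r_in, r_out = geometry.annulus_radii_cm()
    radii = np.linspace(r_in, r_out, n_radial)
    mua = np.asarray(mua, dtype=float)
    acc = np.zeros(mua.shape)
    weights = radii / np.sum(radii)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r, w in zip(radii, weights):
            acc += w * diffusion_reflectance(mua, musp, r, geometry.n_relative)
    return acc


# ---------------------------------------------------------------------------
# scaled Monte Carlo forward model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhotonRecordSet:
    """Exit records of a baseline absorption-free transport simulation.

    ``exit_weights`` w_j and ``path_lengths_cm`` L_j belong to photons that
    left the medium inside the collection annulus; ``n_launched`` photons
    were started in total.  Reflectance for arbitrary (µa, µs) follows by
    Beer–Lambert rescaling:  R = (1/(N·A)) Σ_j w_j exp(−µa L_j µs0/µs).
    """

    exit_weights: np.ndarray
    path_lengths_cm: np.ndarray
    baseline_mus: float
    n_launched: int
    geometry: GeometryConfig = field(default_factory=GeometryConfig)

    def __post_init__(self) -> None:
        w = np.asarray(self.exit_weights, dtype=float)
        ell = np.asarray(self.path_lengths_cm, dtype=float)
        if w.size == 0 or w.shape != ell.shape:
            raise ValueError("weights/path lengths must be nonempty, equal length")
        if np.any(w <= 0) or np.any(w > 1.0):
            raise ValueError("exit weights must lie in (0, 1]")
        if np.any(ell <= 0):
            raise ValueError("path lengths must be positive")
        object.__setattr__(self, "exit_weights", w)
        object.__setattr__(self, "path_lengths_cm", ell)


def simulate_photon_records(baseline_mus: float = 10.0,
                            geometry: GeometryConfig = DEFAULT_GEOMETRY,
                            n_photons: int = 100_000,
                            max_steps: int = 1000,
                            seed: int = 12345) -> PhotonRecordSet:
    """Absorption-free isotropic random walk in a semi-infinite medium.

    Photons launch downward at the origin, take exponentially distributed
    steps (mean 1/µs), scatter isotropically, and exit through z = 0 with
    unit weight (index-matched boundary).  Photons exiting inside the
    collection annulus are recorded with their total path length.  Because
    scattering is isotropic, ``baseline_mus`` plays the role of the reduced
    scattering coefficient during rescaling.

    Path-length rescaling is a local approximation: it is accurate when the
    target µs' is close to ``baseline_mus`` (the exit-radius distribution is
    not rescaled), so the baseline default sits mid-range of tissue µs'.
    """
    rng = np.random.default_rng(seed)
    pos = np.zeros((n_photons, 3))
    direc = np.zeros((n_photons, 3))
    direc[:, 2] = 1.0  # +z into the medium
    path = np.zeros(n_photons)
    active = np.ones(n_photons, dtype=bool)
    r_in, r_out = geometry.annulus_radii_cm()
    out_w, out_l = [], []

    for _ in range(max_steps):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        step = rng.exponential(1.0 / baseline_mus, size=idx.size)
        new_pos = pos[idx] + direc[idx] * step[:, None]
        crossed = new_pos[:, 2] < 0.0
        if crossed.any():
            ci = idx[crossed]
            # shorten the step to the boundary crossing point
            frac = pos[ci, 2] / (pos[ci, 2] - new_pos[crossed, 2])
            exit_xy = pos[ci, :2] + direc[ci, :2] * (step[crossed] * frac)[:, None]
            exit_path = path[ci] + step[crossed] * frac
            radius = np.hypot(exit_xy[:, 0], exit_xy[:, 1])
            hit = (radius >= r_in) & (radius <= r_out)
            if hit.any():
                out_w.append(np.ones(int(hit.sum())))
                out_l.append(exit_path[hit])
            active[ci] = False
        stay = idx[~crossed]
        pos[stay] = new_pos[~crossed]
        path[stay] += step[~crossed]
        # isotropic new direction
        cos_t = rng.uniform(-1.0, 1.0, size=stay.size)
        phi = rng.uniform(0.0, 2.0 * np.pi, size=stay.size)
        sin_t = np.sqrt(1.0 - cos_t ** 2)
        direc[stay, 0] = sin_t * np.cos(phi)
        direc[stay, 1] = sin_t * np.sin(phi)
        direc[stay, 2] = cos_t

    if not out_w:
        raise RuntimeError("no photons collected; enlarge n_photons or annulus")
    return PhotonRecordSet(np.concatenate(out_w), np.concatenate(out_l),
                           baseline_mus=baseline_mus, n_launched=n_photons,
                           geometry=geometry)


def scaled_mc_reflectance(records: PhotonRecordSet, mua: np.ndarray,
                          musp: np.ndarray) -> np.ndarray:
    """Reflectance per unit area from rescaled photon records (cm^-2)."""
    mua = np.atleast_1d(np.asarray(mua, dtype=float))
    musp = np.atleast_1d(np.asarray(musp, dtype=float))
    if np.any(musp <= 0):
        raise ValueError("µs' must be strictly positive for scaled MC")
    scale = records.baseline_mus / musp  # path lengths shrink as µs grows
    ell = records.path_lengths_cm[None, :] * scale[:, None]
    summed = np.sum(records.exit_weights[None, :] * np.exp(-mua[:, None] * ell),
                    axis=1)
    area = records.geometry.annulus_area_cm2()
    return summed / (records.n_launched * area)


# ---------------------------------------------------------------------------
# unified forward interface
# ---------------------------------------------------------------------------

def forward_reflectance(props: OpticalProperties, model: str = "diffusion",
                        geometry: GeometryConfig = DEFAULT_GEOMETRY,
                        records: PhotonRecordSet | None = None) -> ReflectanceSpectrum:
    """Diffuse reflectance spectrum of one optical-property set."""
    if model == "diffusion":
        values = diffusion_reflectance(props.mua, props.musp,
                                       geometry.separation_cm,
                                       geometry.n_relative)
    elif model == "scaled_mc":
        if records is None:
            raise ValueError("scaled_mc requires a PhotonRecordSet")
        values = scaled_mc_reflectance(records, props.mua, props.musp)
    else:
        raise ValueError(f"unknown forward model {model!r}")
    return ReflectanceSpectrum(props.grid, values, provenance="simulated")


def simulate_spectra(params_list: Sequence[TissueParameters],
                     grid: WavelengthGrid,
                     basis: dict[str, AbsorberSpectrum],
                     model: str = "diffusion",
                     geometry: GeometryConfig = DEFAULT_GEOMETRY,
                     records: PhotonRecordSet | None = None
                     ) -> list[ReflectanceSpectrum]:
    """One simulated spectrum per tissue parameter set (deterministic)."""
    if len(params_list) == 0:
        raise ValueError("params_list must be nonempty")
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for params in params_list:
            props = OpticalProperties.from_tissue(params, basis, grid)
            out.append(forward_reflectance(props, model, geometry, records))
    return out


# ---------------------------------------------------------------------------
# bandpass degradation
# ---------------------------------------------------------------------------

def convolve_bandpass(spectrum: ReflectanceSpectrum, fwhm_nm: float,
                      kernel: Callable[[np.ndarray], np.ndarray] | None = None
                      ) -> ReflectanceSpectrum:
    """Degrade a spectrum by a Gaussian (or caller-supplied) source bandpass.

    The Gaussian kernel has σ = FWHM/(2√(2 ln 2)), is discretized on the
    spectrum's grid, truncated at ±3σ, and renormalized to unit sum per
    output sample (no padding — out-of-band reflectance is never invented).
    ``kernel``, if given, maps offsets in nm to non-negative weights and
    replaces the Gaussian (arbitrary LED line shapes); it is truncated at
    the spectrum edges and renormalized the same way.
    """
    if fwhm_nm < 0:
        raise ValueError("fwhm_nm must be non-negative")
    if fwhm_nm == 0 and kernel is None:
        return spectrum
    step = spectrum.grid.step_nm
    if kernel is None:
        sigma = fwhm_nm * FWHM_TO_SIGMA
        half = int(np.floor(3.0 * sigma / step))
        offsets = np.arange(-half, half + 1) * step
        weights = np.exp(-0.5 * (offsets / sigma) ** 2)
    else:
        half = spectrum.grid.count - 1
        offsets = np.arange(-half, half + 1) * step
        weights = np.asarray(kernel(offsets), dtype=float)
        if np.any(weights < 0):
            raise ValueError("kernel weights must be non-negative")
        nz = np.nonzero(weights)[0]
        offsets, weights = offsets[nz[0]:nz[-1] + 1], weights[nz[0]:nz[-1] + 1]
        half = int(round(offsets[-1] / step))
    if weights.size <= 1:
        return replace(spectrum, fwhm_nm=float(fwhm_nm))

    n = spectrum.grid.count
    num = np.zeros(n)
    den = np.zeros(n)
    for k, w in zip(range(-half, half + 1), weights):
        lo, hi = max(0, -k), min(n, n - k)
        num[lo:hi] += w * spectrum.values[lo + k:hi + k]
        den[lo:hi] += w
    return ReflectanceSpectrum(spectrum.grid, num / den,
                               provenance=spectrum.provenance,
                               fwhm_nm=float(fwhm_nm))


# ---------------------------------------------------------------------------
# photon-record persistence (CSV + JSON sidecar)
# ---------------------------------------------------------------------------

def save_photon_records(records: PhotonRecordSet, path: str | Path) -> None:
    """Write records as CSV ``weight,path_length_cm`` with a JSON sidecar."""
    path = Path(path)
    data = np.column_stack([records.exit_weights, records.path_lengths_cm])
    np.savetxt(path, data, delimiter=",", header="weight,path_length_cm",
               comments="")
    sidecar = {
        "baseline_mus": records.baseline_mus,
        "n_launched": records.n_launched,
        "geometry": {
            "separation_cm": records.geometry.separation_cm,
            "annulus_fraction": records.geometry.annulus_fraction,
            "n_relative": records.geometry.n_relative,
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_photon_records(path: str | Path) -> PhotonRecordSet:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return PhotonRecordSet(
        data[:, 0], data[:, 1],
        baseline_mus=meta["baseline_mus"], n_launched=meta["n_launched"],
        geometry=GeometryConfig(**meta["geometry"]),
    )
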