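"""Synthetic cohorts, the training-set fixture, and the liquid-phantom design.

Nothing here is measured data: cohorts are drawn to span the observed
ex vivo breast-tissue ranges of [THb] (10.7–97.9 µM), [βc] (7.0–37.6 µM)
and ⟨µs'⟩ (3.7–11.9 cm^-1); the training fixture carries the 15 published
(THb, βc, ⟨µs'⟩) triples; and the phantom builder realizes the 20-phantom
factorial design (5 crocin steps × 2 hemoglobin levels × 2 scattering
levels) by calibrating each absorber's concentration so its 450–600 nm
band-averaged µa hits the design value exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .forward_model import (
    DEFAULT_GEOMETRY,
    GeometryConfig,
    PhotonRecordSet,
    ReflectanceSpectrum,
    forward_reflectance,
    simulate_spectra,
)
from .optics_core import (
    FULL_GRID,
    LN10,
    AbsorberSpectrum,
    OpticalProperties,
    SUMMARY_BAND_NM,
    SUMMARY_STEP_NM,
    TissueParameters,
    WavelengthGrid,
    build_musp,
    calibrate_power_law_amplitude,
    mua_from_concentrations,
)

logger = logging.getLogger(__name__)

#: Observed tissue ranges spanned by the synthetic cohorts.
THB_RANGE_UM = (10.7, 97.9)
BC_RANGE_UM = (7.0, 37.6)
MUSP_RANGE = (3.7, 11.9)

#: Default hemoglobin oxygen saturation used to split THb into oxy/deoxy.
DEFAULT_SATURATION = 0.7

#: Default scattering power-law exponent for tissue-like media.
DEFAULT_EXPONENT_B = 1.2

#: The 15 published training triples: (THb µM, βc µM, ⟨µs'⟩ cm^-1).
#: Rows 1–5, 6–10, 11–15 sit at the 10th–90th percentiles of THb, βc and
#: ⟨µs'⟩ respectively in the source cohort.
TRAINING_TABLE = (
    (10.7, 7.5, 4.1),
    (18.1, 21.7, 5.3),
    (32.7, 18.6, 11.5),
    (59.3, 21.0, 8.0),
    (97.9, 16.6, 4.4),
    (55.7, 7.0, 3.9),
    (49.6, 11.3, 9.2),
    (32.8, 17.5, 6.3),
    (73.1, 26.0, 8.8),
    (95.9, 37.6, 8.4),
    (24.2, 13.6, 3.7),
    (22.3, 29.3, 4.8),
    (40.3, 31.3, 6.5),
    (91.1, 15.8, 8.9),
    (11.5, 30.8, 11.9),
)

#: Liquid-phantom design: per absorber level, the 5 (Hb, crocin) pairs of
#: 450–600 nm band-averaged µa (cm^-1).  Each pair is realized at both
#: scattering levels (⟨µs'⟩ = 9 and 12 cm^-1) for 20 phantoms in total.
PHANTOM_DESIGN = {
    1: ((0.51, 0.00), (0.51, 0.48), (0.51, 0.72), (0.51, 0.96), (0.50, 1.20)),
    2: ((0.91, 0.00), (0.90, 0.82), (0.89, 1.23), (0.89, 1.64), (0.88, 2.05)),
}
PHANTOM_MUSP_LEVELS = (9.0, 12.0)


@dataclass(frozen=True)
class CohortSpec:
    """Sampling recipe for a synthetic tissue cohort."""

    n: int = 100
    thb_range_um: tuple[float, float] = THB_RANGE_UM
    bc_range_um: tuple[float, float] = BC_RANGE_UM
    musp_range: tuple[float, float] = MUSP_RANGE
    saturation: float = DEFAULT_SATURATION
    exponent_b: float = DEFAULT_EXPONENT_B
    multiplicative_sd: float = 0.03
    additive_sd: float = 0.005  # fraction of the mean reflectance
    correlated_sd: float = 0.02
    correlation_knot_nm: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be at least 1")
        for name in ("thb_range_um", "bc_range_um", "musp_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be positive and ordered")
        if not 0.0 <= self.saturation <= 1.0:
            raise ValueError("saturation must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """One liquid phantom of the factorial design."""

    hb_mean_mua: float
    crocin_mean_mua: float
    target_mean_musp: float
    label: tuple[int, int]  # (absorber level, scattering level index)

    def __post_init__(self) -> None:
        if self.hb_mean_mua < 0 or self.crocin_mean_mua < 0:
            raise ValueError("component mean µa must be non-negative")

    @property
    def total_mean_mua(self) -> float:
        return self.hb_mean_mua + self.crocin_mean_mua


def tissue_parameters_from_summaries(thb_um: float, bc_um: float,
                                     target_mean_musp: float,
                                     saturation: float = DEFAULT_SATURATION,
                                     exponent_b: float = DEFAULT_EXPONENT_B,
                                     ) -> TissueParameters:
    """Tissue parameters realizing given (THb, βc, ⟨µs'⟩) summaries.

    THb is split into oxy/deoxy by the saturation; the power-law amplitude
    is calibrated so the 450–600 nm mean µs' equals the target exactly.
    """
    scattering = calibrate_power_law_amplitude(target_mean_musp,
                                               exponent_b=exponent_b)
    return TissueParameters(
        c_hbo2=saturation * thb_um,
        c_dhb=(1.0 - saturation) * thb_um,
        c_bc=bc_um,
        scattering=scattering,
    )


def table1_fixture(saturation: float = DEFAULT_SATURATION,
                   exponent_b: float = DEFAULT_EXPONENT_B,
                   ) -> list[TissueParameters]:
    """The 15-sample training fixture as tissue parameter sets.

    Oxygen saturation is not part of the published triples; it is an
    explicit, configurable assumption and downstream comparisons use THb,
    never the oxy/deoxy split.
    """
    return [
        tissue_parameters_from_summaries(thb, bc, musp, saturation, exponent_b)
        for thb, bc, musp in TRAINING_TABLE
    ]


def apply_measurement_noise(spectrum: ReflectanceSpectrum,
                            rng: np.random.Generator,
                            multiplicative_sd: float = 0.03,
                            additive_sd: float = 0.005,
                            correlated_sd: float = 0.02,
                            correlation_knot_nm: float = 50.0,
                            ) -> ReflectanceSpectrum:
    """Corrupt a spectrum with the package's measurement-noise model.

    R_noisy = R·g(λ)·(1 + ε_m) + ε_a: per-sample multiplicative and
    additive white noise plus a smooth multiplicative gain field g(λ)
    (standard-normal knots every ``correlation_knot_nm``, linearly
    interpolated) emulating calibration and probe-contact variation.
    The result is clipped at zero.
    """
    grid = spectrum.grid
    knots = np.arange(grid.start_nm, grid.stop_nm + correlation_knot_nm,
                      correlation_knot_nm)
    wl = grid.wavelengths()
    gain = 1.0 + correlated_sd * np.interp(wl, knots,
                                           rng.standard_normal(knots.size))
    values = spectrum.values
    eps_m = rng.normal(0.0, multiplicative_sd, size=values.shape) \
        if multiplicative_sd > 0 else 0.0
    eps_a = rng.normal(0.0, additive_sd * float(np.mean(values)),
                       size=values.shape) if additive_sd > 0 else 0.0
    noisy = np.clip(values * gain * (1.0 + eps_m) + eps_a, 0.0, None)
    return ReflectanceSpectrum(grid, noisy, provenance=spectrum.provenance,
                               fwhm_nm=spectrum.fwhm_nm)


def generate_cohort(spec: CohortSpec,
                    basis: dict[str, AbsorberSpectrum],
                    grid: WavelengthGrid = FULL_GRID,
                    model: str = "diffusion",
                    geometry: GeometryConfig = DEFAULT_GEOMETRY,
                    records: PhotonRecordSet | None = None,
                    ) -> list[tuple[TissueParameters, ReflectanceSpectrum]]:
    """Draw a cohort of tissue parameter sets and their noisy spectra.

    Summaries are drawn uniformly within the spec ranges; each spectrum is
    simulated with the chosen forward model and corrupted as
    R_noisy = R·g(λ)·(1 + ε_m) + ε_a, with ε_m ~ N(0, multiplicative_sd²)
    per sample, ε_a ~ N(0, (additive_sd · mean R)²) per sample, and g(λ) a
    smooth multiplicative gain field, 1 + correlated_sd · z(λ) with z drawn
    i.i.d. standard normal on knots every ``correlation_knot_nm`` and
    linearly interpolated.  The correlated term emulates the calibration
    and probe-contact variation that dominates measured reflectance error
    and, unlike white noise, does not average away as wavelengths are
    added.  Spectra are clipped at zero (clip events are logged and rare
    at the default noise levels).
    """
    rng = np.random.default_rng(spec.seed)
    thb = rng.uniform(*spec.thb_range_um, size=spec.n)
    bc = rng.uniform(*spec.bc_range_um, size=spec.n)
    musp = rng.uniform(*spec.musp_range, size=spec.n)
    params = [
        tissue_parameters_from_summaries(t, b, m, spec.saturation,
                                         spec.exponent_b)
        for t, b, m in zip(thb, bc, musp)
    ]
    clean = simulate_spectra(params, grid, basis, model=model,
                             geometry=geometry, records=records)
    out = []
    n_clipped = 0
    for p, spectrum in zip(params, clean):
        if spec.multiplicative_sd > 0 or spec.additive_sd > 0 \
                or spec.correlated_sd > 0:
            noisy = apply_measurement_noise(
                spectrum, rng,
                multiplicative_sd=spec.multiplicative_sd,
                additive_sd=spec.additive_sd,
                correlated_sd=spec.correlated_sd,
                correlation_knot_nm=spec.correlation_knot_nm)
            n_clipped += int(np.sum(noisy.values == 0.0) -
                             np.sum(spectrum.values == 0.0))
            spectrum = noisy
        out.append((p, spectrum))
    if n_clipped > 0:
        logger.warning("clipped %d negative noisy samples (%.3f%% of all)",
                       n_clipped, 100.0 * n_clipped / (spec.n * grid.count))
    return out


class ToyUnmixingProblem:
    """Three disjoint narrow-band absorbers on a 10-point grid.

    A deliberately small wavelength-selection problem: the grid has 10
    candidate wavelengths (450–585 nm in 15 nm steps), the medium contains
    three narrow Gaussian absorber bands centred at 465, 510 and 555 nm,
    and scattering is fixed.  With k = 3 the search space has C(10,3) = 120
    subsets, so the globally optimal subset can be found by exhaustive
    enumeration — an independent oracle for optimizer correctness.  The
    informative optimum is the triple of band centres.
    """

    def __init__(self, noise_sd: float = 0.02, seed: int = 0,
                 n_starts: int = 2) -> None:
        from .inverse_model import WavelengthSet, extract_properties

        self._extract_properties = extract_properties
        self.grid = WavelengthGrid(450, 585, 15)  # 10 points
        wl = np.arange(440, 601, 1.0)

        def band(center, sigma, peak):
            return peak * np.exp(-0.5 * ((wl - center) / sigma) ** 2) + 100.0

        self.basis = {
            "x": AbsorberSpectrum("x", wl, band(465, 6, 5e4)),
            "y": AbsorberSpectrum("y", wl, band(510, 6, 5e4)),
            "z": AbsorberSpectrum("z", wl, band(555, 6, 5e4)),
        }
        self.names = ("x", "y", "z")
        self.n_starts = n_starts
        from .optics_core import ScatteringModel

        self.scattering = ScatteringModel(amplitude_a=8.0)
        concentration_sets = [
            {"x": 30.0, "y": 10.0, "z": 20.0},
            {"x": 10.0, "y": 25.0, "z": 5.0},
            {"x": 20.0, "y": 15.0, "z": 30.0},
        ]
        rng = np.random.default_rng(seed)
        self.spectra = []
        for conc in concentration_sets:
            props = OpticalProperties(
                self.grid, mua_from_concentrations(conc, self.basis,
                                                   self.grid),
                build_musp(self.scattering, self.grid))
            clean = forward_reflectance(props)
            noisy = clean.values * (
                1 + noise_sd * rng.standard_normal(clean.values.shape))
            self.spectra.append(ReflectanceSpectrum(self.grid, noisy))
        full = WavelengthSet.full(self.grid)
        self.references = [self.extract(s, full) for s in self.spectra]

    def extract(self, spectrum, subset):
        return self._extract_properties(
            spectrum, subset, self.basis, absorber_names=self.names,
            fit_scattering=False, fixed_scattering=self.scattering,
            min_wavelengths=3, n_starts=self.n_starts, seed=0)

    def fitness(self, subset):
        """RMS percent concentration error vs the full-grid references."""
        from .ga_optimizer import FitnessRecord

        errors = np.empty((len(self.spectra), 3))
        for i, (spectrum, ref) in enumerate(zip(self.spectra,
                                                self.references)):
            fit = self.extract(spectrum, subset)
            got = np.array([fit.concentrations[n] for n in self.names])
            want = np.array([ref.concentrations[n] for n in self.names])
            errors[i] = 100.0 * (got - want) / want
        return FitnessRecord(subset, errors,
                             float(np.sqrt(np.mean(errors ** 2))))


def calibrate_concentration_to_mean_mua(absorber: AbsorberSpectrum,
                                        target_mean_mua: float,
                                        lo_nm: float = SUMMARY_BAND_NM[0],
                                        hi_nm: float = SUMMARY_BAND_NM[1],
                                        ) -> float:
    """Concentration (µM) whose band-averaged µa equals the target.

    The band mean of µa is linear in concentration, so this is exact:
    c = target / (ln10 · mean ε · 1e-6).
    """
    if target_mean_mua < 0:
        raise ValueError("target mean µa must be non-negative")
    grid = WavelengthGrid(lo_nm, hi_nm, SUMMARY_STEP_NM)
    mean_ext = float(np.mean(absorber.at(grid.wavelengths())))
    return target_mean_mua / (LN10 * mean_ext * 1e-6)


def generate_phantom_set(basis: dict[str, AbsorberSpectrum],
                         grid: WavelengthGrid = FULL_GRID,
                         model: str = "diffusion",
                         geometry: GeometryConfig = DEFAULT_GEOMETRY,
                         records: PhotonRecordSet | None = None,
                         hb_absorber: str = "hbo2",
                         crocin_absorber: str = "crocin",
                         exponent_b: float = DEFAULT_EXPONENT_B,
                         ) -> list[tuple[PhantomSpec, TissueParameters,
                                         ReflectanceSpectrum]]:
    """The full 20-phantom factorial design with noiseless spectra.

    Hemoglobin and crocin concentrations are calibrated per phantom so the
    450–600 nm mean µa of each component matches its design value; the
    scattering amplitude is calibrated to the level's mean µs'.
    """
    for name in (hb_absorber, crocin_absorber):
        if name not in basis:
            raise KeyError(f"absorber {name!r} missing from basis")
    phantoms = []
    for level, rows in PHANTOM_DESIGN.items():
        for hb_mua, cr_mua in rows:
            for s_idx, target_musp in enumerate(PHANTOM_MUSP_LEVELS):
                spec = PhantomSpec(hb_mua, cr_mua, target_musp,
                                   label=(level, s_idx))
                c_hb = calibrate_concentration_to_mean_mua(basis[hb_absorber],
                                                           hb_mua)
                c_cr = calibrate_concentration_to_mean_mua(
                    basis[crocin_absorber], cr_mua)
                scattering = calibrate_power_law_amplitude(
                    target_musp, exponent_b=exponent_b)
                params = TissueParameters(c_hbo2=c_hb, c_dhb=0.0, c_bc=c_cr,
                                          scattering=scattering)
                conc = {hb_absorber: c_hb, crocin_absorber: c_cr}
                mua = mua_from_concentrations(conc, basis, grid)
                props = OpticalProperties(grid, mua,
                                          build_musp(scattering, grid))
                spectrum = forward_reflectance(props, model, geometry, records)
                phantoms.append((spec, params, spectrum))
    return phantoms
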