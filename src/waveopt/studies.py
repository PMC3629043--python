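"""Computational experiments: bandpass degradation and validation statistics.

* the bandpass study quantifies how widening the source FWHM degrades the
  accuracy of reduced-wavelength extractions against the undegraded
  full-spectrum gold standard;
* Bland–Altman agreement, margin-map correlation, ratio-threshold margin
  classification, and Wilcoxon rank-sum comparison are the statistics used
  to validate reduced-wavelength extractions against full-spectrum ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .forward_model import (
    DEFAULT_GEOMETRY,
    GeometryConfig,
    PhotonRecordSet,
    convolve_bandpass,
    simulate_spectra,
)
from .ga_optimizer import build_training_set
from .inverse_model import WavelengthSet, extract_properties, extraction_errors
from .optics_core import AbsorberSpectrum, FULL_GRID, TissueParameters, WavelengthGrid


# ---------------------------------------------------------------------------
# bandpass-degradation study
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandpassStudyResult:
    """Mean absolute percent extraction error per (wavelength set, FWHM)."""

    fwhm_levels: tuple[float, ...]
    set_labels: tuple[str, ...]
    error_table: pd.DataFrame      # rows: set label, columns: fwhm
    acceptable: pd.DataFrame       # error < threshold
    threshold_pct: float
    per_parameter: pd.DataFrame    # tidy: set, fwhm, parameter, error_pct

    def errors_for(self, label: str) -> np.ndarray:
        return self.error_table.loc[label].to_numpy()


def run_bandpass_study(training_params: Sequence[TissueParameters],
                       sets: Mapping[str, WavelengthSet],
                       fwhms: Sequence[float],
                       basis: Mapping[str, AbsorberSpectrum],
                       threshold_pct: float = 10.0,
                       grid: WavelengthGrid = FULL_GRID,
                       model: str = "diffusion",
                       geometry: GeometryConfig = DEFAULT_GEOMETRY,
                       records: PhotonRecordSet | None = None,
                       n_starts: int = 3,
                       seed: int = 0) -> BandpassStudyResult:
    """Degrade simulated spectra by each FWHM and re-extract at each set.

    For every tissue parameter set, a noiseless spectrum is simulated; the
    full-spectrum extraction of the *undegraded* spectrum is the gold
    standard.  Each (set, FWHM) cell holds the mean absolute percent error
    of (THb, βc, ⟨µs'⟩) across all spectra against that standard.
    """
    spectra = simulate_spectra(list(training_params), grid, basis, model=model,
                               geometry=geometry, records=records)
    training = build_training_set(spectra, basis, model=model,
                                  geometry=geometry, records=records,
                                  n_starts=n_starts, seed=seed)
    rows = []
    for fwhm in fwhms:
        degraded = [convolve_bandpass(s, fwhm) for s in spectra]
        for label, ws in sets.items():
            errs = []
            for spectrum, reference in zip(degraded,
                                           training.reference_extractions):
                reduced = extract_properties(spectrum, ws, basis, model=model,
                                             geometry=geometry,
                                             records=records,
                                             n_starts=n_starts, seed=seed)
                errs.append(np.abs(extraction_errors(reduced, reference)))
            errs = np.asarray(errs)  # (n_spectra, 3)
            for j, pname in enumerate(("THb", "bc", "mean_musp")):
                rows.append({"set": label, "fwhm_nm": fwhm,
                             "parameter": pname,
                             "error_pct": float(np.mean(errs[:, j]))})
    tidy = pd.DataFrame(rows)
    table = tidy.pivot_table(index="set", columns="fwhm_nm",
                             values="error_pct", aggfunc="mean")
    table = table.loc[list(sets), list(fwhms)]
    return BandpassStudyResult(
        fwhm_levels=tuple(float(f) for f in fwhms),
        set_labels=tuple(sets),
        error_table=table,
        acceptable=table < threshold_pct,
        threshold_pct=threshold_pct,
        per_parameter=tidy,
    )


# ---------------------------------------------------------------------------
# agreement and classification statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement of (reduced − full) differences."""

    bias: float
    loa_half_width: float  # 1.96 × SD of the differences
    n: int

    @property
    def limits(self) -> tuple[float, float]:
        return self.bias - self.loa_half_width, self.bias + self.loa_half_width


def bland_altman(full: np.ndarray, reduced: np.ndarray) -> BlandAltmanResult:
    """Agreement between full- and reduced-wavelength extractions.

    Differences are reduced − full, so a positive bias means the reduced
    set over-estimates.  The half-width is 1.96 × sample SD (ddof=1).
    """
    full = np.asarray(full, dtype=float)
    reduced = np.asarray(reduced, dtype=float)
    if full.shape != reduced.shape or full.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    if full.size < 2:
        raise ValueError("at least two paired values are required")
    d = reduced - full
    return BlandAltmanResult(bias=float(np.mean(d)),
                             loa_half_width=float(1.96 * np.std(d, ddof=1)),
                             n=full.size)


@dataclass(frozen=True)
class MarginMap:
    """Pixel map of a scalar endpoint (e.g. the βc/⟨µs'⟩ ratio) with a mask."""

    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = (np.ones(values.shape, dtype=bool) if self.mask is None
                else np.asarray(self.mask, dtype=bool))
        if mask.shape != values.shape:
            raise ValueError("mask must match the value array shape")
        if not np.all(np.isfinite(values[mask])):
            raise ValueError("masked-valid pixels must be finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)

    def valid_pixels(self) -> np.ndarray:
        return self.values[self.mask]


def map_correlation(map_a: MarginMap, map_b: MarginMap) -> float:
    """Pearson correlation of the two maps over their (shared) valid mask."""
    if not np.array_equal(map_a.mask, map_b.mask):
        raise ValueError("maps must share the same valid-pixel mask")
    a, b = map_a.valid_pixels(), map_b.valid_pixels()
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant or single-pixel maps")
    return float(np.corrcoef(a, b)[0, 1])


def classify_margin(margin: MarginMap, ratio_threshold: float = 6.0,
                    pixel_fraction: float = 0.98) -> str:
    """Classify a margin from its βc/⟨µs'⟩ ratio map.

    The margin is "positive" when at least ``pixel_fraction`` of the valid
    pixels have a ratio strictly below ``ratio_threshold`` (low β-carotene
    relative to scattering indicates fibroglandular/malignant rather than
    adipose tissue); otherwise "negative".
    """
    pixels = margin.valid_pixels()
    if pixels.size == 0:
        raise ValueError("margin map has no valid pixels")
    frac = float(np.mean(pixels < ratio_threshold))
    return "positive" if frac >= pixel_fraction else "negative"


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first group
    z: float
    p_value: float


def rank_sum_compare(group_a: np.ndarray,
                     group_b: np.ndarray) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test (normal approximation, tie-corrected).

    Returns the rank sum W of the first group, the tie-corrected standard
    normal deviate, and the two-sided p-value.  When the pooled data are
    completely tied the variance vanishes and p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = rankdata(np.concatenate([a, b]))
    w = float(np.sum(ranks[:n1]))
    mean_w = n1 * (n + 1) / 2.0
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return RankSumResult(statistic=w, z=0.0, p_value=1.0)
    z = (w - mean_w) / np.sqrt(var_w)
    return RankSumResult(statistic=w, z=float(z),
                         p_value=float(2.0 * norm.sf(abs(z))))
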