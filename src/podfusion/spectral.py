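"""Hyperspectral preprocessing.

The reflectance unit of information is a 462-band ROI-mean spectrum over
386-1004 nm.  This module extracts that spectrum from a hyperspectral cube,
removes per-sample scatter with multiplicative scatter correction (MSC),
min-max normalizes, and computes first derivatives for band analysis.

MSC treats each sample spectrum as an affine distortion ``x = b*t + a`` of a
common "ideal spectrum" ``t`` (the dataset mean).  Fitting ordinary least
squares of each sample on the ideal gives the per-sample baseline shift ``a``
(intercept) and offset ``b`` (slope); the corrected spectrum is
``(x - a) / b``.  For a purely affine family this collapses every sample onto
the same curve, which is the testable meaning of "eliminating scatter-induced
spectral differences".
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, EmptyROIError, ShapeError

#: Number of spectral bands the pipeline is built around.
N_BANDS = 462

#: Nominal wavelength coverage of the spectrograph, nm.
WAVELENGTH_RANGE_NM = (386.0, 1004.0)

#: Slope magnitudes below this are treated as degenerate in ``msc_apply``.
SLOPE_TOL = 1e-8

#: Tolerance (nm) for the uniform-grid check in ``first_derivative``.
GRID_TOL_NM = 1e-6


def default_wavelengths(n_bands: int = N_BANDS) -> np.ndarray:
    """Linearly spaced wavelength grid over the nominal range (~1.34 nm step)."""
    lo, hi = WAVELENGTH_RANGE_NM
    return np.linspace(lo, hi, n_bands)


@dataclass(frozen=True)
class Spectrum:
    """A single reflectance spectrum on an explicit wavelength grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        rf = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or rf.ndim != 1 or wl.shape != rf.shape:
            raise ShapeError(
                f"wavelengths {wl.shape} and reflectance {rf.shape} must be "
                "1-D vectors of equal length"
            )
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ShapeError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(rf)):
            raise ShapeError("reflectance contains non-finite values")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", rf)

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)


def roi_mean_spectrum(
    cube: np.ndarray, mask: np.ndarray, wavelengths: np.ndarray | None = None
) -> Spectrum:
    """Per-band arithmetic mean of a hyperspectral cube over an ROI mask.

    Parameters
    ----------
    cube : (H, W, B) array
        Reflectance cube.
    mask : (H, W) boolean array
        Pod pixels; must select at least one pixel.
    wavelengths : (B,) array, optional
        Wavelength grid; defaults to the package grid when ``B == 462``.
    """
    cube = np.asarray(cube, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if cube.ndim != 3 or mask.shape != cube.shape[:2]:
        raise ShapeError(
            f"cube {cube.shape} must be (H, W, B) with mask shaped (H, W), got mask {mask.shape}"
        )
    if not mask.any():
        raise EmptyROIError("ROI mask selects no pixels")
    mean = cube[mask].mean(axis=0)
    if wavelengths is None:
        wavelengths = default_wavelengths(cube.shape[2])
    return Spectrum(wavelengths, mean)


@dataclass
class MSCModel:
    """Fitted multiplicative-scatter-correction model.

    ``ideal`` is the dataset-mean reference spectrum; ``intercepts`` (baseline
    shift a) and ``slopes`` (offset b) are the per-sample OLS coefficients of
    each sample regressed on the ideal.
    """

    ideal: np.ndarray
    intercepts: np.ndarray
    slopes: np.ndarray

    def transform(self, spectra: np.ndarray) -> np.ndarray:
        """Apply ``(x - a) / b`` row-wise to the matrix the model was fit on."""
        spectra = np.asarray(spectra, dtype=float)
        if spectra.shape != (self.slopes.size, self.ideal.size):
            raise ShapeError(
                f"expected {(self.slopes.size, self.ideal.size)}, got {spectra.shape}"
            )
        if np.any(np.abs(self.slopes) <= SLOPE_TOL):
            raise DegenerateInputError("near-zero MSC slope; cannot correct")
        return (spectra - self.intercepts[:, None]) / self.slopes[:, None]

    def to_json(self) -> str:
        return json.dumps(
            {
                "ideal": self.ideal.tolist(),
                "intercepts": self.intercepts.tolist(),
                "slopes": self.slopes.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MSCModel":
        d = json.loads(text)
        return cls(
            ideal=np.asarray(d["ideal"], dtype=float),
            intercepts=np.asarray(d["intercepts"], dtype=float),
            slopes=np.asarray(d["slopes"], dtype=float),
        )


def msc_fit(spectra: np.ndarray) -> MSCModel:
    """Fit MSC: ideal spectrum = column mean; per-sample OLS of sample on ideal.

    Closed-form two-parameter least squares: with t the ideal spectrum,
    b_i = cov(x_i, t) / var(t) and a_i = mean(x_i) - b_i * mean(t).
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2 or spectra.shape[0] < 2:
        raise ShapeError(f"need an (n>=2, bands) matrix, got {spectra.shape}")
    ideal = spectra.mean(axis=0)
    t_centered = ideal - ideal.mean()
    denom = float(t_centered @ t_centered)
    if denom <= 0.0:
        raise DegenerateInputError("ideal spectrum is constant; MSC undefined")
    x_mean = spectra.mean(axis=1)
    slopes = (spectra - x_mean[:, None]) @ t_centered / denom
    intercepts = x_mean - slopes * ideal.mean()
    return MSCModel(ideal=ideal, intercepts=intercepts, slopes=slopes)


def msc_apply(spectrum: Spectrum, a: float, b: float) -> Spectrum:
    """Correct one spectrum: subtract the baseline shift, divide by the offset."""
    if abs(b) <= SLOPE_TOL:
        raise DegenerateInputError(f"MSC slope {b!r} is below tolerance {SLOPE_TOL}")
    return Spectrum(spectrum.wavelengths, (spectrum.reflectance - a) / b)


def msc_correct(spectra: np.ndarray) -> tuple[np.ndarray, MSCModel]:
    """Convenience fit-then-apply over a spectra matrix."""
    model = msc_fit(spectra)
    return model.transform(np.asarray(spectra, dtype=float)), model


def normalize_spectrum(spectrum: Spectrum) -> Spectrum:
    """Min-max scale reflectance to [0, 1]."""
    r = spectrum.reflectance
    lo, hi = float(r.min()), float(r.max())
    if hi <= lo:
        raise DegenerateInputError("constant spectrum cannot be min-max normalized")
    return Spectrum(spectrum.wavelengths, (r - lo) / (hi - lo))


def first_derivative(spectrum: Spectrum) -> Spectrum:
    """First derivative of reflectance with respect to wavelength.

    Central differences on interior points and one-sided differences at the
    ends; exact for quadratics on the uniform grid this pipeline uses.  The
    grid must be uniform to within ``GRID_TOL_NM``.
    """
    wl, r = spectrum.wavelengths, spectrum.reflectance
    if wl.size < 3:
        raise ShapeError("first derivative needs at least 3 bands")
    steps = np.diff(wl)
    if np.ptp(steps) > GRID_TOL_NM:
        raise ShapeError("wavelength grid is not uniform; derivative scheme assumes it")
    return Spectrum(wl, np.gradient(r, wl))
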