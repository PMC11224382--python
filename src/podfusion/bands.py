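"""Distance-correlation band selection and zero-ablation.

Each of the 462 bands is scored against the numerically encoded freshness
label (0..3) with the distance correlation

    dCor(X, Y) = dCov(X, Y) / sqrt(dVar(X) dVar(Y)),

computed from double-centered pairwise-distance matrices with the
population-style 1/n^2 normalization.  dCor lies in [0, 1] and is zero (in
the population) iff X and Y are independent, so it captures the nonlinear
band-label dependence a Pearson coefficient would miss.  Bands scoring
strictly above the threshold (default 0.7) are kept; for ablation studies all
other bands are set to zero, leaving array shapes untouched.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ShapeError

DEFAULT_THRESHOLD = 0.7


def _centered_distances(v: np.ndarray) -> np.ndarray:
    """Double-centered pairwise absolute-distance matrix of a 1-D sample."""
    d = np.abs(v[:, None] - v[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample distance correlation of two equal-length numeric vectors.

    Returns 0.0 (with a warning) when either marginal distance variance is
    zero, i.e. a constant input.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ShapeError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ShapeError("distance correlation needs at least 2 observations")
    a = _centered_distances(x)
    b = _centered_distances(y)
    n2 = x.size**2
    dcov2 = (a * b).sum() / n2
    dvar_x = (a * a).sum() / n2
    dvar_y = (b * b).sum() / n2
    if dvar_x <= 0 or dvar_y <= 0:
        warnings.warn("constant input: distance variance is zero, returning dCor = 0")
        return 0.0
    # tiny negatives from rounding are clipped before the square roots
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)))


@dataclass
class BandMask:
    """Per-band dCor scores and the boolean selection at a threshold."""

    scores: np.ndarray
    selected: np.ndarray
    threshold: float
    wavelengths: np.ndarray | None = None

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def windows(self) -> list[tuple[float, float]]:
        """Contiguous selected runs as (start, end) wavelength pairs."""
        if self.wavelengths is None:
            raise DegenerateInputError("no wavelength grid attached to this mask")
        out: list[tuple[float, float]] = []
        sel = np.flatnonzero(self.selected)
        if sel.size == 0:
            return out
        run_start = sel[0]
        prev = sel[0]
        for i in sel[1:]:
            if i != prev + 1:
                out.append((float(self.wavelengths[run_start]), float(self.wavelengths[prev])))
                run_start = i
            prev = i
        out.append((float(self.wavelengths[run_start]), float(self.wavelengths[prev])))
        return out

    def to_json(self) -> str:
        d = {
            "threshold": self.threshold,
            "scores": self.scores.tolist(),
            "selected": self.selected.astype(int).tolist(),
        }
        if self.wavelengths is not None:
            d["wavelengths"] = self.wavelengths.tolist()
            d["windows"] = self.windows()
        return json.dumps(d)


def score_bands(
    spectra: np.ndarray,
    labels: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    wavelengths: np.ndarray | None = None,
) -> BandMask:
    """dCor of every band against the 0..3 freshness label; mask at threshold.

    Selection is strict: a band is kept iff its score exceeds the threshold.
    """
    spectra = np.asarray(spectra, dtype=float)
    labels = np.asarray(labels, dtype=float).ravel()
    if spectra.ndim != 2 or spectra.shape[0] != labels.size:
        raise ShapeError(f"spectra {spectra.shape} do not align with {labels.size} labels")
    if np.unique(labels).size < 2:
        raise DegenerateInputError("band scoring needs at least two classes present")
    b = _centered_distances(labels)
    n2 = labels.size**2
    dvar_y = (b * b).sum() / n2
    scores = np.empty(spectra.shape[1])
    for j in range(spectra.shape[1]):
        a = _centered_distances(spectra[:, j])
        dvar_x = (a * a).sum() / n2
        if dvar_x <= 0:
            scores[j] = 0.0
            continue
        dcov2 = (a * b).sum() / n2
        scores[j] = np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y))
    return BandMask(
        scores=scores,
        selected=scores > threshold,
        threshold=threshold,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, dtype=float),
    )


def ablate(spectra: np.ndarray, mask: BandMask | np.ndarray) -> np.ndarray:
    """Zero every unselected band; selected bands pass through untouched."""
    spectra = np.asarray(spectra, dtype=float)
    selected = mask.selected if isinstance(mask, BandMask) else np.asarray(mask, dtype=bool)
    if spectra.shape[-1] != selected.size:
        raise ShapeError(f"mask length {selected.size} does not match {spectra.shape[-1]} bands")
    return np.where(selected, spectra, 0.0)
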