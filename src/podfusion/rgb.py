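"""RGB preprocessing: ROI crop, area-average downsampling to the fusion
resolution (22 rows x 21 columns), and the CIELAB green-intensity hue.

The hue parameter H = arctan(b/a) over the pod ROI tracks the green-to-yellow
shift of pods during storage.  We use the two-argument arctangent so the
quadrant survives, and define H = 0 for achromatic pixels (a = b = 0), where
the ratio form is undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2lab

from .errors import EmptyROIError, ShapeError

#: Fusion-plane spatial shape, (rows, cols) — matches the spectral reshape.
FUSION_SHAPE = (22, 21)

#: mean chroma (CIELAB units) below this is treated as achromatic, where the
#: hue angle is undefined; hue = 0 by convention.  0.05 is far below any
#: perceptible chroma.
ACHROMATIC_TOL = 0.05


def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    """Coerce an (H, W, 3) image to float in [0, 1]; 8-bit input is scaled."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ShapeError(f"expected an (H, W, 3) RGB image, got {image.shape}")
    if image.dtype == np.uint8:
        return image.astype(float) / 255.0
    return image.astype(float)


def _area_weights(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) row-stochastic matrix of interval-overlap weights.

    Output cell i covers the input interval [i*n_in/n_out, (i+1)*n_in/n_out);
    each input cell contributes in proportion to its overlap, so the resample
    is an exact box average (and an exact block mean for integer factors).
    """
    edges = np.arange(n_out + 1) * (n_in / n_out)
    w = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo, hi = edges[i], edges[i + 1]
        j0, j1 = int(math.floor(lo)), int(math.ceil(hi))
        for j in range(j0, min(j1, n_in)):
            w[i, j] = min(hi, j + 1) - max(lo, j)
    return w / (n_in / n_out)


def area_average_resize(image: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Box-filter (area-average) resize of an (H, W[, C]) array."""
    image = np.asarray(image, dtype=float)
    out_h, out_w = out_shape
    wr = _area_weights(image.shape[0], out_h)
    wc = _area_weights(image.shape[1], out_w)
    return np.einsum("ih,hwc,jw->ijc", wr, np.atleast_3d(image), wc).reshape(
        out_h, out_w, *image.shape[2:]
    )


def crop_downsample(
    image: np.ndarray,
    roi_box: tuple[int, int, int, int] | None = None,
    out_shape: tuple[int, int] = FUSION_SHAPE,
) -> np.ndarray:
    """Crop ``roi_box`` and area-average downsample to ``out_shape`` (+3 channels).

    Parameters
    ----------
    image : (H, W, 3) array
        sRGB image, float in [0, 1] or 8-bit.
    roi_box : (row0, col0, row1, col1), optional
        0-based half-open pixel rectangle; defaults to the full frame.
    out_shape : (rows, cols)
        Target spatial shape; default (22, 21), the fusion resolution.
    """
    image = _as_float_rgb(image)
    h, w = image.shape[:2]
    if roi_box is None:
        roi_box = (0, 0, h, w)
    r0, c0, r1, c1 = roi_box
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ShapeError(f"ROI box {roi_box} outside image bounds {(h, w)} or degenerate")
    if (r1 - r0) < out_shape[0] or (c1 - c0) < out_shape[1]:
        raise ShapeError(
            f"ROI box {roi_box} smaller than the {out_shape} output; refuse to upsample"
        )
    return area_average_resize(image[r0:r1, c0:c1], out_shape)


@dataclass(frozen=True)
class ColorStats:
    """ROI-mean CIELAB coordinates and the derived hue angle (radians)."""

    mean_L: float
    mean_a: float
    mean_b: float
    hue: float


def green_intensity(image: np.ndarray, mask: np.ndarray | None = None) -> ColorStats:
    """ROI-mean L*, a*, b* (sRGB, D65) and hue H = atan2(mean_b, mean_a)."""
    image = _as_float_rgb(image)
    if mask is None:
        mask = np.ones(image.shape[:2], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape[:2]:
        raise ShapeError(f"mask {mask.shape} does not match image {image.shape[:2]}")
    if not mask.any():
        raise EmptyROIError("ROI mask selects no pixels")
    lab = rgb2lab(image[mask][None, :, :])[0]
    mean_L, mean_a, mean_b = (float(v) for v in lab.mean(axis=0))
    if math.hypot(mean_a, mean_b) < ACHROMATIC_TOL:
        hue = 0.0
    else:
        hue = math.atan2(mean_b, mean_a)
    return ColorStats(mean_L=mean_L, mean_a=mean_a, mean_b=mean_b, hue=hue)
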