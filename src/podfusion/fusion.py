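"""Fusing the two modalities into one tensor.

A 462-band spectrum is reshaped row-major (ascending wavelength) into a
22x21 plane and stacked as a fourth channel behind the 22x21x3 RGB image,
giving a 22x21x4 tensor.  Element counts balance exactly:
22*21*4 = 22*21*3 + 462.

The two modalities have incompatible native scales, so each is brought to
[0, 1] before stacking: RGB by its 8-bit (or already-unit) range, the
spectral plane by per-sample min-max.  The concatenation itself is lossless —
slicing channels 0-2 recovers the scaled RGB bitwise and flattening channel 3
row-major recovers the scaled spectrum bitwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateInputError, InvalidClassError, ShapeError
from .rgb import FUSION_SHAPE
from .spectral import Spectrum

N_CLASSES = 4


def reshape_spectrum_2d(
    spectrum: Spectrum | np.ndarray,
    rows: int = FUSION_SHAPE[0],
    cols: int = FUSION_SHAPE[1],
) -> np.ndarray:
    """Reshape a spectrum into a (rows, cols) plane, row-major in wavelength.

    plane[0, 0] is band 0, plane[0, cols-1] is band cols-1, plane[1, 0] is
    band cols; a row-major flatten of the plane recovers the vector bitwise.
    """
    values = spectrum.reflectance if isinstance(spectrum, Spectrum) else np.asarray(spectrum)
    if values.ndim != 1 or values.size != rows * cols:
        raise ShapeError(
            f"cannot reshape {values.size if values.ndim == 1 else values.shape} "
            f"bands into a {rows}x{cols} plane ({rows * cols} cells)"
        )
    return values.reshape(rows, cols)


def scale_spectral_plane(plane: np.ndarray) -> np.ndarray:
    """Per-sample min-max scale of the spectral plane to [0, 1]."""
    plane = np.asarray(plane, dtype=float)
    lo, hi = float(plane.min()), float(plane.max())
    if hi <= lo:
        raise DegenerateInputError("constant spectral plane cannot be scaled")
    return (plane - lo) / (hi - lo)


@dataclass
class FusedSample:
    """One 22x21x4 model input: channels (R, G, B, spectral) plus its label."""

    tensor: np.ndarray
    label: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 3 or self.tensor.shape[2] != 4:
            raise ShapeError(f"fused tensor must be (rows, cols, 4), got {self.tensor.shape}")
        if int(self.label) not in range(N_CLASSES):
            raise InvalidClassError(f"label {self.label} outside 0..{N_CLASSES - 1}")
        self.label = int(self.label)

    @property
    def rgb(self) -> np.ndarray:
        return self.tensor[:, :, :3]

    @property
    def spectral_plane(self) -> np.ndarray:
        return self.tensor[:, :, 3]


def fuse(
    rgb: np.ndarray,
    plane: np.ndarray,
    label: int,
    provenance: dict | None = None,
    scale: bool = True,
) -> FusedSample:
    """Concatenate RGB and the spectral plane along the channel axis.

    With ``scale=True`` (default) RGB is brought to [0, 1] (dividing by 255
    for 8-bit input) and the plane is min-max scaled per sample; with
    ``scale=False`` both are stacked as given.
    """
    rgb = np.asarray(rgb)
    plane = np.asarray(plane, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ShapeError(f"rgb must be (rows, cols, 3), got {rgb.shape}")
    if plane.shape != rgb.shape[:2]:
        raise ShapeError(f"spatial dims differ: rgb {rgb.shape[:2]} vs plane {plane.shape}")
    if scale:
        rgb = rgb.astype(float) / 255.0 if rgb.dtype == np.uint8 else rgb.astype(float)
        plane = scale_spectral_plane(plane)
    else:
        rgb = rgb.astype(float)
    tensor = np.concatenate([rgb, plane[:, :, None]], axis=2)
    return FusedSample(tensor=tensor, label=label, provenance=provenance or {})


def fuse_dataset(
    rgb_images: np.ndarray, spectra: np.ndarray, labels: np.ndarray
) -> list[FusedSample]:
    """Fuse aligned arrays of n downsampled RGB images and n spectra."""
    n = len(labels)
    if len(rgb_images) != n or len(spectra) != n:
        raise ShapeError(f"unequal sample counts: {len(rgb_images)} rgb, {len(spectra)} spectra, {n} labels")
    rows, cols = rgb_images[0].shape[:2]
    return [
        fuse(rgb_images[i], reshape_spectrum_2d(spectra[i], rows, cols), int(labels[i]),
             provenance={"index": i})
        for i in range(n)
    ]


def save_fused(samples: list[FusedSample], path: str | Path) -> None:
    """Persist fused tensors as one .npy stack with a JSON sidecar."""
    path = Path(path)
    tensors = np.stack([s.tensor for s in samples])
    np.save(path, tensors)
    sidecar = {
        "dims": list(tensors.shape),
        "channels": ["R", "G", "B", "spectral"],
        "scaling": "rgb unit range; spectral per-sample min-max",
        "labels": [s.label for s in samples],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_fused(path: str | Path) -> list[FusedSample]:
    path = Path(path)
    tensors = np.load(path.with_suffix(".npy"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return [
        FusedSample(tensor=t, label=lab)
        for t, lab in zip(tensors, sidecar["labels"], strict=True)
    ]
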