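"""NIfTI volume I/O, brain masking and FLAIR intensity normalization.

Conventions
-----------
* Grids are indexed ``(x, y, z)``: the last axis is the slice (z) axis and
  an axial slice is ``vol.intensities[:, :, z]``.  Voxel indices are 0-based.
* Multi-channel volumes carry a trailing channel axis ``(x, y, z, c)``.
* Label maps use ``0 = background/healthy``, ``1 = WMH``, ``2 = stroke``.

Normalization standardizes intensities to zero mean / unit standard
deviation computed over the brain mask (the "background" excluded from the
statistics is everything outside the mask), then saturates all standardized
values below −3 at −3 so every image shares a consistent background floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import nibabel as nib
from scipy import ndimage

#: Floor value of a normalized image: background voxels sit at (or above)
#: this value after standardization + clipping.  Also used to pad image
#: patches/slices that extend past the volume boundary.
BACKGROUND_FLOOR = -3.0

#: Default class names, index == integer label.
DEFAULT_CLASSES = ("background", "WMH", "stroke")


class DegenerateInputError(ValueError):
    """Raised when an input has no usable signal (constant image, empty mask)."""


@dataclass
class Volume:
    """A 3D (or multi-channel 4D) intensity grid with voxel spacing in mm."""

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channels: tuple[str, ...] = ("FLAIR",)
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim not in (3, 4):
            raise ValueError("intensities must be a 3D or 4D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive mm values")
        n_ch = self.intensities.shape[3] if self.intensities.ndim == 4 else 1
        if len(self.channels) != n_ch:
            # keep channel names consistent with the data
            self.channels = tuple(f"ch{i}" for i in range(n_ch)) if n_ch > 1 else ("FLAIR",)
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.grid_shape:
                raise ValueError("brain_mask shape must match the intensity grid")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[:3]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[3] if self.intensities.ndim == 4 else 1

    def channel_array(self) -> np.ndarray:
        """Intensities as a channel-first array ``(c, x, y, z)``."""
        if self.intensities.ndim == 3:
            return self.intensities[None]
        return np.moveaxis(self.intensities, -1, 0)

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabelMap:
    """Integer class grid on the same lattice as its Volume."""

    labels: np.ndarray
    class_names: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        c = len(self.class_names)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= c):
            raise ValueError(f"label values must lie in [0, {c - 1}]")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_mask(self, class_id: int) -> np.ndarray:
        return self.labels == class_id


def _affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def read_volume(path) -> Volume:
    """Read a NIfTI file into a :class:`Volume`.

    Spacing is taken from the header zooms; intensities are returned as
    stored (no scaling beyond NIfTI's own slope/intercept handling).  A 4D
    file is interpreted as one channel per 4th-dimension index.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(dtype=np.float32))
    except Exception as exc:  # nibabel raises several exception types
        raise IOError(f"cannot read NIfTI volume from {path!r}: {exc}") from exc
    zooms = img.header.get_zooms()[:3]
    if data.ndim == 4:
        channels = tuple(f"ch{i}" for i in range(data.shape[3]))
        return Volume(data, tuple(float(z) for z in zooms), channels)
    return Volume(data, tuple(float(z) for z in zooms))


def write_volume(vol: Volume, path) -> None:
    """Write a Volume to NIfTI with a diagonal affine built from its spacing."""
    img = nib.Nifti1Image(np.asarray(vol.intensities, dtype=np.float32),
                          _affine_from_spacing(vol.spacing))
    img.header.set_zooms(vol.spacing + ((1.0,) if vol.intensities.ndim == 4 else ()))
    nib.save(img, str(path))


def read_labelmap(path, class_names: tuple[str, ...] = DEFAULT_CLASSES) -> LabelMap:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj).astype(np.uint8)
    except Exception as exc:
        raise IOError(f"cannot read NIfTI label map from {path!r}: {exc}") from exc
    return LabelMap(data, class_names)


def write_labelmap(labels: LabelMap, spacing: tuple[float, float, float], path) -> None:
    img = nib.Nifti1Image(labels.labels.astype(np.uint8), _affine_from_spacing(spacing))
    nib.save(img, str(path))


def compute_brain_mask(vol: Volume, threshold_fraction: float = 0.5) -> np.ndarray:
    """Threshold-based brain mask.

    Voxels brighter than ``threshold_fraction`` times a robust maximum (the
    99th intensity percentile of the first channel) are kept; the largest
    connected foreground component is retained and per-slice holes (e.g.
    CSF-dark ventricles) are filled so the mask approximates the
    intracranial volume.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    data = vol.channel_array()[0]
    robust_max = float(np.percentile(data, 99))
    if np.ptp(data) == 0:
        raise DegenerateInputError("constant image: cannot compute a brain mask")
    mask = data > threshold_fraction * robust_max
    if not mask.any():
        raise DegenerateInputError("brain mask is empty at this threshold")
    labelled, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labelled, index=np.arange(1, n + 1))
        mask = labelled == (1 + int(np.argmax(sizes)))
    # fill in-plane holes slice by slice (thick-slice axial acquisitions)
    for z in range(mask.shape[2]):
        mask[:, :, z] = ndimage.binary_fill_holes(mask[:, :, z])
    return mask


def normalize_intensity(vol: Volume) -> Volume:
    """Standardize to zero mean / unit std over the brain mask, then clip.

    The mean and standard deviation are computed per channel over the brain
    mask *before* clipping; afterwards every voxel (background included)
    whose standardized value falls below −3 is saturated at −3, giving all
    images the same background floor.
    """
    if vol.brain_mask is None:
        raise DegenerateInputError("normalize_intensity requires a brain_mask")
    mask = vol.brain_mask
    if not mask.any():
        raise DegenerateInputError("brain mask is empty")
    chans = vol.channel_array().astype(np.float64)
    out = np.empty_like(chans, dtype=np.float32)
    for i, ch in enumerate(chans):
        inside = ch[mask]
        mu = inside.mean()
        sd = inside.std()
        if sd == 0:
            raise DegenerateInputError("zero intensity variance inside the brain mask")
        z = (ch - mu) / sd
        out[i] = np.maximum(z, BACKGROUND_FLOOR, dtype=np.float64).astype(np.float32)
    data = out[0] if vol.n_channels == 1 else np.moveaxis(out, 0, -1)
    return replace(vol, intensities=data)
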