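"""Synthetic FLAIR-like lesion phantoms with gold-standard labels.

The phantom emulates the statistical structure of clinical FLAIR acquisitions
used for WMH/stroke segmentation without attempting MR physics:

* axial-slice-stacked grids with anisotropic voxels (default 1 x 1 x 4 mm);
* an elliptical "brain" of unit tissue intensity on a zero background, with
  a dark central CSF-like region standing in for the ventricles;
* WMH-like lesions: irregular confluent clusters of small ellipsoidal blobs,
  placed preferentially along the ventricular boundary (periventricular)
  with the remainder scattered in deep tissue;
* stroke-like lesions: larger, brighter focal blobs in deep tissue;
* additive Gaussian noise.

Lesion contrasts are expressed in units of the noise standard deviation, so
the defaults below place WMH ~3 sigma and stroke ~4.5 sigma above normal
tissue -- clearly hyperintense, as on real FLAIR.  With the default lesion
counts and grid, background/healthy voxels make up >= 99% of the volume,
reproducing the extreme class imbalance this segmentation problem is known
for.  Everything is a deterministic function of the configured seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import (
    DEFAULT_CLASSES,
    LabelMap,
    Volume,
    write_labelmap,
    write_volume,
)


class PlacementError(RuntimeError):
    """Raised when a lesion cannot be placed after bounded retries."""


@dataclass
class PhantomConfig:
    """Parameters of a single synthetic case.

    Lesion intensity parameters are mean contrasts above normal tissue in
    units of ``noise_sigma``; size ranges are in-plane blob radii in voxels.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 12)
    spacing: tuple[float, float, float] = (1.0, 1.0, 4.0)
    n_wmh_lesions: int = 6
    n_stroke_lesions: int = 1
    wmh_intensity: float = 3.0
    stroke_intensity: float = 4.5
    wmh_size_range: tuple[float, float] = (1.5, 3.5)
    stroke_size_range: tuple[float, float] = (3.5, 6.5)
    noise_sigma: float = 0.1
    channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wmh_lesions < 0 or self.n_stroke_lesions < 0:
            raise ValueError("lesion counts must be >= 0")
        for lo, hi in (self.wmh_size_range, self.stroke_size_range):
            if lo <= 0 or hi < lo:
                raise ValueError("size ranges must be positive and ordered")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if min(self.grid_shape[:2]) < 32 or self.grid_shape[2] < 4:
            raise ValueError("grid too small to host a brain phantom")
        if self.channels not in (1, 2):
            raise ValueError("channels must be 1 (FLAIR) or 2 (FLAIR + pseudo-T1)")


_TISSUE = 1.0
_CSF = 0.25
_MAX_TRIES = 200


def _geometry(shape: tuple[int, int, int]):
    """Brain, ventricle and placement masks for the given grid."""
    nx, ny, nz = shape
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    brain = np.zeros(shape, dtype=bool)
    vent = np.zeros(shape, dtype=bool)
    for z in range(nz):
        taper = np.sqrt(max(0.05, 1.0 - ((z - cz) / (0.75 * nz)) ** 2))
        ax, ay = 0.44 * nx * taper, 0.44 * ny * taper
        brain[:, :, z] = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0
        if abs(z - cz) <= nz / 4:
            vx, vy = 0.10 * nx, 0.22 * ny
            vent[:, :, z] = ((x - cx) / vx) ** 2 + ((y - cy) / vy) ** 2 <= 1.0
    vent &= brain
    tissue = brain & ~vent
    # periventricular ring: tissue within a few voxels of the ventricle wall
    ring = ndimage.binary_dilation(vent, iterations=3) & tissue
    # deep tissue: away from both the brain edge and the ventricle
    deep = ndimage.binary_erosion(brain, iterations=5) & ~ndimage.binary_dilation(
        vent, iterations=2
    )
    return brain, vent, tissue, ring, deep


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    """Boolean mask of an axis-aligned ellipsoid (z radius in slices)."""
    cx, cy, cz = center
    rx, ry, rz = radii
    x0, x1 = max(0, int(cx - rx - 1)), min(shape[0], int(cx + rx + 2))
    y0, y1 = max(0, int(cy - ry - 1)), min(shape[1], int(cy + ry + 2))
    z0, z1 = max(0, int(cz - rz - 1)), min(shape[2], int(cz + rz + 2))
    out = np.zeros(shape, dtype=bool)
    if x0 >= x1 or y0 >= y1 or z0 >= z1:
        return out
    gx, gy, gz = np.meshgrid(
        np.arange(x0, x1), np.arange(y0, y1), np.arange(z0, z1), indexing="ij"
    )
    out[x0:x1, y0:y1, z0:z1] = (
        ((gx - cx) / rx) ** 2 + ((gy - cy) / ry) ** 2 + ((gz - cz) / rz) ** 2 <= 1.0
    )
    return out


def _place_wmh(rng, shape, ring, deep, tissue, size_range) -> np.ndarray:
    """One WMH lesion: a confluent cluster of 2-4 jittered blobs."""
    pool = ring if (rng.random() < 0.7 and ring.any()) else deep
    if not pool.any():
        pool = tissue
    coords = np.argwhere(pool)
    anchor = coords[rng.integers(len(coords))]
    mask = np.zeros(shape, dtype=bool)
    for _ in range(int(rng.integers(2, 5))):
        c = anchor + np.array(
            [rng.normal(0, 2.0), rng.normal(0, 2.0), rng.integers(-1, 2)]
        )
        rx = rng.uniform(*size_range)
        ry = rng.uniform(*size_range)
        rz = rng.uniform(0.5, 1.2)
        mask |= _ellipsoid_mask(shape, c, (rx, ry, rz))
    return mask & tissue


def _place_stroke(rng, shape, deep, tissue, size_range, forbidden) -> np.ndarray:
    """One stroke lesion: a larger focal blob (plus satellites), off-lesion."""
    pool = deep & ~ndimage.binary_dilation(forbidden, iterations=2)
    if not pool.any():
        pool = deep if deep.any() else tissue
    coords = np.argwhere(pool)
    for _ in range(_MAX_TRIES):
        anchor = coords[rng.integers(len(coords))]
        rx = rng.uniform(*size_range)
        ry = rng.uniform(*size_range)
        rz = rng.uniform(0.8, 1.6)
        mask = _ellipsoid_mask(shape, anchor, (rx, ry, rz))
        for _ in range(int(rng.integers(1, 3))):  # satellite bumps
            c = anchor + np.array(
                [rng.normal(0, rx / 2), rng.normal(0, ry / 2), 0]
            )
            mask |= _ellipsoid_mask(
                shape, c, (rx * 0.5, ry * 0.5, max(0.6, rz * 0.6))
            )
        mask &= tissue
        if mask.any() and not (mask & forbidden).any():
            return mask
    raise PlacementError("could not place a stroke lesion away from existing lesions")


def generate_phantom(cfg: PhantomConfig) -> tuple[Volume, LabelMap]:
    """Generate one synthetic case: FLAIR-like volume plus label map."""
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.grid_shape)
    brain, vent, tissue, ring, deep = _geometry(shape)

    image = np.zeros(shape, dtype=np.float64)
    image[brain] = _TISSUE
    image[vent] = _CSF

    labels = np.zeros(shape, dtype=np.uint8)
    contrast = np.zeros(shape, dtype=np.float64)
    for _ in range(cfg.n_wmh_lesions):
        for attempt in range(_MAX_TRIES):
            m = _place_wmh(rng, shape, ring, deep, tissue, cfg.wmh_size_range)
            if m.any():
                break
        else:
            raise PlacementError("could not place a WMH lesion")
        labels[m] = 1
        contrast[m] = cfg.wmh_intensity * cfg.noise_sigma
    wmh_mask = labels == 1
    for _ in range(cfg.n_stroke_lesions):
        m = _place_stroke(rng, shape, deep, tissue, cfg.stroke_size_range, wmh_mask)
        labels[m] = 2
        contrast[m] = cfg.stroke_intensity * cfg.noise_sigma

    # soften in-plane lesion edges slightly; labels stay crisp
    contrast = ndimage.gaussian_filter(contrast, sigma=(0.5, 0.5, 0.0))
    image += contrast
    image += rng.normal(0.0, cfg.noise_sigma, shape)

    if cfg.channels == 2:
        # pseudo-T1: CSF dark, lesions mildly hypo-intense relative to tissue
        t1 = np.zeros(shape, dtype=np.float64)
        t1[brain] = _TISSUE
        t1[vent] = 0.35
        t1 -= 0.5 * contrast
        t1 += rng.normal(0.0, cfg.noise_sigma, shape)
        data = np.stack([image, t1], axis=-1).astype(np.float32)
        vol = Volume(data, cfg.spacing, ("FLAIR", "pseudo-T1"))
    else:
        vol = Volume(image.astype(np.float32), cfg.spacing)
    return vol, LabelMap(labels, DEFAULT_CLASSES)


def generate_cohort(
    n_cases: int,
    cfg: PhantomConfig = PhantomConfig(),
    stroke_fraction: float = 0.35,
    seed: int = 0,
) -> list[tuple[Volume, LabelMap]]:
    """Generate a cohort of cases; all contain WMH, a fixed fraction stroke.

    ``round(stroke_fraction * n_cases)`` cases carry stroke lesions, the rest
    are WMH-only, mirroring typical mixed stroke-service cohorts.  Per-case
    seeds (and a mild +/-2 variation of the WMH lesion count, for volume
    variability across cases) are derived deterministically from ``seed``.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not 0.0 <= stroke_fraction <= 1.0:
        raise ValueError("stroke_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_stroke = int(round(stroke_fraction * n_cases))
    stroke_cases = set(rng.permutation(n_cases)[:n_stroke].tolist())
    cases = []
    for i in range(n_cases):
        n_wmh = max(1, cfg.n_wmh_lesions + int(rng.integers(-2, 3)))
        case_cfg = replace(
            cfg,
            seed=int(rng.integers(2**31)),
            n_wmh_lesions=n_wmh,
            n_stroke_lesions=cfg.n_stroke_lesions if i in stroke_cases else 0,
        )
        cases.append(generate_phantom(case_cfg))
    return cases


def write_cohort(cases, out_dir) -> pd.DataFrame:
    """Write image/label NIfTI pairs plus a TSV manifest; returns the manifest."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, (vol, labels) in enumerate(cases):
        case_id = f"case{i:03d}"
        img_path = os.path.join(out_dir, f"{case_id}_flair.nii.gz")
        lab_path = os.path.join(out_dir, f"{case_id}_labels.nii.gz")
        write_volume(vol, img_path)
        write_labelmap(labels, vol.spacing, lab_path)
        counts = np.bincount(labels.labels.ravel(), minlength=labels.n_classes)
        rows.append(
            {
                "case_id": case_id,
                "image": img_path,
                "labels": lab_path,
                "n_background": int(counts[0]),
                "n_wmh": int(counts[1]),
                "n_stroke": int(counts[2]),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    return manifest
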