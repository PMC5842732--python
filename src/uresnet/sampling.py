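"""Lesion-centred, jittered patch extraction.

Training uses in-plane patches (default 64x64) instead of dense whole-slice
training to counter the ~99.8% background class imbalance.  Patch centers
are drawn without replacement from a fraction of the WMH voxel locations
(default 20%) and of the stroke voxel locations (default 80%), then each
center is shifted by an independent integer jitter Delta_{x,y} drawn
uniformly from [-jitter, +jitter] per in-plane axis (default jitter = half
the patch size) so lesions can occur anywhere in a patch rather than always
at its center.  The slice index is never jittered.

Window geometry: an even-sized window has no central voxel, so the window
is anchored on the half-voxel boundary rounded toward the source voxel
(for a negative shift the stored center moves one voxel over).  This makes
the originating lesion voxel fall inside the window for *every* shift with
|Delta| <= patch_size/2, including both endpoints, which in turn guarantees
every extracted label patch contains at least one lesion voxel.  Windows
crossing the volume boundary are padded (image: background floor; labels:
class 0) rather than rejected, keeping the sampling fractions exact.

The patch set is drawn once and kept fixed across epochs (an epoch is one
pass over the extracted patches).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume_io import BACKGROUND_FLOOR, LabelMap, Volume


@dataclass
class SamplerConfig:
    """Patch sampling parameters."""

    patch_size: int = 64
    wmh_fraction: float = 0.20
    stroke_fraction: float = 0.80
    jitter: int | None = None  # default: patch_size // 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size % 2 or self.patch_size < 8:
            raise ValueError("patch_size must be even and >= 8")
        for f in (self.wmh_fraction, self.stroke_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("sampling fractions must lie in [0, 1]")
        if self.jitter is None:
            self.jitter = self.patch_size // 2
        if not 0 <= self.jitter <= self.patch_size // 2:
            raise ValueError("jitter must lie in [0, patch_size/2]")


@dataclass
class PatchSet:
    """Paired image/label patches treated as independent training samples."""

    images: np.ndarray  # (K, channels, P, P) float32
    labels: np.ndarray  # (K, P, P) uint8
    provenance: pd.DataFrame  # case_id, slice, center_x/y, delta_x/y

    def __len__(self) -> int:
        return self.images.shape[0]

    @staticmethod
    def concatenate(sets: list["PatchSet"]) -> "PatchSet":
        return PatchSet(
            np.concatenate([s.images for s in sets]),
            np.concatenate([s.labels for s in sets]),
            pd.concat([s.provenance for s in sets], ignore_index=True),
        )

    def save(self, path) -> None:
        """Cache to a compressed archive (grids + provenance table)."""
        np.savez_compressed(
            path,
            images=self.images,
            labels=self.labels,
            provenance=self.provenance.to_records(index=False),
        )

    @staticmethod
    def load(path) -> "PatchSet":
        with np.load(path, allow_pickle=True) as d:
            return PatchSet(
                d["images"], d["labels"], pd.DataFrame.from_records(d["provenance"])
            )


def select_centers(labels: LabelMap, cfg: SamplerConfig) -> np.ndarray:
    """Voxel coordinates (K, 3) of sampled lesion locations.

    floor(wmh_fraction * #WMH) coordinates drawn uniformly without
    replacement from WMH voxels, plus floor(stroke_fraction * #stroke) from
    stroke voxels; deterministic given the config seed.  Empty classes
    simply contribute zero centers.
    """
    rng = np.random.default_rng(cfg.seed)
    out = []
    for class_id, frac in ((1, cfg.wmh_fraction), (2, cfg.stroke_fraction)):
        coords = np.argwhere(labels.labels == class_id)
        k = int(frac * len(coords))
        if k > 0:
            out.append(coords[rng.choice(len(coords), size=k, replace=False)])
    if not out:
        return np.empty((0, 3), dtype=np.int64)
    return np.concatenate(out).astype(np.int64)


def jitter_centers(centers: np.ndarray, cfg: SamplerConfig):
    """Apply independent in-plane integer shifts to patch centers.

    Returns ``(shifted_centers, deltas)`` where each delta component is
    drawn uniformly from the inclusive range [-jitter, +jitter].  The
    stored center is nudged one voxel for negative shifts (half-voxel
    anchor rounding, see module docstring) so that the 64x64 window at the
    shifted center always contains the originating voxel.  Slice indices
    are unchanged.
    """
    centers = np.asarray(centers, dtype=np.int64)
    rng = np.random.default_rng(cfg.seed + 1)
    j = cfg.jitter
    deltas = rng.integers(-j, j + 1, size=(len(centers), 2))
    shifted = centers.copy()
    shifted[:, :2] += deltas + (deltas < 0)
    return shifted, deltas


def window_start(center: int, patch_size: int) -> int:
    """First index of the extraction window along one in-plane axis."""
    return center - patch_size // 2


def extract_patches(
    vol: Volume,
    labels: LabelMap,
    centers: np.ndarray,
    cfg: SamplerConfig,
    deltas: np.ndarray | None = None,
    case_id: str = "case",
) -> PatchSet:
    """Extract in-plane image/label windows at the given (jittered) centers.

    Image windows extending past the volume boundary are padded with the
    normalized background floor, label windows with class 0.  Every label
    patch is asserted to contain at least one lesion voxel -- guaranteed by
    the jitter window geometry, so a violation is a programming error.
    """
    p = cfg.patch_size
    chans = vol.channel_array()
    lab = labels.labels
    nx, ny, _ = vol.grid_shape
    if deltas is None:
        deltas = np.zeros((len(centers), 2), dtype=np.int64)
    images = np.full((len(centers), chans.shape[0], p, p), BACKGROUND_FLOOR,
                     dtype=np.float32)
    lpatches = np.zeros((len(centers), p, p), dtype=np.uint8)
    rows = []
    for i, (cx, cy, cz) in enumerate(np.asarray(centers, dtype=np.int64)):
        x0, y0 = window_start(cx, p), window_start(cy, p)
        sx0, sx1 = max(0, x0), min(nx, x0 + p)
        sy0, sy1 = max(0, y0), min(ny, y0 + p)
        dx0, dy0 = sx0 - x0, sy0 - y0
        images[i, :, dx0 : dx0 + sx1 - sx0, dy0 : dy0 + sy1 - sy0] = chans[
            :, sx0:sx1, sy0:sy1, cz
        ]
        lpatches[i, dx0 : dx0 + sx1 - sx0, dy0 : dy0 + sy1 - sy0] = lab[
            sx0:sx1, sy0:sy1, cz
        ]
        assert (lpatches[i] > 0).any(), "patch without lesion voxels: jitter bound violated"
        rows.append(
            {
                "case_id": case_id,
                "slice": int(cz),
                "center_x": int(cx),
                "center_y": int(cy),
                "delta_x": int(deltas[i, 0]),
                "delta_y": int(deltas[i, 1]),
            }
        )
    return PatchSet(images, lpatches, pd.DataFrame(
        rows, columns=["case_id", "slice", "center_x", "center_y",
                       "delta_x", "delta_y"]))


def sample_patches(
    vol: Volume, labels: LabelMap, cfg: SamplerConfig, case_id: str = "case"
) -> PatchSet:
    """Full per-case pipeline: select -> jitter -> extract."""
    centers = select_centers(labels, cfg)
    shifted, deltas = jitter_centers(centers, cfg)
    return extract_patches(vol, labels, shifted, cfg, deltas, case_id)


def sample_cohort(
    cases: list[tuple[Volume, LabelMap]], cfg: SamplerConfig,
    case_ids: list[str] | None = None,
) -> PatchSet:
    """Pool patches over a cohort, with per-case seeds derived from cfg.seed."""
    from dataclasses import replace

    rng = np.random.default_rng(cfg.seed)
    sets = []
    for i, (vol, labels) in enumerate(cases):
        cid = case_ids[i] if case_ids is not None else f"case{i:03d}"
        sub = replace(cfg, seed=int(rng.integers(2**31)))
        s = sample_patches(vol, labels, sub, cid)
        if len(s):
            sets.append(s)
    if not sets:
        p = cfg.patch_size
        return PatchSet(
            np.empty((0, cases[0][0].n_channels, p, p), dtype=np.float32),
            np.empty((0, p, p), dtype=np.uint8),
            pd.DataFrame(columns=["case_id", "slice", "center_x", "center_y",
                                  "delta_x", "delta_y"]),
        )
    return PatchSet.concatenate(sets)


def augment_flips(patches: PatchSet, seed: int = 0) -> PatchSet:
    """Left-right flip each patch independently with probability 0.5.

    Image and label patches are flipped identically (last in-plane axis);
    deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    flip = rng.random(len(patches)) < 0.5
    images = patches.images.copy()
    labels = patches.labels.copy()
    images[flip] = images[flip][..., ::-1]
    labels[flip] = labels[flip][..., ::-1]
    prov = patches.provenance.copy()
    prov["flipped"] = flip
    return PatchSet(images, labels, prov)
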