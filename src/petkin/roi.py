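"""Threshold region-growing ROI extraction on dynamic volumes.

Mirrors the image-processing step used to delineate a hot lesion: all
frames of the dynamic scan are summed, a region is grown from the hottest
voxel, keeping only voxels with uptake strictly greater than 50% of the
maximum value within the grown region, and the resulting 3-D mask is
applied to the original frames to read out the time-activity curve.

Connectivity is 6-neighbour (faces only) by default; the threshold is
relative, so the mask is invariant under global intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .tac import TimeActivityCurve

__all__ = [
    "DynamicVolume",
    "RoiMask",
    "sum_frames",
    "grow_roi",
    "extract_tac",
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
]


@dataclass(frozen=True)
class DynamicVolume:
    """4-D dynamic volume: frames x z x y x x, activity in kBq/ml."""

    voxels: np.ndarray
    frame_times: np.ndarray  # frame midpoints, min
    voxel_volume: float = 1.0  # ml
    frame_durations: np.ndarray | None = None

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 4 or vox.shape[0] == 0:
            raise ValueError("voxels must be a nonempty 4-D array (frames, z, y, x)")
        if np.any(vox < 0):
            raise ValueError("negative voxel values")
        ft = np.asarray(self.frame_times, dtype=float)
        if ft.size != vox.shape[0]:
            raise ValueError("frame_times length must match the frame axis")
        if ft.size > 1 and np.any(np.diff(ft) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        fd = self.frame_durations
        if fd is not None:
            fd = np.asarray(fd, dtype=float)
            if fd.size != ft.size or np.any(fd <= 0):
                raise ValueError("invalid frame_durations")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "frame_times", ft)
        object.__setattr__(self, "frame_durations", fd)

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]


@dataclass(frozen=True)
class RoiMask:
    """Boolean 3-D mask; a single 6-connected component containing the seed."""

    mask: np.ndarray
    seed: tuple

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 3 or not m.any():
            raise ValueError("mask must be a nonempty 3-D boolean array")
        object.__setattr__(self, "mask", m)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def sum_frames(vol: DynamicVolume, duration_weighted: bool = False) -> np.ndarray:
    """Voxelwise sum across frames.

    With ``duration_weighted`` each frame is weighted by its duration,
    yielding the time-integral of the voxel time courses.
    """
    if duration_weighted:
        if vol.frame_durations is None:
            raise ValueError("duration weighting requires frame_durations")
        w = vol.frame_durations
        return np.tensordot(w, vol.voxels, axes=(0, 0))
    return vol.voxels.sum(axis=0)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def grow_roi(
    summed: np.ndarray,
    seed: tuple | None = None,
    threshold_frac: float = 0.5,
    connectivity: int = 6,
) -> RoiMask:
    """Grow a region from the seed over voxels above a relative threshold.

    Voxels are kept when strictly greater than ``threshold_frac`` times the
    maximum value within the grown region; the reference maximum starts at
    the seed value and is iterated to a fixpoint, so the threshold tracks
    the lesion maximum rather than the seed.  ``seed`` defaults to the
    global maximum voxel.
    """
    summed = np.asarray(summed, dtype=float)
    if summed.ndim != 3:
        raise ValueError("summed must be 3-D")
    structure = _STRUCTURES.get(connectivity)
    if structure is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    if not 0 <= threshold_frac < 1:
        raise ValueError("threshold_frac must be in [0, 1)")
    if seed is None:
        seed = np.unravel_index(int(np.argmax(summed)), summed.shape)
    seed = tuple(int(i) for i in seed)
    if summed[seed] <= 0:
        raise ValueError("seed voxel has no uptake")
    region_max = float(summed[seed])
    mask = None
    for _ in range(100):  # fixpoint loop; monotone, terminates quickly
        above = summed > threshold_frac * region_max
        above[seed] = True  # seed always belongs to its own region
        labels, _ = ndimage.label(above, structure=structure)
        new_mask = labels == labels[seed]
        new_max = float(summed[new_mask].max())
        if mask is not None and np.array_equal(new_mask, mask) and new_max == region_max:
            break
        mask, region_max = new_mask, new_max
    if summed[seed] <= threshold_frac * region_max:
        raise ValueError(
            f"seed value {summed[seed]:g} is below the threshold "
            f"{threshold_frac:g} x region max {region_max:g}"
        )
    return RoiMask(mask=mask, seed=seed)


def extract_tac(vol: DynamicVolume, roi: RoiMask, label: str = "roi") -> TimeActivityCurve:
    """Per-frame mean concentration over the mask voxels."""
    if roi.mask.shape != vol.voxels.shape[1:]:
        raise ValueError("mask shape does not match the volume frames")
    values = vol.voxels[:, roi.mask].mean(axis=1)
    return TimeActivityCurve(
        vol.frame_times, values, frame_durations=vol.frame_durations, label=label
    )


def save_volume(vol: DynamicVolume, path) -> None:
    """Write the 4-D volume as NIfTI (x, y, z, t axis order)."""
    img = nib.Nifti1Image(np.transpose(vol.voxels, (3, 2, 1, 0)), affine=np.eye(4))
    nib.save(img, str(path))


def load_volume(path, frame_times, voxel_volume=1.0, frame_durations=None) -> DynamicVolume:
    data = np.asanyarray(nib.load(str(path)).dataobj)
    return DynamicVolume(
        np.transpose(data, (3, 2, 1, 0)), frame_times, voxel_volume, frame_durations
    )


def save_mask(roi: RoiMask, path) -> None:
    img = nib.Nifti1Image(
        np.transpose(roi.mask.astype(np.uint8), (2, 1, 0)), affine=np.eye(4)
    )
    nib.save(img, str(path))


def load_mask(path, seed=(0, 0, 0)) -> RoiMask:
    data = np.asanyarray(nib.load(str(path)).dataobj) > 0
    return RoiMask(mask=np.transpose(data, (2, 1, 0)), seed=tuple(seed))
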