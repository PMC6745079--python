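"""ROI operations for graft-region analysis on multi-echo volumes.

Regions along an ACL graft are boolean voxel masks on the image grid (1 mm
isotropic by default).  The operations mirror the quantitative workflow:
per-ROI mean decay curves, construction of the graft/bone interface by a
2 mm Euclidean dilation of the intra-bone graft, ROI orientation relative to
the main field B0 (line of best fit through per-slice centroids), the Dice
similarity coefficient, and the symmetric intra-rater relative error.

The B0 axis is never inferred from image metadata: it is an explicit field of
:class:`VoxelMask` (default: array axis 2, scanner z).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .estimation import DecayCurve
from .signal_model import EchoSchedule

__all__ = [
    "VoxelMask",
    "roi_mean_curve",
    "grow_interface",
    "angle_to_b0",
    "dice",
    "intra_rater_error",
]


@dataclass(frozen=True)
class VoxelMask:
    """A labelled 3D boolean ROI with physical voxel size.

    voxel_size
        mm per axis (3-tuple), all positive.
    b0_axis
        array axis pointing along the scanner's main field (default 2).
    """

    grid: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b0_axis: int = 2
    label: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=bool)
        if g.ndim != 3:
            raise ValueError("mask grid must be 3D")
        vs = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in vs):
            raise ValueError("voxel size must be positive")
        if self.b0_axis not in (0, 1, 2):
            raise ValueError("b0_axis must be 0, 1 or 2")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "voxel_size", vs)

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    def to_nifti(self, path, affine=None) -> None:
        import nibabel as nib

        if affine is None:
            affine = np.diag([*self.voxel_size, 1.0])
        nib.save(nib.Nifti1Image(self.grid.astype(np.uint8), affine), str(path))

    @classmethod
    def from_nifti(cls, path, b0_axis: int = 2, label: str = "") -> "VoxelMask":
        import nibabel as nib

        img = nib.load(str(path))
        vs = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj) > 0, vs, b0_axis, label)


def roi_mean_curve(
    volumes, mask: VoxelMask, schedule: EchoSchedule
) -> DecayCurve:
    """Mean signal inside the mask at each echo, as a decay curve.

    ``volumes`` is a sequence of 3D arrays, one per echo time of the schedule
    (ascending order), all sharing the mask's grid.
    """
    tes = schedule.all_tes
    if len(volumes) != tes.size:
        raise ValueError(f"expected {tes.size} volumes, got {len(volumes)}")
    if mask.n_voxels == 0:
        raise ValueError("empty ROI mask")
    means = []
    for vol in volumes:
        vol = np.asarray(vol, dtype=float)
        if vol.shape != mask.grid.shape:
            raise ValueError("volume grid does not match mask grid")
        means.append(float(vol[mask.grid].mean()))
    return DecayCurve(tes, np.array(means), schedule.name)


def _ball_structure(radius_mm: float, voxel_size) -> np.ndarray:
    """Euclidean-ball structuring element in voxel units for anisotropic voxels."""
    half = [int(np.floor(radius_mm / v)) for v in voxel_size]
    zz = [np.arange(-h, h + 1) * v for h, v in zip(half, voxel_size)]
    X, Y, Z = np.meshgrid(*zz, indexing="ij")
    return X**2 + Y**2 + Z**2 <= radius_mm**2 + 1e-9


def grow_interface(graft: VoxelMask, radius_mm: float = 2.0) -> VoxelMask:
    """Interface shell: dilate the graft by ``radius_mm`` and remove the graft.

    Dilation is by a Euclidean ball in physical mm (3D).  The result is
    disjoint from the input by construction.
    """
    if graft.n_voxels == 0:
        raise ValueError("empty graft mask")
    if radius_mm < min(graft.voxel_size):
        raise ValueError("radius must be at least one voxel")
    structure = _ball_structure(radius_mm, graft.voxel_size)
    dilated = ndimage.binary_dilation(graft.grid, structure=structure)
    return replace(
        graft,
        grid=dilated & ~graft.grid,
        label=(graft.label + "/interface").lstrip("/"),
    )


def _slice_centroids(mask: VoxelMask, slice_axis: int) -> np.ndarray:
    """Physical-space centroids (mm) of each non-empty slice along slice_axis."""
    pts = []
    n_slices = mask.grid.shape[slice_axis]
    for k in range(n_slices):
        sl = np.take(mask.grid, k, axis=slice_axis)
        if not sl.any():
            continue
        ij = np.argwhere(sl).mean(axis=0)
        idx = np.empty(3)
        other = [a for a in range(3) if a != slice_axis]
        idx[slice_axis] = k
        idx[other[0]], idx[other[1]] = ij
        pts.append(idx * np.asarray(mask.voxel_size))
    return np.asarray(pts)


def angle_to_b0(mask: VoxelMask, slice_axis: int | None = None) -> float:
    """Angle (degrees, in [0, 90]) between the ROI's long axis and B0.

    Computes the centroid of the in-plane mask on every slice along
    ``slice_axis`` (default: the B0 axis), fits a 3D line through the
    centroids by total least squares (principal component), and returns the
    acute angle between that line and the B0 direction.
    """
    if slice_axis is None:
        slice_axis = mask.b0_axis
    pts = _slice_centroids(mask, slice_axis)
    if pts.shape[0] < 2:
        raise ValueError("mask must span at least 2 slices along the slice axis")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    b0 = np.zeros(3)
    b0[mask.b0_axis] = 1.0
    cosang = np.clip(np.abs(direction @ b0) / np.linalg.norm(direction), 0.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dice(a: VoxelMask, b: VoxelMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|)."""
    if a.grid.shape != b.grid.shape:
        raise ValueError("masks must share a grid")
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        raise ValueError("both masks are empty")
    return float(2.0 * np.logical_and(a.grid, b.grid).sum() / (na + nb))


def intra_rater_error(est1, est2) -> dict[str, float]:
    """Symmetric relative percent difference between two repeated estimates.

    ``|x1 - x2| / mean(x1, x2) * 100`` for each of t2s and f_bw.  Accepts any
    pair of objects with ``t2s`` and ``f_bw`` attributes (e.g. corrected
    estimates from two ROI placements of the same region).
    """
    out = {}
    for attr in ("t2s", "f_bw"):
        x1, x2 = getattr(est1, attr), getattr(est2, attr)
        if x1 <= 0 or x2 <= 0:
            raise ValueError(f"{attr} values must be positive")
        out[f"rel_err_{attr}_pct"] = float(200.0 * abs(x1 - x2) / (x1 + x2))
    return out
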