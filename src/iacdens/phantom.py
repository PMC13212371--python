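"""Synthetic CT phantoms with calcific inserts of known ground truth.

A phantom is a 3D Hounsfield-unit volume of soft-tissue-like background
noise into which geometric calcific inserts (spheres, ellipsoids, shells)
are stamped, one or more per intracranial artery.  Because every insert's
geometry and HU profile are known analytically, the phantom provides exact
ground truth against which the quantification engine can be tested without
any real scan.

Voxel membership in an insert is decided by the voxel-center-inside-shape
rule, the simplest deterministic convention; it also makes partial-volume
behaviour at thick (3 mm) slices directly observable: the realized
(voxel-counted) volume differs from the analytic shape volume and
converges to it as the slice thickness shrinks.

HU values are rounded to integers, emulating CT storage, and background
noise is clipped below the 130-HU detection floor by default so phantoms
contain no spurious calcification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .quantify import ARTERY_IDS, DETECTION_FLOOR_HU, assign_density_category, category_label

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "VoxelGrid",
    "CalcInsert",
    "PhantomTruth",
    "generate_phantom",
    "truth_table",
    "write_nifti",
    "read_nifti",
]

HU_MIN = -1024
HU_MAX = 3071


@dataclass
class VoxelGrid:
    """3D HU volume with physical voxel spacing (mm) and origin (mm).

    Voxel (i, j, k) has its center at ``origin + (i*dx, j*dy, k*dz)``,
    matching the diagonal NIfTI affine the grid is written with.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or 0 in self.data.shape:
            raise ValueError(f"data must be a non-empty 3D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(v) for v in self.origin)
        if self.data.min() < HU_MIN or self.data.max() > HU_MAX:
            raise ValueError(f"HU values outside [{HU_MIN}, {HU_MAX}]")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class CalcInsert:
    """One geometric calcific insert.

    ``hu_profile`` is either ``("uniform", value)`` or
    ``("graded", core_hu, rim_hu)``; a graded insert ramps linearly in
    normalized radius from ``core_hu`` at the center to ``rim_hu`` at the
    surface.  A ``shell`` occupies normalized radii in
    ``(inner_fraction, 1]`` of the bounding ellipsoid.
    """

    artery_id: str
    center_mm: Tuple[float, float, float]
    shape: str  # sphere | ellipsoid | shell
    radii_mm: Tuple[float, float, float]
    hu_profile: tuple = ("uniform", 300.0)
    inner_fraction: float = 0.6  # shells only

    def __post_init__(self) -> None:
        if self.artery_id not in ARTERY_IDS:
            raise ValueError(f"unknown artery_id {self.artery_id!r}; expected one of {ARTERY_IDS}")
        if self.shape not in ("sphere", "ellipsoid", "shell"):
            raise ValueError(f"unknown shape {self.shape!r}")
        self.radii_mm = tuple(float(r) for r in self.radii_mm)
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("radii must be strictly positive")
        if self.shape == "sphere" and len(set(self.radii_mm)) != 1:
            raise ValueError("sphere requires equal radii on all axes")
        kind = self.hu_profile[0]
        if kind == "uniform":
            pass
        elif kind == "graded":
            core, rim = self.hu_profile[1], self.hu_profile[2]
            if core < rim:
                raise ValueError(f"graded profile requires core_hu >= rim_hu, got {core} < {rim}")
        else:
            raise ValueError(f"unknown hu_profile kind {kind!r}")
        if self.shape == "shell" and not (0.0 < self.inner_fraction < 1.0):
            raise ValueError("inner_fraction must lie in (0, 1)")

    # --- analytic ground truth -------------------------------------------

    @property
    def true_volume_mm3(self) -> float:
        """Analytic shape volume (continuous geometry, not voxel-counted)."""
        rx, ry, rz = self.radii_mm
        full = 4.0 / 3.0 * math.pi * rx * ry * rz
        if self.shape == "shell":
            return full * (1.0 - self.inner_fraction**3)
        return full

    @property
    def true_mean_hu(self) -> float:
        """Volume-weighted analytic mean HU of the continuous shape."""
        if self.hu_profile[0] == "uniform":
            return float(self.hu_profile[1])
        core, rim = float(self.hu_profile[1]), float(self.hu_profile[2])
        # E[r] over a uniform ellipsoid is 3/4; over a shell (f, 1] it is
        # (3/4) * (1 - f^4) / (1 - f^3).
        if self.shape == "shell":
            f = self.inner_fraction
            mean_r = 0.75 * (1.0 - f**4) / (1.0 - f**3)
        else:
            mean_r = 0.75
        return rim + (core - rim) * (1.0 - mean_r)

    # --- discrete geometry ------------------------------------------------

    def normalized_radius(self, coords: np.ndarray) -> np.ndarray:
        """Normalized elliptic radius of physical points (n, 3), in mm."""
        rel = (np.asarray(coords, dtype=float) - np.asarray(self.center_mm)) / np.asarray(
            self.radii_mm
        )
        return np.sqrt((rel**2).sum(axis=-1))

    def contains(self, coords: np.ndarray) -> np.ndarray:
        r = self.normalized_radius(coords)
        if self.shape == "shell":
            return (r > self.inner_fraction) & (r <= 1.0)
        return r <= 1.0

    def hu_at(self, coords: np.ndarray) -> np.ndarray:
        """HU of the insert profile at physical points (before rounding)."""
        if self.hu_profile[0] == "uniform":
            return np.full(len(np.atleast_2d(coords)), float(self.hu_profile[1]))
        core, rim = float(self.hu_profile[1]), float(self.hu_profile[2])
        r = np.clip(self.normalized_radius(coords), 0.0, 1.0)
        return rim + (core - rim) * (1.0 - r)


@dataclass
class PhantomTruth:
    """Full specification of a phantom: inserts plus background model."""

    inserts: list = field(default_factory=list)
    background_hu_mean: float = 40.0
    background_hu_sd: float = 10.0
    background_clip_max: float = DETECTION_FLOOR_HU - 1  # no spurious calcification
    seed: int = 0


def _voxel_centers(grid_shape, spacing, origin, index_arrays):
    """Physical mm coordinates of voxel centers for given index arrays."""
    sp = np.asarray(spacing, dtype=float)
    org = np.asarray(origin, dtype=float)
    idx = np.stack(index_arrays, axis=-1).astype(float)
    return org + idx * sp


def _insert_bounding_slices(insert: CalcInsert, grid_shape, spacing, origin):
    lo, hi = [], []
    for ax in range(3):
        c = insert.center_mm[ax] - origin[ax]
        r = insert.radii_mm[ax]
        i0 = int(np.floor((c - r) / spacing[ax]))
        i1 = int(np.ceil((c + r) / spacing[ax]))
        lo.append(max(i0, 0))
        hi.append(min(i1 + 1, grid_shape[ax]))
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def _insert_in_grid(insert: CalcInsert, grid_shape, spacing, origin) -> bool:
    for ax in range(3):
        lo = insert.center_mm[ax] - insert.radii_mm[ax]
        hi = insert.center_mm[ax] + insert.radii_mm[ax]
        if lo < origin[ax] or hi > origin[ax] + (grid_shape[ax] - 1) * spacing[ax]:
            return False
    return True


def _insert_membership(insert, grid_shape, spacing, origin) -> np.ndarray:
    """Boolean voxel-membership array for one insert (voxel-center rule)."""
    member = np.zeros(grid_shape, dtype=bool)
    sl = _insert_bounding_slices(insert, grid_shape, spacing, origin)
    ii, jj, kk = np.meshgrid(
        np.arange(sl[0].start, sl[0].stop),
        np.arange(sl[1].start, sl[1].stop),
        np.arange(sl[2].start, sl[2].stop),
        indexing="ij",
    )
    coords = _voxel_centers(grid_shape, spacing, origin, (ii, jj, kk))
    inside = insert.contains(coords.reshape(-1, 3)).reshape(ii.shape)
    member[sl] = inside
    return member


def generate_phantom(
    spec: PhantomTruth,
    grid_shape: Tuple[int, int, int],
    spacing: Tuple[float, float, float] = (0.6, 0.6, 3.0),
    seed: Optional[int] = None,
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0),
    mask_margin_mm: float = 1.2,
):
    """Render a phantom spec into a HU grid plus per-artery ROI masks.

    Returns ``(VoxelGrid, masks)`` where ``masks`` maps each artery_id with
    at least one insert to a boolean array covering its inserts plus a
    soft-tissue margin of ``mask_margin_mm`` (dilation per axis).

    Raises ``ValueError`` if any insert does not fit inside the grid,
    naming the offending insert.
    """
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    grid_shape = tuple(int(s) for s in grid_shape)
    if seed is None:
        seed = spec.seed

    for i, ins in enumerate(spec.inserts):
        if not _insert_in_grid(ins, grid_shape, spacing, origin):
            raise ValueError(
                f"insert {i} ({ins.artery_id}, {ins.shape} at {ins.center_mm} mm) "
                f"does not fit inside grid {grid_shape} at spacing {spacing}"
            )

    rng = np.random.default_rng(seed)
    data = rng.normal(spec.background_hu_mean, spec.background_hu_sd, size=grid_shape)
    data = np.clip(data, HU_MIN, spec.background_clip_max)
    data = np.rint(data).astype(np.int16)

    memberships = []
    for ins in spec.inserts:
        member = _insert_membership(ins, grid_shape, spacing, origin)
        idx = np.argwhere(member)
        if idx.size:
            coords = _voxel_centers(grid_shape, spacing, origin, (idx[:, 0], idx[:, 1], idx[:, 2]))
            hu = np.rint(np.clip(ins.hu_at(coords), HU_MIN, HU_MAX)).astype(np.int16)
            data[idx[:, 0], idx[:, 1], idx[:, 2]] = hu
        memberships.append(member)

    masks = {}
    margin_vox = tuple(int(np.ceil(mask_margin_mm / s)) for s in spacing)
    struct = np.ones(tuple(2 * m + 1 for m in margin_vox), dtype=bool)
    from scipy.ndimage import binary_dilation

    for ins, member in zip(spec.inserts, memberships):
        dilated = binary_dilation(member, structure=struct) if member.any() else member
        if ins.artery_id in masks:
            masks[ins.artery_id] |= dilated
        else:
            masks[ins.artery_id] = dilated

    grid = VoxelGrid(data=data, spacing=spacing, origin=origin)
    return grid, masks


def truth_table(spec: PhantomTruth, grid: VoxelGrid, masks: dict) -> pd.DataFrame:
    """Realized per-insert ground truth by direct voxel enumeration.

    This enumeration is deliberately written as an explicit scan over the
    emitted grid, independent of the quantification code paths, so it can
    serve as the oracle the quantify module is tested against.
    """
    for ins in spec.inserts:
        if not _insert_in_grid(ins, grid.shape, grid.spacing, grid.origin):
            raise ValueError(f"spec/grid mismatch: insert for {ins.artery_id} outside grid")
        if ins.artery_id not in masks:
            raise ValueError(f"spec/grid mismatch: no mask for {ins.artery_id}")

    vox_vol = grid.voxel_volume_mm3
    rows = []
    for i, ins in enumerate(spec.inserts):
        count = 0
        hu_sum = 0.0
        hu_max = None
        sl = _insert_bounding_slices(ins, grid.shape, grid.spacing, grid.origin)
        for ii in range(sl[0].start, sl[0].stop):
            for jj in range(sl[1].start, sl[1].stop):
                for kk in range(sl[2].start, sl[2].stop):
                    x = grid.origin[0] + ii * grid.spacing[0]
                    y = grid.origin[1] + jj * grid.spacing[1]
                    z = grid.origin[2] + kk * grid.spacing[2]
                    if not ins.contains(np.array([[x, y, z]]))[0]:
                        continue
                    hu = float(grid.data[ii, jj, kk])
                    if hu >= DETECTION_FLOOR_HU:
                        count += 1
                        hu_sum += hu
                        hu_max = hu if hu_max is None else max(hu_max, hu)
        category = assign_density_category(hu_max)
        rows.append(
            {
                "insert_index": i,
                "artery_id": ins.artery_id,
                "shape": ins.shape,
                "true_volume_mm3": ins.true_volume_mm3,
                "true_mean_hu": ins.true_mean_hu,
                "realized_voxel_count": count,
                "realized_volume_mm3": count * vox_vol,
                "realized_hu_sum": hu_sum,
                "realized_mean_hu": (hu_sum / count) if count else None,
                "realized_max_hu": hu_max,
                "realized_category": category,
                "realized_category_label": category_label(category),
            }
        )
    return pd.DataFrame(rows)


def write_nifti(grid: VoxelGrid, path) -> None:
    img = nib.Nifti1Image(np.asarray(grid.data, dtype=np.int16), grid.affine)
    nib.save(img, str(path))


def write_mask_nifti(mask: np.ndarray, grid: VoxelGrid, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), grid.affine)
    nib.save(img, str(path))


def read_nifti(path) -> VoxelGrid:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    aff = img.affine
    spacing = tuple(float(v) for v in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(v) for v in aff[:3, 3])
    return VoxelGrid(data=data, spacing=spacing, origin=origin)
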