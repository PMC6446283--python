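"""Axis-aligned 3D volumes, NIfTI-1 I/O, rigid transforms and resampling.

The pipeline works on two grids: a fine anatomical grid (nominally 1 mm
isotropic, the ROI placement reference) and the coarse sodium grid
(nominally 3.6 mm isotropic).  Only axis-aligned geometries are supported;
oblique acquisitions are rejected at load time.  Conventions: 0-based voxel
indices, world coordinates in mm, voxel-center addressing (world position
of index (0,0,0) is the volume origin).

Registration *estimation* is out of scope — transforms are always known
(simulator ground truth or user supplied) and merely applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "GridSpec",
    "Volume",
    "RigidTransform",
    "IDENTITY",
    "read_nifti",
    "write_nifti",
    "resample_to_grid",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an axis-aligned voxel grid (shape, spacing mm, origin mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be three dims >= 1, got {self.shape}")
        if any(not s > 0 for s in self.spacing):
            raise ValueError(f"spacing must be > 0 on all axes, got {self.spacing}")

    def world_to_voxel(self, points) -> np.ndarray:
        """World mm -> continuous 0-based voxel index."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = (pts - np.asarray(self.origin)) / np.asarray(self.spacing)
        return idx[0] if np.asarray(points).ndim == 1 else idx

    def voxel_to_world(self, indices) -> np.ndarray:
        """Continuous voxel index -> world mm (inverse of world_to_voxel)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        pts = idx * np.asarray(self.spacing) + np.asarray(self.origin)
        return pts[0] if np.asarray(indices).ndim == 1 else pts

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) world coordinates of all voxel centers (C order)."""
        grids = np.meshgrid(
            *[np.arange(n) for n in self.shape], indexing="ij"
        )
        idx = np.stack([g.ravel() for g in grids], axis=1).astype(float)
        return self.voxel_to_world(idx)

    @property
    def center(self) -> tuple[float, float, float]:
        """World coordinates of the geometric volume center."""
        return tuple(
            o + (n - 1) / 2.0 * s
            for o, n, s in zip(self.origin, self.shape, self.spacing)
        )


@dataclass(frozen=True)
class Volume:
    """A 3D intensity (or integer label) image on an axis-aligned grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D, got ndim={self.data.ndim}")
        GridSpec(self.data.shape, self.spacing, self.origin)  # validates
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("intensities must be finite")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(tuple(self.data.shape), tuple(self.spacing), tuple(self.origin))

    def world_to_voxel(self, points) -> np.ndarray:
        return self.grid.world_to_voxel(points)

    def voxel_to_world(self, indices) -> np.ndarray:
        return self.grid.voxel_to_world(indices)

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data)


def _rotation_matrix(rotation_deg) -> np.ndarray:
    """Rotation about x, then y, then z (fixed axes): R = Rz @ Ry @ Rx."""
    ax, ay, az = np.deg2rad(rotation_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion: rotate about ``center_mm`` (x, then y, then z axes,
    angles in degrees), then translate by ``translation_mm``.

    ``apply`` maps a point through the forward motion; ``apply_inverse``
    undoes it — their composition is the identity to machine precision.
    """

    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def is_identity(self) -> bool:
        return all(v == 0 for v in self.translation_mm) and all(
            v == 0 for v in self.rotation_deg
        )

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r = _rotation_matrix(self.rotation_deg)
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        out = (pts - c) @ r.T + c + t
        return out[0] if np.asarray(points).ndim == 1 else out

    def apply_inverse(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r = _rotation_matrix(self.rotation_deg)
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        out = (pts - c - t) @ r + c
        return out[0] if np.asarray(points).ndim == 1 else out

    def at_center(self, grid: GridSpec) -> "RigidTransform":
        """Same motion parameters, pivoting about a grid's volume center."""
        return replace(self, center_mm=grid.center)


IDENTITY = RigidTransform()


# ---------------------------------------------------------------------------
# NIfTI-1 I/O


def read_nifti(path) -> Volume:
    """Read an axis-aligned NIfTI-1 volume.

    Raises ``ValueError`` for non-axis-aligned (oblique) orientations and
    ``IOError``/``nibabel`` errors for malformed files.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises several error types
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    affine = img.affine
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-6 * max(1.0, np.max(np.abs(rot))):
        raise ValueError(
            f"unsupported orientation in {path}: only axis-aligned volumes "
            "are supported"
        )
    spacing = tuple(float(abs(v)) for v in np.diag(rot))
    origin = tuple(float(v) for v in affine[:3, 3])
    if data.ndim != 3:
        data = np.squeeze(data)
    return Volume(data=np.asarray(data), spacing=spacing, origin=origin)


def write_nifti(vol: Volume, path) -> None:
    """Write a volume as NIfTI-1 with a diagonal affine."""
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vol.spacing
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(np.asarray(vol.data), affine), str(path))


# ---------------------------------------------------------------------------
# resampling


_ORDERS = {"nearest": 0, "trilinear": 1}


def resample_to_grid(
    src: Volume,
    target: GridSpec | Volume,
    transform: RigidTransform = IDENTITY,
    interpolation: str = "trilinear",
    fill: float = 0.0,
) -> Volume:
    """Resample ``src`` onto ``target``'s grid after moving it by ``transform``.

    The output voxel at world position q takes the source value at
    ``transform.apply_inverse(q)`` (i.e. the image content is displaced by
    the forward transform).  Out-of-field voxels receive ``fill``.  The
    identity transform onto an identical grid returns the input bit-exactly.
    """
    if interpolation not in _ORDERS:
        raise ValueError(
            f"interpolation must be one of {sorted(_ORDERS)}, got {interpolation!r}"
        )
    tgt = target.grid if isinstance(target, Volume) else target
    if transform.is_identity and tgt == src.grid:
        return Volume(src.data.copy(), tuple(tgt.spacing), tuple(tgt.origin))
    pts = tgt.voxel_centers()
    sample = src.world_to_voxel(transform.apply_inverse(pts))
    out = ndimage.map_coordinates(
        np.asarray(src.data, dtype=float),
        sample.T,
        order=_ORDERS[interpolation],
        mode="constant",
        cval=fill,
    ).reshape(tgt.shape)
    return Volume(out, tuple(tgt.spacing), tuple(tgt.origin))
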