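"""Fixed-area circular ROI protocol and measurement extraction.

The measurement protocol places identically sized circular ROIs
(0.508 cm^2, i.e. radius ~4.02 mm) at predetermined anatomic landmarks on
three consecutive slices, per reader.  ROI geometry is defined in world mm
on the anatomical reference grid and re-rasterized on whichever grid it is
measured on (the two grids differ: 1 mm reference vs 3.6 mm sodium), so a
"copied" ROI covers the same physical disc on both.

Reader variability is modeled as an in-plane Gaussian jitter of the ROI
center, deterministic per (reader, subject, visit, region, side, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .grid import GridSpec, Volume
from .phantom import Cohort, derive_seed
from .relaxometry import AcquisitionSpec, CompartmentLibrary, quantify_tsc

__all__ = [
    "RoiSpec",
    "RoiMask",
    "roi_mask",
    "extract_mean",
    "reader_place",
    "measure_all",
    "read_landmarks",
    "write_landmarks",
]

DEFAULT_AREA_CM2 = 0.508
DEFAULT_N_SLICES = 3


@dataclass(frozen=True)
class RoiSpec:
    """A circular landmark ROI: fixed in-plane area, replicated on
    ``n_slices`` consecutive slices along ``slice_axis``."""

    region: str
    side: str  # "left" | "right" | "midline"
    center_mm: tuple[float, float, float]
    area_cm2: float = DEFAULT_AREA_CM2
    n_slices: int = DEFAULT_N_SLICES
    slice_axis: int = 2

    def __post_init__(self) -> None:
        if not self.area_cm2 > 0:
            raise ValueError("area_cm2 must be > 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.slice_axis not in (0, 1, 2):
            raise ValueError("slice_axis must be 0, 1 or 2")
        if self.side == "midline" and self.region not in ("pons", "reference"):
            raise ValueError(
                f"side='midline' is only valid for pons/reference, got {self.region!r}"
            )

    @property
    def radius_mm(self) -> float:
        """In-plane disc radius from the fixed area: r = sqrt(area / pi)."""
        return float(np.sqrt(self.area_cm2 * 100.0 / np.pi))


@dataclass(frozen=True)
class RoiMask:
    """Realized voxel mask of an ROI on a specific grid."""

    indices: np.ndarray  # (N, 3) int voxel indices
    grid: GridSpec

    @property
    def n_voxels(self) -> int:
        return int(self.indices.shape[0])


def roi_mask(spec: RoiSpec, grid: GridSpec | Volume) -> RoiMask:
    """Rasterize an ROI on a grid.

    A voxel is included iff its center lies within the disc radius of the
    ROI center in-plane, on the ``n_slices`` consecutive slices centered on
    the landmark slice (shifted inward at volume edges).  Raises
    ``ValueError`` naming the landmark when the ROI leaves the field of view.
    """
    g = grid.grid if isinstance(grid, Volume) else grid
    axis = spec.slice_axis
    inplane = [a for a in (0, 1, 2) if a != axis]
    cidx = g.world_to_voxel(np.asarray(spec.center_mm, dtype=float))
    if np.any(cidx < -0.5) or np.any(cidx > np.asarray(g.shape) - 0.5):
        raise ValueError(
            f"ROI center for {spec.region}/{spec.side} lies outside the grid"
        )
    k0 = int(np.round(cidx[axis]))
    half = (spec.n_slices - 1) // 2
    lo = k0 - half
    hi = lo + spec.n_slices - 1
    # shift inward at edges
    if lo < 0:
        lo, hi = 0, spec.n_slices - 1
    if hi > g.shape[axis] - 1:
        hi = g.shape[axis] - 1
        lo = hi - spec.n_slices + 1
    if lo < 0:
        raise ValueError(
            f"ROI {spec.region}/{spec.side}: {spec.n_slices} slices do not fit "
            f"along axis {axis} (extent {g.shape[axis]})"
        )
    r = spec.radius_mm
    # candidate in-plane index window around the center
    spans = []
    for a in inplane:
        w = int(np.ceil(r / g.spacing[a])) + 1
        spans.append(np.arange(int(np.floor(cidx[a])) - w, int(np.ceil(cidx[a])) + w + 1))
    ii, jj = np.meshgrid(spans[0], spans[1], indexing="ij")
    da = (ii - cidx[inplane[0]]) * g.spacing[inplane[0]]
    db = (jj - cidx[inplane[1]]) * g.spacing[inplane[1]]
    keep = (da**2 + db**2) <= r**2
    ii, jj = ii[keep], jj[keep]
    if ii.size == 0:
        raise ValueError(f"ROI {spec.region}/{spec.side} covers no voxel centers")
    if (
        ii.min() < 0
        or jj.min() < 0
        or ii.max() > g.shape[inplane[0]] - 1
        or jj.max() > g.shape[inplane[1]] - 1
    ):
        raise ValueError(
            f"ROI {spec.region}/{spec.side} extends outside the field of view"
        )
    per_slice = np.empty((ii.size, 3), dtype=int)
    per_slice[:, inplane[0]] = ii
    per_slice[:, inplane[1]] = jj
    blocks = []
    for k in range(lo, hi + 1):
        b = per_slice.copy()
        b[:, axis] = k
        blocks.append(b)
    return RoiMask(np.concatenate(blocks, axis=0), g)


def extract_mean(vol: Volume, mask: RoiMask) -> float:
    """Arithmetic mean of the masked voxels."""
    if mask.n_voxels == 0:
        raise ValueError("empty ROI mask")
    if mask.grid != vol.grid:
        raise ValueError("mask and volume are on different grids")
    i, j, k = mask.indices.T
    return float(np.mean(np.asarray(vol.data, dtype=float)[i, j, k]))


def reader_place(
    spec: RoiSpec,
    reader: str,
    jitter_sd_mm: float,
    seed: int,
    subject: str = "",
    visit: str = "",
) -> RoiSpec:
    """Reader-specific ROI placement: the nominal center displaced by an
    in-plane Gaussian jitter of SD ``jitter_sd_mm`` per axis, deterministic
    per (reader, subject, visit, region, side, seed)."""
    if jitter_sd_mm < 0:
        raise ValueError("jitter_sd_mm must be >= 0")
    if jitter_sd_mm == 0:
        return spec
    child = derive_seed(seed, "reader", reader, subject, visit, spec.region, spec.side)
    rng = np.random.default_rng(child)
    delta = rng.normal(0.0, jitter_sd_mm, size=2)
    inplane = [a for a in (0, 1, 2) if a != spec.slice_axis]
    center = list(spec.center_mm)
    center[inplane[0]] += delta[0]
    center[inplane[1]] += delta[1]
    return replace(spec, center_mm=tuple(center))


def _landmark_specs(landmarks: pd.DataFrame) -> list[RoiSpec]:
    required = {"region", "side", "x_mm", "y_mm", "z_mm"}
    missing = required - set(landmarks.columns)
    if missing:
        raise ValueError(f"landmark table missing columns: {sorted(missing)}")
    specs = []
    for row in landmarks.itertuples():
        kwargs = {}
        if "area_cm2" in landmarks.columns:
            kwargs["area_cm2"] = float(row.area_cm2)
        if "n_slices" in landmarks.columns:
            kwargs["n_slices"] = int(row.n_slices)
        specs.append(
            RoiSpec(
                region=str(row.region),
                side=str(row.side),
                center_mm=(float(row.x_mm), float(row.y_mm), float(row.z_mm)),
                **kwargs,
            )
        )
    return specs


def measure_all(
    cohort: Cohort,
    landmarks: pd.DataFrame,
    readers: tuple[str, ...] = ("reader1", "reader2"),
    lib: CompartmentLibrary | None = None,
    acq: AcquisitionSpec | None = None,
    jitter_sd_mm: float = 1.0,
    seed: int = 0,
    weight_convention: str = "per-compartment",
) -> pd.DataFrame:
    """Measure every landmark in every session for every reader.

    For each (session, reader): jitter each landmark center, map it through
    the session's rigid repositioning (the known "registration"), rasterize
    the ROI on the sodium grid, and convert the ROI mean signal to a
    concentration against the reference-tube ROI mean from the same image.
    Returns one record per (subject, visit, reader, region, side) with
    columns ``mean_signal``, ``concentration`` and ``n_voxels``.
    """
    lib = lib or cohort.lib
    acq = acq or cohort.acq
    specs = _landmark_specs(landmarks)
    ref_specs = [s for s in specs if s.region == "reference"]
    if not ref_specs:
        raise ValueError(
            "landmark table has no 'reference' entry: the reference tube ROI "
            "is required for calibration"
        )
    ref_spec0 = ref_specs[0]
    tissue_specs = [s for s in specs if s.region != "reference"]
    unknown = {s.region for s in tissue_specs} - set(lib.regions)
    if unknown:
        raise ValueError(f"landmark regions not in compartment library: {sorted(unknown)}")
    ref_relax, ref_conc = cohort.lib.reference[0], lib.reference[1]

    records = []
    for sess in cohort.sessions:
        if sess.sodium is None:
            raise ValueError(
                f"session {sess.subject}/{sess.visit} has no rendered image "
                "(cohort generated with render=False)"
            )
        vol = sess.sodium
        transform = sess.spec.transform.at_center(cohort.labels.grid)
        for reader in readers:
            placed_ref = reader_place(
                ref_spec0, reader, jitter_sd_mm, seed, sess.subject, sess.visit
            )
            ref_center = transform.apply(np.asarray(placed_ref.center_mm))
            ref_mask = roi_mask(replace(placed_ref, center_mm=tuple(ref_center)), vol.grid)
            s_ref = extract_mean(vol, ref_mask)
            if s_ref <= 0:
                raise ValueError(
                    f"non-positive reference signal in session "
                    f"{sess.subject}/{sess.visit}"
                )
            for spec in tissue_specs:
                placed = reader_place(
                    spec, reader, jitter_sd_mm, seed, sess.subject, sess.visit
                )
                center = transform.apply(np.asarray(placed.center_mm))
                mask = roi_mask(replace(placed, center_mm=tuple(center)), vol.grid)
                s_tiss = extract_mean(vol, mask)
                conc = quantify_tsc(
                    max(s_tiss, 0.0),
                    s_ref,
                    ref_conc,
                    lib.spec(spec.region),
                    ref_relax,
                    acq,
                    weight_convention=weight_convention,
                )
                records.append(
                    {
                        "subject": sess.subject,
                        "visit": sess.visit,
                        "reader": reader,
                        "region": spec.region,
                        "side": spec.side,
                        "mean_signal": s_tiss,
                        "concentration": conc,
                        "n_voxels": mask.n_voxels,
                    }
                )
    return pd.DataFrame.from_records(records)


def read_landmarks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _landmark_specs(df)  # validates
    return df


def write_landmarks(landmarks: pd.DataFrame, path) -> None:
    landmarks.to_csv(path, index=False)
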