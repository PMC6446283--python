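"""Synthetic test-retest cohort: digital head phantoms with known truth.

This module stands in for scanner data: it builds a geometric head phantom
(GM shell, WM core, bilateral caudate heads, pons, bilateral cerebellum,
CSF ventricles) plus an external cylindrical reference tube on a fine
anatomical grid, synthesizes the noiseless sodium signal each compartment
would produce at the configured TR/TE (the exact forward inverse of the
quantification equation), degrades it with partial-volume blurring, rigid
repositioning, per-session gain drift and Rician noise, and resamples it to
the coarse sodium grid.

The geometry is deliberately schematic — region sizes are chosen so every
region has a blur-free core large enough for the fixed-area ROI protocol;
no anatomical realism is claimed.  Everything is reproducible from one
master seed; per-session streams are derived by stable hashing of
(subject, visit) so cohorts are extensible without reshuffling.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridSpec, RigidTransform, Volume, resample_to_grid
from .relaxometry import (
    AcquisitionSpec,
    CompartmentLibrary,
    saturation_factor,
    te_decay,
)

__all__ = [
    "Ellipsoid",
    "CylinderZ",
    "PhantomConfig",
    "SessionSpec",
    "SessionRecord",
    "Cohort",
    "default_phantom_config",
    "default_landmarks",
    "build_label_volume",
    "synthesize_sodium_image",
    "add_rician_noise",
    "simulate_cohort",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def derive_seed(master_seed: int, *key_parts) -> int:
    """Stable child seed (< 2^31) from a master seed and a string key."""
    key = "|".join(str(p) for p in key_parts)
    return (int(master_seed) * 2654435761 + zlib.crc32(key.encode())) % (2**31)


@dataclass(frozen=True)
class Ellipsoid:
    label: int
    region: str
    side: str  # "left" | "right" | "midline" | "" (side-less structure)
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]

    def mask(self, grid_pts: tuple[np.ndarray, ...]) -> np.ndarray:
        x, y, z = grid_pts
        cx, cy, cz = self.center_mm
        rx, ry, rz = self.radii_mm
        return (
            ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
        ) <= 1.0


@dataclass(frozen=True)
class CylinderZ:
    """Axis-parallel (z) cylinder, used for the external reference tube."""

    label: int
    region: str
    side: str
    center_xy_mm: tuple[float, float]
    radius_mm: float
    z_range_mm: tuple[float, float]

    def mask(self, grid_pts: tuple[np.ndarray, ...]) -> np.ndarray:
        x, y, z = grid_pts
        cx, cy = self.center_xy_mm
        r2 = ((x - cx) ** 2 + (y - cy) ** 2) <= self.radius_mm**2
        return r2 & (z >= self.z_range_mm[0]) & (z <= self.z_range_mm[1])


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom geometry, per-region truth and session-variability settings.

    ``primitives`` are painted in order — later primitives take precedence
    on overlap.  ``concentrations`` / ``between_subject_sd`` are mmol/kg wet
    weight; ``laterality_offset`` holds left-minus-right concentration
    offsets for regions with distinct left/right structures.  ``gain_sd``,
    ``translation_amp_mm``, ``rotation_amp_deg`` and ``noise_sigma``
    parameterize per-session variability (simulator choices, not measured
    values).
    """

    anat_shape: tuple[int, int, int] = (144, 168, 132)
    anat_spacing_mm: float = 1.0
    sodium_spacing_mm: float = 3.6
    primitives: tuple = ()
    concentrations: dict = field(default_factory=dict)
    between_subject_sd: dict = field(default_factory=dict)
    laterality_offset: dict = field(default_factory=dict)
    gain_sd: float = 0.02
    translation_amp_mm: float = 2.0
    rotation_amp_deg: float = 2.0
    noise_sigma: float = 1.5
    reference_concentration: float = 102.7

    def __post_init__(self) -> None:
        if not self.sodium_spacing_mm > self.anat_spacing_mm:
            raise ValueError("sodium grid must be coarser than anatomical grid")
        if self.gain_sd < 0 or self.noise_sigma < 0:
            raise ValueError("gain_sd and noise_sigma must be >= 0")
        labels = [p.label for p in self.primitives]
        if len(labels) != len(set(labels)):
            raise ValueError("primitive labels must be unique")

    @property
    def anat_grid(self) -> GridSpec:
        s = self.anat_spacing_mm
        return GridSpec(self.anat_shape, (s, s, s))

    @property
    def sodium_grid(self) -> GridSpec:
        # centered on the anatomical field of view so that the two grids
        # share a mirror axis (keeps the default phantom left/right symmetric)
        s = self.sodium_spacing_mm
        shape = tuple(
            int(np.ceil(n * self.anat_spacing_mm / s)) for n in self.anat_shape
        )
        origin = tuple(
            ((n_a - 1) * self.anat_spacing_mm - (n_s - 1) * s) / 2.0
            for n_a, n_s in zip(self.anat_shape, shape)
        )
        return GridSpec(shape, (s, s, s), origin)

    @property
    def label_table(self) -> dict[int, tuple[str, str]]:
        """label -> (region, side)."""
        return {p.label: (p.region, p.side) for p in self.primitives}


# on the anatomical grid's left/right mirror axis ((nx-1)/2 = 71.5 mm), so
# bilateral structures and landmarks rasterize mirror-symmetrically
_HEAD_CENTER = (71.5, 96.0, 66.0)


def default_phantom_config(lib: CompartmentLibrary | None = None) -> PhantomConfig:
    """Default 6-region head phantom with an external 0.6% NaCl tube.

    Region ground-truth concentrations and between-subject SDs come from the
    compartment library defaults; the caudate head carries a +4.4 mmol/kg
    left-minus-right offset by default (the one laterality effect the study
    design is meant to resolve).
    """
    if lib is None:
        from .relaxometry import default_library

        lib, _ = default_library()
    cx, cy, cz = _HEAD_CENTER
    prims = (
        Ellipsoid(1, "GM", "", (cx, cy, cz), (58.0, 62.0, 54.0)),
        Ellipsoid(2, "WM", "", (cx, cy, cz), (40.0, 44.0, 38.0)),
        Ellipsoid(8, "CSF", "left", (cx - 10.5, cy - 4, cz + 6), (10.0, 18.0, 13.0)),
        Ellipsoid(9, "CSF", "right", (cx + 10.5, cy - 4, cz + 6), (10.0, 18.0, 13.0)),
        Ellipsoid(3, "HCN", "left", (cx - 32, cy - 2, cz + 6), (11.5, 11.5, 11.5)),
        Ellipsoid(4, "HCN", "right", (cx + 32, cy - 2, cz + 6), (11.5, 11.5, 11.5)),
        Ellipsoid(5, "pons", "midline", (cx, cy - 14, cz - 32), (11.0, 11.0, 13.0)),
        Ellipsoid(6, "cerebellum", "left", (cx - 20, cy - 20, cz - 24), (12.0, 11.0, 11.0)),
        Ellipsoid(7, "cerebellum", "right", (cx + 20, cy - 20, cz - 24), (12.0, 11.0, 11.0)),
        CylinderZ(10, "reference", "midline", (cx, 14.0), 10.0, (20.0, 112.0)),
    )
    return PhantomConfig(
        primitives=prims,
        concentrations={r: lib.concentration(r) for r in lib.regions},
        between_subject_sd=dict(lib.between_subject_sd),
        laterality_offset={"HCN": 4.4},
        reference_concentration=lib.reference[1],
    )


def default_landmarks(config: PhantomConfig | None = None) -> pd.DataFrame:
    """Landmark table (region, side, x_mm, y_mm, z_mm) for the default phantom.

    Covers the ROI protocol's nine brain landmarks (bilateral GM, WM, HCN,
    cerebellum; midline pons) plus bilateral ventricular CSF and the
    reference tube.  Landmarks sit in region cores, clear of compartment
    boundaries on the sodium grid.
    """
    cx, cy, cz = _HEAD_CENTER
    rows = [
        ("GM", "left", cx - 45, cy + 20, cz),
        ("GM", "right", cx + 45, cy + 20, cz),
        ("WM", "left", cx - 20, cy + 24, cz),
        ("WM", "right", cx + 20, cy + 24, cz),
        ("HCN", "left", cx - 32, cy - 2, cz + 6),
        ("HCN", "right", cx + 32, cy - 2, cz + 6),
        ("pons", "midline", cx, cy - 14, cz - 32),
        ("cerebellum", "left", cx - 20, cy - 20, cz - 24),
        ("cerebellum", "right", cx + 20, cy - 20, cz - 24),
        ("CSF", "left", cx - 10.5, cy - 4, cz + 6),
        ("CSF", "right", cx + 10.5, cy - 4, cz + 6),
        ("reference", "midline", cx, 14.0, cz),
    ]
    return pd.DataFrame(rows, columns=["region", "side", "x_mm", "y_mm", "z_mm"])


@dataclass(frozen=True)
class SessionSpec:
    """One scan session: gain, repositioning and noise settings."""

    subject: str
    visit: str
    gain: float = 1.0
    transform: RigidTransform = RigidTransform()
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError("gain must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass
class SessionRecord:
    subject: str
    visit: str
    spec: SessionSpec
    sodium: Volume | None  # None when the cohort was generated truth-only


@dataclass
class Cohort:
    """A simulated cohort: label phantom, per-session images and the truth."""

    config: PhantomConfig
    lib: CompartmentLibrary
    acq: AcquisitionSpec
    labels: Volume
    truth: pd.DataFrame  # subject, region, side, label, true_conc
    sessions: list[SessionRecord]
    seed: int

    def truth_lookup(self) -> dict[tuple[str, str, str], float]:
        """(subject, region, side) -> true concentration."""
        return {
            (r.subject, r.region, r.side): r.true_conc
            for r in self.truth.itertuples()
        }

    def true_concentration(self, subject: str, region: str, side: str) -> float:
        """Ground truth for a measurement; side-less structures (e.g. the GM
        shell measured bilaterally) fall back to their single truth entry."""
        table = self.truth_lookup()
        if (subject, region, side) in table:
            return table[(subject, region, side)]
        return table[(subject, region, "")]


# ---------------------------------------------------------------------------
# phantom construction and forward signal model


def build_label_volume(config: PhantomConfig) -> Volume:
    """Rasterize the phantom primitives into an anatomical-grid label volume.

    Background is 0; primitives are painted in declaration order (later
    primitives win on overlap).  Raises ``ValueError`` if no primitives are
    configured or any primitive rasterizes to zero voxels.
    """
    if not config.primitives:
        raise ValueError("phantom config has no primitives")
    g = config.anat_grid
    axes = [
        np.arange(n) * s + o
        for n, s, o in zip(g.shape, g.spacing, g.origin)
    ]
    pts = np.meshgrid(*axes, indexing="ij", sparse=True)
    labels = np.zeros(g.shape, dtype=np.int16)
    for prim in config.primitives:
        m = prim.mask(pts)
        if not m.any():
            raise ValueError(
                f"primitive {prim.region}/{prim.side} (label {prim.label}) "
                "rasterizes to zero voxels"
            )
        labels[m] = prim.label
    # painting order may have fully covered an earlier primitive
    present = set(np.unique(labels))
    for prim in config.primitives:
        if prim.label not in present:
            raise ValueError(
                f"region {prim.region}/{prim.side} (label {prim.label}) "
                "is empty after precedence resolution"
            )
    return Volume(labels, (config.anat_spacing_mm,) * 3)


def signal_scale(region: str, lib: CompartmentLibrary, acq: AcquisitionSpec) -> float:
    """Noiseless signal per unit concentration for a compartment:
    ``sat(TR, T1) * D(TE)`` with the compartment's own decay weights."""
    spec = lib.spec(region)
    return saturation_factor(acq.tr_ms, spec.t1_ms) * te_decay(acq.te_ms, spec)


def _conc_by_label(
    config: PhantomConfig,
    overrides: dict[int, float] | None,
) -> dict[int, float]:
    out = {}
    for label, (region, _side) in config.label_table.items():
        if region == "reference":
            out[label] = config.reference_concentration
        else:
            if region not in config.concentrations:
                raise ValueError(f"no concentration configured for region {region!r}")
            out[label] = config.concentrations[region]
    if overrides:
        unknown = set(overrides) - set(out)
        if unknown:
            raise ValueError(f"concentration overrides for unknown labels: {unknown}")
        out.update(overrides)
    return out


def synthesize_sodium_image(
    labels: Volume,
    lib: CompartmentLibrary,
    acq: AcquisitionSpec,
    session: SessionSpec,
    config: PhantomConfig,
    conc_by_label: dict[int, float] | None = None,
) -> Volume:
    """Noiseless sodium-grid image for one session.

    Per-voxel signal on the anatomical grid is
    ``gain * concentration(label) * saturation_factor(TR, T1) * te_decay(TE)``;
    the image is blurred with a Gaussian PSF of FWHM one sodium voxel
    (partial-volume model), rigidly displaced by the session transform, and
    sampled at the sodium-grid voxel centers (trilinear).  Deterministic
    given the session.
    """
    table = config.label_table
    present = set(np.unique(labels.data)) - {0}
    unknown = present - set(table)
    if unknown:
        raise ValueError(f"label volume contains labels not in config: {unknown}")
    for label, (region, _s) in table.items():
        if region != "reference" and region not in lib.regions:
            raise ValueError(f"region {region!r} not present in compartment library")
    conc = _conc_by_label(config, conc_by_label)
    lut = np.zeros(max(table) + 1, dtype=float)
    for label, (region, _s) in table.items():
        lut[label] = conc[label] * signal_scale(region, lib, acq)
    signal = lut[labels.data]
    sigma_vox = (config.sodium_spacing_mm / _FWHM_TO_SIGMA) / config.anat_spacing_mm
    blurred = ndimage.gaussian_filter(signal, sigma=sigma_vox, mode="constant")
    anat = Volume(blurred, labels.spacing, labels.origin)
    transform = session.transform.at_center(anat.grid)
    sodium = resample_to_grid(anat, config.sodium_grid, transform, "trilinear")
    return sodium.with_data(sodium.data * session.gain)


def add_rician_noise(vol: Volume, sigma: float, seed: int) -> Volume:
    """Magnitude-reconstruction (Rician) noise: ``|v + n1 + i*n2|`` with
    independent ``n1, n2 ~ Normal(0, sigma)``.  ``sigma = 0`` returns the
    input unchanged; reproducible by seed."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return vol
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=vol.data.shape)
    n2 = rng.normal(0.0, sigma, size=vol.data.shape)
    return vol.with_data(np.hypot(vol.data + n1, n2))


# ---------------------------------------------------------------------------
# cohort generation


_VISITS = ("V1", "V2", "V3")


def _draw_session(
    subject: str,
    visit: str,
    config: PhantomConfig,
    master_seed: int,
) -> SessionSpec:
    seed = derive_seed(master_seed, "session", subject, visit)
    rng = np.random.default_rng(seed)
    gain = max(1.0 + config.gain_sd * rng.standard_normal(), 0.5)
    t = rng.uniform(-config.translation_amp_mm, config.translation_amp_mm, 3)
    r = rng.uniform(-config.rotation_amp_deg, config.rotation_amp_deg, 3)
    if config.translation_amp_mm == 0:
        t = np.zeros(3)
    if config.rotation_amp_deg == 0:
        r = np.zeros(3)
    return SessionSpec(
        subject=subject,
        visit=visit,
        gain=float(gain),
        transform=RigidTransform(tuple(t), tuple(r)),
        noise_sigma=config.noise_sigma,
        seed=derive_seed(master_seed, "noise", subject, visit),
    )


def simulate_cohort(
    n_subjects: int = 12,
    seed: int = 0,
    config: PhantomConfig | None = None,
    lib: CompartmentLibrary | None = None,
    acq: AcquisitionSpec | None = None,
    visits: tuple[str, ...] = _VISITS,
    render: bool = True,
) -> Cohort:
    """Simulate the full test-retest cohort.

    Per-subject region truths are drawn ``Normal(region mean,
    between_subject_sd)`` (clipped at 20% of the mean to stay positive);
    bilateral regions with a configured laterality offset split it
    symmetrically (left = truth + offset/2, right = truth - offset/2).
    All visits of a subject share the subject truth and differ only by
    independently drawn session effects (gain, repositioning, noise).
    Fully reproducible from ``seed``; with ``render=False`` only truth and
    session tables are generated (no images).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if config is None:
        config = default_phantom_config(lib)
    if lib is None or acq is None:
        from .relaxometry import default_library

        dlib, dacq = default_library()
        lib = lib or dlib
        acq = acq or dacq
    labels = build_label_volume(config) if render else None

    truth_rows = []
    sessions: list[SessionRecord] = []
    subjects = [f"sub-{i + 1:02d}" for i in range(n_subjects)]
    for subject in subjects:
        rng = np.random.default_rng(derive_seed(seed, "subject", subject))
        conc_by_label: dict[int, float] = {}
        region_truth: dict[str, float] = {}
        for region in sorted({r for r, _ in config.label_table.values()}):
            if region == "reference":
                continue
            mean = config.concentrations[region]
            sd = config.between_subject_sd.get(region, 0.0)
            c = mean + sd * rng.standard_normal()
            region_truth[region] = max(c, 0.2 * mean)
        for label, (region, side) in sorted(config.label_table.items()):
            if region == "reference":
                truth_rows.append(
                    (subject, region, side, label, config.reference_concentration)
                )
                continue
            offset = config.laterality_offset.get(region, 0.0)
            c = region_truth[region]
            if side == "left":
                c += offset / 2.0
            elif side == "right":
                c -= offset / 2.0
            conc_by_label[label] = c
            truth_rows.append((subject, region, side, label, c))
        for visit in visits:
            spec = _draw_session(subject, visit, config, seed)
            sodium = None
            if render:
                sodium = synthesize_sodium_image(
                    labels, lib, acq, spec, config, conc_by_label
                )
                sodium = add_rician_noise(sodium, spec.noise_sigma, spec.seed)
            sessions.append(SessionRecord(subject, visit, spec, sodium))

    truth = pd.DataFrame(
        truth_rows, columns=["subject", "region", "side", "label", "true_conc"]
    )
    if labels is None:
        labels = Volume(
            np.zeros((1, 1, 1), dtype=np.int16), (config.anat_spacing_mm,) * 3
        )
    return Cohort(config, lib, acq, labels, truth, sessions, seed)


def zero_variability(config: PhantomConfig) -> PhantomConfig:
    """A degenerate copy of ``config``: no between-subject spread, no
    laterality offset, no gain drift, no repositioning, no noise."""
    return replace(
        config,
        between_subject_sd={k: 0.0 for k in config.between_subject_sd},
        laterality_offset={},
        gain_sd=0.0,
        translation_amp_mm=0.0,
        rotation_amp_deg=0.0,
        noise_sigma=0.0,
    )
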