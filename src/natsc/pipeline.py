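"""Orchestration: simulate -> quantify -> analyze as reproducible runs.

Each stage reads/writes plain files (NIfTI-1 volumes, CSV tables, a JSON
run manifest) so stages can be re-run or swapped independently; a run is
fully determined by its resolved configuration plus the master seed, and
the manifest written next to the outputs is sufficient to re-execute it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grid import RigidTransform, Volume, read_nifti, write_nifti
from .phantom import (
    Cohort,
    PhantomConfig,
    SessionRecord,
    SessionSpec,
    build_label_volume,
    default_landmarks,
    default_phantom_config,
    simulate_cohort,
)
from .relaxometry import default_library
from .roi import measure_all, read_landmarks, write_landmarks
from .stats import summarize

log = logging.getLogger("natsc")

__all__ = ["RunConfig", "run_simulate", "run_quantify", "run_analyze", "run_all"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "natsc-run"
    n_subjects: int = 12
    noise_sigma: float | None = None  # None -> phantom default
    jitter_sd_mm: float = 1.0
    readers: tuple[str, ...] = ("reader1", "reader2")
    weight_convention: str = "per-compartment"
    overrides: dict = field(default_factory=dict)  # PhantomConfig field overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config fields: {sorted(bad)}")
        if "readers" in raw:
            raw["readers"] = tuple(raw["readers"])
        return cls(**raw)

    def phantom_config(self) -> PhantomConfig:
        from dataclasses import replace

        cfg = default_phantom_config()
        if self.overrides:
            cfg = replace(cfg, **self.overrides)
        if self.noise_sigma is not None:
            cfg = replace(cfg, noise_sigma=float(self.noise_sigma))
        return cfg


def _manifest(cfg: RunConfig, phantom: PhantomConfig) -> dict:
    return {
        "package": "natsc",
        "version": __version__,
        "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
        "jitter_sd_mm": cfg.jitter_sd_mm,
        "readers": list(cfg.readers),
        "weight_convention": cfg.weight_convention,
        "phantom": {
            "anat_shape": list(phantom.anat_shape),
            "anat_spacing_mm": phantom.anat_spacing_mm,
            "sodium_spacing_mm": phantom.sodium_spacing_mm,
            "concentrations": phantom.concentrations,
            "between_subject_sd": phantom.between_subject_sd,
            "laterality_offset": phantom.laterality_offset,
            "gain_sd": phantom.gain_sd,
            "translation_amp_mm": phantom.translation_amp_mm,
            "rotation_amp_deg": phantom.rotation_amp_deg,
            "noise_sigma": phantom.noise_sigma,
            "reference_concentration": phantom.reference_concentration,
        },
    }


def _session_filename(subject: str, visit: str) -> str:
    return f"{subject}_{visit}_na.nii.gz"


def run_simulate(cfg: RunConfig) -> Cohort:
    """Simulate the cohort and write session images, truth and manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phantom = cfg.phantom_config()
    log.info("simulating cohort: %d subjects, seed=%d", cfg.n_subjects, cfg.seed)
    cohort = simulate_cohort(n_subjects=cfg.n_subjects, seed=cfg.seed, config=phantom)
    write_nifti(cohort.labels, out / "labels.nii.gz")
    sess_rows = []
    for rec in cohort.sessions:
        fname = _session_filename(rec.subject, rec.visit)
        write_nifti(rec.sodium, out / fname)
        t = rec.spec.transform
        sess_rows.append(
            {
                "subject": rec.subject,
                "visit": rec.visit,
                "gain": rec.spec.gain,
                "tx_mm": t.translation_mm[0],
                "ty_mm": t.translation_mm[1],
                "tz_mm": t.translation_mm[2],
                "rx_deg": t.rotation_deg[0],
                "ry_deg": t.rotation_deg[1],
                "rz_deg": t.rotation_deg[2],
                "noise_sigma": rec.spec.noise_sigma,
                "noise_seed": rec.spec.seed,
                "file": fname,
            }
        )
    pd.DataFrame(sess_rows).to_csv(out / "sessions.csv", index=False)
    cohort.truth.to_csv(out / "truth.csv", index=False)
    write_landmarks(default_landmarks(phantom), out / "landmarks.csv")
    (out / "manifest.json").write_text(
        json.dumps(_manifest(cfg, phantom), indent=2, sort_keys=True) + "\n"
    )
    log.info("wrote %d session volumes to %s", len(sess_rows), out)
    return cohort


def load_cohort(run_dir) -> Cohort:
    """Reassemble a cohort from a simulate run directory."""
    run = Path(run_dir)
    manifest = json.loads((run / "manifest.json").read_text())
    sessions_df = pd.read_csv(run / "sessions.csv")
    missing = [
        row.file
        for row in sessions_df.itertuples()
        if not (run / row.file).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing session files in {run}: {missing}")
    lib, acq = default_library()
    from dataclasses import replace

    phantom = default_phantom_config(lib)
    pm = manifest.get("phantom", {})
    phantom = replace(
        phantom,
        concentrations=pm.get("concentrations", phantom.concentrations),
        between_subject_sd=pm.get("between_subject_sd", phantom.between_subject_sd),
        laterality_offset=pm.get("laterality_offset", phantom.laterality_offset),
        gain_sd=pm.get("gain_sd", phantom.gain_sd),
        translation_amp_mm=pm.get("translation_amp_mm", phantom.translation_amp_mm),
        rotation_amp_deg=pm.get("rotation_amp_deg", phantom.rotation_amp_deg),
        noise_sigma=pm.get("noise_sigma", phantom.noise_sigma),
        reference_concentration=pm.get(
            "reference_concentration", phantom.reference_concentration
        ),
    )
    labels = read_nifti(run / "labels.nii.gz")
    truth = pd.read_csv(run / "truth.csv", keep_default_na=False)
    truth["true_conc"] = truth["true_conc"].astype(float)
    sessions = []
    for row in sessions_df.itertuples():
        spec = SessionSpec(
            subject=row.subject,
            visit=row.visit,
            gain=float(row.gain),
            transform=RigidTransform(
                (row.tx_mm, row.ty_mm, row.tz_mm),
                (row.rx_deg, row.ry_deg, row.rz_deg),
            ),
            noise_sigma=float(row.noise_sigma),
            seed=int(row.noise_seed),
        )
        vol = read_nifti(run / row.file)
        sessions.append(SessionRecord(row.subject, row.visit, spec, vol))
    return Cohort(
        phantom, lib, acq, labels, truth, sessions, int(manifest.get("seed", 0))
    )


def run_quantify(cfg: RunConfig, cohort: Cohort | None = None) -> pd.DataFrame:
    """Measure all ROIs in all sessions; writes ``measurements.csv``."""
    out = Path(cfg.out_dir)
    if cohort is None:
        cohort = load_cohort(out)
    landmarks_path = out / "landmarks.csv"
    landmarks = (
        read_landmarks(landmarks_path)
        if landmarks_path.exists()
        else default_landmarks(cohort.config)
    )
    measurements = measure_all(
        cohort,
        landmarks,
        readers=cfg.readers,
        jitter_sd_mm=cfg.jitter_sd_mm,
        seed=cfg.seed,
        weight_convention=cfg.weight_convention,
    )
    out.mkdir(parents=True, exist_ok=True)
    measurements.to_csv(out / "measurements.csv", index=False)
    log.info("wrote %d measurements to %s", len(measurements), out)
    return measurements


def run_analyze(cfg: RunConfig, measurements: pd.DataFrame | None = None):
    """Summarize a measurement table into the report files."""
    out = Path(cfg.out_dir)
    if measurements is None:
        path = out / "measurements.csv"
        if not path.exists():
            raise FileNotFoundError(f"no measurement table at {path}")
        try:
            measurements = pd.read_csv(path)
        except Exception as exc:
            raise ValueError(f"malformed measurement CSV {path}: {exc}") from exc
    report = summarize(measurements, seed=cfg.seed)
    report.write(out)
    log.info("wrote report to %s", out)
    return report


def run_all(cfg: RunConfig):
    """simulate -> quantify -> analyze in one go."""
    cohort = run_simulate(cfg)
    measurements = run_quantify(cfg, cohort)
    return run_analyze(cfg, measurements)
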