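"""Relaxation-corrected quantification of tissue sodium concentration (TSC).

Cerebral sodium MRI measures the total sodium signal per voxel.  To turn the
signal ratio between tissue and an external reference phantom of known
concentration into an absolute concentration in mmol/kg wet weight, two
relaxation effects acquired at finite TR and TE must be corrected:

* incomplete longitudinal recovery, ``1 - exp(-TR/T1)``, which differs
  between tissue and reference because their T1 differ;
* transverse decay during TE.  Sodium in tissue relaxes biexponentially
  (fast/slow components with weights ``alfa``/``beta``, typically 0.6/0.4
  for brain parenchyma) while CSF and free solutions decay
  monoexponentially (``alfa = 0``).

The quantification reads::

    [Na]_tiss = (S_tiss / S_ref) * [Na]_ref
                * (1 - exp(-TR/T1_ref)) / (1 - exp(-TR/T1_tiss))
                * (a_r e^(-TE/T2f_ref) + b_r e^(-TE/T2s_ref))
                  / (a_t e^(-TE/T2f_tiss) + b_t e^(-TE/T2s_tiss))

Two conventions for the compartment weights are supported, see
:func:`correction_factor`.  All times are milliseconds; tissue
concentrations are mmol/kg wet weight, the reference concentration mmol/L
(treated as numerically interchangeable for calibration purposes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "RelaxationSpec",
    "AcquisitionSpec",
    "CompartmentLibrary",
    "saturation_factor",
    "te_decay",
    "correction_factor",
    "quantify_tsc",
    "default_library",
    "load_library",
]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class RelaxationSpec:
    """Relaxation constants of one compartment.

    Parameters
    ----------
    t1_ms : float
        Longitudinal relaxation time (ms).
    t2_fast_ms, t2_slow_ms : float
        Fast and slow transverse components (ms); ``t2_fast_ms <= t2_slow_ms``.
    weight_fast, weight_slow : float
        Dimensionless compartment weights ("alfa"/"beta"); must sum to 1.
    """

    t1_ms: float
    t2_fast_ms: float
    t2_slow_ms: float
    weight_fast: float
    weight_slow: float

    def __post_init__(self) -> None:
        for name in ("t1_ms", "t2_fast_ms", "t2_slow_ms"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.weight_fast < 0 or self.weight_slow < 0:
            raise ValueError("compartment weights must be non-negative")
        if abs(self.weight_fast + self.weight_slow - 1.0) > _WEIGHT_TOL:
            raise ValueError(
                "weight_fast + weight_slow must equal 1 "
                f"(got {self.weight_fast + self.weight_slow})"
            )
        if self.t2_fast_ms > self.t2_slow_ms:
            raise ValueError("t2_fast_ms must not exceed t2_slow_ms")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Sequence parameters relevant to the quantification.

    ``flip_deg`` is informational only: the quantification assumes the
    acquisition operates in a regime where flip-angle/steady-state effects
    cancel in the tissue/reference ratio.
    """

    tr_ms: float = 120.0
    te_ms: float = 0.2
    voxel_mm: float = 3.6
    flip_deg: float = 87.0

    def __post_init__(self) -> None:
        if not self.tr_ms > 0:
            raise ValueError("tr_ms must be > 0")
        if self.te_ms < 0:
            raise ValueError("te_ms must be >= 0")
        if not self.voxel_mm > 0:
            raise ValueError("voxel_mm must be > 0")


#: Brain regions every compartment library must provide.
REQUIRED_REGIONS = ("GM", "WM", "HCN", "pons", "cerebellum", "CSF")


@dataclass(frozen=True)
class CompartmentLibrary:
    """Region -> (relaxation spec, nominal concentration) lookup.

    ``entries`` maps region names to ``(RelaxationSpec, concentration)`` in
    mmol/kg wet weight; ``reference`` holds the external phantom's spec and
    its concentration in mmol/L.  ``between_subject_sd`` carries the
    population spread used by the synthetic cohort generator (mmol/kg WW).
    """

    entries: Mapping[str, tuple[RelaxationSpec, float]]
    reference: tuple[RelaxationSpec, float]
    between_subject_sd: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [r for r in REQUIRED_REGIONS if r not in self.entries]
        if missing:
            raise ValueError(f"library missing required regions: {missing}")
        for name, (_, conc) in self.entries.items():
            if not conc > 0:
                raise ValueError(f"concentration for {name!r} must be > 0")
        if not self.reference[1] > 0:
            raise ValueError("reference concentration must be > 0")

    @property
    def regions(self) -> list[str]:
        return list(self.entries)

    def spec(self, region: str) -> RelaxationSpec:
        if region == "reference":
            return self.reference[0]
        return self.entries[region][0]

    def concentration(self, region: str) -> float:
        if region == "reference":
            return self.reference[1]
        return self.entries[region][1]


def saturation_factor(tr_ms: float, t1_ms: float) -> float:
    """Longitudinal saturation factor ``1 - exp(-TR/T1)``.

    Strictly in (0, 1) for finite positive TR and T1; monotonically
    increasing in TR (full recovery in the TR >> T1 limit).
    """
    tr = np.asarray(tr_ms, dtype=float)
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(tr <= 0) or np.any(t1 <= 0):
        raise ValueError("tr_ms and t1_ms must be > 0")
    out = -np.expm1(-tr / t1)
    return float(out) if out.ndim == 0 else out


def te_decay(
    te_ms: float,
    relax: RelaxationSpec,
    weights: tuple[float, float] | None = None,
) -> float:
    """Biexponential transverse decay at echo time TE.

    Returns ``alfa*exp(-TE/T2f) + beta*exp(-TE/T2s)``, in (0, 1]; equals 1
    at TE = 0 and decreases monotonically with TE.  ``weights`` overrides
    the spec's own (alfa, beta) pair — used by the shared-weight formula
    convention (see :func:`correction_factor`).
    """
    te = np.asarray(te_ms, dtype=float)
    if np.any(te < 0):
        raise ValueError("te_ms must be >= 0")
    if weights is None:
        wf, ws = relax.weight_fast, relax.weight_slow
    else:
        wf, ws = weights
    out = wf * np.exp(-te / relax.t2_fast_ms) + ws * np.exp(-te / relax.t2_slow_ms)
    return float(out) if out.ndim == 0 else out


def correction_factor(
    tiss: RelaxationSpec,
    ref: RelaxationSpec,
    acq: AcquisitionSpec,
    weight_convention: str = "per-compartment",
) -> float:
    """Relaxation correction multiplying the raw signal ratio.

    ``[sat(TR, T1_ref) / sat(TR, T1_tiss)] * [D_ref(TE) / D_tiss(TE)]``
    where ``D`` is :func:`te_decay`.  Equals 1 when ``tiss == ref``.

    weight_convention
        ``"per-compartment"`` (default): each compartment's decay uses its
        own alfa/beta — the reference phantom decays by its own physics.
        ``"tissue"``: the tissue class's alfa/beta pair is applied to both
        numerator and denominator, i.e. a single shared pair as in the
        compact printed form of the equation.  At short TE the two differ
        by ~1% for monoexponential tissue classes.
    """
    if weight_convention == "per-compartment":
        ref_weights = None
    elif weight_convention == "tissue":
        ref_weights = (tiss.weight_fast, tiss.weight_slow)
    else:
        raise ValueError(
            f"weight_convention must be 'per-compartment' or 'tissue', "
            f"got {weight_convention!r}"
        )
    sat = saturation_factor(acq.tr_ms, ref.t1_ms) / saturation_factor(
        acq.tr_ms, tiss.t1_ms
    )
    dec = te_decay(acq.te_ms, ref, weights=ref_weights) / te_decay(acq.te_ms, tiss)
    return sat * dec


def quantify_tsc(
    s_tiss,
    s_ref: float,
    ref_conc: float,
    tiss: RelaxationSpec,
    ref: RelaxationSpec,
    acq: AcquisitionSpec,
    weight_convention: str = "per-compartment",
):
    """Tissue sodium concentration from a tissue/reference signal pair.

    ``(s_tiss / s_ref) * ref_conc * correction_factor(...)`` — linear in
    ``s_tiss``, inverse in ``s_ref``; returns ``ref_conc`` exactly for
    ``s_tiss == s_ref`` and ``tiss == ref`` (self-calibration identity).

    Accepts scalar or array ``s_tiss``; units: mmol/kg wet weight.
    """
    s_t = np.asarray(s_tiss, dtype=float)
    if s_ref <= 0:
        raise ZeroDivisionError(f"reference signal must be > 0, got {s_ref}")
    if np.any(s_t < 0):
        raise ValueError("tissue signal must be >= 0")
    if not ref_conc > 0:
        raise ValueError("ref_conc must be > 0")
    cf = correction_factor(tiss, ref, acq, weight_convention=weight_convention)
    out = (s_t / s_ref) * ref_conc * cf
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# config loading


def _relax_from_dict(d: Mapping) -> RelaxationSpec:
    return RelaxationSpec(
        t1_ms=float(d["t1_ms"]),
        t2_fast_ms=float(d["t2_fast_ms"]),
        t2_slow_ms=float(d["t2_slow_ms"]),
        weight_fast=float(d["weight_fast"]),
        weight_slow=float(d["weight_slow"]),
    )


def load_library(cfg: Mapping) -> tuple[CompartmentLibrary, AcquisitionSpec]:
    """Build a :class:`CompartmentLibrary` and :class:`AcquisitionSpec` from
    a parsed declarative config (see ``config/default.yaml`` for the schema).
    """
    acq_d = cfg.get("acquisition", {})
    acq = AcquisitionSpec(
        tr_ms=float(acq_d.get("tr_ms", 120.0)),
        te_ms=float(acq_d.get("te_ms", 0.2)),
        voxel_mm=float(acq_d.get("voxel_mm", 3.6)),
        flip_deg=float(acq_d.get("flip_deg", 87.0)),
    )
    classes = {name: _relax_from_dict(d) for name, d in cfg["classes"].items()}
    entries = {}
    sds = {}
    for region, d in cfg["regions"].items():
        cls = d["class"]
        if cls not in classes:
            raise ValueError(f"region {region!r} references unknown class {cls!r}")
        entries[region] = (classes[cls], float(d["concentration"]))
        if "between_subject_sd" in d:
            sds[region] = float(d["between_subject_sd"])
    ref_d = cfg["reference"]
    reference = (_relax_from_dict(ref_d["relaxation"]), float(ref_d["concentration_mmol_l"]))
    lib = CompartmentLibrary(entries=entries, reference=reference, between_subject_sd=sds)
    return lib, acq


def default_library() -> tuple[CompartmentLibrary, AcquisitionSpec]:
    """The shipped default constants (brain/CSF classes, 0.6% NaCl reference)."""
    text = resources.files("natsc").joinpath("config/default.yaml").read_text()
    return load_library(yaml.safe_load(text))
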