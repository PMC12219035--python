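"""Vergence-based refraction prediction for four published IOL power formulas.

Each formula estimates an effective lens position (ELP) from preoperative
biometry and a lens constant, then runs a thin-lens vergence chain from the
spectacle plane through the cornea to the IOL plane and on to the retina.
Here the chain is inverted: given the *implanted* IOL power, each function
returns the spectacle-plane spherical-equivalent refraction the eye is
predicted to have.

Implemented formulas and the variants used (see docs/formula_provenance.md):

* SRK/T   — corrected axial length above 24.2 mm, corneal-height square-root
            clamp, A-constant → ACD-constant conversion, retinal thickness
            term, n = 1.336 / 0.333 vergence constants.
* Hoffer Q — personalized-ACD ELP with tangent terms (arguments in degrees)
            and the short/long-eye adjustment, axial length clamped to
            [18.5, 31] mm inside the ELP expression.
* Holladay 1 — corneal-height anatomical ACD (AG cap 13.5 mm) plus surgeon
            factor, modified axial length AL + 0.2 mm, n = 1.336 / (4/3 − 1).
* Haigis  — ELP = a0 + a1·ACD + a2·AL; corneal power from the measured
            radius with the 1.3315 fictitious corneal index.

All refraction functions are vectorized over their biometry arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .biometry_io import BiometryRecord, Cohort

__all__ = [
    "FormulaId",
    "LensConstants",
    "PredictionResult",
    "default_constants",
    "predict_refraction",
    "predict_cohort",
    "convert_a_constant",
    "load_external_predictions",
    "coverage_report",
    "srkt_refraction",
    "hofferq_refraction",
    "holladay1_refraction",
    "haigis_refraction",
    "srkt_elp",
    "hofferq_elp",
    "holladay1_elp",
    "haigis_elp",
]

#: Aqueous/vitreous refractive index shared by the vergence chains.
NA = 1.336
#: Keratometric index used to convert diopters <-> corneal radius.
DEFAULT_KERATOMETRIC_INDEX = 1.3375
#: Fictitious corneal index of the Haigis formula.
HAIGIS_CORNEAL_INDEX = 1.3315
DEFAULT_VERTEX_MM = 12.0


class FormulaId(str, Enum):
    SRKT = "SRKT"
    HOFFER_Q = "HofferQ"
    HOLLADAY1 = "Holladay1"
    HAIGIS = "Haigis"
    EXTERNAL = "External"


#: Which LensConstants field each formula's scalar optimization acts on.
SCALAR_CONSTANT_FIELD: dict[FormulaId, str] = {
    FormulaId.SRKT: "A_const",
    FormulaId.HOFFER_Q: "pACD_mm",
    FormulaId.HOLLADAY1: "SF_mm",
    FormulaId.HAIGIS: "haigis_a0",
    FormulaId.EXTERNAL: "offset_D",
}

_REQUIRED_FIELDS: dict[FormulaId, tuple[str, ...]] = {
    FormulaId.SRKT: ("A_const",),
    FormulaId.HOFFER_Q: ("pACD_mm",),
    FormulaId.HOLLADAY1: ("SF_mm",),
    FormulaId.HAIGIS: ("haigis_a0", "haigis_a1", "haigis_a2"),
    FormulaId.EXTERNAL: ("offset_D",),
}


@dataclass(frozen=True)
class LensConstants:
    """Formula-specific lens constant set.

    Only the fields relevant to ``formula_id`` are required; the rest may stay
    unset. ``offset_D`` holds the mean-error offset of an externally computed
    (closed-source) formula after calibration.
    """

    formula_id: FormulaId
    A_const: float | None = None
    pACD_mm: float | None = None
    SF_mm: float | None = None
    haigis_a0: float | None = None
    haigis_a1: float | None = None
    haigis_a2: float | None = None
    offset_D: float | None = None

    def __post_init__(self) -> None:
        for name in _REQUIRED_FIELDS[self.formula_id]:
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(
                    f"{self.formula_id.value} constants require a finite {name}"
                )

    @property
    def scalar(self) -> float:
        """The formula's single optimizable constant."""
        return float(getattr(self, SCALAR_CONSTANT_FIELD[self.formula_id]))

    def with_scalar(self, value: float) -> "LensConstants":
        """Copy with the optimizable constant replaced; other fields unchanged."""
        return replace(self, **{SCALAR_CONSTANT_FIELD[self.formula_id]: float(value)})


def default_constants(formula_id: FormulaId) -> LensConstants:
    """Shipped default constants for the SN60WF lens.

    These are population-optimized starting values for the Alcon SN60WF;
    any serious use should re-optimize on local outcomes (see
    ``iolbench.constant_opt``). The Haigis triplet fixes a1 = 0.4, a2 = 0.1
    (single-constant mode; only a0 is optimized).
    """
    table = {
        FormulaId.SRKT: LensConstants(FormulaId.SRKT, A_const=119.082),
        FormulaId.HOFFER_Q: LensConstants(FormulaId.HOFFER_Q, pACD_mm=5.727),
        FormulaId.HOLLADAY1: LensConstants(FormulaId.HOLLADAY1, SF_mm=1.860),
        FormulaId.HAIGIS: LensConstants(
            FormulaId.HAIGIS, haigis_a0=-0.739, haigis_a1=0.4, haigis_a2=0.1
        ),
        FormulaId.EXTERNAL: LensConstants(FormulaId.EXTERNAL, offset_D=0.0),
    }
    return table[formula_id]


@dataclass(frozen=True)
class PredictionResult:
    patient_id: str
    formula_id: FormulaId
    predicted_ref_D: float
    elp_mm: float | None = None  # absent for External predictions


# ---------------------------------------------------------------------------
# ELP models
# ---------------------------------------------------------------------------

def srkt_elp(al_mm, km_d, a_const):
    """SRK/T effective lens position (ACD-est), mm.

    Uses the corrected axial length above 24.2 mm, the corneal-width
    regression, the corneal-height dome with its square-root clamp, and the
    A-constant → ACD-constant conversion ACDconst = 0.62467·A − 68.747.
    """
    al = np.asarray(al_mm, dtype=float)
    km = np.asarray(km_d, dtype=float)
    r = 337.5 / km
    lcor = np.where(al > 24.2, -3.446 + 1.715 * al - 0.0237 * al**2, al)
    cw = -5.41 + 0.58412 * lcor + 0.098 * km
    h = r - np.sqrt(np.clip(r * r - cw * cw / 4.0, 0.0, None))
    acd_const = 0.62467 * a_const - 68.747
    return h + (acd_const - 3.336)


def hofferq_elp(al_mm, km_d, pacd_mm):
    """Hoffer Q effective lens position, mm (tangent arguments in degrees).

    Axial length is clamped to [18.5, 31] mm inside the expression, per the
    published short/long-eye handling.
    """
    al = np.clip(np.asarray(al_mm, dtype=float), 18.5, 31.0)
    km = np.asarray(km_d, dtype=float)
    m = np.where(al <= 23.0, 1.0, -1.0)
    g = np.where(al <= 23.0, 28.0, 23.5)
    tan = lambda deg: np.tan(np.deg2rad(deg))
    return (
        pacd_mm
        + 0.3 * (al - 23.5)
        + tan(km) ** 2
        + 0.1 * m * (23.5 - al) ** 2 * tan(0.1 * (g - al) ** 2)
        - 0.99166
    )


def holladay1_elp(al_mm, km_d, sf_mm):
    """Holladay 1 effective lens position: anatomical ACD + surgeon factor, mm."""
    al = np.asarray(al_mm, dtype=float)
    km = np.asarray(km_d, dtype=float)
    r = 337.5 / km
    ag = np.minimum(al * 12.5 / 23.45, 13.5)
    aacd = 0.56 + r - np.sqrt(np.clip(r * r - ag * ag / 4.0, 0.0, None))
    return aacd + sf_mm


def haigis_elp(al_mm, acd_mm, a0, a1, a2):
    """Haigis effective lens position d = a0 + a1·ACD + a2·AL, mm."""
    return a0 + a1 * np.asarray(acd_mm, dtype=float) + a2 * np.asarray(al_mm, dtype=float)


# ---------------------------------------------------------------------------
# Refraction (vergence chains, inverted for the implanted power)
# ---------------------------------------------------------------------------

def _holladay_style_refraction(lopt, r, elp, power, vertex_mm, ncm1):
    """Closed-form spectacle refraction of the Holladay/SRK-T vergence chain.

    ``lopt`` is the optical axial length, ``r`` the corneal radius (mm),
    ``elp`` the predicted lens position (mm), ``ncm1`` the corneal index
    minus one (0.333 for SRK/T, 1/3 for Holladay 1).
    """
    na, v = NA, vertex_mm
    num = 1000.0 * na * (na * r - ncm1 * lopt) - power * (lopt - elp) * (
        na * r - ncm1 * elp
    )
    den = na * (v * (na * r - ncm1 * lopt) + lopt * r) - 0.001 * power * (
        lopt - elp
    ) * (v * (na * r - ncm1 * elp) + elp * r)
    return num / den


def srkt_refraction(al_mm, km_d, iol_power_d, a_const, vertex_mm=DEFAULT_VERTEX_MM):
    """SRK/T predicted spectacle refraction (D) for an implanted power."""
    al = np.asarray(al_mm, dtype=float)
    km = np.asarray(km_d, dtype=float)
    r = 337.5 / km
    elp = srkt_elp(al, km, a_const)
    lopt = al + (0.65696 - 0.02029 * al)  # retinal-thickness corrected length
    return _holladay_style_refraction(lopt, r, elp, iol_power_d, vertex_mm, 0.333)


def holladay1_refraction(al_mm, km_d, iol_power_d, sf_mm, vertex_mm=DEFAULT_VERTEX_MM):
    """Holladay 1 predicted spectacle refraction (D) for an implanted power."""
    al = np.asarray(al_mm, dtype=float)
    km = np.asarray(km_d, dtype=float)
    r = 337.5 / km
    elp = holladay1_elp(al, km, sf_mm)
    lopt = al + 0.2
    return _holladay_style_refraction(lopt, r, elp, iol_power_d, vertex_mm, 1.0 / 3.0)


def hofferq_refraction(al_mm, km_d, iol_power_d, pacd_mm, vertex_mm=DEFAULT_VERTEX_MM):
    """Hoffer Q predicted spectacle refraction (D) for an implanted power.

    Inverts the published power formula
    P = 1336/(AL − C − 0.05) − 1.336/(1.336/(K + R) − (C + 0.05)/1000)
    for the corneal-plane refraction R, then moves it to the spectacle plane.
    """
    al = np.asarray(al_mm, dtype=float)
    km = np.asarray(km_d, dtype=float)
    c = hofferq_elp(al, km, pacd_mm)
    t = 1336.0 / (al - c - 0.05) - np.asarray(iol_power_d, dtype=float)
    rc = 1.336 / (1.336 / t + (c + 0.05) / 1000.0) - km
    return rc / (1.0 + (vertex_mm / 1000.0) * rc)


def haigis_refraction(
    al_mm,
    acd_mm,
    km_d,
    iol_power_d,
    a0,
    a1,
    a2,
    vertex_mm=DEFAULT_VERTEX_MM,
    keratometric_index=DEFAULT_KERATOMETRIC_INDEX,
):
    """Haigis predicted spectacle refraction (D) for an implanted power.

    Corneal radius is recovered from keratometric diopters with
    ``keratometric_index`` and converted back to corneal power with the
    formula's own fictitious index 1.3315.
    """
    al = np.asarray(al_mm, dtype=float)
    km = np.asarray(km_d, dtype=float)
    r = 1000.0 * (keratometric_index - 1.0) / km
    dc = 1000.0 * (HAIGIS_CORNEAL_INDEX - 1.0) / r
    d = haigis_elp(al, acd_mm, a0, a1, a2)
    n = NA
    l_m, d_m = al / 1000.0, d / 1000.0
    q = n / (l_m - d_m) - np.asarray(iol_power_d, dtype=float)
    z = n / (n / q + d_m)
    rc = z - dc
    return rc / (1.0 + (vertex_mm / 1000.0) * rc)


# ---------------------------------------------------------------------------
# Record-level interface
# ---------------------------------------------------------------------------

def _refraction_and_elp(
    formula_id: FormulaId,
    al: np.ndarray,
    acd: np.ndarray,
    km: np.ndarray,
    power: np.ndarray,
    constants: LensConstants,
    vertex_mm: float,
) -> tuple[np.ndarray, np.ndarray]:
    if constants.formula_id is not formula_id:
        raise ValueError(
            f"constants are for {constants.formula_id.value}, not {formula_id.value}"
        )
    if formula_id is FormulaId.SRKT:
        elp = srkt_elp(al, km, constants.A_const)
        ref = srkt_refraction(al, km, power, constants.A_const, vertex_mm)
    elif formula_id is FormulaId.HOFFER_Q:
        elp = hofferq_elp(al, km, constants.pACD_mm)
        ref = hofferq_refraction(al, km, power, constants.pACD_mm, vertex_mm)
    elif formula_id is FormulaId.HOLLADAY1:
        elp = holladay1_elp(al, km, constants.SF_mm)
        ref = holladay1_refraction(al, km, power, constants.SF_mm, vertex_mm)
    elif formula_id is FormulaId.HAIGIS:
        elp = haigis_elp(al, acd, constants.haigis_a0, constants.haigis_a1, constants.haigis_a2)
        ref = haigis_refraction(
            al, acd, km, power,
            constants.haigis_a0, constants.haigis_a1, constants.haigis_a2,
            vertex_mm,
        )
    else:
        raise ValueError(f"{formula_id.value} has no native refraction model")
    return np.asarray(ref, dtype=float), np.asarray(elp, dtype=float)


def predict_refraction(
    formula_id: FormulaId,
    record: "BiometryRecord",
    constants: LensConstants,
    vertex_mm: float = DEFAULT_VERTEX_MM,
) -> PredictionResult:
    """Predict one eye's postoperative spectacle-plane refraction.

    Raises a ValueError naming the record if the predicted lens position
    falls outside (0, AL) — a sign the constants or biometry are implausible.
    """
    if not 0.0 <= vertex_mm <= 20.0:
        raise ValueError(f"vertex_mm must be in [0, 20], got {vertex_mm}")
    km = (record.K1_D + record.K2_D) / 2.0
    ref, elp = _refraction_and_elp(
        formula_id,
        np.asarray(record.AL_mm),
        np.asarray(record.ACD_mm),
        np.asarray(km),
        np.asarray(record.iol_power_D),
        constants,
        vertex_mm,
    )
    elp_f = float(elp)
    if not (0.0 < elp_f < record.AL_mm):
        raise ValueError(
            f"{formula_id.value} ELP {elp_f:.3f} mm outside (0, AL) for "
            f"patient {record.patient_id}"
        )
    return PredictionResult(
        patient_id=record.patient_id,
        formula_id=formula_id,
        predicted_ref_D=float(ref),
        elp_mm=elp_f,
    )


def predict_cohort(
    formula_id: FormulaId,
    cohort: "Cohort",
    constants: LensConstants,
    vertex_mm: float = DEFAULT_VERTEX_MM,
    *,
    check_elp: bool = True,
) -> np.ndarray:
    """Vectorized predicted refraction for every record, aligned with cohort order.

    ``check_elp=False`` skips the (0, AL) lens-position validity check; the
    constant optimizer uses it while scanning brackets that include
    nonphysical constants, then re-validates its final answer.
    """
    al = cohort.column("AL_mm")
    acd = cohort.column("ACD_mm")
    km = (cohort.column("K1_D") + cohort.column("K2_D")) / 2.0
    power = cohort.column("iol_power_D")
    ref, elp = _refraction_and_elp(formula_id, al, acd, km, power, constants, vertex_mm)
    bad = ~((elp > 0.0) & (elp < al))
    if check_elp and np.any(bad):
        ids = [cohort.records[i].patient_id for i in np.flatnonzero(bad)[:5]]
        raise ValueError(
            f"{formula_id.value} ELP outside (0, AL) for {int(bad.sum())} record(s), "
            f"e.g. {ids}"
        )
    return ref


# ---------------------------------------------------------------------------
# A-constant conversions
# ---------------------------------------------------------------------------

#: Standard published linear maps from an SRK-style A-constant to the other
#: formulas' constants. Config-overridable via the ``coefficients`` argument.
A_CONVERSIONS: dict[str, tuple[float, float]] = {
    "pACD": (0.58357, -63.896),   # Hoffer Q personalized ACD
    "SF": (0.5663, -65.60),       # Holladay 1 surgeon factor
    "acd_const": (0.62467, -68.747),  # SRK/T internal ACD constant
    "a0": (0.62467, -72.434),     # Haigis a0 with a1 = 0.4, a2 = 0.1
}


def convert_a_constant(
    A: float,
    target: str,
    coefficients: Mapping[str, tuple[float, float]] | None = None,
) -> float:
    """Convert an A-constant to a pACD / SF / ACD-const / a0 equivalent (mm)."""
    if not 110.0 <= A <= 125.0:
        raise ValueError(f"A-constant {A} outside the plausible range [110, 125]")
    table = dict(A_CONVERSIONS)
    if coefficients:
        table.update(coefficients)
    if target not in table:
        raise ValueError(f"unknown conversion target {target!r}; know {sorted(table)}")
    slope, intercept = table[target]
    return slope * A + intercept


# ---------------------------------------------------------------------------
# External (closed-source) formula adapter
# ---------------------------------------------------------------------------

def load_external_predictions(
    path: str | Path, formula_label: str
) -> tuple[dict[str, float], pd.DataFrame]:
    """Load per-eye predicted refractions computed outside this package.

    The file must be delimited text with ``patient_id`` and ``predicted_ref_D``
    columns. Returns (mapping patient_id → predicted refraction, reject log).
    Duplicate patient ids are an error; non-numeric predictions reject the row.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("patient_id", "predicted_ref_D"):
        if col not in df.columns:
            raise ValueError(f"external prediction file for {formula_label} lacks column {col}")
    preds: dict[str, float] = {}
    rejects: list[dict] = []
    for i, (pid, cell) in enumerate(zip(df["patient_id"], df["predicted_ref_D"])):
        pid = str(pid).strip()
        if pid in preds:
            raise ValueError(f"duplicate patient_id {pid!r} in {formula_label} predictions")
        try:
            preds[pid] = float(cell)
        except ValueError:
            rejects.append({"row": i, "patient_id": pid, "reason": "non-numeric prediction"})
    log = pd.DataFrame(rejects, columns=["row", "patient_id", "reason"])
    return preds, log


def coverage_report(predictions: Mapping[str, float], cohort: "Cohort") -> list[str]:
    """Cohort eyes with no external prediction (downstream analyses restrict to
    the intersection of eyes covered by every compared formula)."""
    return [pid for pid in cohort.patient_ids() if pid not in predictions]
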