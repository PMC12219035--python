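"""Cohort data model, delimited-file I/O, keratometric features and eligibility filtering.

A cohort is an ordered collection of per-eye records: preoperative optical
biometry (axial length, anterior chamber depth, lens thickness, central
corneal thickness, white-to-white, flat/steep keratometry), the power of the
implanted intraocular lens, and the 1-month postoperative spherical-equivalent
refraction. Files are plain delimited text (CSV by default, TSV supported)
with a header row; a column-name mapping lets arbitrary headers feed the
canonical schema.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BiometryRecord",
    "Cohort",
    "EligibilityConfig",
    "DerivedFeatures",
    "read_cohort",
    "write_cohort",
    "apply_eligibility",
    "derive_features",
    "NUMERIC_FIELDS",
    "DEFAULT_BOUNDS",
]

#: Numeric per-eye fields, in canonical column order.
NUMERIC_FIELDS: tuple[str, ...] = (
    "age_years",
    "AL_mm",
    "ACD_mm",
    "LT_mm",
    "CCT_um",
    "WTW_mm",
    "K1_D",
    "K2_D",
    "iol_power_D",
    "postop_ref_D",
)

STRING_FIELDS: tuple[str, ...] = ("patient_id", "eye", "sex", "lens_model")

#: Canonical column order for cohort files.
COLUMNS: tuple[str, ...] = (
    "patient_id",
    "eye",
    "sex",
    *NUMERIC_FIELDS,
    "lens_model",
    "bscva_at_least_20_40",
)

#: Plausibility bounds covering the validity ranges of the implemented
#: vergence formulas; config-overridable. Units: mm, µm, D, years.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "AL_mm": (18.0, 35.0),
    "ACD_mm": (1.5, 5.0),
    "LT_mm": (2.5, 6.5),
    "CCT_um": (400.0, 700.0),
    "WTW_mm": (9.0, 14.0),
    "K1_D": (35.0, 52.0),
    "K2_D": (35.0, 52.0),
    "iol_power_D": (0.0, 40.0),
}

#: Fields that must be present (non-missing) for a record to be usable by the
#: formula roster. postop_ref_D is required because every evaluation needs it.
REQUIRED_FOR_FORMULAS: tuple[str, ...] = (
    "AL_mm",
    "ACD_mm",
    "LT_mm",
    "CCT_um",
    "WTW_mm",
    "K1_D",
    "K2_D",
    "iol_power_D",
    "postop_ref_D",
)

_TRUTHY = {"true", "t", "1", "yes", "y"}
_FALSY = {"false", "f", "0", "no", "n"}


@dataclass
class BiometryRecord:
    """One eye's preoperative biometry, implanted IOL power and 1-month refraction.

    ``postop_ref_D`` is the spherical equivalent (sphere + cylinder/2) at the
    spectacle plane. K1/K2 are canonicalized so that K2 >= K1 (steep >= flat);
    inputs violating this are swapped on construction.
    """

    patient_id: str
    eye: str | None = None  # "R" / "L"
    age_years: float = math.nan
    sex: str | None = None  # "F" / "M"
    AL_mm: float = math.nan
    ACD_mm: float = math.nan
    LT_mm: float = math.nan
    CCT_um: float = math.nan
    WTW_mm: float = math.nan
    K1_D: float = math.nan
    K2_D: float = math.nan
    iol_power_D: float = math.nan
    postop_ref_D: float = math.nan
    lens_model: str = "SN60WF"
    bscva_at_least_20_40: bool = True

    def __post_init__(self) -> None:
        if (
            math.isfinite(self.K1_D)
            and math.isfinite(self.K2_D)
            and self.K2_D < self.K1_D
        ):
            self.K1_D, self.K2_D = self.K2_D, self.K1_D


class DerivedFeatures(NamedTuple):
    Km_D: float
    r_mm: float
    astigmatism_D: float


@dataclass
class Cohort:
    """Ordered, labeled collection of :class:`BiometryRecord`.

    ``rejects`` carries row-level parse failures from :func:`read_cohort`
    (empty for programmatically built cohorts).
    """

    label: str
    records: list[BiometryRecord] = field(default_factory=list)
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "patient_id", "reason"])
    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BiometryRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Canonical-column DataFrame view (copy) of the records."""
        rows = []
        for r in self.records:
            d = {f.name: getattr(r, f.name) for f in fields(r)}
            rows.append(d)
        df = pd.DataFrame(rows, columns=list(COLUMNS))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str) -> "Cohort":
        records = []
        for row in df.itertuples(index=False):
            d = row._asdict()
            records.append(
                BiometryRecord(
                    patient_id=str(d["patient_id"]),
                    eye=_none_if_blank(d.get("eye")),
                    sex=_none_if_blank(d.get("sex")),
                    lens_model=str(d.get("lens_model", "") or ""),
                    bscva_at_least_20_40=bool(d.get("bscva_at_least_20_40", True)),
                    **{k: float(d[k]) if pd.notna(d[k]) else math.nan for k in NUMERIC_FIELDS},
                )
            )
        return cls(label=label, records=records)

    def column(self, name: str) -> np.ndarray:
        """Numeric field as a float array, aligned with record order."""
        if name not in NUMERIC_FIELDS:
            raise KeyError(f"not a numeric field: {name}")
        return np.array([getattr(r, name) for r in self.records], dtype=float)

    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]


def _none_if_blank(v: object) -> str | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    s = str(v).strip()
    return s or None


@dataclass
class EligibilityConfig:
    """Inclusion/exclusion policy applied by :func:`apply_eligibility`.

    Exclusion reasons are checked in order: (a) missing or out-of-bounds data
    needed by the formulas, (b) postoperative best spectacle-corrected visual
    acuity worse than 20/40, (c) wrong lens model, (d) second eye of a patient
    already included (kept eye chosen by ``tie_break``; only "first" — earlier
    row in file order — is implemented).
    """

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    require_lens_model: str | None = "SN60WF"
    drop_bscva_failures: bool = True
    one_eye_per_patient: bool = True
    tie_break: str = "first"
    required_fields: tuple[str, ...] = REQUIRED_FOR_FORMULAS

    def __post_init__(self) -> None:
        for var, (lo, hi) in self.bounds.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {var} must be finite with min < max")
        if self.tie_break != "first":
            raise ValueError(f"unsupported tie_break: {self.tie_break!r}")


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    delimiter: str | None = None,
    label: str | None = None,
) -> Cohort:
    """Read a delimited cohort file into a :class:`Cohort`.

    Parameters
    ----------
    path
        Delimited text file (UTF-8) with a header row. Delimiter inferred from
        the extension (``.tsv`` → tab, else comma) unless given explicitly.
    schema
        Mapping from file column names to canonical field names. Identity for
        columns already carrying canonical names.

    Blank numeric cells become NaN (explicit missingness); cells that are
    non-blank but unparseable exclude the whole row, which is recorded in the
    returned cohort's ``rejects`` table.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    if schema:
        df = df.rename(columns=dict(schema))

    required_cols = {"patient_id", *NUMERIC_FIELDS}
    missing_cols = sorted(required_cols - set(df.columns))
    if missing_cols:
        raise ValueError(
            "cohort file is missing required column(s): " + ", ".join(missing_cols)
        )

    reject_rows: list[dict] = []
    records: list[BiometryRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = dict(zip(df.columns, row))
        numeric: dict[str, float] = {}
        bad: str | None = None
        for col in NUMERIC_FIELDS:
            cell = raw.get(col, "").strip()
            if cell == "":
                numeric[col] = math.nan
            else:
                try:
                    numeric[col] = float(cell)
                except ValueError:
                    bad = col
                    break
        if bad is not None:
            reject_rows.append(
                {
                    "row": i,
                    "patient_id": raw.get("patient_id", ""),
                    "reason": f"unparseable numeric cell in column {bad}",
                }
            )
            continue
        records.append(
            BiometryRecord(
                patient_id=str(raw.get("patient_id", "")).strip(),
                eye=_none_if_blank(raw.get("eye", "")),
                sex=_none_if_blank(raw.get("sex", "")),
                lens_model=str(raw.get("lens_model", "")).strip(),
                bscva_at_least_20_40=_parse_bool(raw.get("bscva_at_least_20_40", "")),
                **numeric,
            )
        )
    cohort = Cohort(label=label or path.stem, records=records)
    cohort.rejects = pd.DataFrame(reject_rows, columns=["row", "patient_id", "reason"])
    return cohort


def _parse_bool(cell: str) -> bool:
    s = str(cell).strip().lower()
    if s in _FALSY:
        return False
    if s in _TRUTHY or s == "":
        return True
    raise ValueError(f"unparseable boolean cell: {cell!r}")


def write_cohort(
    cohort: Cohort, path: str | Path, *, delimiter: str = ","
) -> None:
    """Write a cohort as delimited text, floats at 6 significant digits."""
    df = cohort.to_frame()
    df.to_csv(path, sep=delimiter, index=False, float_format="%.6g")


def apply_eligibility(
    cohort: Cohort, config: EligibilityConfig | None = None
) -> tuple[Cohort, pd.DataFrame]:
    """Apply inclusion/exclusion criteria; return (kept cohort, exclusion log).

    The log has one row per excluded record with the first matching reason,
    reasons checked in the order documented on :class:`EligibilityConfig`.
    Idempotent: a cohort that passed once passes unchanged.
    """
    if config is None:
        config = EligibilityConfig()
    if len(cohort) == 0:
        raise ValueError("apply_eligibility requires a non-empty cohort")

    kept: list[BiometryRecord] = []
    log_rows: list[dict] = []
    seen: set[str] = set()
    for rec in cohort.records:
        reason = _exclusion_reason(rec, config, seen)
        if reason is None:
            kept.append(rec)
            if config.one_eye_per_patient:
                seen.add(rec.patient_id)
        else:
            log_rows.append(
                {"patient_id": rec.patient_id, "eye": rec.eye or "", "reason": reason}
            )
    if not kept:
        warnings.warn(
            f"eligibility filtering removed every record of cohort {cohort.label!r}",
            stacklevel=2,
        )
    log = pd.DataFrame(log_rows, columns=["patient_id", "eye", "reason"])
    return Cohort(label=cohort.label, records=kept), log


def _exclusion_reason(
    rec: BiometryRecord, config: EligibilityConfig, seen: set[str]
) -> str | None:
    # (a) missing or out-of-bounds data needed by the formulas
    for var in config.required_fields:
        v = getattr(rec, var)
        if not math.isfinite(v):
            return f"missing {var}"
    for var, (lo, hi) in config.bounds.items():
        v = getattr(rec, var, math.nan)
        if math.isfinite(v) and not (lo <= v <= hi):
            return f"out-of-bounds {var}"
    # (b) postoperative acuity
    if config.drop_bscva_failures and not rec.bscva_at_least_20_40:
        return "BSCVA worse than 20/40"
    # (c) lens model
    if config.require_lens_model and rec.lens_model != config.require_lens_model:
        return f"lens model {rec.lens_model or '<none>'} != {config.require_lens_model}"
    # (d) one eye per patient
    if config.one_eye_per_patient and rec.patient_id in seen:
        return "second eye excluded"
    return None


def derive_features(
    record: BiometryRecord, keratometric_index: float = 1.3375
) -> DerivedFeatures:
    """Mean keratometry Km = (K1+K2)/2, corneal radius and astigmatism.

    The corneal radius of curvature follows the keratometric convention
    r_mm = 1000·(n_k − 1)/Km with n_k defaulting to 1.3375 (the biometer
    convention for keratometric diopters).
    """
    k1, k2 = record.K1_D, record.K2_D
    if not (math.isfinite(k1) and math.isfinite(k2)) or k1 <= 0 or k2 <= 0:
        raise ValueError(
            f"keratometry must be positive and present (patient {record.patient_id}): "
            f"K1={k1}, K2={k2}"
        )
    km = (k1 + k2) / 2.0
    return DerivedFeatures(
        Km_D=km,
        r_mm=1000.0 * (keratometric_index - 1.0) / km,
        astigmatism_D=k2 - k1,
    )
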