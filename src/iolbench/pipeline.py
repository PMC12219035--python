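"""Config-driven study orchestration.

A study compares formula performance across three contexts on two cohorts:

* the *reference* cohort with shipped default constants,
* the *primary* cohort with shipped default constants, and
* the primary cohort after lens-constant optimization on a 70% training
  split, with every optimized-context metric computed strictly on the
  held-out 30% test split.

The report bundle is a pure function of (config, input files): identical
config and seed produce byte-identical output files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .biometry_io import Cohort, EligibilityConfig, apply_eligibility, read_cohort
from .constant_opt import (
    SplitSpec,
    mean_error,
    offset_calibrate,
    optimize_constant,
    split_cohort,
)
from .evaluation import (
    ComparisonReport,
    DEFAULT_THRESHOLDS,
    cohort_comparison,
    compare_formulas,
    paired_abs_error_ttest,
    summarize_performance,
)
from .formulas import (
    FormulaId,
    LensConstants,
    default_constants,
    load_external_predictions,
    predict_cohort,
)
from .synthetic_data import builtin_profile, generate_cohort

__all__ = ["CohortSource", "StudyConfig", "StudyReport", "run_study", "load_config"]

NATIVE_FORMULAS: tuple[FormulaId, ...] = (
    FormulaId.SRKT,
    FormulaId.HOFFER_Q,
    FormulaId.HOLLADAY1,
    FormulaId.HAIGIS,
)


@dataclass(frozen=True)
class CohortSource:
    """Either a delimited cohort file or a simulator profile + size."""

    profile: str | None = None  # "aravind_like" / "umich_like"
    path: str | None = None
    n: int | None = None
    seed: int | None = None
    noise_sd_D: float | None = None  # override the profile's refraction noise

    def __post_init__(self) -> None:
        if (self.profile is None) == (self.path is None):
            raise ValueError("specify exactly one of profile or path")
        if self.profile is not None and self.n is None:
            raise ValueError("simulated cohort sources need n")


@dataclass(frozen=True)
class StudyConfig:
    primary: CohortSource
    reference: CohortSource
    formulas: tuple[FormulaId, ...] = NATIVE_FORMULAS
    external_predictions: Mapping[str, str] = field(default_factory=dict)
    #: Per-formula overrides of the starting ("before") constants, e.g.
    #: {"SRKT": {"A_const": 119.582}}. Optimization starts from these.
    constant_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    vertex_mm: float = 12.0
    keratometric_index: float = 1.3375
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    train_fraction: float = 0.70
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["formulas"] = [f.value for f in self.formulas]
        d["external_predictions"] = dict(self.external_predictions)
        d["constant_overrides"] = {
            k: dict(v) for k, v in self.constant_overrides.items()
        }
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> StudyConfig:
    """Read a StudyConfig from YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    for key in ("primary", "reference"):
        raw[key] = CohortSource(**raw[key])
    if "formulas" in raw:
        raw["formulas"] = tuple(FormulaId(f) for f in raw["formulas"])
    if "thresholds" in raw:
        raw["thresholds"] = tuple(float(t) for t in raw["thresholds"])
    return StudyConfig(**raw)


@dataclass
class StudyReport:
    """In-memory report bundle; ``write`` serializes it deterministically."""

    config: StudyConfig
    cohort_table: pd.DataFrame
    performance: dict[str, pd.DataFrame]          # context -> table
    comparisons: dict[str, ComparisonReport]      # context -> report
    before_after: pd.DataFrame
    optimized_constants: dict[str, LensConstants]
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        try:
            written.append(_write_csv(self.cohort_table, out / "cohort_table.csv"))
            for ctx, table in sorted(self.performance.items()):
                written.append(_write_csv(table, out / f"performance_{ctx}.csv"))
                written.append(
                    _write_json(
                        table.to_dict(orient="records"), out / f"performance_{ctx}.json"
                    )
                )
            for ctx, rep in sorted(self.comparisons.items()):
                written.append(
                    _write_csv(
                        rep.adjusted_p.reset_index(names="formula"),
                        out / f"pairwise_adjusted_p_{ctx}.csv",
                    )
                )
            written.append(_write_csv(self.before_after, out / "before_after_ttests.csv"))
            written.append(
                _write_json(
                    {
                        f: {k: v for k, v in asdict(c).items() if v is not None}
                        for f, c in sorted(self.optimized_constants.items())
                    },
                    out / "constants_optimized.json",
                )
            )
            written.append(_write_json(self.manifest, out / "manifest.json"))
        except Exception:
            for p in written:  # keep the bundle all-or-nothing
                p.unlink(missing_ok=True)
            raise


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def _write_json(obj: object, path: Path) -> Path:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, FormulaId):
            return o.value
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(
        json.dumps(obj, sort_keys=True, indent=1, default=_default) + "\n",
        encoding="utf-8",
    )
    return path


def _load_cohort(source: CohortSource, fallback_seed: int) -> Cohort:
    if source.path is not None:
        return read_cohort(source.path)
    profile = builtin_profile(source.profile)
    if source.noise_sd_D is not None:
        profile.noise_sd_D = source.noise_sd_D
    seed = source.seed if source.seed is not None else fallback_seed
    return generate_cohort(profile, source.n, seed)


def _performance_table(
    errors_by_formula: Mapping[str, np.ndarray],
    cohort_label: str,
    thresholds: tuple[float, ...],
) -> pd.DataFrame:
    rows = [
        summarize_performance(
            e, thresholds, formula_id=f, cohort_label=cohort_label
        ).to_dict()
        for f, e in errors_by_formula.items()
    ]
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full comparison study and return the report bundle.

    Stages: load/simulate cohorts → eligibility filtering → default-constant
    contexts on both cohorts → 70/30 split of the primary cohort →
    per-formula constant optimization (or mean-error offset calibration for
    external formulas) on the training split → held-out-test evaluation →
    statistical battery. Any stage failure aborts before files are written.
    """
    seed = config.seed
    primary_raw = _load_cohort(config.primary, fallback_seed=seed)
    reference_raw = _load_cohort(config.reference, fallback_seed=seed + 1)
    elig = EligibilityConfig()
    primary, log_primary = apply_eligibility(primary_raw, elig)
    reference, log_reference = apply_eligibility(reference_raw, elig)

    native = [f for f in config.formulas if f is not FormulaId.EXTERNAL]
    defaults: dict[FormulaId, LensConstants] = {}
    for f in native:
        const = default_constants(f)
        if f.value in config.constant_overrides:
            const = replace(
                const,
                **{k: float(v) for k, v in config.constant_overrides[f.value].items()},
            )
        defaults[f] = const
    vertex = config.vertex_mm

    externals: dict[str, dict[str, float]] = {}
    for label, path in sorted(config.external_predictions.items()):
        preds, _rejects = load_external_predictions(path, label)
        externals[label] = preds

    def errors_for(cohort: Cohort, constants: Mapping[FormulaId, LensConstants]):
        meas = cohort.column("postop_ref_D")
        out: dict[str, np.ndarray] = {}
        for f in native:
            out[f.value] = predict_cohort(f, cohort, constants[f], vertex) - meas
        return out

    def external_errors(cohort: Cohort, offset: Mapping[str, float] | None = None):
        meas = cohort.column("postop_ref_D")
        ids = cohort.patient_ids()
        out: dict[str, np.ndarray] = {}
        for label, preds in externals.items():
            covered = [i for i, pid in enumerate(ids) if pid in preds]
            if len(covered) != len(ids):
                raise ValueError(
                    f"external formula {label} covers {len(covered)}/{len(ids)} eyes "
                    "of the evaluated cohort; restrict to the intersection"
                )
            vec = np.array([preds[pid] for pid in ids]) - meas
            if offset is not None:
                vec = vec - offset[label]
            out[label] = vec
        return out

    # Context 1: reference cohort, shipped default constants.
    ref_errors = errors_for(reference, defaults)
    # Context 2: primary cohort (all eyes), shipped default constants.
    prim_errors = errors_for(primary, defaults)

    # Context 3: optimize on 70% of primary, evaluate on the held-out 30%.
    split = SplitSpec(train_fraction=config.train_fraction, seed=seed + 2)
    train, test = split_cohort(primary, split)
    train_ids = set(train.patient_ids())
    test_ids = set(test.patient_ids())
    assert not (train_ids & test_ids), "train/test leakage"

    optimized: dict[str, LensConstants] = {}
    train_me_after: dict[str, float] = {}
    for f in native:
        const = optimize_constant(f, train, constants=defaults[f], vertex_mm=vertex)
        optimized[f.value] = const
        train_me_after[f.value] = mean_error(f, train, const, vertex)
    ext_offsets: dict[str, float] = {}
    for label, preds in externals.items():
        ids = train.patient_ids()
        covered = [pid for pid in ids if pid in preds]
        if len(covered) != len(ids):
            raise ValueError(f"external formula {label} does not cover the training split")
        ext_offsets[label] = offset_calibrate(
            np.array([preds[pid] for pid in ids]), train.column("postop_ref_D")
        )

    test_errors_before = errors_for(test, defaults)
    test_errors_after = errors_for(
        test, {f: optimized[f.value] for f in native}
    )
    if externals:
        test_errors_before |= external_errors(test)
        test_errors_after |= external_errors(test, offset=ext_offsets)

    # Before/after paired t-tests on the held-out absolute errors.
    ba_rows = []
    for name in test_errors_after:
        t, p = paired_abs_error_ttest(
            np.abs(test_errors_before[name]), np.abs(test_errors_after[name])
        )
        ba_rows.append(
            {
                "formula": name,
                "mae_before_D": float(np.mean(np.abs(test_errors_before[name]))),
                "mae_after_D": float(np.mean(np.abs(test_errors_after[name]))),
                "t": t,
                "p": p,
            }
        )
    before_after = pd.DataFrame(ba_rows)

    performance = {
        "reference_default": _performance_table(
            ref_errors, reference.label, config.thresholds
        ),
        "primary_default": _performance_table(
            prim_errors, primary.label, config.thresholds
        ),
        "primary_default_test": _performance_table(
            test_errors_before, f"{primary.label}-test", config.thresholds
        ),
        "primary_optimized_test": _performance_table(
            test_errors_after, f"{primary.label}-test", config.thresholds
        ),
    }
    # The Friedman/Wilcoxon battery needs at least three formulas.
    comparisons = {
        ctx: compare_formulas(pd.DataFrame({k: np.abs(v) for k, v in errs.items()}))
        for ctx, errs in (
            ("reference_default", ref_errors),
            ("primary_default", prim_errors),
            ("primary_optimized_test", test_errors_after),
        )
        if len(errs) >= 3
    }
    cohort_table = cohort_comparison(primary, reference)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": seed,
        "n_primary": len(primary),
        "n_reference": len(reference),
        "n_train": len(train),
        "n_test": len(test),
        "excluded_primary": len(log_primary),
        "excluded_reference": len(log_reference),
        "train_me_after_optimization_D": train_me_after,
        "external_offsets_D": ext_offsets,
        "leakage_audit": {
            "train_test_overlap": 0,
            "optimization_used_only_train_ids": True,
        },
    }
    return StudyReport(
        config=config,
        cohort_table=cohort_table,
        performance=performance,
        comparisons=comparisons,
        before_after=before_after,
        optimized_constants=optimized,
        manifest=manifest,
    )
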