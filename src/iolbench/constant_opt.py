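"""Lens-constant optimization: zero the mean prediction error on a training split.

The prediction error of an eye is (predicted − measured) refraction. Because
each formula's predicted refraction is strictly monotone in its scalar lens
constant (A-constant, pACD, surgeon factor, or Haigis a0), the training-set
mean error ME(c) is a strictly monotone function of the constant and the
"empirical optimization" reduces to bracketed root-finding on ME(c) = 0.

Closed-source formulas whose constants cannot be touched are calibrated by
subtracting the training-set mean error from every prediction instead
(:func:`offset_calibrate`), which is locally equivalent to a constant shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .biometry_io import Cohort
from .formulas import (
    DEFAULT_VERTEX_MM,
    FormulaId,
    LensConstants,
    SCALAR_CONSTANT_FIELD,
    default_constants,
    predict_cohort,
)

__all__ = [
    "SplitSpec",
    "split_cohort",
    "mean_error",
    "optimize_constant",
    "offset_calibrate",
    "DEFAULT_BRACKETS",
]

#: Default root-finding brackets for each formula's scalar constant.
DEFAULT_BRACKETS: dict[FormulaId, tuple[float, float]] = {
    FormulaId.SRKT: (110.0, 125.0),       # A-constant
    FormulaId.HOFFER_Q: (2.0, 9.0),       # pACD, mm
    FormulaId.HOLLADAY1: (-2.0, 5.0),     # surgeon factor, mm
    FormulaId.HAIGIS: (-3.0, 3.0),        # a0, mm
}


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test partition: ``train_fraction`` of eyes train, rest test."""

    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def split_cohort(cohort: Cohort, spec: SplitSpec) -> tuple[Cohort, Cohort]:
    """Deterministic random partition into (train, test) cohorts.

    Sizes are round(n·fraction) and the remainder; membership is a pure
    function of (seed, record order). Record order within each side follows
    the original cohort order.
    """
    n = len(cohort)
    if n < 10:
        raise ValueError(f"cohort too small to split: n={n} < 10")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = round(n * spec.train_fraction)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    train = Cohort(
        label=f"{cohort.label}-train", records=[cohort.records[i] for i in train_idx]
    )
    test = Cohort(
        label=f"{cohort.label}-test", records=[cohort.records[i] for i in test_idx]
    )
    return train, test


def mean_error(
    formula_id: FormulaId,
    cohort: Cohort,
    constants: LensConstants,
    vertex_mm: float = DEFAULT_VERTEX_MM,
    *,
    check_elp: bool = True,
) -> float:
    """Mean prediction error ME = mean(predicted − measured) over the cohort, D."""
    preds = predict_cohort(formula_id, cohort, constants, vertex_mm, check_elp=check_elp)
    measured = cohort.column("postop_ref_D")
    return float(np.mean(preds - measured))


def optimize_constant(
    formula_id: FormulaId,
    train: Cohort,
    bracket: tuple[float, float] | None = None,
    tol: float = 1e-6,
    constants: LensConstants | None = None,
    vertex_mm: float = DEFAULT_VERTEX_MM,
) -> LensConstants:
    """Zero the training-set mean prediction error over the formula's scalar constant.

    Parameters
    ----------
    bracket
        Search interval for the constant; defaults per formula
        (:data:`DEFAULT_BRACKETS`). ME must change sign across it.
    tol
        Required |training ME| of the returned constants, diopters.
    constants
        Starting constant set; non-scalar fields (e.g. Haigis a1, a2) are
        carried through unchanged.

    Raises a ValueError if ME does not change sign across the bracket (widen
    it) or if sampled ME values are not monotone in the constant.
    """
    if formula_id not in DEFAULT_BRACKETS:
        raise ValueError(f"{formula_id.value} has no optimizable native constant")
    base = constants if constants is not None else default_constants(formula_id)
    lo, hi = bracket if bracket is not None else DEFAULT_BRACKETS[formula_id]

    def me(c: float) -> float:
        # Bracket endpoints may imply nonphysical lens positions; the final
        # constant is re-validated with the ELP check on.
        return mean_error(
            formula_id, train, base.with_scalar(c), vertex_mm, check_elp=False
        )

    grid = np.linspace(lo, hi, 7)
    vals = np.array([me(c) for c in grid])
    diffs = np.diff(vals)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError(
            f"mean error is not monotone in the {formula_id.value} constant over "
            f"[{lo}, {hi}]; sampled ME = {np.round(vals, 4).tolist()}"
        )
    if vals[0] * vals[-1] > 0:
        raise ValueError(
            f"mean error does not change sign over the {formula_id.value} bracket "
            f"[{lo}, {hi}] (ME {vals[0]:+.3f} → {vals[-1]:+.3f} D); widen the bracket"
        )
    root = brentq(me, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
    out = base.with_scalar(float(root))
    achieved = mean_error(formula_id, train, out, vertex_mm)
    if abs(achieved) >= tol:
        raise RuntimeError(
            f"optimization left |training ME| = {abs(achieved):.2e} D >= tol {tol}"
        )
    return out


def offset_calibrate(
    train_predictions: np.ndarray, train_measured: np.ndarray
) -> float:
    """Mean-error offset for a closed-source formula.

    Returns offset_D = mean(predicted − measured) on the training eyes.
    Subtracting it from every prediction zeroes the training ME; the same
    offset is then applied unchanged to test-set predictions.
    """
    p = np.asarray(train_predictions, dtype=float)
    m = np.asarray(train_measured, dtype=float)
    if p.shape != m.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {m.shape}")
    if p.size == 0:
        raise ValueError("cannot calibrate on an empty training set")
    return float(np.mean(p - m))
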