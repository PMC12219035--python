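"""Synthetic biometry cohorts with the structure the analysis pipeline assumes.

Real per-eye cataract-surgery datasets are rarely shareable, so the pipeline
is exercised on simulated cohorts built from population profiles:

1. correlated preoperative biometry drawn from a truncated joint normal with
   profile means/SDs/correlations;
2. a per-eye refraction target drawn from the practice pattern
   (emmetropia-seeking vs. a wider, more myopic target mix);
3. the implanted IOL power chosen as the half-diopter grid power whose
   ground-truth-formula predicted refraction is closest to the target
   (ties to the lower power), mimicking surgeon power selection;
4. the measured 1-month refraction set to the ground-truth prediction plus
   Gaussian noise.

Two built-in profiles emulate a South Indian tertiary-care population
(``aravind_like``: shorter, steeper eyes, younger, near-emmetropic targets
with small spread) and a Midwestern US population (``umich_like``: longer
eyes, older, more myopic and more dispersed targets).

Marginal means/SDs are population-level inputs; the correlations are
stipulated, transparent defaults — the generator reproduces marginal moments
and practice-pattern direction, not any real cohort's joint distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .biometry_io import BiometryRecord, Cohort, DEFAULT_BOUNDS
from .formulas import (
    FormulaId,
    LensConstants,
    default_constants,
    haigis_refraction,
    hofferq_refraction,
    holladay1_refraction,
    srkt_refraction,
)

__all__ = ["PopulationProfile", "builtin_profile", "generate_cohort", "BIOMETRY_VARS"]

#: Simulated biometry variables, in correlation-matrix order.
BIOMETRY_VARS: tuple[str, ...] = (
    "age_years",
    "AL_mm",
    "ACD_mm",
    "LT_mm",
    "CCT_um",
    "WTW_mm",
    "K1_D",
    "K2_D",
)

#: Default biometric SDs where the population tables publish only means.
_DEFAULT_SDS: dict[str, float] = {
    "age_years": 9.5,
    "ACD_mm": 0.35,
    "LT_mm": 0.40,
    "CCT_um": 33.0,
    "WTW_mm": 0.45,
    "K1_D": 1.5,
    "K2_D": 1.5,
}

#: Truncation bounds: eligibility plausibility bounds plus an age range.
_DEFAULT_TRUNCATION: dict[str, tuple[float, float]] = {
    "age_years": (40.0, 95.0),
    **{k: v for k, v in DEFAULT_BOUNDS.items() if k in BIOMETRY_VARS},
}


def _default_correlations() -> np.ndarray:
    """Stipulated biometric correlations: longer eyes have deeper chambers,
    flatter corneas and slightly thinner lenses; K1/K2 move together."""
    c = np.eye(len(BIOMETRY_VARS))
    idx = {v: i for i, v in enumerate(BIOMETRY_VARS)}

    def set_(a: str, b: str, r: float) -> None:
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = r

    set_("AL_mm", "ACD_mm", 0.45)
    set_("AL_mm", "K1_D", -0.35)
    set_("AL_mm", "K2_D", -0.35)
    set_("AL_mm", "LT_mm", -0.20)
    set_("K1_D", "K2_D", 0.90)
    return c


@dataclass
class PopulationProfile:
    """Distributional parameters for simulating one surgical population."""

    label: str
    means: dict[str, float]
    sds: dict[str, float]
    correlations: np.ndarray = field(default_factory=_default_correlations)
    sex_female_ratio: float = 0.5
    right_eye_ratio: float = 0.5
    target_mean_D: float = 0.0      # refraction-target policy (spherical equivalent)
    target_sd_D: float = 0.33
    truth_formula_id: FormulaId = FormulaId.SRKT
    truth_constants: LensConstants | None = None
    noise_sd_D: float = 0.30        # measurement + model noise on postop refraction
    iol_power_grid: np.ndarray = field(
        default_factory=lambda: np.arange(6.0, 30.0 + 1e-9, 0.5)
    )
    truncation_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TRUNCATION)
    )

    def __post_init__(self) -> None:
        missing = [v for v in BIOMETRY_VARS if v not in self.means or v not in self.sds]
        if missing:
            raise ValueError(f"profile lacks mean/SD for {missing}")
        if any(self.sds[v] <= 0 for v in BIOMETRY_VARS):
            raise ValueError("all SDs must be positive")
        if self.noise_sd_D < 0:
            raise ValueError("noise_sd_D must be >= 0")
        c = np.asarray(self.correlations, dtype=float)
        k = len(BIOMETRY_VARS)
        if c.shape != (k, k) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("correlation matrix must be symmetric with unit diagonal")
        try:
            np.linalg.cholesky(c)
        except np.linalg.LinAlgError as exc:
            raise ValueError("correlation matrix is not positive definite") from exc
        self.correlations = c
        if self.truth_constants is None:
            self.truth_constants = default_constants(self.truth_formula_id)


def builtin_profile(population_id: str) -> PopulationProfile:
    """Built-in population profiles: ``aravind_like`` or ``umich_like``.

    Marginal means (age, AL, ACD, LT, CCT, WTW, K1, K2), AL SDs, sex and
    laterality mixes, and refraction-target policies encode the published
    summary statistics of the two populations the profiles emulate; the
    remaining SDs and all correlations are the documented defaults.
    """
    if population_id == "aravind_like":
        return PopulationProfile(
            label="aravind_like",
            means={
                "age_years": 60.52,
                "AL_mm": 23.19,
                "ACD_mm": 3.28,
                "LT_mm": 4.24,
                "CCT_um": 526.13,
                "WTW_mm": 11.89,
                "K1_D": 44.20,
                "K2_D": 44.86,
            },
            sds={**_DEFAULT_SDS, "AL_mm": 0.94},
            sex_female_ratio=417 / 985,
            right_eye_ratio=556 / 985,
            target_mean_D=0.10,
            target_sd_D=0.33,
        )
    if population_id == "umich_like":
        return PopulationProfile(
            label="umich_like",
            means={
                "age_years": 70.73,
                "AL_mm": 24.15,
                "ACD_mm": 3.25,
                "LT_mm": 4.53,
                "CCT_um": 552.58,
                "WTW_mm": 12.09,
                "K1_D": 43.44,
                "K2_D": 44.32,
            },
            sds={**_DEFAULT_SDS, "AL_mm": 1.35},
            sex_female_ratio=570 / 1003,
            right_eye_ratio=512 / 1003,
            target_mean_D=-0.59,
            target_sd_D=0.93,
        )
    raise ValueError(f"unknown population_id {population_id!r}")


def _truth_predictor(profile: PopulationProfile) -> Callable:
    c = profile.truth_constants
    fid = profile.truth_formula_id
    if fid is FormulaId.SRKT:
        return lambda al, acd, km, p: srkt_refraction(al, km, p, c.A_const)
    if fid is FormulaId.HOFFER_Q:
        return lambda al, acd, km, p: hofferq_refraction(al, km, p, c.pACD_mm)
    if fid is FormulaId.HOLLADAY1:
        return lambda al, acd, km, p: holladay1_refraction(al, km, p, c.SF_mm)
    if fid is FormulaId.HAIGIS:
        return lambda al, acd, km, p: haigis_refraction(
            al, acd, km, p, c.haigis_a0, c.haigis_a1, c.haigis_a2
        )
    raise ValueError(f"{fid.value} cannot serve as a ground-truth formula")


def _draw_biometry(
    profile: PopulationProfile, n: int, rng: np.random.Generator
) -> np.ndarray:
    mu = np.array([profile.means[v] for v in BIOMETRY_VARS])
    sd = np.array([profile.sds[v] for v in BIOMETRY_VARS])
    cov = np.outer(sd, sd) * profile.correlations
    lo = np.array([profile.truncation_bounds[v][0] for v in BIOMETRY_VARS])
    hi = np.array([profile.truncation_bounds[v][1] for v in BIOMETRY_VARS])
    kept: list[np.ndarray] = []
    total = 0
    for _ in range(100):  # retry cap for truncation rejection
        draw = rng.multivariate_normal(mu, cov, size=max(n, 64), method="cholesky")
        ok = np.all((draw >= lo) & (draw <= hi), axis=1)
        kept.append(draw[ok])
        total += int(ok.sum())
        if total >= n:
            return np.vstack(kept)[:n]
    raise RuntimeError(
        "truncated-normal rejection sampling exhausted its retry cap; "
        "widen truncation_bounds or check means/SDs"
    )


def generate_cohort(profile: PopulationProfile, n: int, seed: int) -> Cohort:
    """Simulate a cohort of ``n`` eyes (one per patient) from a profile.

    Fully deterministic in (profile, n, seed). The measured postoperative
    refraction is the ground-truth formula's prediction at the implanted
    power plus N(0, noise_sd_D²) noise, so evaluating the truth formula with
    the truth constants at zero noise recovers every refraction exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    bio = _draw_biometry(profile, n, rng)
    cols = {v: bio[:, i].copy() for i, v in enumerate(BIOMETRY_VARS)}
    # Canonicalize steep/flat meridians (K2 >= K1).
    swap = cols["K1_D"] > cols["K2_D"]
    k1 = np.where(swap, cols["K2_D"], cols["K1_D"])
    k2 = np.where(swap, cols["K1_D"], cols["K2_D"])
    cols["K1_D"], cols["K2_D"] = k1, k2
    km = (k1 + k2) / 2.0

    targets = rng.normal(profile.target_mean_D, profile.target_sd_D, size=n)
    predict = _truth_predictor(profile)
    grid = np.asarray(profile.iol_power_grid, dtype=float)
    pred_grid = predict(
        cols["AL_mm"][:, None], cols["ACD_mm"][:, None], km[:, None], grid[None, :]
    )
    # Grid power whose predicted refraction is closest to the target;
    # argmin takes the first (= lower) power on ties.
    pick = np.argmin(np.abs(pred_grid - targets[:, None]), axis=1)
    iol_power = grid[pick]
    true_ref = pred_grid[np.arange(n), pick]
    postop = true_ref + rng.normal(0.0, profile.noise_sd_D, size=n)

    sex = np.where(rng.random(n) < profile.sex_female_ratio, "F", "M")
    eye = np.where(rng.random(n) < profile.right_eye_ratio, "R", "L")

    records = [
        BiometryRecord(
            patient_id=f"{profile.label}-{i:05d}",
            eye=str(eye[i]),
            age_years=float(cols["age_years"][i]),
            sex=str(sex[i]),
            AL_mm=float(cols["AL_mm"][i]),
            ACD_mm=float(cols["ACD_mm"][i]),
            LT_mm=float(cols["LT_mm"][i]),
            CCT_um=float(cols["CCT_um"][i]),
            WTW_mm=float(cols["WTW_mm"][i]),
            K1_D=float(cols["K1_D"][i]),
            K2_D=float(cols["K2_D"][i]),
            iol_power_D=float(iol_power[i]),
            postop_ref_D=float(postop[i]),
            lens_model="SN60WF",
            bscva_at_least_20_40=True,
        )
        for i in range(n)
    ]
    return Cohort(label=profile.label, records=records)
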