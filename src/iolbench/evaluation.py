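"""Performance metrics and the statistical comparison battery.

Per-formula accuracy is summarized from the per-eye prediction errors
e = predicted − measured refraction: mean error (ME), mean / median absolute
error (MAE / MedAE), root mean square absolute error (RMSAE), sample SD of
the signed error, and the percentage of eyes within absolute-error
thresholds. Formulas are compared on the same eyes with a Friedman test plus
pairwise two-sided Wilcoxon signed-rank tests (Pratt zero handling) under
Bonferroni correction; paired before/after constant settings are compared
with a paired t-test on absolute errors; cohorts are compared variable-wise
with two-sided Student t-tests (laterality as a two-proportion z-test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .biometry_io import Cohort

__all__ = [
    "PerformanceSummary",
    "ComparisonReport",
    "summarize_performance",
    "compare_formulas",
    "paired_abs_error_ttest",
    "cohort_comparison",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class PerformanceSummary:
    """Error-distribution summary for one formula on one cohort."""

    formula_id: str
    cohort_label: str
    n: int
    ME_D: float
    MAE_D: float
    MedAE_D: float
    RMSAE_D: float
    SD_D: float
    pct_within: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "formula": self.formula_id,
            "cohort": self.cohort_label,
            "n": self.n,
            "ME_D": self.ME_D,
            "MAE_D": self.MAE_D,
            "MedAE_D": self.MedAE_D,
            "RMSAE_D": self.RMSAE_D,
            "SD_D": self.SD_D,
        }
        for t, pct in sorted(self.pct_within.items()):
            d[f"within_{t}D_pct"] = pct
        return d


@dataclass(frozen=True)
class ComparisonReport:
    """Friedman omnibus plus Bonferroni-adjusted pairwise Wilcoxon results."""

    formulas: tuple[str, ...]
    friedman_stat: float
    friedman_p: float
    raw_p: pd.DataFrame
    adjusted_p: pd.DataFrame
    significant: pd.DataFrame  # adjusted p < alpha, off-diagonal
    alpha: float = 0.05
    n_eyes: int = 0


def summarize_performance(
    errors: Sequence[float] | np.ndarray,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    formula_id: str = "",
    cohort_label: str = "",
) -> PerformanceSummary:
    """Summary statistics of signed prediction errors (diopters).

    ``pct_within[t]`` counts |e| <= t inclusively. SD uses the n−1
    denominator; RMSAE = sqrt(mean(e²)) so RMSAE² = ME² + SD²·(n−1)/n.
    """
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("cannot summarize an empty error vector")
    ae = np.abs(e)
    return PerformanceSummary(
        formula_id=formula_id,
        cohort_label=cohort_label,
        n=int(e.size),
        ME_D=float(np.mean(e)),
        MAE_D=float(np.mean(ae)),
        MedAE_D=float(np.median(ae)),
        RMSAE_D=float(np.sqrt(np.mean(e**2))),
        SD_D=float(np.std(e, ddof=1)) if e.size > 1 else 0.0,
        pct_within={
            float(t): float(100.0 * np.mean(ae <= t)) for t in thresholds
        },
    )


def compare_formulas(
    abs_errors: pd.DataFrame, alpha: float = 0.05
) -> ComparisonReport:
    """Friedman + pairwise Wilcoxon signed-rank comparison of formulas.

    ``abs_errors``: rows = eyes, columns = formulas, no missing cells
    (restrict to the intersection of eyes covered by every formula upstream).
    Wilcoxon uses Pratt handling of zero differences; Bonferroni adjustment
    multiplies each raw p by the number of formula pairs (capped at 1).
    """
    if abs_errors.isna().any().any():
        raise ValueError(
            "abs_errors has missing cells; restrict to the intersection of eyes "
            "covered by every formula before comparing"
        )
    cols = list(abs_errors.columns)
    if len(cols) < 3:
        raise ValueError("need at least 3 formulas for the Friedman test")
    if len(abs_errors) < 10:
        raise ValueError("need at least 10 eyes for the comparison battery")

    mat = abs_errors.to_numpy(dtype=float)
    if np.allclose(mat, mat[:, [0]]):
        # All formulas identical on every eye: no signal; scipy's tie
        # correction degenerates, so report the exact no-difference result.
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.friedmanchisquare(*(mat[:, j] for j in range(mat.shape[1])))

    m = len(cols) * (len(cols) - 1) // 2
    raw = pd.DataFrame(np.ones((len(cols), len(cols))), index=cols, columns=cols)
    for a, b in combinations(cols, 2):
        d = abs_errors[a].to_numpy() - abs_errors[b].to_numpy()
        if np.all(d == 0):
            p_ab = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p_ab = float(
                    stats.wilcoxon(
                        abs_errors[a],
                        abs_errors[b],
                        zero_method="pratt",
                        alternative="two-sided",
                    ).pvalue
                )
        raw.loc[a, b] = raw.loc[b, a] = p_ab
    adjusted = np.minimum(raw * m, 1.0)
    np.fill_diagonal(adjusted.values, 1.0)
    significant = (adjusted < alpha) & ~np.eye(len(cols), dtype=bool)
    return ComparisonReport(
        formulas=tuple(cols),
        friedman_stat=float(stat),
        friedman_p=float(p),
        raw_p=raw,
        adjusted_p=adjusted,
        significant=significant,
        alpha=alpha,
        n_eyes=len(abs_errors),
    )


def paired_abs_error_ttest(
    abs_a: np.ndarray, abs_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided paired t-test on absolute errors of the same eyes.

    Used to test whether re-optimizing constants changed a formula's
    absolute error. Zero-variance difference vectors (every eye changed by
    the same amount) are degenerate for the t statistic; they are reported
    with a warning as p = 1 when the common difference is zero and p = 0
    otherwise.
    """
    a = np.asarray(abs_a, dtype=float)
    b = np.asarray(abs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must be aligned")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.ptp(d) < 1e-12:  # zero variance up to float rounding
        warnings.warn(
            "zero-variance paired differences; t-test is degenerate", stacklevel=2
        )
        return (0.0, 1.0) if abs(d[0]) < 1e-12 else (float("inf") * np.sign(d[0]), 0.0)
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


_COMPARISON_VARS: tuple[str, ...] = (
    "age_years",
    "iol_power_D",
    "postop_ref_D",
    "ACD_mm",
    "AL_mm",
    "CCT_um",
    "K1_D",
    "K2_D",
    "LT_mm",
    "WTW_mm",
)


def cohort_comparison(a: Cohort, b: Cohort) -> pd.DataFrame:
    """Variable-wise demographic/biometric comparison of two cohorts.

    For each variable: per-sex and overall means in both cohorts, the
    within-cohort sex-difference p (two-sided Student t-test), and the
    between-cohort p (two-sided Student t-test on all eyes). Derived rows Km
    and astigmatism are included. Laterality is compared as the proportion of
    right eyes with two-proportion z-tests. Variables missing everywhere in
    either cohort are omitted with a note row.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both cohorts must be non-empty")

    def frame(c: Cohort) -> pd.DataFrame:
        df = c.to_frame()
        df["Km_D"] = (df["K1_D"] + df["K2_D"]) / 2.0
        df["astigmatism_D"] = df["K2_D"] - df["K1_D"]
        return df

    fa, fb = frame(a), frame(b)
    variables = list(_COMPARISON_VARS) + ["Km_D", "astigmatism_D"]
    rows = []
    for var in variables:
        xa = fa[var].to_numpy(dtype=float)
        xb = fb[var].to_numpy(dtype=float)
        xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
        if xa.size == 0 or xb.size == 0:
            rows.append({"variable": var, "note": "absent in one cohort"})
            continue
        row = {"variable": var, "note": ""}
        for tag, f, x in ((a.label, fa, xa), (b.label, fb, xb)):
            vals = f[var].to_numpy(dtype=float)
            sex = f["sex"].astype(str).to_numpy()
            fem = vals[(sex == "F") & np.isfinite(vals)]
            mal = vals[(sex == "M") & np.isfinite(vals)]
            row[f"{tag}_mean_F"] = float(np.mean(fem)) if fem.size else np.nan
            row[f"{tag}_mean_M"] = float(np.mean(mal)) if mal.size else np.nan
            row[f"{tag}_mean"] = float(np.mean(x))
            with warnings.catch_warnings():
                # constant columns trigger scipy precision-loss warnings
                warnings.simplefilter("ignore", RuntimeWarning)
                if fem.size > 1 and mal.size > 1:
                    row[f"{tag}_sex_p"] = float(stats.ttest_ind(fem, mal).pvalue)
                else:
                    row[f"{tag}_sex_p"] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            row["between_p"] = float(stats.ttest_ind(xa, xb).pvalue)
        rows.append(row)

    # Laterality: right-eye proportions, two-proportion z-tests.
    def right_counts(f: pd.DataFrame) -> tuple[int, int]:
        eyes = f["eye"].astype(str)
        known = eyes.isin(["R", "L"])
        return int((eyes == "R").sum()), int(known.sum())

    ra, na_ = right_counts(fa)
    rb, nb_ = right_counts(fb)
    lat = {"variable": "laterality_right_prop", "note": "two-proportion z-test"}
    if na_ and nb_:
        lat[f"{a.label}_mean"] = ra / na_
        lat[f"{b.label}_mean"] = rb / nb_
        _, lat["between_p"] = proportions_ztest([ra, rb], [na_, nb_])
        lat["between_p"] = float(lat["between_p"])
    else:
        lat["note"] = "laterality unavailable"
    rows.append(lat)
    return pd.DataFrame(rows)
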