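import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from iolbench.biometry_io import Cohort
from iolbench.evaluation import (
    cohort_comparison,
    compare_formulas,
    paired_abs_error_ttest,
    summarize_performance,
)

import oracles
from conftest import make_record


class TestSummarizePerformance:
    def test_three_error_arithmetic(self):
        s = summarize_performance([0.1, -0.3, 0.2])
        assert s.ME_D == pytest.approx(0.0, abs=1e-15)
        assert s.MAE_D == pytest.approx(0.2)
        assert s.MedAE_D == pytest.approx(0.2)
        assert s.RMSAE_D == pytest.approx(np.sqrt(0.14 / 3))
        assert s.pct_within[0.25] == pytest.approx(100 * 2 / 3)
        assert s.pct_within[0.5] == 100.0

    def test_all_zero_errors(self):
        s = summarize_performance(np.zeros(10))
        assert (s.ME_D, s.MAE_D, s.MedAE_D, s.RMSAE_D, s.SD_D) == (0, 0, 0, 0, 0)
        assert all(v == 100.0 for v in s.pct_within.values())

    def test_matches_loop_oracle(self, rng):
        e = rng.normal(0.05, 0.4, 1000)
        s = summarize_performance(e)
        ref = oracles.loop_summary(list(e))
        assert s.ME_D == pytest.approx(ref["ME"], abs=1e-12)
        assert s.MAE_D == pytest.approx(ref["MAE"], abs=1e-12)
        assert s.MedAE_D == pytest.approx(ref["MedAE"], abs=1e-12)
        assert s.RMSAE_D == pytest.approx(ref["RMSAE"], abs=1e-12)
        assert s.SD_D == pytest.approx(ref["SD"], abs=1e-12)

    def test_threshold_boundary_inclusive(self):
        s = summarize_performance([0.25, -0.25, 0.2500000001])
        assert s.pct_within[0.25] == pytest.approx(100 * 2 / 3)

    def test_empty_vector_raises(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_performance([])

    @given(
        e=arrays(
            float,
            st.integers(2, 60),
            elements=st.floats(-3, 3, allow_nan=False, width=32),
        )
    )
    def test_metric_identities(self, e):
        s = summarize_performance(e)
        n = s.n
        assert s.MAE_D <= s.RMSAE_D + 1e-12
        assert s.RMSAE_D**2 == pytest.approx(
            s.ME_D**2 + s.SD_D**2 * (n - 1) / n, abs=1e-12
        )
        pcts = [s.pct_within[t] for t in sorted(s.pct_within)]
        assert all(a <= b + 1e-12 for a, b in zip(pcts, pcts[1:]))


class TestCompareFormulas:
    def _matrix(self, rng, n=40, k=4, shift=0.0):
        base = np.abs(rng.normal(0.3, 0.2, size=(n, 1)))
        noise = np.abs(rng.normal(0.0, 0.05, size=(n, k)))
        m = base + noise
        m[:, 0] += shift
        return pd.DataFrame(m, columns=[f"F{j}" for j in range(k)])

    def test_identical_columns_no_signal(self, rng):
        col = np.abs(rng.normal(0.3, 0.2, 30))
        df = pd.DataFrame({"A": col, "B": col, "C": col})
        rep = compare_formulas(df)
        assert rep.friedman_stat == 0.0 and rep.friedman_p == 1.0
        assert not rep.significant.to_numpy().any()

    def test_concordant_shift_matches_exact_signed_rank_tail(self, rng):
        """All 30 differences concordant: raw p is the exact two-sided
        sign-rank tail 2/2^30."""
        a = rng.uniform(0.1, 1.0, 30)
        b = a + 0.2 + rng.uniform(0.0, 0.01, 30)  # distinct magnitudes, one sign
        c = a + rng.normal(0.0, 0.3, 30)  # third column so Friedman runs
        rep = compare_formulas(pd.DataFrame({"A": a, "B": np.abs(b), "C": np.abs(c)}))
        assert rep.raw_p.loc["A", "B"] == pytest.approx(2.0**-29, rel=1e-12)

    def test_friedman_matches_hand_rank_formula(self, rng):
        m = rng.normal(0.4, 0.2, size=(12, 3))  # continuous → no ties
        df = pd.DataFrame(np.abs(m), columns=["A", "B", "C"])
        rep = compare_formulas(df.reindex(range(12)))
        hand = oracles.friedman_statistic_no_ties(np.abs(m).tolist())
        assert rep.friedman_stat == pytest.approx(hand, abs=1e-10)

    def test_bonferroni_dominates_raw_and_flags_subset(self, rng):
        df = self._matrix(rng, shift=0.15)
        rep = compare_formulas(df)
        assert (rep.adjusted_p.to_numpy() >= rep.raw_p.to_numpy() - 1e-15).all()
        raw_flags = (rep.raw_p < rep.alpha).to_numpy()
        adj_flags = rep.significant.to_numpy()
        assert np.all(adj_flags <= raw_flags)
        off = ~np.eye(len(df.columns), dtype=bool)
        m = off.sum() // 2
        expected = np.minimum(rep.raw_p.to_numpy() * m, 1.0)
        assert rep.adjusted_p.to_numpy()[off] == pytest.approx(expected[off])

    def test_invariant_under_eye_permutation(self, rng):
        df = self._matrix(rng, shift=0.1)
        perm = rng.permutation(len(df))
        rep1 = compare_formulas(df)
        rep2 = compare_formulas(df.iloc[perm].reset_index(drop=True))
        assert rep1.friedman_stat == pytest.approx(rep2.friedman_stat)
        assert rep1.raw_p.to_numpy() == pytest.approx(rep2.raw_p.to_numpy())

    def test_missing_cells_rejected(self, rng):
        df = self._matrix(rng)
        df.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="intersection"):
            compare_formulas(df)

    def test_preconditions(self, rng):
        with pytest.raises(ValueError, match="3 formulas"):
            compare_formulas(pd.DataFrame({"A": [0.1] * 12, "B": [0.2] * 12}))
        with pytest.raises(ValueError, match="10 eyes"):
            compare_formulas(pd.DataFrame({c: [0.1] * 5 for c in "ABC"}))


class TestPairedTTest:
    def test_identical_vectors_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            t, p = paired_abs_error_ttest([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert (t, p) == (0.0, 1.0)

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            t, p = paired_abs_error_ttest([0.2, 0.3, 0.4], [0.1, 0.2, 0.3])
        assert p == 0.0 and t == np.inf

    def test_ordinary_case_matches_scipy(self, rng):
        from scipy import stats

        a = np.abs(rng.normal(0.3, 0.1, 50))
        b = np.abs(rng.normal(0.27, 0.1, 50))
        t, p = paired_abs_error_ttest(a, b)
        ref = stats.ttest_rel(a, b)
        assert (t, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))

    def test_rejection_rate_matches_noncentral_t_power(self, rng):
        """Monte-Carlo rejection rate at alpha=0.05 for a true mean |e|
        reduction, against the analytic noncentral-t power."""
        from scipy import stats

        n, delta, sd, reps = 100, 0.02, 0.1, 3000
        nc = delta / (sd / np.sqrt(n))
        tcrit = stats.t.ppf(0.975, n - 1)
        power = 1 - stats.nct.cdf(tcrit, n - 1, nc) + stats.nct.cdf(-tcrit, n - 1, nc)
        diffs = rng.normal(delta, sd, size=(reps, n))
        base = np.abs(rng.normal(0.3, 0.05, size=(reps, n))) + 1.0
        rejected = 0
        for i in range(reps):
            _, p = paired_abs_error_ttest(base[i] + diffs[i], base[i])
            rejected += p < 0.05
        assert rejected / reps == pytest.approx(power, abs=0.03)


def _al_cohort(label, values, rng):
    records = []
    for i, v in enumerate(values):
        records.append(
            make_record(
                pid=f"{label}-{i}",
                al=float(np.clip(v, 18.5, 34.5)),
                sex="F" if rng.random() < 0.5 else "M",
                eye="R" if rng.random() < 0.5 else "L",
            )
        )
    return Cohort(label, records)


class TestCohortComparison:
    def test_cohort_vs_itself_null(self, aravind_cohort):
        # same records under a distinct label so per-cohort columns stay apart
        b = Cohort("copy", list(aravind_cohort.records))
        table = cohort_comparison(aravind_cohort, b)
        rows = table[table["note"] == ""]
        assert np.allclose(rows["between_p"].astype(float), 1.0)
        assert np.allclose(
            rows[f"{aravind_cohort.label}_mean"].astype(float),
            rows["copy_mean"].astype(float),
        )

    def test_axial_length_difference_detected(self, rng):
        a = _al_cohort("short", rng.normal(23.19, 0.94, 985), rng)
        b = _al_cohort("long", rng.normal(24.15, 1.35, 1003), rng)
        table = cohort_comparison(a, b).set_index("variable")
        assert table.loc["AL_mm", "between_p"] < 0.01
        assert table.loc["AL_mm", "short_mean"] < table.loc["AL_mm", "long_mean"]

    def test_type_i_error_calibrated(self, rng):
        """Equal-mean cohorts: the between-group t-test rejects ~5% of the time."""
        reps, hits = 400, 0
        for _ in range(reps):
            a = _al_cohort("a", rng.normal(23.5, 0.9, 50), rng)
            b = _al_cohort("b", rng.normal(23.5, 0.9, 50), rng)
            p = cohort_comparison(a, b).set_index("variable").loc["AL_mm", "between_p"]
            hits += p < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.025)

    def test_empty_cohort_rejected(self, aravind_cohort):
        with pytest.raises(ValueError, match="non-empty"):
            cohort_comparison(aravind_cohort, Cohort("empty", []))
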