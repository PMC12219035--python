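import numpy as np
import pytest
from hypothesis import given, strategies as st

from iolbench.biometry_io import Cohort
from iolbench.formulas import (
    FormulaId,
    LensConstants,
    convert_a_constant,
    coverage_report,
    default_constants,
    haigis_elp,
    haigis_refraction,
    hofferq_refraction,
    holladay1_refraction,
    load_external_predictions,
    predict_cohort,
    predict_refraction,
    srkt_refraction,
)

import oracles
from conftest import EYE_PANEL, make_record

NATIVE = [FormulaId.SRKT, FormulaId.HOFFER_Q, FormulaId.HOLLADAY1, FormulaId.HAIGIS]

_IMPL = {
    "SRKT": lambda al, km, acd, p, c, v=12.0: float(srkt_refraction(al, km, p, c, v)),
    "HofferQ": lambda al, km, acd, p, c, v=12.0: float(hofferq_refraction(al, km, p, c, v)),
    "Holladay1": lambda al, km, acd, p, c, v=12.0: float(holladay1_refraction(al, km, p, c, v)),
    "Haigis": lambda al, km, acd, p, c, v=12.0: float(
        haigis_refraction(al, acd, km, p, c, 0.4, 0.1, v)
    ),
}

_DEFAULT_SCALAR = {"SRKT": 119.082, "HofferQ": 5.727, "Holladay1": 1.860, "Haigis": -0.739}

# Frozen values computed with the independent vergence-chain oracle
# (tests/oracles.py) on the five-eye panel; regression guard at 1e-4 D.
_FROZEN = {
    "SRKT": [-0.251002, -0.602385, 0.266939, -0.210847, -0.086034],
    "HofferQ": [0.275210, -0.445568, 0.404745, -0.201140, -0.005766],
    "Holladay1": [-0.160784, -0.621922, 0.275814, -0.133163, -0.214122],
    "Haigis": [-4.627926, -4.442824, -2.787087, -2.738194, -1.865849],
}


class TestOracleEquivalence:
    @pytest.mark.parametrize("name", list(_IMPL))
    def test_matches_independent_vergence_chain(self, name):
        """Closed-form inversions agree with step-by-step forward root-finding."""
        c = _DEFAULT_SCALAR[name]
        for al, km, acd, p in EYE_PANEL:
            mine = _IMPL[name](al, km, acd, p, c)
            ref = oracles.ORACLES[name](al, km, acd, p, c)
            assert mine == pytest.approx(ref, abs=0.01)

    @pytest.mark.parametrize("name", list(_FROZEN))
    def test_frozen_panel_values(self, name):
        c = _DEFAULT_SCALAR[name]
        got = [_IMPL[name](al, km, acd, p, c) for al, km, acd, p in EYE_PANEL]
        assert got == pytest.approx(_FROZEN[name], abs=1e-4)


class TestFormulaProperties:
    def test_haigis_degenerate_elp_equals_a0(self):
        assert float(haigis_elp(24.0, 3.3, a0=4.2, a1=0.0, a2=0.0)) == 4.2

    @pytest.mark.parametrize("name", list(_IMPL))
    def test_refraction_strictly_decreasing_in_iol_power(self, name):
        powers = np.arange(6.0, 34.01, 0.5)
        for al, km, acd, _ in EYE_PANEL:
            refs = np.array([_IMPL[name](al, km, acd, p, _DEFAULT_SCALAR[name]) for p in powers])
            assert np.all(np.diff(refs) < 0), f"{name} not monotone at AL={al}"

    @pytest.mark.parametrize("name", list(_IMPL))
    def test_refraction_strictly_increasing_in_constant(self, name):
        """A deeper predicted lens position (larger constant) shifts the
        prediction hyperopic; this monotonicity underwrites unique-root
        constant optimization."""
        lo, hi = {
            "SRKT": (116.0, 122.0),
            "HofferQ": (3.5, 7.5),
            "Holladay1": (0.0, 3.5),
            "Haigis": (-1.5, 1.5),
        }[name]
        grid = np.linspace(lo, hi, 9)
        al, km, acd, p = EYE_PANEL[2]
        refs = np.array([_IMPL[name](al, km, acd, p, c) for c in grid])
        assert np.all(np.diff(refs) > 0)

    @pytest.mark.parametrize("name", list(_IMPL))
    def test_vertex_zero_gives_corneal_plane_refraction(self, name):
        al, km, acd, p = EYE_PANEL[1]
        c = _DEFAULT_SCALAR[name]
        spectacle = _IMPL[name](al, km, acd, p, c, 12.0)
        corneal = _IMPL[name](al, km, acd, p, c, 0.0)
        # move the 12 mm value to the corneal plane by the vertex relation
        assert spectacle / (1 - 0.012 * spectacle) == pytest.approx(corneal, abs=1e-9)

    @given(
        al=st.floats(20.0, 28.0),
        km=st.floats(40.0, 48.0),
        power=st.floats(8.0, 30.0),
    )
    def test_srkt_finite_over_plausible_inputs(self, al, km, power):
        ref = float(srkt_refraction(al, km, power, 119.082))
        assert np.isfinite(ref)
        assert -40.0 < ref < 40.0


class TestRecordInterface:
    def test_predict_refraction_result_fields(self):
        rec = make_record(al=23.5, km=43.5, acd=3.2, power=21.0)
        res = predict_refraction(FormulaId.SRKT, rec, default_constants(FormulaId.SRKT))
        assert res.patient_id == rec.patient_id
        assert 0.0 < res.elp_mm < rec.AL_mm
        assert res.predicted_ref_D == pytest.approx(0.266939, abs=1e-4)

    def test_constants_formula_mismatch_raises(self):
        rec = make_record()
        with pytest.raises(ValueError, match="constants are for"):
            predict_refraction(FormulaId.SRKT, rec, default_constants(FormulaId.HAIGIS))

    def test_elp_out_of_range_names_record(self):
        rec = make_record(pid="weird")
        bad = LensConstants(FormulaId.HAIGIS, haigis_a0=-5.0, haigis_a1=0.0, haigis_a2=0.0)
        with pytest.raises(ValueError, match="weird"):
            predict_refraction(FormulaId.HAIGIS, rec, bad)

    def test_missing_required_constant_field_raises(self):
        with pytest.raises(ValueError, match="A_const"):
            LensConstants(FormulaId.SRKT)

    def test_predict_cohort_matches_per_record(self, panel_cohort):
        const = default_constants(FormulaId.HOFFER_Q)
        vec = predict_cohort(FormulaId.HOFFER_Q, panel_cohort, const)
        for i, rec in enumerate(panel_cohort.records):
            single = predict_refraction(FormulaId.HOFFER_Q, rec, const)
            assert vec[i] == pytest.approx(single.predicted_ref_D, abs=1e-12)


class TestAConstantConversion:
    def test_near_shipped_optimized_constants(self):
        # empirical optimized constants need not coincide exactly
        assert convert_a_constant(119.082, "pACD") == pytest.approx(5.727, abs=0.5)
        assert convert_a_constant(119.082, "SF") == pytest.approx(1.860, abs=0.5)

    def test_deterministic(self):
        assert convert_a_constant(118.0, "SF") == convert_a_constant(118.0, "SF")

    def test_strictly_increasing_in_a(self):
        grid = np.linspace(110.0, 125.0, 31)
        for target in ("pACD", "SF"):
            vals = [convert_a_constant(a, target) for a in grid]
            assert np.all(np.diff(vals) > 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError, match="range"):
            convert_a_constant(100.0, "pACD")
        with pytest.raises(ValueError, match="unknown conversion"):
            convert_a_constant(118.0, "bogus")


class TestExternalPredictions:
    def test_three_row_file(self, tmp_path):
        p = tmp_path / "ext.csv"
        p.write_text("patient_id,predicted_ref_D\na,0.1\nb,-0.2\nc,0.3\n")
        preds, log = load_external_predictions(p, "Barrett")
        assert preds == {"a": 0.1, "b": -0.2, "c": 0.3}
        assert log.empty

    def test_coverage_report_lists_missing_eyes(self, tmp_path, panel_cohort):
        p = tmp_path / "ext.csv"
        rows = "".join(f"{r.patient_id},0.0\n" for r in panel_cohort.records[:-1])
        p.write_text("patient_id,predicted_ref_D\n" + rows)
        preds, _ = load_external_predictions(p, "Barrett")
        assert coverage_report(preds, panel_cohort) == [panel_cohort.records[-1].patient_id]

    def test_duplicate_id_raises(self, tmp_path):
        p = tmp_path / "ext.csv"
        p.write_text("patient_id,predicted_ref_D\na,0.1\na,0.2\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_external_predictions(p, "Barrett")

    def test_non_numeric_rejected_with_log(self, tmp_path):
        p = tmp_path / "ext.csv"
        p.write_text("patient_id,predicted_ref_D\na,0.1\nb,oops\n")
        preds, log = load_external_predictions(p, "Barrett")
        assert preds == {"a": 0.1}
        assert list(log["patient_id"]) == ["b"]

    def test_round_tripped_srkt_equals_in_process_srkt(self, tmp_path, panel_cohort):
        """Self-consistency: the external-file path reproduces the native path."""
        const = default_constants(FormulaId.SRKT)
        native = predict_cohort(FormulaId.SRKT, panel_cohort, const)
        p = tmp_path / "srkt.csv"
        lines = ["patient_id,predicted_ref_D"] + [
            f"{r.patient_id},{float(v)!r}" for r, v in zip(panel_cohort.records, native)
        ]
        p.write_text("\n".join(lines) + "\n")
        preds, _ = load_external_predictions(p, "SRKT-ext")
        meas = panel_cohort.column("postop_ref_D")
        ext_errors = np.array(
            [preds[r.patient_id] for r in panel_cohort.records]
        ) - meas
        assert ext_errors == pytest.approx(native - meas, abs=1e-12)
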