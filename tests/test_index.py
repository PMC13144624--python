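"""Unit and property tests for the Hb/kg index arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbkg.index import (
    CTD_HOUR_COLUMNS,
    ConfigurationError,
    FEMALE_NADLER,
    InvalidInputError,
    MALE_NADLER,
    MissingDataError,
    classify_bmi_group,
    classify_ctd_group,
    compute_ctd_loss,
    compute_ebv,
    compute_hbkg_index,
    compute_initial_hb_mass,
    compute_intraop_loss,
    compute_transfused_hb,
)


def _record(sex="male", height=1.80, weight=80.0, hb0=135.0, hb1=110.0,
            drain_hb=30.0, total_ml=500.0, units=0):
    return {
        "sex": sex, "height_m": height, "weight_kg": weight,
        "hb_t0": hb0, "hb_t1": hb1, "drain_hb": drain_hb,
        "ctd_total_ml": total_ml, "prbc_units": units,
    }


class TestEBV:
    @pytest.mark.parametrize("sex,height,weight,expected", [
        ("male", 1.80, 80.0, 0.3669 * 1.80**3 + 0.03219 * 80 + 0.6041),
        ("female", 1.60, 60.0, 0.3561 * 1.60**3 + 0.03308 * 60 + 0.1833),
    ])
    def test_hand_evaluated_polynomial(self, sex, height, weight, expected):
        assert compute_ebv(height, weight, sex=sex) == pytest.approx(expected)
        # the two printed worked values, to their printed precision
        assert compute_ebv(1.80, 80.0, sex="male") == pytest.approx(5.319, abs=5e-4)
        assert compute_ebv(1.60, 60.0, sex="female") == pytest.approx(3.627, abs=5e-4)

    def test_constant_term_limit(self):
        # as height, weight -> 0 the polynomial approaches k3
        eps = 1e-9
        assert compute_ebv(eps, eps, sex="male") == pytest.approx(MALE_NADLER.k3)
        assert compute_ebv(eps, eps, sex="female") == pytest.approx(FEMALE_NADLER.k3)

    @pytest.mark.parametrize("height,weight", [(0.0, 80.0), (1.8, 0.0), (-1.0, 70.0)])
    def test_nonpositive_inputs_rejected(self, height, weight):
        with pytest.raises(InvalidInputError):
            compute_ebv(height, weight, sex="male")

    @given(h=st.floats(1.3, 2.1), w=st.floats(35, 200), dh=st.floats(0.01, 0.3),
           dw=st.floats(0.5, 30))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_height_and_weight(self, h, w, dh, dw):
        base = compute_ebv(h, w, sex="female")
        assert compute_ebv(h + dh, w, sex="female") > base
        assert compute_ebv(h, w + dw, sex="female") > base


class TestStepOperations:
    def test_initial_mass_is_volume_times_concentration(self):
        assert compute_initial_hb_mass(5.0, 140.0) == pytest.approx(700.0)
        assert compute_initial_hb_mass(5.0, 0.0) == 0.0
        assert compute_initial_hb_mass(3.627, 120.0) == pytest.approx(435.24)
        with pytest.raises(InvalidInputError):
            compute_initial_hb_mass(5.0, -1.0)

    def test_intraop_loss_consistent_mode(self):
        assert compute_intraop_loss(135, 110, 5.0) == pytest.approx(125.0)
        assert compute_intraop_loss(120, 120, 4.2) == 0.0

    def test_intraop_loss_literal_mode_keeps_printed_form(self):
        # mass difference multiplied by EBV once more (units g*L)
        assert compute_intraop_loss(135, 110, 5.0, mode="literal") == pytest.approx(625.0)

    def test_intraop_loss_unknown_mode(self):
        with pytest.raises(ConfigurationError):
            compute_intraop_loss(135, 110, 5.0, mode="bogus")

    def test_hemoconcentration_is_propagated_with_warning(self):
        with pytest.warns(UserWarning, match="negative intraoperative"):
            loss = compute_intraop_loss(110, 120, 5.0)
        assert loss == pytest.approx(-50.0)

    def test_ctd_loss_converts_ml_to_l(self):
        assert compute_ctd_loss(500.0, 30.0) == pytest.approx(15.0)
        assert compute_ctd_loss([40.0] * 18, 25.0) == pytest.approx(18.0)
        assert compute_ctd_loss(800.0, 0.0) == 0.0

    def test_ctd_loss_per_interval_concentrations(self):
        # volume-weighted: 30 g/L on 100 mL + 10 g/L on 300 mL = 6 g
        assert compute_ctd_loss([100.0, 300.0], [30.0, 10.0]) == pytest.approx(6.0)
        with pytest.raises(InvalidInputError):
            compute_ctd_loss([100.0, 300.0], [30.0])

    def test_ctd_loss_negative_volume_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_ctd_loss([-1.0, 50.0], 30.0)

    def test_transfused_hb(self):
        assert compute_transfused_hb(0) == 0.0
        assert compute_transfused_hb(1) == pytest.approx(43.0)
        assert compute_transfused_hb(2, grams_per_unit=52.0) == pytest.approx(104.0)
        with pytest.raises(InvalidInputError):
            compute_transfused_hb(-1)


class TestComposedIndex:
    def test_worked_example(self):
        res = compute_hbkg_index(_record())
        assert res.ebv == pytest.approx(5.319, abs=5e-4)
        assert res.intraop_loss == pytest.approx(25 * res.ebv)
        assert res.ctd_loss == pytest.approx(15.0)
        assert res.index == pytest.approx((res.intraop_loss + 15.0) / 80.0)
        assert res.index == pytest.approx(1.850, abs=2e-3)
        # one PRBC unit lowers the index by exactly 43/weight
        res_tx = compute_hbkg_index(_record(units=1))
        assert res_tx.index == pytest.approx(1.312, abs=2e-3)

    def test_no_loss_gives_zero_index(self):
        res = compute_hbkg_index(_record(hb1=135.0, drain_hb=0.0, total_ml=0.0))
        assert res.index == 0.0

    def test_missing_field_error_names_field(self):
        rec = _record()
        del rec["hb_t1"]
        with pytest.raises(MissingDataError, match="hb_t1"):
            compute_hbkg_index(rec)
        rec = _record()
        rec["drain_hb"] = float("nan")
        with pytest.raises(MissingDataError, match="drain_hb"):
            compute_hbkg_index(rec)

    @given(units=st.integers(0, 6), weight=st.floats(45, 150),
           gpu=st.floats(30, 60))
    @settings(max_examples=50, deadline=None)
    def test_transfusion_additivity(self, units, weight, gpu):
        base = compute_hbkg_index(_record(weight=weight), grams_per_unit=gpu)
        tx = compute_hbkg_index(_record(weight=weight, units=units), grams_per_unit=gpu)
        assert tx.index == pytest.approx(base.index - units * gpu / weight, abs=1e-12)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_ctd_homogeneity(self, scale):
        vols = np.linspace(60, 5, 18)
        assert compute_ctd_loss(vols * scale, 30.0) == pytest.approx(
            scale * compute_ctd_loss(vols, 30.0), rel=1e-12)

    @given(data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_index_invariant_to_hourly_partition(self, data):
        # only the 18-h total matters, not how hours split it
        total = data.draw(st.floats(50, 1500))
        weights = np.array(data.draw(
            st.lists(st.floats(0.01, 1.0), min_size=18, max_size=18)))
        vols = total * weights / weights.sum()
        rec_a = {**_record(), "ctd_total_ml": None}
        rec_a.update({c: v for c, v in zip(CTD_HOUR_COLUMNS, vols)})
        del rec_a["ctd_total_ml"]
        rec_b = _record(total_ml=total)
        a = compute_hbkg_index(rec_a).index
        b = compute_hbkg_index(rec_b).index
        assert a == pytest.approx(b, rel=1e-9)


class TestClassification:
    @pytest.mark.parametrize("bmi,group", [
        (22.0, "I"), (24.9, "I"), (24.999, "I"),
        (25.0, "II"), (29.9, "II"), (30.0, "III"), (41.0, "III"),
    ])
    def test_bmi_groups_half_open(self, bmi, group):
        assert classify_bmi_group(bmi) == group

    def test_bmi_invalid(self):
        with pytest.raises(InvalidInputError):
            classify_bmi_group(0.0)

    @pytest.mark.parametrize("vol,group", [(0.0, "I"), (499.0, "I"), (500.0, "II")])
    def test_ctd_groups(self, vol, group):
        assert classify_ctd_group(vol) == group
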