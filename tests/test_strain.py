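"""Apparent strains and the cumulative strain partition identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skinstrain.growth import GrowthSeries, fit_sigmoid, logistic
from skinstrain.strain import (
    DiscStrainRecord,
    StrainInputWarning,
    apparent_strains,
    cumulative_strains,
    strain_time_course,
    whole_fruit_cm_areas,
)

positive_area = st.floats(1.0, 500.0)


def record(a_i, a_cm, a_dcm, dafb=100.0):
    return DiscStrainRecord("cv", dafb, a_i, a_cm, a_dcm)


class TestApparentStrains:
    def test_direct_substitution(self):
        ap = apparent_strains(record(78.5, 72.0, 66.0))
        assert ap.eps_exc_iso_pct == pytest.approx(9.848, abs=1e-3)
        assert ap.eps_extr_pct == pytest.approx(9.091, abs=1e-3)
        assert ap.eps_total_pct == pytest.approx(18.939, abs=1e-3)

    def test_fully_relaxed_disc_has_zero_strain(self):
        ap = apparent_strains(record(50.0, 50.0, 50.0))
        assert (ap.eps_exc_iso_pct, ap.eps_extr_pct, ap.eps_total_pct) == (0, 0, 0)

    @given(a_i=positive_area, a_cm=positive_area, a_dcm=positive_area)
    @settings(max_examples=200, derandomize=True)
    def test_total_independent_of_cm_area(self, a_i, a_cm, a_dcm):
        """The exc+iso and extr components always sum to (A_i - A_DCM)/A_DCM."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", StrainInputWarning)
            ap = apparent_strains(record(a_i, a_cm, a_dcm))
        direct = (a_i - a_dcm) / a_dcm * 100.0
        assert ap.eps_total_pct == pytest.approx(direct, rel=1e-12, abs=1e-12)

    def test_negative_release_warns_but_computes(self):
        with pytest.warns(StrainInputWarning):
            rec = record(50.0, 52.0, 49.0)
        assert apparent_strains(rec).eps_exc_iso_pct < 0


class TestWholeFruitScaling:
    def test_proportional_scaling(self):
        rec = record(50.0, 45.0, 40.0)  # ratios 0.9, 0.8
        a_cm, a_dcm = whole_fruit_cm_areas(rec, 400.0)
        assert a_cm == pytest.approx(360.0)
        assert a_dcm == pytest.approx(320.0)

    def test_no_release_maps_to_full_area(self):
        rec = record(50.0, 50.0, 45.0)
        a_cm, _ = whole_fruit_cm_areas(rec, 400.0)
        assert a_cm == pytest.approx(400.0)

    def test_fruit_level_apparent_strains_match_disc_level(self):
        rec = record(50.0, 45.0, 40.0)
        a_cm, a_dcm = whole_fruit_cm_areas(rec, 400.0)
        fruit_rec = record(400.0, a_cm, a_dcm)
        disc, fruit = apparent_strains(rec), apparent_strains(fruit_rec)
        assert fruit.eps_exc_iso_pct == pytest.approx(disc.eps_exc_iso_pct, rel=1e-12)
        assert fruit.eps_extr_pct == pytest.approx(disc.eps_extr_pct, rel=1e-12)


class TestCumulativeStrains:
    def test_worked_partition(self):
        cs = cumulative_strains(record(50.0, 45.0, 40.0), a_total_cm2=400.0, a0_cm2=1.0)
        assert cs.eps_total == pytest.approx(399.0)
        assert cs.eps_exc_iso == pytest.approx(40.0)
        assert cs.eps_extr == pytest.approx(40.0)
        assert cs.eps_resid == pytest.approx(319.0)
        assert cs.eps_plastic == pytest.approx(359.0)

    def test_bloom_state_is_strain_free(self):
        cs = cumulative_strains(record(50.0, 50.0, 50.0), a_total_cm2=1.0, a0_cm2=1.0)
        for v in (cs.eps_total, cs.eps_exc_iso, cs.eps_extr, cs.eps_resid):
            assert v == pytest.approx(0.0, abs=1e-12)

    @given(
        a_i=positive_area,
        r_cm=st.floats(0.5, 1.1),
        r_dcm=st.floats(0.5, 1.1),
        a_total=st.floats(2.0, 500.0),
        a0=st.floats(0.5, 2.0),
    )
    @settings(max_examples=300, derandomize=True)
    def test_conservation_identity(self, a_i, r_cm, r_dcm, a_total, a0):
        """eps_total = eps_exc+iso + eps_extr + eps_resid, always."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", StrainInputWarning)
            rec = record(a_i, a_i * r_cm, a_i * r_dcm)
        cs = cumulative_strains(rec, a_total, a0)
        total = cs.eps_exc_iso + cs.eps_extr + cs.eps_resid
        assert abs(cs.eps_total - total) < 1e-9
        assert cs.eps_plastic == pytest.approx(cs.eps_extr + cs.eps_resid, rel=1e-12)

    def test_doubling_a0_halves_all_components(self):
        rec = record(50.0, 45.0, 40.0)
        c1 = cumulative_strains(rec, 400.0, 1.0)
        c2 = cumulative_strains(rec, 400.0, 2.0)
        # (A - A0)/A0 = A/A0 - 1: the A/A0 part halves exactly
        assert c2.eps_total + 1 == pytest.approx((c1.eps_total + 1) / 2)
        assert c2.eps_exc_iso == pytest.approx(c1.eps_exc_iso / 2)
        assert c2.eps_extr == pytest.approx(c1.eps_extr / 2)

    def test_invalid_reference_area(self):
        with pytest.raises(ValueError):
            cumulative_strains(record(50, 45, 40), 400.0, a0_cm2=0.0)


@pytest.fixture(scope="module")
def growth_fit():
    t = np.arange(40.0, 161.0, 10.0)
    return fit_sigmoid(GrowthSeries("cv", t, logistic(t, 400, 0.06, 95)))


class TestTimeCourse:

    def test_constant_ratio_closed_form(self, growth_fit):
        """With fixed disc ratios, eps_resid follows A_total * r_dcm - A0."""
        times = [60.0, 90.0, 120.0, 150.0]
        recs = [record(50.0, 45.0, 40.0, dafb=t) for t in times]
        table = strain_time_course(recs, growth_fit, a0_cm2=1.0)
        for t in times:
            expected = float(growth_fit.predict(t)) * 0.8 - 1.0
            assert table.loc[t, "eps_resid_mean"] == pytest.approx(expected, rel=1e-9)
        assert bool(table["eps_total_monotone"].iloc[0])

    def test_single_disc_has_undefined_se(self, growth_fit):
        recs = [record(50.0, 45.0, 40.0, dafb=t) for t in (60.0, 90.0)]
        table = strain_time_course(recs, growth_fit)
        assert table["n"].tolist() == [1, 1]
        assert table["eps_total_se"].isna().all()

    def test_requires_two_sampling_times(self, growth_fit):
        with pytest.raises(ValueError):
            strain_time_course([record(50, 45, 40)], growth_fit)

    def test_extrapolation_flagged(self, growth_fit):
        recs = [record(50.0, 45.0, 40.0, dafb=t) for t in (90.0, 200.0)]
        with pytest.warns(UserWarning, match="extrapolation"):
            table = strain_time_course(
                recs, growth_fit, fitted_times=np.arange(40.0, 161.0, 10.0)
            )
        assert not table.loc[90.0, "extrapolated"]
        assert table.loc[200.0, "extrapolated"]
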