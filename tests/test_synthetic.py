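"""Generator determinism, noiseless closed loops, profile validation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from skinstrain.growth import GrowthSeries, fit_sigmoid
from skinstrain.strain import DiscStrainRecord, apparent_strains, cumulative_strains
from skinstrain.synthetic import (
    DEFAULT_TIMES,
    CultivarProfile,
    default_profiles,
    generate_dataset,
)
from skinstrain.tensile import TensileCurve, analyze_curve


class TestDeterminism:
    def test_same_seed_same_tables(self, profiles):
        apple, _ = profiles
        b1 = generate_dataset(apple, n_fruit=4, n_strips_per_time=2, curve_samples=60)
        b2 = generate_dataset(apple, n_fruit=4, n_strips_per_time=2, curve_samples=60)
        for name, df in b1.tables.items():
            pd.testing.assert_frame_equal(df, b2.tables[name])

    def test_same_seed_byte_identical_csvs(self, profiles, tmp_path):
        apple, _ = profiles
        for sub in ("one", "two"):
            generate_dataset(apple, n_fruit=3, n_strips_per_time=1, curve_samples=60).write(
                tmp_path / sub
            )
        for f in (tmp_path / "one").iterdir():
            assert f.read_bytes() == (tmp_path / "two" / f.name).read_bytes()

    def test_different_seed_differs(self, profiles):
        apple, _ = profiles
        other = dataclasses.replace(apple, seed=apple.seed + 1)
        b1 = generate_dataset(apple, n_fruit=3, n_strips_per_time=1, curve_samples=60)
        b2 = generate_dataset(other, n_fruit=3, n_strips_per_time=1, curve_samples=60)
        assert not b1.tables["growth"]["area_cm2"].equals(b2.tables["growth"]["area_cm2"])


class TestNoiselessClosedLoop:
    def test_growth_parameters_recovered_exactly(self, noiseless_bundle):
        profile = noiseless_bundle.profile
        g = noiseless_bundle.tables["growth"]
        whole = g[g["region"] == "whole"].groupby("dafb")["area_cm2"].mean()
        fit = fit_sigmoid(GrowthSeries("cv", whole.index.to_numpy(), whole.to_numpy()))
        assert fit.a_max == pytest.approx(profile.a_max_cm2, rel=1e-6)
        assert fit.k == pytest.approx(profile.k_growth, rel=1e-6)
        assert fit.t_mid == pytest.approx(profile.t_mid, rel=1e-6)

    def test_strain_partition_identity_is_exact(self, noiseless_bundle):
        profile = noiseless_bundle.profile
        for row in noiseless_bundle.tables["disc_areas"].itertuples():
            rec = DiscStrainRecord("cv", row.dafb, row.a_i_mm2, row.a_cm_mm2, row.a_dcm_mm2)
            cs = cumulative_strains(rec, float(profile.area_cm2(row.dafb)), 1.0)
            resid = cs.eps_total - (cs.eps_exc_iso + cs.eps_extr + cs.eps_resid)
            assert abs(resid) < 1e-9

    def test_final_apparent_strains_match_design(self, noiseless_bundle):
        df = noiseless_bundle.tables["disc_areas"]
        last = df[df["dafb"] == df["dafb"].max()].iloc[0]
        ap = apparent_strains(
            DiscStrainRecord("cv", last.dafb, last.a_i_mm2, last.a_cm_mm2, last.a_dcm_mm2)
        )
        truth = noiseless_bundle.truth
        assert ap.eps_total_pct == pytest.approx(truth["apparent_eps_total_final_pct"], rel=1e-9)
        assert ap.eps_exc_iso_pct == pytest.approx(
            truth["apparent_eps_exc_iso_final_pct"], rel=1e-9
        )

    def test_area_ordering_invariants_hold(self, noiseless_bundle):
        df = noiseless_bundle.tables["disc_areas"]
        assert (df["a_i_mm2"] >= df["a_cm_mm2"] - 1e-12).all()
        assert (df["a_cm_mm2"] >= df["a_dcm_mm2"] - 1e-12).all()
        cm = noiseless_bundle.tables["cuticle_mass"]
        assert (cm["cm_ug"] >= cm["dcm_ug"]).all()

    def test_tensile_truth_recovered(self, noiseless_bundle):
        curves = noiseless_bundle.tables["tensile_curves"]
        strip = noiseless_bundle.truth["tensile_strips"][-1]
        grp = curves[curves["strip_id"] == strip["strip_id"]].sort_values("strain_pct")
        summary = analyze_curve(
            TensileCurve(
                strip_id=strip["strip_id"], cultivar="cv", dafb=strip["dafb"],
                strain_pct=grp["strain_pct"].to_numpy(), force_n=grp["force_n"].to_numpy(),
            )
        )
        assert summary.f_max_n == pytest.approx(strip["f_max"], rel=1e-9)
        assert summary.eps_max_pct == pytest.approx(strip["eps_max"], rel=1e-9)
        assert summary.stiffness_n_per_pct == pytest.approx(strip["stiffness"], rel=0.02)


class TestProfiles:
    def test_default_profiles_document_study_conditions(self):
        apple, tommy = default_profiles()
        assert apple.a_max_cm2 * apple.k_growth / 4 == pytest.approx(3.03, rel=1e-9)
        assert tommy.a_max_cm2 * tommy.k_growth / 4 == pytest.approx(3.85, rel=1e-9)
        assert (apple.t_mid, tommy.t_mid) == (94.0, 103.0)

    def test_designed_final_apparent_strains(self, bundles):
        apple_truth = bundles[0].truth
        tommy_truth = bundles[1].truth
        assert apple_truth["apparent_eps_total_final_pct"] == pytest.approx(28.9, abs=0.05)
        assert tommy_truth["apparent_eps_total_final_pct"] == pytest.approx(24.9, abs=0.05)

    def test_validation_gates(self):
        apple, _ = default_profiles()
        with pytest.raises(ValueError):
            dataclasses.replace(apple, cv_area=0.9)
        with pytest.raises(ValueError):
            dataclasses.replace(apple, k_growth=-0.1)
        with pytest.raises(ValueError):
            dataclasses.replace(apple, c_dcm=1.5)  # ratio would leave (0, 1.2]

    def test_generation_input_gates(self, profiles):
        apple, _ = profiles
        with pytest.raises(ValueError):
            generate_dataset(apple, times=())
        with pytest.raises(ValueError):
            generate_dataset(apple, n_fruit=0)

    def test_truth_bundle_serializes(self, tmp_path, profiles):
        apple, _ = profiles
        bundle = generate_dataset(apple, n_fruit=2, n_strips_per_time=1, curve_samples=60)
        bundle.write(tmp_path)
        assert (tmp_path / "truth.json").exists()
        assert (tmp_path / "growth.csv").exists()


def test_tensile_trends_follow_development(bundles):
    """Across DAFB, stiffness rises and fracture strain falls (both cultivars)."""
    for bundle in bundles:
        truths = pd.DataFrame(bundle.truth["tensile_strips"])
        per_time = truths.groupby("dafb")[["stiffness", "eps_max"]].first()
        assert per_time["stiffness"].is_monotonic_increasing
        assert per_time["eps_max"].is_monotonic_decreasing
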