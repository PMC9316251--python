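"""Girth/volume/surface oracles, allometric normalization, derived subsets."""

import math

import numpy as np
import pytest

import torsoshape as ts
from torsoshape.anthro import (AllometricCoefficients, allometric_normalize,
                               compute_volume_surface, contour_girth_mm,
                               derive_model_parameters, extract_anthropometrics)
from torsoshape.geometry import (Band, band_centres, extract_band_profiles,
                                 extract_limb_profiles, locate_xiphoid,
                                 segment_and_align)
from torsoshape.pipeline import analytic_profile_set

from conftest import cylinder_scan


def _bands_from_radius(radius_fn, z_values, n=400):
    """Noise-free circular bands with radius radius_fn(z) (mm)."""
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return [Band(points=np.column_stack([radius_fn(z) * np.cos(theta),
                                         radius_fn(z) * np.sin(theta)]),
                 centre_height=float(z))
            for z in z_values]


class TestGirths:
    def test_cylinder_girths(self):
        """r = 15 cm cylinder: every torso girth is 2*pi*15 = 94.25 cm."""
        p, scan = cylinder_scan(radius_mm=150.0, noise_mm=0.0, n=60000, seed=2)
        lm = locate_xiphoid(scan.neck_height_mm, scan.buttock_height_mm)
        profiles = extract_band_profiles(segment_and_align(scan, lm))
        truth = {"thigh_girth_cm": p.thigh_girth_cm, "bicep_girth_cm": p.bicep_girth_cm,
                 "leg_volume_l": p.leg_volume_l, "arm_volume_l": p.arm_volume_l,
                 "leg_sa_m2": p.leg_sa_m2, "arm_sa_m2": p.arm_sa_m2}
        rec = extract_anthropometrics(profiles, lm, limb_truth=truth,
                                      height_cm=p.height_cm)
        expected = 2 * math.pi * 15.0
        for girth in (rec.waist_girth, rec.stomach_girth, rec.hip_girth,
                      rec.chest_girth):
            assert girth == pytest.approx(expected, rel=0.005)
        assert rec.waist_girth == pytest.approx(rec.stomach_girth, rel=0.005)

    def test_waist_matches_superellipse_quadrature_oracle(self, small_cohort,
                                                          small_basis):
        """Scan-extracted waist girth vs the analytic perimeter oracle."""
        for p, scan in zip(small_cohort.participants[:2], small_cohort.scans[:2]):
            pcs, rec = ts.scan_features(scan, small_basis, participant=p)
            assert rec.waist_girth == pytest.approx(p.waist_girth_cm(), rel=0.005)

    def test_hourglass_waist_located_at_minimum(self):
        """A surface with its minimum girth mid-torso puts the waist there."""
        zs = band_centres(400.0)
        bands = _bands_from_radius(
            lambda z: 150.0 - 40.0 * np.exp(-((z - 200.0) / 80.0) ** 2), zs)
        from torsoshape.geometry import ProfileSet
        profiles = ProfileSet(bands=bands, torso_length=400.0)
        lm = ts.Landmarks(neck_height=700.0, buttock_height=0.0,
                          xiphoid_height=400.0)
        rec = extract_anthropometrics(
            profiles, lm, limb_truth={
                "thigh_girth_cm": (56, 56), "bicep_girth_cm": (33, 33),
                "leg_volume_l": (9, 9), "arm_volume_l": (3, 3),
                "leg_sa_m2": (0.5, 0.5), "arm_sa_m2": (0.3, 0.3)},
            height_cm=177.9)
        girths = [contour_girth_mm(b) for b in profiles.bands]
        assert int(np.argmin(girths)) == 12  # middle of 25 bands
        assert rec.waist_girth == pytest.approx(2 * math.pi * 11.0, rel=0.01)


class TestVolumeSurface:
    def test_cylinder_volume_and_lateral_surface(self):
        zs = (np.arange(25) + 0.5) / 25 * 500.0  # 500 mm segment incl. end caps
        bands = _bands_from_radius(lambda z: 100.0, zs)
        vol, sa = compute_volume_surface(bands)
        assert vol == pytest.approx(math.pi * 10.0**2 * 50.0 / 1000.0, rel=0.01)
        assert sa == pytest.approx(2 * math.pi * 0.10 * 0.50, rel=0.01)

    def test_cone_volume(self):
        """r: 10 cm -> 0 over h = 30 cm; midpoint-style rule within 2%."""
        h = 300.0
        zs = (np.arange(25) + 0.5) / 25 * h
        bands = _bands_from_radius(lambda z: 100.0 * (1.0 - z / h) + 1e-9, zs)
        vol, _ = compute_volume_surface(bands)
        # (1/3) pi r^2 h = (1/3) pi (100 mm)^2 (300 mm) = 3.1416 L
        assert vol == pytest.approx(math.pi * 100.0**2 * 300.0 / 3.0 / 1e6,
                                    rel=0.02)

    def test_single_band_raises(self):
        bands = _bands_from_radius(lambda z: 100.0, [10.0])
        with pytest.raises(ValueError, match="2 bands"):
            compute_volume_surface(bands)

    def test_unordered_heights_raise(self):
        bands = _bands_from_radius(lambda z: 100.0, [10.0, 30.0, 20.0])
        with pytest.raises(ValueError, match="increasing"):
            compute_volume_surface(bands)

    def test_limb_extraction_close_to_truth(self, small_cohort):
        """Scan-extracted limb girths match generator truth within 2%."""
        p, scan = small_cohort.participants[0], small_cohort.scans[0]
        lm = locate_xiphoid(scan.neck_height_mm, scan.buttock_height_mm)
        limbs = extract_limb_profiles(scan, lm)
        thigh = max(contour_girth_mm(b) for b in limbs["left_leg"]) / 10.0
        bicep = max(contour_girth_mm(b) for b in limbs["left_arm"]) / 10.0
        assert thigh == pytest.approx(p.thigh_girth_cm[0], rel=0.02)
        assert bicep == pytest.approx(p.bicep_girth_cm[0], rel=0.02)


class TestAllometricNormalization:
    def test_exact_power(self):
        assert allometric_normalize(100.0, 10.0, beta=2.0) == pytest.approx(1.0)

    def test_beta_zero_is_identity(self):
        assert allometric_normalize(42.0, 180.0, beta=0.0) == pytest.approx(42.0)

    def test_proportional_subjects_normalize_equal(self):
        beta = 1.3
        heights = np.array([160.0, 175.0, 190.0])
        y = 0.04 * heights**beta
        normed = [allometric_normalize(v, h, beta) for v, h in zip(y, heights)]
        np.testing.assert_allclose(normed, normed[0])

    def test_normalization_removes_height_dependence(self):
        rng = np.random.default_rng(0)
        heights = rng.normal(177.9, 6.8, 500)
        y = 0.5 * heights**1.0 * np.exp(0.001 * rng.standard_normal(500))
        normed = y / heights
        assert abs(np.corrcoef(normed, heights)[0, 1]) < 0.05

    def test_non_positive_inputs_raise(self):
        with pytest.raises(ValueError):
            allometric_normalize(-1.0, 180.0, 1.0)
        with pytest.raises(ValueError):
            allometric_normalize(10.0, 0.0, 1.0)


class TestDerivedParameters:
    @pytest.fixture()
    def record(self):
        return ts.AnthroRecord(
            waist_girth=90.0, stomach_girth=95.0, hip_girth=100.0,
            chest_girth=98.0, torso_length=40.0,
            thigh_girth=(55.0, 57.0), bicep_girth=(33.0, 35.0),
            torso_volume=40.0, leg_volume=(10.0, 10.0), arm_volume=(5.0, 5.0),
            torso_sa=0.6, leg_sa=(0.5, 0.5), arm_sa=(0.25, 0.25),
            height=177.9)

    def test_averages_and_ratios(self, record):
        params = derive_model_parameters(
            record, AllometricCoefficients(default_beta=0.0))
        assert params.size5["avg_thigh_girth"] == pytest.approx(56.0)
        assert params.volume5["torso_limbs_volume_ratio"] == pytest.approx(40.0 / 30.0)
        assert params.volume5["legs_arms_volume_ratio"] == pytest.approx(2.0)

    def test_wht5r_closed_form(self, record):
        assert record.wht5r == pytest.approx(90.0 / math.sqrt(177.9), abs=1e-9)
        assert record.wht5r == pytest.approx(6.748, abs=0.001)

    def test_exactly_five_per_subset(self, record):
        params = derive_model_parameters(record)
        assert len(params.size5) == len(params.volume5) == len(params.sa5) == 5
        assert len(params.as_row()) == 15

    def test_waist_above_stomach_rejected(self):
        with pytest.raises(ValueError, match="waist"):
            ts.AnthroRecord(
                waist_girth=99.0, stomach_girth=95.0, hip_girth=100.0,
                chest_girth=98.0, torso_length=40.0,
                thigh_girth=(55.0, 57.0), bicep_girth=(33.0, 35.0),
                torso_volume=40.0, leg_volume=(10.0, 10.0), arm_volume=(5.0, 5.0),
                torso_sa=0.6, leg_sa=(0.5, 0.5), arm_sa=(0.25, 0.25),
                height=177.9)


def test_analytic_profiles_match_scan_girths(small_cohort):
    """The analytic profile set and the scan pipeline agree on girths."""
    p, scan = small_cohort.participants[3], small_cohort.scans[3]
    lm = locate_xiphoid(scan.neck_height_mm, scan.buttock_height_mm)
    scan_profiles = extract_band_profiles(segment_and_align(scan, lm))
    exact_profiles = analytic_profile_set(p)
    for bs, be in zip(scan_profiles.bands[::6], exact_profiles.bands[::6]):
        assert contour_girth_mm(bs) == pytest.approx(contour_girth_mm(be),
                                                     rel=0.01)
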