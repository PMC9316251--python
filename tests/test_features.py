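"""Fourier-descriptor identities and shape-basis contracts."""

import numpy as np
import pytest

import torsoshape as ts
from torsoshape.features import (FREQUENCIES, ClosedContour, complex_to_real,
                                 fit_shape_basis, fourier_descriptors,
                                 profile_set_features, project_to_shape_params,
                                 real_to_complex, reconstruct_contour,
                                 smooth_and_resample)

from conftest import circle_band


def uniform_contour(fx, fy, m=128):
    t = 2 * np.pi * np.arange(m) / m
    return ClosedContour(points=np.column_stack([fx(t), fy(t)]), centre_height=0.0)


class TestSmoothAndResample:
    def test_reproduces_constant_radius(self):
        for m in (64, 128, 200):
            contour = smooth_and_resample(
                circle_band(300, radius=1.0, uniform=True), m=m)
            r = np.hypot(contour.points[:, 0], contour.points[:, 1])
            np.testing.assert_allclose(r, 1.0, atol=1e-6)

    def test_smoothing_reduces_noise(self):
        pts = circle_band(400, radius=1.0, noise=0.02, seed=7)
        raw_rms = np.sqrt(np.mean((np.hypot(*pts.T) - 1.0) ** 2))
        contour = smooth_and_resample(pts)
        r = np.hypot(contour.points[:, 0], contour.points[:, 1])
        smooth_rms = np.sqrt(np.mean((r - 1.0) ** 2))
        assert smooth_rms < raw_rms

    def test_angular_gap_raises(self):
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, 1.5 * np.pi, 200)  # 270-degree arc
        pts = np.column_stack([np.cos(theta), np.sin(theta)])
        with pytest.raises(ValueError, match="gap"):
            smooth_and_resample(pts)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            smooth_and_resample(np.zeros((5, 2)))


class TestFourierDescriptors:
    def test_unit_circle(self):
        c = fourier_descriptors(uniform_contour(np.cos, np.sin))
        idx = FREQUENCIES.index(1)
        assert c[idx] == pytest.approx(1.0, abs=1e-9)
        others = np.delete(c, idx)
        assert np.max(np.abs(others)) < 1e-9

    def test_ellipse_closed_form(self):
        a, b = 2.0, 1.0
        c = fourier_descriptors(uniform_contour(lambda t: a * np.cos(t),
                                                lambda t: b * np.sin(t)))
        assert c[FREQUENCIES.index(1)] == pytest.approx((a + b) / 2, abs=1e-9)
        assert c[FREQUENCIES.index(-1)] == pytest.approx((a - b) / 2, abs=1e-9)
        mask = [k not in (1, -1) for k in FREQUENCIES]
        assert np.max(np.abs(c[mask])) < 1e-9

    def test_translation_only_moves_dc(self):
        base = fourier_descriptors(uniform_contour(np.cos, np.sin))
        tx, ty = 0.3, -0.7
        shifted = fourier_descriptors(
            uniform_contour(lambda t: np.cos(t) + tx, lambda t: np.sin(t) + ty))
        assert shifted[0] - base[0] == pytest.approx(tx + 1j * ty, abs=1e-12)
        np.testing.assert_allclose(shifted[1:], base[1:], atol=1e-12)

    @pytest.mark.parametrize("k", [1, -1, 2, -2])
    def test_rotation_phase_law(self, k):
        """Rotating the shape by phi leaves |c_k| fixed and shifts the phase
        by -(k-1)phi under the uniform-polar-angle resampling convention."""
        def radius(t):
            # harmonics at n = 1, 2, 3 so every tested frequency is non-trivial
            return 1.0 + 0.08 * np.cos(t) + 0.2 * np.cos(2 * t) + 0.1 * np.sin(3 * t)

        phi = 0.4
        base = fourier_descriptors(
            uniform_contour(lambda t: radius(t) * np.cos(t),
                            lambda t: radius(t) * np.sin(t)))
        rot = fourier_descriptors(
            uniform_contour(lambda t: radius(t - phi) * np.cos(t),
                            lambda t: radius(t - phi) * np.sin(t)))
        i = FREQUENCIES.index(k)
        assert abs(rot[i]) == pytest.approx(abs(base[i]), abs=1e-9)
        assert rot[i] == pytest.approx(base[i] * np.exp(-1j * (k - 1) * phi),
                                       abs=1e-9)

    def test_radius_fft_alternative(self):
        """The real-FFT radius convention: a circle of radius R about its
        centroid has R at frequency 0 and nothing elsewhere."""
        c = fourier_descriptors(uniform_contour(lambda t: 2.0 * np.cos(t),
                                                lambda t: 2.0 * np.sin(t)),
                                kind="radius")
        assert c[0] == pytest.approx(2.0, abs=1e-9)
        assert np.max(np.abs(c[1:])) < 1e-9
        with pytest.raises(ValueError, match="kind"):
            fourier_descriptors(uniform_contour(np.cos, np.sin), kind="bogus")

    def test_round_trip_area_within_two_percent(self):
        """The 10 kept coefficients reconstruct an ellipse-like contour's area."""
        def radius(t):
            return 1.0 + 0.15 * np.cos(2 * t) + 0.05 * np.cos(3 * t + 0.5)

        contour = uniform_contour(lambda t: 1.4 * radius(t) * np.cos(t),
                                  lambda t: radius(t) * np.sin(t))
        rec = reconstruct_contour(fourier_descriptors(contour))

        def shoelace(p):
            x, y = p[:, 0], p[:, 1]
            return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

        assert shoelace(rec) == pytest.approx(shoelace(contour.points), rel=0.02)


def test_feature_vector_contract(small_cohort, small_basis):
    """Every torso yields exactly 250 complex (500 real) features."""
    scan = small_cohort.scans[0]
    lm = ts.locate_xiphoid(scan.neck_height_mm, scan.buttock_height_mm)
    scaled = ts.centroid_size_scale(
        ts.extract_band_profiles(ts.segment_and_align(scan, lm)))
    feats = profile_set_features(scaled)
    assert feats.shape == (500,)
    assert len(real_to_complex(feats)) == 250
    np.testing.assert_allclose(complex_to_real(real_to_complex(feats)), feats)


class TestShapeBasis:
    def test_rank_one_recovery(self):
        rng = np.random.default_rng(0)
        direction = rng.standard_normal(500)
        direction /= np.linalg.norm(direction)
        x = 3.0 + np.outer(rng.standard_normal(40), direction)
        basis = fit_shape_basis(x, k=10)
        cosine = abs(basis.components[0] @ direction)
        assert cosine > 0.999
        assert np.all(basis.eigenvalues[1:] < 1e-20 * basis.eigenvalues[0] + 1e-12)

    def test_orthonormality_large_cohort(self):
        rng = np.random.default_rng(1)
        basis = fit_shape_basis(rng.standard_normal((5000, 500)), k=10)
        gram = basis.components @ basis.components.T
        assert np.max(np.abs(gram - np.eye(10))) < 1e-8
        assert np.all(np.diff(basis.eigenvalues) <= 1e-10)

    def test_row_permutation_invariance(self, reference_features):
        b1 = fit_shape_basis(reference_features, k=10)
        rng = np.random.default_rng(5)
        b2 = fit_shape_basis(reference_features[rng.permutation(60)], k=10)
        np.testing.assert_allclose(b2.components, b1.components, atol=1e-8)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            fit_shape_basis(np.zeros((5, 500)), k=10)  # n <= k
        bad = np.random.default_rng(0).standard_normal((20, 500))
        bad[3, 7] = np.nan
        with pytest.raises(ValueError):
            fit_shape_basis(bad, k=10)

    def test_save_load_roundtrip(self, small_basis, tmp_path):
        path = tmp_path / "basis.json"
        small_basis.save(path)
        loaded = ts.ShapeBasis.load(path)
        np.testing.assert_allclose(loaded.components, small_basis.components)
        np.testing.assert_allclose(loaded.mean, small_basis.mean)
        assert loaded.n_fit == small_basis.n_fit


class TestProjection:
    def test_mean_maps_to_zero(self, small_basis):
        np.testing.assert_allclose(
            project_to_shape_params(small_basis.mean, small_basis), 0.0,
            atol=1e-9)

    def test_reconstruction_identity(self, small_basis):
        f = small_basis.mean + 2.0 * small_basis.components[2]
        pcs = project_to_shape_params(f, small_basis)
        expected = np.zeros(10)
        expected[2] = 2.0
        np.testing.assert_allclose(pcs, expected, atol=1e-9)

    def test_length_mismatch_raises(self, small_basis):
        with pytest.raises(ValueError, match="length"):
            project_to_shape_params(np.zeros(100), small_basis)

    def test_external_cohort_scores_are_correlated(self, reference_features,
                                                   default_config):
        """Scores of a different cohort on a frozen basis are not orthogonal."""
        from torsoshape.cohort import generate_participant
        from torsoshape.pipeline import participant_features

        basis = fit_shape_basis(reference_features, k=10)
        seqs = np.random.SeedSequence([91, 4]).spawn(40)
        other = np.vstack([
            participant_features(
                generate_participant(default_config, i, np.random.default_rng(s)))
            for i, s in enumerate(seqs)])
        scores = project_to_shape_params(other, basis)
        corr = np.corrcoef(scores.T)
        off = np.abs(corr - np.diag(np.diag(corr)))
        assert off.max() > 0.05
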