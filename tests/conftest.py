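"""Shared fixtures: small deterministic cohorts, scans and shape bases."""

import numpy as np
import pytest

import torsoshape as ts
from torsoshape.pipeline import build_reference_basis, participant_features


@pytest.fixture(scope="session")
def default_config():
    return ts.GeneratorConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """Four-subject cohort with scans (deterministic)."""
    return ts.generate_cohort(ts.GeneratorConfig(n_subjects=4, seed=42))


@pytest.fixture(scope="session")
def small_basis(default_config):
    """Shape basis fit on a small analytic reference cohort."""
    return build_reference_basis(default_config, n_ref=60, seed=3)


@pytest.fixture(scope="session")
def reference_features(default_config):
    """Analytic feature matrix of a 60-subject reference cohort."""
    seqs = np.random.SeedSequence([3, 77]).spawn(60)
    feats = np.empty((60, 500))
    for i, seq in enumerate(seqs):
        p = ts.generate_participant(default_config, i, np.random.default_rng(seq))
        feats[i] = participant_features(p)
    return feats


def circle_band(n=200, radius=1.0, noise=0.0, seed=0, centre=(0.0, 0.0),
                uniform=False):
    """Points on a circle, optional radial noise.

    ``uniform=True`` places points at exactly uniform angles, so the band
    centroid coincides with the circle centre and the radius function is a
    true constant (the noise-free exactness oracle); random angles emulate
    scanner sampling.
    """
    rng = np.random.default_rng(seed)
    if uniform:
        theta = 2 * np.pi * np.arange(n) / n
    else:
        theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = radius + noise * rng.standard_normal(n)
    return np.column_stack([centre[0] + r * np.cos(theta),
                            centre[1] + r * np.sin(theta)])


def cylinder_scan(radius_mm=150.0, noise_mm=0.0, n=60000, seed=0):
    """Noisy scan of the circular-cylinder participant (no limbs)."""
    p = ts.cylinder_participant(radius_mm=radius_mm)
    cfg = ts.GeneratorConfig(n_points=n, scanner_noise_sd_mm=noise_mm,
                             render_limbs=False)
    return p, ts.render_scan(p, cfg, np.random.default_rng(seed))
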