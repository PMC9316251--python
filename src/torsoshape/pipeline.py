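"""End-to-end orchestration: cohort -> scans -> features -> parameter table
-> model comparison.

The shape basis is fit once on a separate synthetic reference cohort
(mirroring the study design, in which eigenvectors came from an external
reference sample) and then frozen; study cohorts are projected onto it.
Reference features are computed from noise-free analytic contours, study
features from the full scan-processing chain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bodycomp
from .anthro import derive_model_parameters, extract_anthropometrics
from .cohort import (Cohort, GeneratorConfig, LabeledScan, SyntheticParticipant,
                     generate_participant, render_scan)
from .comparison import MODEL_TYPES, ModelComparison
from .features import (ShapeBasis, fit_shape_basis, profile_set_features,
                       project_to_shape_params)
from .geometry import (Band, ProfileSet, band_centres, centroid_size_scale,
                       extract_band_profiles, extract_limb_profiles,
                       locate_xiphoid, segment_and_align)
from .report import ComparisonReport

__all__ = [
    "analytic_profile_set",
    "participant_features",
    "build_reference_basis",
    "scan_features",
    "run_study",
    "compare_models",
]


def analytic_profile_set(p: SyntheticParticipant, n_theta: int = 256) -> ProfileSet:
    """Exact band contours sampled from the parametric surface (no scan).

    Bands are placed at the standard 25 centres of the torso segment; the
    frame matches the scan pipeline's anatomical convention (z = 0 at the
    buttock, x/y origin on the xiphoid-level centre line).
    """
    length = p.xiphoid_height_mm - p.buttock_height_mm
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    x0 = p.centre_x(p.xiphoid_height_mm)
    bands = []
    for c in band_centres(length):
        pts = p.section_points(p.buttock_height_mm + c, theta)
        pts = pts - np.array([x0, 0.0])
        bands.append(Band(points=pts, centre_height=float(c)))
    return ProfileSet(bands=bands, torso_length=length)


def participant_features(p: SyntheticParticipant) -> np.ndarray:
    """500-real shape features straight from the analytic surface."""
    scaled = centroid_size_scale(analytic_profile_set(p))
    return profile_set_features(scaled, fast=True)


def build_reference_basis(config: GeneratorConfig | None = None,
                          n_ref: int = 400, seed: int = 1234,
                          k: int = 10) -> ShapeBasis:
    """Fit the frozen shape basis on a synthetic reference cohort.

    The reference cohort shares the generator's population structure but is
    drawn from its own seed, so study cohorts are genuinely projected onto
    eigenvectors from a different sample.
    """
    config = config or GeneratorConfig()
    seqs = np.random.SeedSequence([seed, 77]).spawn(n_ref)
    feats = np.empty((n_ref, 500))
    for i, seq in enumerate(seqs):
        p = generate_participant(config, i, np.random.default_rng(seq))
        feats[i] = participant_features(p)
    return fit_shape_basis(feats, k=k, seed=seed)


def scan_features(scan: LabeledScan, basis: ShapeBasis,
                  smoothing: float | str = "auto",
                  limb_source: str = "scan",
                  participant: SyntheticParticipant | None = None):
    """Full per-scan processing: segmentation to shape parameters + anthro.

    Returns (shape_params (10,), AnthroRecord).  ``limb_source`` "scan"
    extracts limb measures from the limb proxy clouds; "truth" reads them
    from the participant record (fast mode).
    """
    landmarks = locate_xiphoid(scan.neck_height_mm, scan.buttock_height_mm)
    torso = segment_and_align(scan, landmarks)
    profiles = extract_band_profiles(torso)
    scaled = centroid_size_scale(profiles)
    feats = profile_set_features(scaled, smoothing=smoothing)
    pcs = project_to_shape_params(feats, basis)

    if limb_source == "scan":
        limb_bands = extract_limb_profiles(scan, landmarks)
        record = extract_anthropometrics(
            profiles, landmarks, limb_bands=limb_bands,
            height_cm=participant.height_cm if participant else None,
            subject_id=scan.subject_id, smoothing=smoothing)
    elif limb_source == "truth":
        if participant is None:
            raise ValueError("limb_source='truth' requires the participant record")
        truth = {"thigh_girth_cm": participant.thigh_girth_cm,
                 "bicep_girth_cm": participant.bicep_girth_cm,
                 "leg_volume_l": participant.leg_volume_l,
                 "arm_volume_l": participant.arm_volume_l,
                 "leg_sa_m2": participant.leg_sa_m2,
                 "arm_sa_m2": participant.arm_sa_m2}
        record = extract_anthropometrics(
            profiles, landmarks, limb_truth=truth,
            height_cm=participant.height_cm, subject_id=scan.subject_id,
            smoothing=smoothing)
    else:
        raise ValueError("limb_source must be 'scan' or 'truth'")
    return pcs, record


def run_study(config: GeneratorConfig, basis: ShapeBasis | None = None,
              n_ref: int = 400, limb_source: str = "scan",
              cohort: Cohort | None = None) -> pd.DataFrame:
    """Generate (or accept) a cohort and build the full parameter table.

    Columns: subject_id, PC1..PC10, the three size subsets, the measured
    dependents fat_pct / tpfr, and the generator truth for recovery checks.
    """
    if basis is None:
        basis = build_reference_basis(config, n_ref=n_ref,
                                      seed=(config.seed + 101) % (2**31))

    n = config.n_subjects if cohort is None else len(cohort.participants)
    if cohort is None:
        # stream subjects with the same seed derivation as generate_cohort,
        # so results match a pre-generated cohort without holding every
        # scan in memory
        subj_seqs = np.random.SeedSequence(config.seed).spawn(n)

        def subjects():
            for i, seq in enumerate(subj_seqs):
                stream = np.random.default_rng(seq)
                p = generate_participant(config, i, stream)
                yield p, render_scan(p, config, stream)
    else:
        def subjects():
            yield from zip(cohort.participants, cohort.scans)

    meas_seqs = np.random.SeedSequence([config.seed, 1]).spawn(n)
    rows = []
    for (p, scan), seq in zip(subjects(), meas_seqs):
        pcs, record = scan_features(scan, basis, limb_source=limb_source,
                                    participant=p)
        params = derive_model_parameters(record)
        adp, bia = bodycomp.emulate_measurements(
            p, config, np.random.default_rng(seq))
        row = {"subject_id": p.id}
        row.update({f"PC{i + 1}": pcs[i] for i in range(len(pcs))})
        row.update(params.as_row())
        row["fat_pct"] = adp.fat_pct
        row["tpfr"] = bia.tpfr
        row["fat_pct_true"] = p.fat_pct_true
        row["tpfr_true"] = p.tpfr_true
        row["shape_large_true"] = p.shape_large
        row["shape_small_true"] = p.shape_small
        rows.append(row)
    return pd.DataFrame(rows)


def compare_models(study: pd.DataFrame, dependents=("fat_pct", "tpfr"),
                   seed: int = 0, model_types=MODEL_TYPES,
                   cv_folds: int = 10) -> dict[str, ComparisonReport]:
    """Fit the six model types for each dependent and wrap them in reports."""
    comp = ModelComparison(study, cv_folds=cv_folds)
    out = {}
    for dep in dependents:
        rows = comp.fit(dep, seed=seed, model_types=model_types)
        out[dep] = ComparisonReport(rows=rows, dependent=dep, seed=seed,
                                    meta={"n": len(study)})
    return out
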