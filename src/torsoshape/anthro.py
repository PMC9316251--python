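"""Traditional anthropometrics from band profiles, plus allometric
normalization and the derived 5-parameter model subsets.

Girths are arc lengths of the smoothed band contours; volumes integrate
cross-section areas along the segment; surface areas sum conical-frustum
lateral strips.  Point clouds are mm; this module reports girths/lengths in
cm, volumes in litres, surface areas in m^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .features import M_DEFAULT, smooth_and_resample
from .geometry import Band, Landmarks, ProfileSet

__all__ = [
    "AnthroRecord",
    "AllometricCoefficients",
    "DerivedParameterSet",
    "contour_girth_mm",
    "extract_anthropometrics",
    "compute_volume_surface",
    "allometric_normalize",
    "derive_model_parameters",
]


@dataclass
class AnthroRecord:
    """Per-subject size measures (cm / litres / m^2)."""

    waist_girth: float
    stomach_girth: float
    hip_girth: float
    chest_girth: float
    torso_length: float
    thigh_girth: tuple[float, float]   # left, right
    bicep_girth: tuple[float, float]
    torso_volume: float
    leg_volume: tuple[float, float]
    arm_volume: tuple[float, float]
    torso_sa: float
    leg_sa: tuple[float, float]
    arm_sa: tuple[float, float]
    height: float
    subject_id: int = -1

    def __post_init__(self) -> None:
        scalars = [self.waist_girth, self.stomach_girth, self.hip_girth,
                   self.chest_girth, self.torso_length, self.torso_volume,
                   self.torso_sa, self.height]
        if any(v <= 0 for v in scalars):
            raise ValueError("all anthropometric measures must be positive")
        if self.waist_girth > self.stomach_girth + 1e-9:
            raise ValueError("waist girth (regional minimum) cannot exceed stomach girth")

    @property
    def wht5r(self) -> float:
        """Waist girth / sqrt(height): the central-obesity size index."""
        return self.waist_girth / math.sqrt(self.height)


@dataclass(frozen=True)
class AllometricCoefficients:
    """Per-measure allometric parameters for ln y = alpha + beta ln H.

    The published exponents for this protocol come from external reference
    work and are not reproduced here; beta defaults to 1.0 for every girth
    and length (and height-proportional normalization is the stated rule
    for volumes and surface areas).  Override per measure via ``overrides``.
    """

    default_beta: float = 1.0
    overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    source: str = "default-isometric"

    def beta(self, measure: str) -> float:
        if measure in self.overrides:
            return self.overrides[measure][1]
        return self.default_beta


def contour_girth_mm(band: Band, m: int = M_DEFAULT,
                     smoothing: float | str = "auto") -> float:
    """Arc length (mm) of the smoothed closed contour of one band."""
    contour = smooth_and_resample(band.points, m, band.centre_height, smoothing)
    pts = contour.points
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _contour_area_perimeter(points: np.ndarray) -> tuple[float, float]:
    x, y = points[:, 0], points[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    d = np.diff(np.vstack([points, points[:1]]), axis=0)
    return float(area), float(np.hypot(d[:, 0], d[:, 1]).sum())


def compute_volume_surface(bands: list[Band], m: int = M_DEFAULT,
                           smoothing: float | str = "auto") -> tuple[float, float]:
    """Volume (litres) and lateral surface area (m^2) of a banded segment.

    Cross-section areas are integrated trapezoidally over the band-centre
    heights, extended by half-spacing end slabs so the full segment length
    is covered; the lateral surface sums conical-frustum strips between
    consecutive contours plus matching end strips.  Band heights must be
    strictly increasing.
    """
    if len(bands) < 2:
        raise ValueError("need at least 2 bands to integrate a segment")
    z = np.array([b.centre_height for b in bands], dtype=float)
    if np.any(np.diff(z) <= 0):
        raise ValueError("band heights must be strictly increasing")

    areas = np.empty(len(bands))
    perims = np.empty(len(bands))
    radii = np.empty(len(bands))
    for i, b in enumerate(bands):
        contour = smooth_and_resample(b.points, m, b.centre_height, smoothing)
        areas[i], perims[i] = _contour_area_perimeter(contour.points)
        c = contour.points.mean(axis=0)
        radii[i] = np.hypot(*(contour.points - c).T).mean()

    vol = np.trapezoid(areas, z)
    vol += 0.5 * (z[1] - z[0]) * areas[0] + 0.5 * (z[-1] - z[-2]) * areas[-1]

    dz = np.diff(z)
    slant = np.sqrt(dz**2 + np.diff(radii) ** 2)
    sa = float(np.sum(0.5 * (perims[:-1] + perims[1:]) * slant))
    sa += 0.5 * (z[1] - z[0]) * perims[0] + 0.5 * (z[-1] - z[-2]) * perims[-1]
    return float(vol) / 1e6, sa / 1e6  # mm^3 -> L, mm^2 -> m^2


def extract_anthropometrics(profiles: ProfileSet, landmarks: Landmarks,
                            limb_bands: dict[str, list[Band]] | None = None,
                            height_cm: float | None = None,
                            limb_truth: dict | None = None,
                            subject_id: int = -1,
                            smoothing: float | str = "auto") -> AnthroRecord:
    """Extract the full size record from torso (and optionally limb) bands.

    Girth conventions: waist is the minimum torso girth, stomach the maximum
    between the waist and the hips, hip the lowest (buttock-level) band,
    chest the maximum above the waist.  Limb girths are band maxima.  When
    ``limb_bands`` is None, limb measures are taken from ``limb_truth``
    (generator ground truth; "fast mode").
    """
    girths = np.array([contour_girth_mm(b, smoothing=smoothing) for b in profiles.bands])
    waist_idx = int(np.argmin(girths))
    waist = girths[waist_idx]
    lower = girths[: waist_idx + 1]
    if len(lower) == 0:
        raise ValueError("empty waist-to-hip search region")
    stomach = float(lower.max())
    hip = float(girths[0])
    chest = float(girths[waist_idx:].max())

    torso_vol, torso_sa = compute_volume_surface(profiles.bands, smoothing=smoothing)
    torso_len_cm = (landmarks.xiphoid_height - landmarks.buttock_height) / 10.0
    height = height_cm if height_cm is not None else (landmarks.neck_height / 10.0) / 0.85

    if limb_bands is not None:
        def limb(label):
            bands = limb_bands[label]
            g = max(contour_girth_mm(b, smoothing=smoothing) for b in bands) / 10.0
            v, s = compute_volume_surface(bands, smoothing=smoothing)
            return g, v, s

        ll, rl = limb("left_leg"), limb("right_leg")
        la, ra = limb("left_arm"), limb("right_arm")
        thigh, leg_v, leg_s = (ll[0], rl[0]), (ll[1], rl[1]), (ll[2], rl[2])
        bicep, arm_v, arm_s = (la[0], ra[0]), (la[1], ra[1]), (la[2], ra[2])
    elif limb_truth is not None:
        thigh = tuple(limb_truth["thigh_girth_cm"])
        bicep = tuple(limb_truth["bicep_girth_cm"])
        leg_v = tuple(limb_truth["leg_volume_l"])
        arm_v = tuple(limb_truth["arm_volume_l"])
        leg_s = tuple(limb_truth["leg_sa_m2"])
        arm_s = tuple(limb_truth["arm_sa_m2"])
    else:
        raise ValueError("provide either limb_bands or limb_truth")

    return AnthroRecord(
        waist_girth=waist / 10.0, stomach_girth=stomach / 10.0,
        hip_girth=hip / 10.0, chest_girth=chest / 10.0,
        torso_length=torso_len_cm,
        thigh_girth=thigh, bicep_girth=bicep,
        torso_volume=torso_vol, leg_volume=leg_v, arm_volume=arm_v,
        torso_sa=torso_sa, leg_sa=leg_s, arm_sa=arm_s,
        height=height, subject_id=subject_id,
    )


def allometric_normalize(y: float, height: float, beta: float) -> float:
    """Height-normalize a measure: y / H^beta.

    The additive constant alpha of ln y = alpha + beta ln H is absorbed (it
    rescales every subject identically); beta = 0 is the identity, and a
    measure exactly proportional to H^beta normalizes to a constant.
    """
    if y <= 0 or height <= 0:
        raise ValueError("measure and height must be positive")
    return y / height**beta


def derive_model_parameters(record: AnthroRecord,
                            coeffs: AllometricCoefficients | None = None) -> "DerivedParameterSet":
    """Build the three 5-parameter size subsets used by the regression models.

    Left/right measures are averaged; torso:limbs and legs:arms ratios are
    formed from the raw values (height normalization cancels in ratios);
    girths and lengths are allometrically height-normalized, volumes and
    surface areas divided by height.
    """
    c = coeffs or AllometricCoefficients()
    h = record.height

    def norm(name, value):
        return allometric_normalize(value, h, c.beta(name))

    avg_thigh = 0.5 * (record.thigh_girth[0] + record.thigh_girth[1])
    avg_bicep = 0.5 * (record.bicep_girth[0] + record.bicep_girth[1])
    avg_leg_v = 0.5 * sum(record.leg_volume)
    avg_arm_v = 0.5 * sum(record.arm_volume)
    avg_leg_s = 0.5 * sum(record.leg_sa)
    avg_arm_s = 0.5 * sum(record.arm_sa)

    limbs_v = 2.0 * avg_leg_v + 2.0 * avg_arm_v
    limbs_s = 2.0 * avg_leg_s + 2.0 * avg_arm_s
    if limbs_v <= 0 or limbs_s <= 0 or avg_arm_v <= 0 or avg_arm_s <= 0:
        raise ValueError("limb totals must be positive to form ratios")

    size5 = {
        "hip_girth": norm("hip_girth", record.hip_girth),
        "torso_length": norm("torso_length", record.torso_length),
        "wht5r": record.wht5r,
        "avg_thigh_girth": norm("thigh_girth", avg_thigh),
        "avg_bicep_girth": norm("bicep_girth", avg_bicep),
    }
    volume5 = {
        "torso_volume": record.torso_volume / h,
        "avg_leg_volume": avg_leg_v / h,
        "avg_arm_volume": avg_arm_v / h,
        "torso_limbs_volume_ratio": record.torso_volume / limbs_v,
        "legs_arms_volume_ratio": (2.0 * avg_leg_v) / (2.0 * avg_arm_v),
    }
    sa5 = {
        "torso_sa": record.torso_sa / h,
        "avg_leg_sa": avg_leg_s / h,
        "avg_arm_sa": avg_arm_s / h,
        "torso_limbs_sa_ratio": record.torso_sa / limbs_s,
        "legs_arms_sa_ratio": (2.0 * avg_leg_s) / (2.0 * avg_arm_s),
    }
    return DerivedParameterSet(size5=size5, volume5=volume5, sa5=sa5)


@dataclass
class DerivedParameterSet:
    """The three fixed 5-parameter size subsets (model-contract precondition)."""

    size5: dict[str, float]
    volume5: dict[str, float]
    sa5: dict[str, float]

    def __post_init__(self) -> None:
        for name, d in (("size5", self.size5), ("volume5", self.volume5),
                        ("sa5", self.sa5)):
            if len(d) != 5:
                raise ValueError(f"{name} must contain exactly 5 parameters")
        for key in ("torso_limbs_volume_ratio", "legs_arms_volume_ratio"):
            if self.volume5[key] <= 0:
                raise ValueError(f"{key} must be positive")
        for key in ("torso_limbs_sa_ratio", "legs_arms_sa_ratio"):
            if self.sa5[key] <= 0:
                raise ValueError(f"{key} must be positive")

    def as_row(self) -> dict[str, float]:
        return {**self.size5, **self.volume5, **self.sa5}
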