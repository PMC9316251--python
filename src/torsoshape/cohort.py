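"""Synthetic cohort generator.

Emulates a male study cohort for the torso-shape pipeline: each participant
is defined by four independent latent factors,

* ``A``   — overall adiposity (drives girths, limb sizes, weight),
* ``C``   — central fat distribution (drives waist/stomach relative to hip),
* ``s_L`` — large-scale torso-shape factor (low angular frequency, k <= 2),
* ``s_S`` — small-scale torso-shape factor (high angular frequencies, k = 5-8),

all standard normal.  The torso surface is a generalized cylinder whose
cross-sections are superellipses with cosine harmonic perturbations; this
family has analytic girth/area/volume oracles and lets the two shape factors
act at separable spatial scales.  Arms and legs are tapered cylinder proxies
placed clear of the torso.

The two study dependents are generated as

    fat%  = fat_mean + beta_size * z(WHT.5R) + beta_largeshape * s_L + eps
    TPFR  = tpfr_mean + gamma_central * C + gamma_smallshape * s_S + eps'

where z(WHT.5R) is the cohort-standardized waist-girth/sqrt(height) index
computed from the participant's *true* (noise-free) geometry.  Residual
standard deviations default to the values that make the marginal SDs of
fat% and TPFR match the configured cohort targets.

Units: point clouds and landmark heights are millimetres; anthropometric
tables are centimetres; volumes litres; masses kilograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "GeneratorConfig",
    "SyntheticParticipant",
    "LabeledScan",
    "Cohort",
    "generate_participant",
    "render_scan",
    "generate_cohort",
    "cylinder_participant",
    "superellipse_radius",
    "wht5r_reference_stats",
]

# Landmark heights as fractions of stature (scan frame, floor = 0).
_NECK_FRAC = 0.85
_BUTTOCK_FRAC = 0.48
_XIPHOID_OF_SPAN = 0.60  # xiphoid sits at 60% of the buttock->neck span

# Torso cross-section stations as fractions of the buttock->neck span,
# with baseline sagittal (a) and transverse (b) semi-axes in mm for a
# 177.9 cm reference stature.  b > a everywhere: torsos are wider than deep,
# which keeps the principal-axis alignment well conditioned.
_STATIONS = np.array([0.00, 0.21, 0.39, 0.60, 0.80, 1.00])
_BASE_A = np.array([118.0, 112.0, 102.0, 112.0, 100.0, 55.0])
_BASE_B = np.array([168.0, 152.0, 142.0, 162.0, 150.0, 60.0])
# Anterior (belly) offset of the section centre, mm at reference stature.
_BASE_CX = np.array([0.0, 12.0, 8.0, 2.0, 0.0, 0.0])

# Sensitivity of the semi-axes to the latent factors, per station:
# a-axis (depth) responds more strongly to adiposity/centrality than b.
_A_ADIP = np.array([0.030, 0.050, 0.070, 0.020, 0.020, 0.010])
_B_ADIP = np.array([0.020, 0.030, 0.050, 0.020, 0.020, 0.010])
_A_CENT = np.array([0.000, 0.040, 0.060, 0.000, 0.000, 0.000])
_B_CENT = np.array([0.000, 0.020, 0.040, 0.000, 0.000, 0.000])

_HARMONICS = (2, 3, 4, 5, 6, 7, 8)
# Baseline relative amplitude per harmonic and its loading on s_L / s_S.
_HARM_BASE = {2: 0.030, 3: 0.012, 4: 0.008, 5: 0.005, 6: 0.005, 7: 0.005, 8: 0.004}
_HARM_SL = {2: 0.010, 3: 0.0, 4: 0.0, 5: 0.0, 6: 0.0, 7: 0.0, 8: 0.0}
_HARM_SS = {2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0035, 6: 0.0028, 7: 0.0021, 8: 0.0018}
_HARM_IDIO = {2: 0.004, 3: 0.003, 4: 0.002, 5: 0.0015, 6: 0.0015, 7: 0.0015, 8: 0.001}

_RETRY_BUDGET = 200


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Marginal calibration targets (height, fat%, TPFR means/SDs) default to
    the study cohort's summary statistics; the residual SDs ``sigma_fat`` /
    ``sigma_tpfr`` default to ``None`` meaning "derive the value that makes
    the marginal SD hit its target given the effect sizes".
    """

    n_subjects: int = 93
    seed: int = 0
    height_mean_cm: float = 177.9
    height_sd_cm: float = 6.8
    fat_mean_pct: float = 21.02
    fat_sd_pct: float = 7.82
    tpfr_mean: float = 1.57
    tpfr_sd: float = 0.22
    beta_size: float = 6.0
    beta_largeshape: float = 3.5
    gamma_central: float = 0.12
    gamma_smallshape: float = 0.13
    sigma_fat: float | None = None
    sigma_tpfr: float | None = None
    scanner_noise_sd_mm: float = 2.0
    n_points: int = 200000
    superellipse_exponent: float = 2.5
    latent_correlation: float = 0.0  # corr(A, C); stresses collinearity handling
    adp_noise_sd_l: float = 0.05
    bia_noise_sd_kg: float = 0.10
    adp_equation: str = "siri"
    render_limbs: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("height_sd_cm", "fat_sd_pct", "tpfr_sd", "scanner_noise_sd_mm",
                     "adp_noise_sd_l", "bia_noise_sd_kg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sigma_fat is not None and self.sigma_fat < 0:
            raise ValueError("sigma_fat must be >= 0")
        if self.sigma_tpfr is not None and self.sigma_tpfr < 0:
            raise ValueError("sigma_tpfr must be >= 0")
        if not -0.95 <= self.latent_correlation <= 0.95:
            raise ValueError("latent_correlation must be in [-0.95, 0.95]")
        if self.n_points < 100:
            raise ValueError("n_points must be >= 100")

    @property
    def resolved_sigma_fat(self) -> float:
        if self.sigma_fat is not None:
            return self.sigma_fat
        resid = self.fat_sd_pct**2 - self.beta_size**2 - self.beta_largeshape**2
        return math.sqrt(max(resid, 0.25))

    @property
    def resolved_sigma_tpfr(self) -> float:
        if self.sigma_tpfr is not None:
            return self.sigma_tpfr
        resid = self.tpfr_sd**2 - self.gamma_central**2 - self.gamma_smallshape**2
        return math.sqrt(max(resid, 1e-4))


@dataclass
class SyntheticParticipant:
    """Ground truth for one subject: latents, geometry, and body composition."""

    id: int
    height_cm: float
    weight_kg: float
    adiposity: float          # A
    centrality: float         # C
    shape_large: float        # s_L
    shape_small: float        # s_S
    neck_height_mm: float
    buttock_height_mm: float
    xiphoid_height_mm: float
    station_z_mm: np.ndarray          # absolute heights of the section stations
    station_a_mm: np.ndarray          # sagittal semi-axes
    station_b_mm: np.ndarray          # transverse semi-axes
    station_cx_mm: np.ndarray         # anterior centre offsets
    superellipse_exponent: float
    harmonic_amp: dict[int, float]    # relative amplitude per angular frequency
    harmonic_phase: dict[int, float]  # radians
    thigh_girth_cm: tuple[float, float]
    bicep_girth_cm: tuple[float, float]
    leg_volume_l: tuple[float, float]
    arm_volume_l: tuple[float, float]
    leg_sa_m2: tuple[float, float]
    arm_sa_m2: tuple[float, float]
    fat_pct_true: float
    tpfr_true: float
    trunk_fat_kg: float
    limb_fat_kg: tuple[float, float, float, float]  # left leg, right leg, left arm, right arm
    wht5r_true: float
    _a_interp: PchipInterpolator = field(repr=False, default=None)
    _b_interp: PchipInterpolator = field(repr=False, default=None)
    _cx_interp: PchipInterpolator = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if np.any(self.station_a_mm <= 0) or np.any(self.station_b_mm <= 0):
            raise ValueError("semi-axes must be positive")
        if not 0.0 < self.fat_pct_true < 100.0:
            raise ValueError("true fat fraction must lie in (0, 100)%")
        if self.trunk_fat_kg <= 0 or any(m <= 0 for m in self.limb_fat_kg):
            raise ValueError("fat masses must be positive")
        if not self.buttock_height_mm < self.xiphoid_height_mm < self.neck_height_mm:
            raise ValueError("xiphoid must lie strictly between buttock and neck")
        self._a_interp = PchipInterpolator(self.station_z_mm, self.station_a_mm)
        self._b_interp = PchipInterpolator(self.station_z_mm, self.station_b_mm)
        self._cx_interp = PchipInterpolator(self.station_z_mm, self.station_cx_mm)

    # -- parametric surface ------------------------------------------------

    def semi_axes(self, z_mm):
        """Sagittal/transverse semi-axes (a, b) at absolute height z (mm)."""
        z = np.clip(z_mm, self.station_z_mm[0], self.station_z_mm[-1])
        return float(self._a_interp(z)), float(self._b_interp(z))

    def centre_x(self, z_mm) -> float:
        z = np.clip(z_mm, self.station_z_mm[0], self.station_z_mm[-1])
        return float(self._cx_interp(z))

    def radius(self, theta, z_mm):
        """Cross-section radius about the section centre at height z (mm)."""
        a, b = self.semi_axes(z_mm)
        r = superellipse_radius(theta, a, b, self.superellipse_exponent)
        mod = np.ones_like(np.asarray(theta, dtype=float))
        for k in _HARMONICS:
            amp = self.harmonic_amp.get(k, 0.0)
            if amp:
                mod = mod + amp * np.cos(k * np.asarray(theta) + self.harmonic_phase.get(k, 0.0))
        return r * mod

    def section_points(self, z_mm, theta):
        """Surface points (x, y) of the section at height z, torso frame (mm)."""
        r = self.radius(theta, z_mm)
        return np.column_stack([self.centre_x(z_mm) + r * np.cos(theta),
                                r * np.sin(theta)])

    def girth_mm(self, z_mm, n: int = 2048) -> float:
        """Analytic section girth (polygon quadrature on the true surface)."""
        theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        pts = self.section_points(z_mm, theta)
        d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def section_area_mm2(self, z_mm, n: int = 2048) -> float:
        theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        pts = self.section_points(z_mm, theta)
        x, y = pts[:, 0], pts[:, 1]
        return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))

    def torso_volume_l(self, n_z: int = 101) -> float:
        """True torso volume between buttock and xiphoid (litres)."""
        zs = np.linspace(self.buttock_height_mm, self.xiphoid_height_mm, n_z)
        areas = np.array([self.section_area_mm2(z) for z in zs])
        return float(np.trapezoid(areas, zs) / 1e6)

    def torso_sa_m2(self, n_z: int = 101) -> float:
        """Approximate true torso lateral surface area (m^2)."""
        zs = np.linspace(self.buttock_height_mm, self.xiphoid_height_mm, n_z)
        per = np.array([self.girth_mm(z) for z in zs])
        return float(np.trapezoid(per, zs) / 1e6)

    def waist_girth_cm(self) -> float:
        """Minimum torso girth (cm), searched over the torso segment."""
        zs = np.linspace(self.buttock_height_mm, self.xiphoid_height_mm, 61)
        return min(self.girth_mm(z) for z in zs) / 10.0


@dataclass
class LabeledScan:
    """One noisy surface sampling of a participant plus its landmark sidecar."""

    points_mm: np.ndarray  # (N, 3)
    neck_height_mm: float
    buttock_height_mm: float
    subject_id: int

    def __post_init__(self) -> None:
        self.points_mm = np.asarray(self.points_mm, dtype=float)
        if self.points_mm.ndim != 2 or self.points_mm.shape[1] != 3 or len(self.points_mm) == 0:
            raise ValueError("points must be a non-empty (N, 3) array")
        zmin, zmax = self.points_mm[:, 2].min(), self.points_mm[:, 2].max()
        if not (zmin <= self.buttock_height_mm <= zmax and zmin <= self.neck_height_mm <= zmax):
            raise ValueError("landmark heights must lie inside the cloud z-range")

    @property
    def landmarks(self) -> dict[str, float]:
        return {"neck_height_mm": self.neck_height_mm,
                "buttock_height_mm": self.buttock_height_mm}


@dataclass
class Cohort:
    participants: list[SyntheticParticipant]
    scans: list[LabeledScan]
    truth: "pd.DataFrame"  # noqa: F821 - typed lazily to keep import light


def superellipse_radius(theta, a: float, b: float, p: float):
    """Radius of the superellipse |x/a|^p + |y/b|^p = 1 at polar angle theta."""
    c, s = np.cos(theta), np.sin(theta)
    return (np.abs(c / a) ** p + np.abs(s / b) ** p) ** (-1.0 / p)


def _latents(config: GeneratorConfig, rng: np.random.Generator):
    a, c = rng.standard_normal(2)
    rho = config.latent_correlation
    if rho:
        c = rho * a + math.sqrt(1.0 - rho * rho) * c
    s_l, s_s = rng.standard_normal(2)
    return a, c, s_l, s_s


def _torso_geometry(config: GeneratorConfig, height_cm: float, adi: float, cen: float,
                    neck_frac: float, buttock_frac: float):
    """Station heights and semi-axes for given stature and latent factors."""
    h = height_cm / 177.9
    height_mm = height_cm * 10.0
    buttock = buttock_frac * height_mm
    neck = neck_frac * height_mm
    z = buttock + _STATIONS * (neck - buttock)
    a = _BASE_A * h * (1.0 + _A_ADIP * adi + _A_CENT * cen)
    b = _BASE_B * h * (1.0 + _B_ADIP * adi + _B_CENT * cen)
    cx = _BASE_CX * h * (1.0 + 0.25 * adi + 0.15 * cen)
    return z, a, b, cx, buttock, neck


def wht5r_reference_stats(config: GeneratorConfig, n: int = 800) -> tuple[float, float]:
    """Population mean/SD of the true WHT.5R index under this configuration.

    Computed once per configuration from an internal fixed-seed latent sample
    (independent of the cohort's random stream), so that the fat%-model's
    standardized size term z(WHT.5R) has a stable, config-determined scale.
    """
    rng = np.random.default_rng(987654321)
    vals = np.empty(n)
    for i in range(n):
        height = config.height_mean_cm + config.height_sd_cm * rng.standard_normal()
        adi, cen, _, _ = _latents(config, rng)
        p = _minimal_torso(config, height, adi, cen)
        vals[i] = p.waist_girth_cm() / math.sqrt(height)
    return float(vals.mean()), float(vals.std(ddof=1))


_WHT5R_CACHE: dict[tuple, tuple[float, float]] = {}


def _wht5r_stats_cached(config: GeneratorConfig) -> tuple[float, float]:
    key = (config.height_mean_cm, config.height_sd_cm, config.superellipse_exponent,
           config.latent_correlation)
    if key not in _WHT5R_CACHE:
        _WHT5R_CACHE[key] = wht5r_reference_stats(config)
    return _WHT5R_CACHE[key]


class _Sections:
    """Light stand-in with just enough surface methods for WHT.5R statistics."""

    def __init__(self, z, a, b, cx, p, zlo, zhi):
        self._ai = PchipInterpolator(z, a)
        self._bi = PchipInterpolator(z, b)
        self._cxi = PchipInterpolator(z, cx)
        self.p = p
        self.zlo, self.zhi = zlo, zhi

    def girth_mm(self, z_mm, n: int = 720) -> float:
        theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        a, b = float(self._ai(z_mm)), float(self._bi(z_mm))
        r = superellipse_radius(theta, a, b, self.p)
        x = float(self._cxi(z_mm)) + r * np.cos(theta)
        y = r * np.sin(theta)
        d = np.diff(np.column_stack([np.append(x, x[0]), np.append(y, y[0])]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def waist_girth_cm(self) -> float:
        # vectorized over a z-grid x theta-grid: perimeters of all sections
        zs = np.linspace(self.zlo, self.zhi, 25)
        theta = np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
        a = self._ai(zs)[:, None]
        b = self._bi(zs)[:, None]
        r = (np.abs(np.cos(theta)[None, :] / a) ** self.p
             + np.abs(np.sin(theta)[None, :] / b) ** self.p) ** (-1.0 / self.p)
        x = r * np.cos(theta)[None, :]
        y = r * np.sin(theta)[None, :]
        dx = np.diff(np.concatenate([x, x[:, :1]], axis=1), axis=1)
        dy = np.diff(np.concatenate([y, y[:, :1]], axis=1), axis=1)
        per = np.hypot(dx, dy).sum(axis=1)
        return float(per.min()) / 10.0


def _minimal_torso(config: GeneratorConfig, height_cm: float, adi: float, cen: float) -> _Sections:
    z, a, b, cx, buttock, neck = _torso_geometry(config, height_cm, adi, cen,
                                                 _NECK_FRAC, _BUTTOCK_FRAC)
    xiph = buttock + _XIPHOID_OF_SPAN * (neck - buttock)
    return _Sections(z, a, b, cx, config.superellipse_exponent, buttock, xiph)


def _leg_radius_profile(t):
    """Relative leg radius vs normalized height t (0 = ankle, 1 = buttock).

    Linear calf-to-thigh taper with a short plateau at the top so the
    maximum (thigh) girth is observable inside the extraction window.
    """
    return 0.55 + 0.45 * np.minimum(np.asarray(t) / 0.92, 1.0)


def _arm_radius_profile(t):
    """Relative arm radius vs normalized height t (0 = bottom, 1 = shoulder).

    A Gaussian bicep bulge at t = 1/3 (below the xiphoid level, so the
    maximum girth lies inside the torso-height observation window)."""
    return 0.78 + 0.22 * np.exp(-(((np.asarray(t) - 1.0 / 3.0) / 0.20) ** 2))


def _profile_vol_sa(r_top_mm: float, profile, z0: float, z1: float,
                    n: int = 400) -> tuple[float, float]:
    """Volume (L) and lateral surface (m^2) of a profiled cylinder."""
    z = np.linspace(z0, z1, n)
    r = r_top_mm * profile((z - z0) / (z1 - z0))
    vol = np.trapezoid(math.pi * r**2, z) / 1e6
    drdz = np.gradient(r, z)
    sa = np.trapezoid(2.0 * math.pi * r * np.sqrt(1.0 + drdz**2), z) / 1e6
    return float(vol), float(sa)


def _limb_truth(config: GeneratorConfig, height_cm: float, adi: float,
                rng: np.random.Generator):
    """Thigh/bicep girths, limb volumes and surface areas (truth, per side)."""
    h = height_cm / 177.9
    asym_t = 0.004 * rng.standard_normal()
    asym_b = 0.006 * rng.standard_normal()
    idio_t = 0.03 * rng.standard_normal()
    idio_b = 0.04 * rng.standard_normal()
    thigh = 56.0 * h * (1.0 + 0.05 * adi + idio_t)
    bicep = 33.0 * h * (1.0 + 0.06 * adi + idio_b)
    thigh_lr = (thigh * (1.0 + asym_t), thigh * (1.0 - asym_t))
    bicep_lr = (bicep * (1.0 + asym_b), bicep * (1.0 - asym_b))

    height_mm = height_cm * 10.0
    leg_z0, leg_z1 = 0.08 * height_mm, _BUTTOCK_FRAC * height_mm
    arm_z0, arm_z1 = 0.50 * height_mm, 0.80 * height_mm

    legs, arms, leg_sa, arm_sa = [], [], [], []
    for g in thigh_lr:
        v, s = _profile_vol_sa(g * 10.0 / (2.0 * math.pi), _leg_radius_profile,
                               leg_z0, leg_z1)
        legs.append(v)
        leg_sa.append(s)
    for g in bicep_lr:
        v, s = _profile_vol_sa(g * 10.0 / (2.0 * math.pi), _arm_radius_profile,
                               arm_z0, arm_z1)
        arms.append(v)
        arm_sa.append(s)
    return thigh_lr, bicep_lr, tuple(legs), tuple(arms), tuple(leg_sa), tuple(arm_sa)


def generate_participant(config: GeneratorConfig, id: int,
                         stream: np.random.Generator) -> SyntheticParticipant:
    """Draw one participant's latent factors, geometry and body composition.

    Deterministic given (config, id, stream state).  Draws that violate a
    ground-truth invariant (e.g. non-physical fat fraction) are rejected and
    the offending noise redrawn, up to a bounded retry budget.
    """
    height = config.height_mean_cm + config.height_sd_cm * stream.standard_normal()
    height = float(np.clip(height, 140.0, 215.0))
    adi, cen, s_l, s_s = _latents(config, stream)
    neck_frac = _NECK_FRAC + 0.006 * stream.standard_normal()
    buttock_frac = _BUTTOCK_FRAC + 0.006 * stream.standard_normal()

    z, a, b, cx, buttock, neck = _torso_geometry(config, height, adi, cen,
                                                 neck_frac, buttock_frac)
    xiphoid = buttock + _XIPHOID_OF_SPAN * (neck - buttock)

    amp, phase = {}, {}
    for k in _HARMONICS:
        amp[k] = (_HARM_BASE[k]
                  + _HARM_SL[k] * s_l
                  + _HARM_SS[k] * s_s
                  + _HARM_IDIO[k] * stream.standard_normal())
        phase[k] = 0.05 * stream.standard_normal()

    thigh, bicep, leg_v, arm_v, leg_sa, arm_sa = _limb_truth(config, height, adi, stream)

    sections = _Sections(z, a, b, cx, config.superellipse_exponent, buttock, xiphoid)
    wht5r = sections.waist_girth_cm() / math.sqrt(height)
    mu, sd = _wht5r_stats_cached(config)
    z_wht5r = (wht5r - mu) / sd if sd > 0 else 0.0

    sigma_fat = config.resolved_sigma_fat
    sigma_tpfr = config.resolved_sigma_tpfr
    fat_struct = (config.fat_mean_pct + config.beta_size * z_wht5r
                  + config.beta_largeshape * s_l)
    tpfr_struct = (config.tpfr_mean + config.gamma_central * cen
                   + config.gamma_smallshape * s_s)

    fat = fat_struct + sigma_fat * stream.standard_normal()
    for _ in range(_RETRY_BUDGET):
        if 1.0 < fat < 60.0:
            break
        fat = fat_struct + sigma_fat * stream.standard_normal()
    else:
        raise RuntimeError("retry budget exhausted drawing a physical fat fraction")

    tpfr = tpfr_struct + sigma_tpfr * stream.standard_normal()
    for _ in range(_RETRY_BUDGET):
        if 0.4 < tpfr < 4.0:
            break
        tpfr = tpfr_struct + sigma_tpfr * stream.standard_normal()
    else:
        raise RuntimeError("retry budget exhausted drawing a physical TPFR")

    h = height / 177.9
    lean = 65.5 * h**2 * math.exp(0.04 * stream.standard_normal())
    weight = lean / (1.0 - fat / 100.0)

    fat_mass = fat / 100.0 * weight
    # ~8% of fat mass sits in head/neck/other, outside trunk+limbs
    fat_tl = 0.92 * fat_mass
    trunk_fat = fat_tl * tpfr / (1.0 + tpfr)
    limbs_total = fat_tl / (1.0 + tpfr)
    limb_fat = (0.37 * limbs_total, 0.37 * limbs_total,
                0.13 * limbs_total, 0.13 * limbs_total)

    return SyntheticParticipant(
        id=id, height_cm=height, weight_kg=weight,
        adiposity=adi, centrality=cen, shape_large=s_l, shape_small=s_s,
        neck_height_mm=neck, buttock_height_mm=buttock, xiphoid_height_mm=xiphoid,
        station_z_mm=z, station_a_mm=a, station_b_mm=b, station_cx_mm=cx,
        superellipse_exponent=config.superellipse_exponent,
        harmonic_amp=amp, harmonic_phase=phase,
        thigh_girth_cm=thigh, bicep_girth_cm=bicep,
        leg_volume_l=leg_v, arm_volume_l=arm_v, leg_sa_m2=leg_sa, arm_sa_m2=arm_sa,
        fat_pct_true=fat, tpfr_true=tpfr,
        trunk_fat_kg=trunk_fat, limb_fat_kg=limb_fat,
        wht5r_true=wht5r,
    )


def cylinder_participant(radius_mm: float = 150.0, height_cm: float = 177.9,
                         id: int = 0, exponent: float = 2.0) -> SyntheticParticipant:
    """A degenerate participant with circular cross-sections of fixed radius.

    Every analytic property is closed form (girth = 2*pi*r), which makes this
    the standard oracle object in the test-suite.
    """
    height_mm = height_cm * 10.0
    buttock = _BUTTOCK_FRAC * height_mm
    neck = _NECK_FRAC * height_mm
    z = buttock + _STATIONS * (neck - buttock)
    r = np.full_like(z, radius_mm)
    return SyntheticParticipant(
        id=id, height_cm=height_cm, weight_kg=80.0,
        adiposity=0.0, centrality=0.0, shape_large=0.0, shape_small=0.0,
        neck_height_mm=neck, buttock_height_mm=buttock,
        xiphoid_height_mm=buttock + _XIPHOID_OF_SPAN * (neck - buttock),
        station_z_mm=z, station_a_mm=r.copy(), station_b_mm=r.copy(),
        station_cx_mm=np.zeros_like(z),
        superellipse_exponent=exponent,
        harmonic_amp={}, harmonic_phase={},
        thigh_girth_cm=(56.0, 56.0), bicep_girth_cm=(33.0, 33.0),
        leg_volume_l=(9.0, 9.0), arm_volume_l=(3.0, 3.0),
        leg_sa_m2=(0.55, 0.55), arm_sa_m2=(0.30, 0.30),
        fat_pct_true=21.0, tpfr_true=1.57,
        trunk_fat_kg=9.0, limb_fat_kg=(2.0, 2.0, 0.8, 0.8),
        wht5r_true=2.0 * math.pi * radius_mm / 10.0 / math.sqrt(height_cm),
    )


def _sample_torso(p: SyntheticParticipant, n: int, rng: np.random.Generator) -> np.ndarray:
    # pad past both landmarks so they always lie inside the cloud's z-range
    z = rng.uniform(p.buttock_height_mm - 20.0, p.neck_height_mm + 20.0, n)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    # vectorized over points: interpolate semi-axes per point
    a = p._a_interp(z)
    b = p._b_interp(z)
    r = (np.abs(np.cos(theta) / a) ** p.superellipse_exponent
         + np.abs(np.sin(theta) / b) ** p.superellipse_exponent) ** (-1.0 / p.superellipse_exponent)
    mod = np.ones(n)
    for k, amp in p.harmonic_amp.items():
        if amp:
            mod += amp * np.cos(k * theta + p.harmonic_phase.get(k, 0.0))
    r = r * mod
    x = p._cx_interp(z) + r * np.cos(theta)
    y = r * np.sin(theta)
    return np.column_stack([x, y, z])


def _sample_limbs(p: SyntheticParticipant, n: int, rng: np.random.Generator) -> np.ndarray:
    """Leg and arm cylinder proxies.  Legs sit below the buttock landmark;
    arms are offset laterally well clear of the torso envelope."""
    height_mm = p.height_cm * 10.0
    h = p.height_cm / 177.9
    clouds = []
    n_leg = n * 15 // 100  # per side
    n_arm = n * 10 // 100

    leg_z0, leg_z1 = 0.08 * height_mm, p.buttock_height_mm - 1e-6
    for side, girth in zip((+1, -1), p.thigh_girth_cm):
        r_top = girth * 10.0 / (2.0 * math.pi)
        z = rng.uniform(leg_z0, leg_z1, n_leg)
        r = r_top * _leg_radius_profile((z - leg_z0) / (leg_z1 - leg_z0))
        theta = rng.uniform(0, 2 * np.pi, n_leg)
        clouds.append(np.column_stack([r * np.cos(theta),
                                       side * 95.0 * h + r * np.sin(theta), z]))

    arm_z0, arm_z1 = 0.50 * height_mm, 0.80 * height_mm
    y_off = 330.0 * h  # well clear of the torso envelope (downward-V posture)
    for side, girth in zip((+1, -1), p.bicep_girth_cm):
        r_top = girth * 10.0 / (2.0 * math.pi)
        z = rng.uniform(arm_z0, arm_z1, n_arm)
        r = r_top * _arm_radius_profile((z - arm_z0) / (arm_z1 - arm_z0))
        theta = rng.uniform(0, 2 * np.pi, n_arm)
        clouds.append(np.column_stack([r * np.cos(theta),
                                       side * y_off + r * np.sin(theta), z]))
    return np.vstack(clouds)


def render_scan(p: SyntheticParticipant, config: GeneratorConfig,
                stream: np.random.Generator) -> LabeledScan:
    """Sample a noisy point cloud from the participant's true surface.

    One scan per subject is rendered (the real protocol's median-of-three
    selection is a non-goal).  Isotropic Gaussian noise of
    ``scanner_noise_sd_mm`` is added to every point; the landmark sidecar is
    noise-free and fully determined by the participant.
    """
    n = config.n_points
    if config.render_limbs:
        n_torso = n - (n * 15 // 100) * 2 - (n * 10 // 100) * 2
        pts = [_sample_torso(p, n_torso, stream), _sample_limbs(p, n, stream)]
        points = np.vstack(pts)
    else:
        points = _sample_torso(p, n, stream)
    if config.scanner_noise_sd_mm > 0:
        points = points + stream.normal(0.0, config.scanner_noise_sd_mm, points.shape)
    return LabeledScan(points_mm=points, neck_height_mm=p.neck_height_mm,
                       buttock_height_mm=p.buttock_height_mm, subject_id=p.id)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate the full cohort: participants, scans, and a ground-truth table.

    (config.seed) fully determines every output: per-subject random streams
    are spawned from a single SeedSequence so subjects are independent and
    reproducible.
    """
    import pandas as pd

    seqs = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    participants, scans, rows = [], [], []
    for i, seq in enumerate(seqs):
        stream = np.random.default_rng(seq)
        p = generate_participant(config, i, stream)
        scan = render_scan(p, config, stream)
        participants.append(p)
        scans.append(scan)
        rows.append({
            "subject_id": p.id, "height_cm": p.height_cm, "weight_kg": p.weight_kg,
            "adiposity": p.adiposity, "centrality": p.centrality,
            "shape_large": p.shape_large, "shape_small": p.shape_small,
            "fat_pct_true": p.fat_pct_true, "tpfr_true": p.tpfr_true,
            "wht5r_true": p.wht5r_true,
            "trunk_fat_kg": p.trunk_fat_kg,
            "neck_height_mm": p.neck_height_mm,
            "buttock_height_mm": p.buttock_height_mm,
            "xiphoid_height_mm": p.xiphoid_height_mm,
        })
    return Cohort(participants=participants, scans=scans, truth=pd.DataFrame(rows))
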