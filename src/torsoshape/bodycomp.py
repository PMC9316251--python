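"""Reference body-composition measurements: ADP and segmental BIA.

Air-displacement plethysmography (ADP) yields body density from mass and
measured body volume, converted to a fat percentage with a two-compartment
density equation (Siri, Schutte or Brozek, selectable; the study protocol
assigned them by population group, which is out of scope here — the tag is
explicit).  Segmental bioelectrical impedance (BIA) yields trunk and limb
fat masses whose ratio is the trunk:peripheral fat ratio (TPFR).

Both repeat-measurement acceptance protocols are modelled: ADP repeats a
third volume reading when the first two disagree by more than 150 mL and
accepts the mean of the closest pair; BIA takes two repeats and averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import GeneratorConfig, SyntheticParticipant

__all__ = [
    "AdpMeasurement",
    "BiaMeasurement",
    "ThirdReadingRequired",
    "DENSITY_EQUATIONS",
    "adp_accept_volume",
    "density_to_fat_fraction",
    "fat_fraction_to_density",
    "emulate_measurements",
]

# fat% = (c1 / D - c2) * 100 with D in kg/L; standard two-compartment forms
DENSITY_EQUATIONS: dict[str, tuple[float, float]] = {
    "siri": (4.95, 4.50),
    "schutte": (4.374, 3.928),
    "brozek": (4.570, 4.142),
}

ADP_TOLERANCE_L = 0.150


class ThirdReadingRequired(Exception):
    """Signal: the first two ADP volume readings differ by more than 150 mL."""


@dataclass
class AdpMeasurement:
    readings_l: list[float]
    accepted_volume_l: float
    body_mass_kg: float
    equation: str

    @property
    def density(self) -> float:
        return self.body_mass_kg / self.accepted_volume_l

    @property
    def fat_pct(self) -> float:
        return density_to_fat_fraction(self.density, self.equation)


@dataclass
class BiaMeasurement:
    """Two repeats of segmental fat masses (kg) and their averages.

    Segments ordered (trunk, left leg, right leg, left arm, right arm).
    """

    repeats_kg: np.ndarray  # (2, 5)

    def __post_init__(self) -> None:
        self.repeats_kg = np.asarray(self.repeats_kg, dtype=float)
        if self.repeats_kg.shape != (2, 5):
            raise ValueError("expected two repeats of five segmental fat masses")
        if np.any(self.repeats_kg < 0):
            raise ValueError("fat masses must be non-negative")

    @property
    def averaged_kg(self) -> np.ndarray:
        return self.repeats_kg.mean(axis=0)

    @property
    def tpfr(self) -> float:
        avg = self.averaged_kg
        limbs = avg[1:].sum()
        if limbs <= 0:
            raise ValueError("limb fat masses sum to zero; TPFR undefined")
        return float(avg[0] / limbs)


def adp_accept_volume(readings: list[float]) -> float:
    """Apply the ADP acceptance rule to 2 or 3 volume readings (litres).

    Two readings within 150 mL are averaged; if they differ by more,
    ``ThirdReadingRequired`` is raised.  With three readings the closest
    pair is averaged, ties resolved in favour of the earliest pair.
    """
    if len(readings) < 2:
        raise ValueError("need at least two volume readings")
    if len(readings) == 2:
        v1, v2 = readings
        if abs(v1 - v2) > ADP_TOLERANCE_L:
            raise ThirdReadingRequired(
                f"readings differ by {abs(v1 - v2) * 1000:.0f} mL > 150 mL")
        return 0.5 * (v1 + v2)
    pairs = [(0, 1), (0, 2), (1, 2)]
    best = min(pairs, key=lambda ij: abs(readings[ij[0]] - readings[ij[1]]))
    return 0.5 * (readings[best[0]] + readings[best[1]])


def density_to_fat_fraction(density: float, equation: str = "siri") -> float:
    """Body fat percentage from whole-body density (kg/L)."""
    if equation not in DENSITY_EQUATIONS:
        raise ValueError(f"unknown density equation {equation!r}")
    if not 0.9 < density < 1.2:
        raise ValueError(f"body density {density:.3f} kg/L outside (0.9, 1.2)")
    c1, c2 = DENSITY_EQUATIONS[equation]
    return (c1 / density - c2) * 100.0


def fat_fraction_to_density(fat_pct: float, equation: str = "siri") -> float:
    """Inverse of the density equation: D = c1 / (fat/100 + c2)."""
    c1, c2 = DENSITY_EQUATIONS[equation]
    return c1 / (fat_pct / 100.0 + c2)


def emulate_measurements(p: SyntheticParticipant, config: GeneratorConfig,
                         stream: np.random.Generator) -> tuple[AdpMeasurement, BiaMeasurement]:
    """Run a participant through the emulated ADP and BIA protocols.

    ADP volume readings are the true body volume (mass over the density
    implied by the true fat fraction) plus Gaussian noise; the acceptance
    rule decides whether a third reading is taken.  BIA segmental fat
    masses are the true masses plus Gaussian noise, duplicated and averaged.
    With both noise SDs at zero the measured values equal the truth exactly.
    """
    eq = config.adp_equation
    true_density = fat_fraction_to_density(p.fat_pct_true, eq)
    true_volume = p.weight_kg / true_density

    readings = list(true_volume + config.adp_noise_sd_l * stream.standard_normal(2))
    try:
        accepted = adp_accept_volume(readings)
    except ThirdReadingRequired:
        readings.append(true_volume + config.adp_noise_sd_l * stream.standard_normal())
        accepted = adp_accept_volume(readings)
    adp = AdpMeasurement(readings_l=readings, accepted_volume_l=accepted,
                         body_mass_kg=p.weight_kg, equation=eq)

    truth = np.array([p.trunk_fat_kg, *p.limb_fat_kg])
    repeats = truth[None, :] + config.bia_noise_sd_kg * stream.standard_normal((2, 5))
    repeats = np.clip(repeats, 0.0, None)
    bia = BiaMeasurement(repeats_kg=repeats)
    return adp, bia
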