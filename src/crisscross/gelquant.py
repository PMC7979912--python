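"""Spontaneous-nucleation quantification from agarose-gel densitometry.

Spurious (seed-independent) nucleation is too rare to count directly, so it
is inferred from gels: slats are incubated without seeds (a two-step
protocol: a nucleation phase at permissive conditions, then a growth phase
that extends whatever nuclei formed into ribbons of gel-visible length), and
the ribbon-band intensity of each unseeded lane is compared with a seeded
control lane whose ribbon concentration is known from the seed concentration
(near-complete seed conversion).  Ribbon concentration divided by the
nucleation-phase duration gives a nucleation rate in mol/L/s.

Intensities are background-subtracted integrated band intensities in
arbitrary units; intensity is assumed linear in loaded ribbon mass through
the control (single-point calibration).  Lanes below the detection floor
(about 65 pg of DNA per lane, i.e. roughly half a million 5-um ribbons or
~200 fM in a 4-uL reaction) never yield a point estimate — they are
reported as censored upper bounds at the floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

__all__ = [
    "AVOGADRO",
    "RibbonSpec",
    "GelLane",
    "RateEstimate",
    "slats_per_ribbon",
    "ribbons_to_molar",
    "molar_to_ribbons",
    "ribbon_mass",
    "nucleation_rate_endpoint",
    "unseeded_rate_from_gel",
    "round_sig",
]

AVOGADRO = 6.02214076e23
HOUR = 3600.0

#: default detection floor as a ribbon concentration (mol/L)
DETECTION_FLOOR_M = 200e-15


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class RibbonSpec:
    """Geometry/composition of a ribbon population for mass conversions.

    length : ribbon contour length, nm
    delta : extension per slat, nm
    slat_nt : mean nucleotides per slat (core + brush)
    nt_mass : g/mol per nucleotide of ssDNA
    """

    length: float
    delta: float = 1.5
    slat_nt: float = 66.0
    nt_mass: float = 330.0

    def __post_init__(self) -> None:
        for name in ("length", "delta", "slat_nt", "nt_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def slats_per_ribbon(self) -> float:
        return self.length / self.delta


def slats_per_ribbon(length_nm: float, delta: float = 1.5) -> float:
    """Slats in a ribbon of a given contour length: ``length / delta``.

    A 5-um ribbon at 1.5 nm per slat holds ~3300 slats (2 significant
    figures for reporting; the exact value is returned).
    """
    if length_nm <= 0 or delta <= 0:
        raise ValueError("length and delta must be positive")
    return length_nm / delta


def ribbons_to_molar(count: float, volume_uL: float) -> float:
    """Ribbon count in a reaction volume -> molar concentration."""
    if volume_uL <= 0:
        raise ValueError("volume must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / (AVOGADRO * volume_uL * 1e-6)


def molar_to_ribbons(conc_M: float, volume_uL: float) -> float:
    """Inverse of :func:`ribbons_to_molar`."""
    if volume_uL <= 0:
        raise ValueError("volume must be positive")
    return conc_M * AVOGADRO * volume_uL * 1e-6


def ribbon_mass(spec: RibbonSpec, count: float) -> float:
    """Total ssDNA mass (grams) of ``count`` ribbons of the given spec."""
    if count < 0:
        raise ValueError("count must be non-negative")
    return count * spec.slats_per_ribbon * spec.slat_nt * spec.nt_mass / AVOGADRO


def nucleation_rate_endpoint(ribbon_conc_M: float, duration_h: float) -> float:
    """Endpoint nucleation rate (mol/L/s) from accumulated ribbons.

    200 fM of ribbons over 100 h is ~0.6 aM/s.
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    if ribbon_conc_M < 0:
        raise ValueError("concentration must be non-negative")
    return ribbon_conc_M / (duration_h * HOUR)


@dataclass(frozen=True)
class GelLane:
    """One background-subtracted gel lane."""

    intensity: float
    loaded_volume_uL: float
    reaction_volume_uL: float
    duration_h: float
    role: str  # 'unseeded' | 'seeded_control' | 'ladder'
    seed_conc: float | None = None  # mol/L, controls only
    label: str = ""

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if self.loaded_volume_uL <= 0 or self.reaction_volume_uL <= 0:
            raise ValueError("volumes must be positive")
        if self.role not in ("unseeded", "seeded_control", "ladder"):
            raise ValueError(f"unknown lane role {self.role!r}")


@dataclass(frozen=True)
class RateEstimate:
    """Nucleation-rate result for one unseeded lane.

    ``censored`` lanes carry an upper bound (the detection floor expressed as
    rate and concentration), never a point estimate.
    """

    label: str
    ribbon_conc_M: float  # estimate, or the floor when censored
    rate_M_per_s: float
    censored: bool
    duration_h: float

    def report(self) -> str:
        rate = round_sig(self.rate_M_per_s * 1e18, 1)  # aM/s, 1 s.f.
        if self.censored:
            return f"{self.label}: < {rate} aM/s (below gel detection floor)"
        return f"{self.label}: {rate} aM/s"


def unseeded_rate_from_gel(
    lanes: Sequence[GelLane],
    nucleation_phase_h: float | None = None,
    detection_floor_M: float = DETECTION_FLOOR_M,
    seed_conversion: float = 1.0,
) -> List[RateEstimate]:
    """Nucleation rates of unseeded lanes against a seeded control lane.

    The control lane's ribbon concentration is ``seed_conc * seed_conversion``
    (near-complete conversion by default).  Each unseeded lane's ribbon
    concentration is the intensity ratio to the control, corrected for loaded
    fraction, times the control concentration; dividing by the nucleation
    phase duration (``nucleation_phase_h``, defaulting to each lane's own
    duration) gives the rate.  Lanes whose intensity falls below the
    detection floor are censored: they yield the floor as an upper bound.
    """
    controls = [l for l in lanes if l.role == "seeded_control"]
    if len(controls) != 1:
        raise ValueError("exactly one seeded_control lane is required")
    control = controls[0]
    if control.intensity <= 0:
        raise ValueError("control lane intensity must be positive")
    if control.seed_conc is None or control.seed_conc <= 0:
        raise ValueError("control lane needs a known positive seed_conc")
    control_conc = control.seed_conc * seed_conversion
    # intensity per (mol/L in the reaction), per uL loaded
    control_specific = control.intensity / (control_conc * control.loaded_volume_uL)

    results = []
    for lane in lanes:
        if lane.role != "unseeded":
            continue
        duration = nucleation_phase_h or lane.duration_h
        if duration <= 0:
            raise ValueError("nucleation-phase duration must be positive")
        conc = lane.intensity / (control_specific * lane.loaded_volume_uL)
        if conc < detection_floor_M:
            results.append(
                RateEstimate(
                    label=lane.label,
                    ribbon_conc_M=detection_floor_M,
                    rate_M_per_s=nucleation_rate_endpoint(detection_floor_M, duration),
                    censored=True,
                    duration_h=duration,
                )
            )
        else:
            results.append(
                RateEstimate(
                    label=lane.label,
                    ribbon_conc_M=conc,
                    rate_M_per_s=nucleation_rate_endpoint(conc, duration),
                    censored=False,
                    duration_h=duration,
                )
            )
    if not results:
        raise ValueError("no unseeded lanes to quantify")
    return results
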