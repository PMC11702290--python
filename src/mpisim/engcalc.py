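"""Closed-form engineering and dosimetry calculators.

Pure functions for the scanner's back-of-envelope numbers: resistive heat
load of the triangle-driven shift coils, parallel thermal resistance of the
cooling circuits, gantry gear-train speed and sweep time, Joule temperature
rise, and the per-voxel iron dose expected in cerebral gray matter.
No intermediate rounding anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CoilBank",
    "VoxelDoseBreakdown",
    "triangle_heat_load",
    "parallel_thermal_resistance",
    "gear_train_speed",
    "sweep_time",
    "voxel_iron_mass",
    "joule_temperature_rise",
    "SHIFT_COIL_BANK",
]


@dataclass(frozen=True)
class CoilBank:
    """DC resistances (ohm) of a set of series-driven coils."""

    resistances: tuple

    def __post_init__(self):
        if len(self.resistances) == 0 or any(r <= 0 for r in self.resistances):
            raise ValueError("resistances must be a nonempty positive list")

    @property
    def total_resistance(self) -> float:
        return float(sum(self.resistances))


#: The four shift racetrack coils (two inner at 310 mOhm, two outer at
#: 399 mOhm, DC at 25 C).
SHIFT_COIL_BANK = CoilBank(resistances=(0.310, 0.310, 0.399, 0.399))


def triangle_heat_load(i_peak, coils: CoilBank):
    """Resistive power (W) of a 100%-duty triangle current drive.

    A triangle wave of peak I has RMS I/sqrt(3), so P = I^2/3 x sum(R).
    The four shift coils at 250 A_peak dissipate 29.5 kW.
    """
    if i_peak < 0:
        raise ValueError("i_peak must be nonnegative")
    return i_peak ** 2 / 3.0 * coils.total_resistance


def parallel_thermal_resistance(branch_resistances):
    """Net thermal resistance (K/W) of parallel cooling branches."""
    branches = list(branch_resistances)
    if not branches:
        raise ValueError("need at least one branch")
    if any(r <= 0 for r in branches):
        raise ValueError("branch resistances must be positive")
    return 1.0 / sum(1.0 / r for r in branches)


def gear_train_speed(input_rpm, ratios=()):
    """Output speed of a gear train: input RPM times the product of ratios."""
    out = float(input_rpm)
    for r in ratios:
        if r <= 0:
            raise ValueError("gear ratios must be positive")
        out *= r
    return out


def sweep_time(gantry_rpm, degrees):
    """Seconds for the gantry to sweep the given angle."""
    if gantry_rpm <= 0:
        raise ValueError("gantry_rpm must be positive")
    return (degrees / 360.0) * 60.0 / gantry_rpm


@dataclass(frozen=True)
class VoxelDoseBreakdown:
    """Iron mass per voxel with its intermediate quantities (unrounded)."""

    mass_ng: float
    blood_concentration_ug_per_ml: float
    tissue_concentration_ug_per_ml: float
    voxel_volume_ul: float


def voxel_iron_mass(dose=5.0, blood_volume_per_mass=65.0,
                    tissue_blood_fraction=0.05, voxel_edge=6.0
                    ) -> VoxelDoseBreakdown:
    """Expected iron mass per voxel for an intravascular SPION dose.

    ``dose`` (mg_Fe/kg body mass) distributed over ``blood_volume_per_mass``
    (mL/kg) gives the blood iron concentration; scaling by the tissue blood
    volume fraction (about 5% in gray matter) and the voxel volume
    (``voxel_edge`` mm cubed) gives nanograms of iron per voxel.  Defaults
    reproduce the 830 ng_Fe per 6 mm gray-matter voxel estimate; a blood
    fraction of 1 gives the large-vessel value (~16.6 ug).
    """
    if dose <= 0 or blood_volume_per_mass <= 0 or voxel_edge <= 0:
        raise ValueError("dose, blood volume, and voxel edge must be positive")
    if not 0 <= tissue_blood_fraction <= 1:
        raise ValueError("tissue_blood_fraction must be in [0, 1]")
    blood_conc = dose / blood_volume_per_mass * 1e3       # ug/mL
    tissue_conc = blood_conc * tissue_blood_fraction      # ug/mL
    voxel_ul = voxel_edge ** 3                            # mm^3 = uL
    mass_ng = tissue_conc * voxel_ul * 1e-3 * 1e3         # ug/mL * mL -> ug -> ng
    return VoxelDoseBreakdown(mass_ng=mass_ng,
                              blood_concentration_ug_per_ml=blood_conc,
                              tissue_concentration_ug_per_ml=tissue_conc,
                              voxel_volume_ul=voxel_ul)


def joule_temperature_rise(power, thermal_resistance):
    """Steady-state temperature rise (K): power (W) times R_th (K/W)."""
    if power < 0 or thermal_resistance < 0:
        raise ValueError("power and thermal resistance must be nonnegative")
    return power * thermal_resistance
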