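"""Reduced-unit conventions for the DPD model.

The single interaction cutoff r_c is the reduced length unit, the thermal
energy k_BT the reduced energy unit, and the mass of one water bead (three
H2O molecules, 54 Da) the reduced mass unit.  r_c defaults to the water-bead
diameter, 2 x 3.23 A = 6.46 A; with liquid water at 1 g/cm^3 this places
3.0 beads in every r_c^3, the standard DPD liquid density.
"""

from __future__ import annotations

from dataclasses import dataclass

# Avogadro x 1e-24: beads per A^3 for density 1 g/cm^3 and mass 1 Da
_N_A_PER_A3 = 0.602214076

ANGSTROM_PER_NM = 10.0


@dataclass(frozen=True)
class SimulationUnits:
    """Mapping between reduced simulation units and physical units.

    Parameters
    ----------
    r_c : float
        Angstrom represented by one reduced length (interaction cutoff).
    kT : float
        Reduced thermal energy; the thermostat target. Conventionally 1.
    mass_unit : float
        Daltons per reduced mass unit (one water bead).
    time_per_step_ps : float
        Physical picoseconds reported per DPD step.  This is a bookkeeping
        convention for mapping step counts to nanosecond-scale run lengths,
        not a dynamical time calibration.
    """

    r_c: float = 6.46
    kT: float = 1.0
    mass_unit: float = 54.0
    time_per_step_ps: float = 3.0

    def __post_init__(self) -> None:
        if min(self.r_c, self.kT, self.mass_unit, self.time_per_step_ps) <= 0:
            raise ValueError("all unit scales must be positive")

    @property
    def rho(self) -> float:
        """Reduced bead number density implied by liquid water (~3.0)."""
        return _N_A_PER_A3 / self.mass_unit * self.r_c**3

    def to_reduced(self, x_angstrom: float) -> float:
        return x_angstrom / self.r_c

    def to_angstrom(self, x_reduced: float) -> float:
        return x_reduced * self.r_c

    def to_nm(self, x_reduced: float) -> float:
        return x_reduced * self.r_c / ANGSTROM_PER_NM

    def steps_for(self, nanoseconds: float) -> int:
        """Number of DPD steps reported as `nanoseconds` of mapped time."""
        import math

        return math.ceil(nanoseconds * 1000.0 / self.time_per_step_ps)


def angstrom_to_reduced(x: float, units: SimulationUnits) -> float:
    """Convert a length in angstrom to reduced units (x / r_c)."""
    return units.to_reduced(x)


DEFAULT_UNITS = SimulationUnits()
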