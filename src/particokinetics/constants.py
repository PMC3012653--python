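"""Physical constants used throughout the package (SI units).

The Boltzmann constant is derived as R/N_A rather than taken directly, so
that the Stokes-Einstein diffusivity is computed literally as RT/(3 N_A pi mu d).
"""

from dataclasses import dataclass

#: molar gas constant, J/(mol K)
GAS_CONSTANT = 8.314462618

#: Avogadro's number, 1/mol
AVOGADRO = 6.02214076e23

#: standard gravitational acceleration, m/s^2
GRAVITY = 9.81

#: Boltzmann constant, J/K, derived as R / N_A
BOLTZMANN = GAS_CONSTANT / AVOGADRO


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of physical constants, overridable for non-terrestrial what-ifs."""

    g: float = GRAVITY
    gas_constant: float = GAS_CONSTANT
    avogadro: float = AVOGADRO

    @property
    def boltzmann(self) -> float:
        return self.gas_constant / self.avogadro


CONSTANTS = PhysicalConstants()
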