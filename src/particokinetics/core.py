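"""Domain types and closed-form particokinetic quantities.

Spherical particles settling and diffusing in static, viscous cell-culture
medium: Stokes terminal velocity, Stokes-Einstein diffusivity, the particle
Reynolds number (laminar-flow validity screen), and the fractal-agglomerate
model of Sterling-type flocs (particle count, porosity, effective density,
agglomerate settling velocity).

All quantities are SI.  Use :mod:`particokinetics.units` to convert
lab-friendly inputs at the boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .constants import BOLTZMANN, GRAVITY
from .units import convert_units

#: default packing factor for randomly packed spherical monomers
DEFAULT_PACKING_FACTOR = 0.637

#: particle Reynolds number above which the creeping-flow assumption fails
REYNOLDS_LIMIT = 1.0


class LaminarFlowError(ValueError):
    """The particle Reynolds number violates the creeping-flow assumption."""


class BuoyantParticleWarning(UserWarning):
    """Particle is less dense than the medium; it drifts upward."""


@dataclass(frozen=True)
class Medium:
    """Static liquid culture medium.

    Parameters
    ----------
    temperature : float
        Absolute temperature, K.
    viscosity : float
        Dynamic viscosity, Pa.s (water at 37 C is about 6.9e-4).
    density : float
        Fluid density, kg/m^3.
    """

    temperature: float
    viscosity: float
    density: float

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.viscosity <= 0:
            raise ValueError(f"viscosity must be positive, got {self.viscosity}")
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")

    @classmethod
    def from_lab(
        cls,
        temperature_c: float,
        viscosity_mpa_s: float,
        density_g_ml: float,
    ) -> "Medium":
        """Build from Celsius, mPa.s (= cP) and g/mL."""
        return cls(
            temperature=convert_units(temperature_c, "degC", "K"),
            viscosity=convert_units(viscosity_mpa_s, "mPa.s", "Pa.s"),
            density=convert_units(density_g_ml, "g/mL", "kg/m^3"),
        )


@dataclass(frozen=True)
class ParticleSpec:
    """A primary spherical particle.

    Parameters
    ----------
    diameter : float
        Hydrodynamic diameter, m.
    density : float
        Material density, kg/m^3.
    label : str
        Free-text identifier.
    """

    diameter: float
    density: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"diameter must be positive, got {self.diameter}")
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")

    @property
    def volume(self) -> float:
        """Solid volume of the sphere, m^3."""
        return math.pi * self.diameter**3 / 6.0

    @property
    def surface_area(self) -> float:
        """Geometric surface area of the sphere, m^2."""
        return math.pi * self.diameter**2


@dataclass(frozen=True)
class AgglomerateSpec:
    """A fractal agglomerate of identical spherical monomers.

    The solid mass of the agglomerate scales with its envelope diameter as
    d_agg^DF; the remaining envelope volume is pore space filled with
    trapped medium.  DF near 3 means efficient space filling (dense,
    fast-settling agglomerates), DF near 2 means loose, tenuous flocs whose
    effective density approaches that of the medium as they grow.

    Parameters
    ----------
    monomer : ParticleSpec
        The primary particle.
    agglomerate_diameter : float
        Hydrodynamic (envelope) diameter of the agglomerate, m; must be at
        least the monomer diameter.
    fractal_dimension : float
        DF, in (1, 3].
    packing_factor : float
        PF, in (0, 1]; 0.637 for randomly packed spheres.
    """

    monomer: ParticleSpec
    agglomerate_diameter: float
    fractal_dimension: float
    packing_factor: float = DEFAULT_PACKING_FACTOR

    def __post_init__(self) -> None:
        if self.agglomerate_diameter < self.monomer.diameter:
            raise ValueError(
                "agglomerate diameter "
                f"{self.agglomerate_diameter} is smaller than the monomer "
                f"diameter {self.monomer.diameter}"
            )
        if not 1.0 < self.fractal_dimension <= 3.0:
            raise ValueError(
                f"fractal dimension must be in (1, 3], got {self.fractal_dimension}"
            )
        if not 0.0 < self.packing_factor <= 1.0:
            raise ValueError(
                f"packing factor must be in (0, 1], got {self.packing_factor}"
            )

    @property
    def diameter(self) -> float:
        """Hydrodynamic diameter used for transport (the envelope diameter)."""
        return self.agglomerate_diameter

    @property
    def size_ratio(self) -> float:
        return self.agglomerate_diameter / self.monomer.diameter

    @property
    def particle_count(self) -> float:
        """Np, the number of monomers per agglomerate (continuous, unrounded)."""
        return self.size_ratio**self.fractal_dimension / self.packing_factor

    @property
    def porosity(self) -> float:
        """Envelope volume fraction occupied by trapped medium, in [0, 1)."""
        return 1.0 - self.size_ratio ** (self.fractal_dimension - 3.0)

    @property
    def solid_mass(self) -> float:
        """Total monomer mass per agglomerate, kg (trapped medium excluded)."""
        return self.particle_count * self.monomer.density * self.monomer.volume

    @property
    def constituent_surface_area(self) -> float:
        """Summed monomer surface area per agglomerate, m^2."""
        return self.particle_count * self.monomer.surface_area

    @property
    def label(self) -> str:
        return self.monomer.label


@dataclass(frozen=True)
class AgglomerateProperties:
    """Derived transport-relevant properties of a fractal agglomerate."""

    particle_count: float
    porosity: float
    effective_density: float
    sedimentation_velocity: float


def agglomerate_diameter_for_count(
    monomer: ParticleSpec,
    particle_count: float,
    fractal_dimension: float,
    packing_factor: float = DEFAULT_PACKING_FACTOR,
) -> float:
    """Envelope diameter of an agglomerate containing ``particle_count`` monomers.

    Inverts Np = (d_agg/d)^DF / PF.  Note that for Np below 1/PF the formal
    result is smaller than the monomer itself; callers modelling a single
    particle should use the bare monomer instead.
    """
    if particle_count <= 0:
        raise ValueError("particle_count must be positive")
    return monomer.diameter * (particle_count * packing_factor) ** (
        1.0 / fractal_dimension
    )


def stokes_velocity(particle: ParticleSpec, medium: Medium) -> float:
    """Stokes terminal sedimentation velocity, m/s.

    V = g (rho_p - rho_f) d^2 / (18 mu).  Positive means downward settling;
    a buoyant particle (rho_p < rho_f) gives a negative value (upward drift)
    and a :class:`BuoyantParticleWarning`.
    """
    delta_rho = particle.density - medium.density
    if delta_rho < 0:
        warnings.warn(
            f"particle density {particle.density} kg/m^3 is below the medium "
            f"density {medium.density} kg/m^3; it will drift upward",
            BuoyantParticleWarning,
            stacklevel=2,
        )
    return GRAVITY * delta_rho * particle.diameter**2 / (18.0 * medium.viscosity)


def stokes_einstein_diffusivity(particle: ParticleSpec | AgglomerateSpec,
                                medium: Medium) -> float:
    """Stokes-Einstein Brownian diffusivity, m^2/s.

    D = k_B T / (3 pi mu d), with k_B computed as R/N_A and d the
    hydrodynamic diameter (the envelope diameter for an agglomerate).
    """
    return BOLTZMANN * medium.temperature / (
        3.0 * math.pi * medium.viscosity * particle.diameter
    )


def reynolds_number(diameter: float, velocity: float, medium: Medium) -> float:
    """Particle Reynolds number rho_f |V| d / mu (dimensionless)."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return medium.density * abs(velocity) * diameter / medium.viscosity


def check_laminar(
    diameter: float,
    velocity: float,
    medium: Medium,
    policy: str = "error",
) -> float:
    """Screen the creeping-flow assumption; returns the Reynolds number.

    Stokes drag (and hence both transport coefficients) requires Re < 1.
    ``policy`` is ``"error"`` (raise :class:`LaminarFlowError`) or ``"warn"``.
    """
    re = reynolds_number(diameter, velocity, medium)
    if re >= REYNOLDS_LIMIT:
        msg = (
            f"particle Reynolds number {re:.3g} >= {REYNOLDS_LIMIT}: the "
            "laminar (creeping flow) assumption behind Stokes drag is violated"
        )
        if policy == "error":
            raise LaminarFlowError(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    return re


def agglomerate_properties(spec: AgglomerateSpec, medium: Medium) -> AgglomerateProperties:
    """Particle count, porosity, effective density and settling velocity.

    The agglomerate is treated as an impermeable sphere of its envelope
    diameter whose density is the porosity-weighted mix of monomer material
    and trapped medium:

        Np      = (d_agg/d)^DF / PF
        eps     = 1 - (d_agg/d)^(DF-3)
        rho_agg = (1 - eps) rho_p + eps rho_f
        V_agg   = g (rho_agg - rho_f) d^(3-DF) d_agg^(DF-1) / (18 mu)

    V_agg is algebraically the Stokes velocity of a solid sphere of diameter
    d_agg and density rho_agg, since (rho_agg - rho_f) carries the factor
    (d/d_agg)^(3-DF).  At DF=3, PF=1 everything collapses to the solid
    monomer sphere model.
    """
    d = spec.monomer.diameter
    d_agg = spec.agglomerate_diameter
    df = spec.fractal_dimension
    eps = spec.porosity
    rho_agg = (1.0 - eps) * spec.monomer.density + eps * medium.density
    v_agg = (
        GRAVITY
        * (rho_agg - medium.density)
        * d ** (3.0 - df)
        * d_agg ** (df - 1.0)
        / (18.0 * medium.viscosity)
    )
    return AgglomerateProperties(
        particle_count=spec.particle_count,
        porosity=eps,
        effective_density=rho_agg,
        sedimentation_velocity=v_agg,
    )


def transport_coefficients(
    particle: ParticleSpec | AgglomerateSpec, medium: Medium
) -> tuple[float, float]:
    """(diffusivity, sedimentation velocity) for a particle or agglomerate."""
    diffusivity = stokes_einstein_diffusivity(particle, medium)
    if isinstance(particle, AgglomerateSpec):
        velocity = agglomerate_properties(particle, medium).sedimentation_velocity
    else:
        velocity = stokes_velocity(particle, medium)
    return diffusivity, velocity
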