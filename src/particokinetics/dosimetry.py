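"""Delivered-dose metrics: number, surface area and mass per deposition area.

The transport solver produces a delivered *fraction* time course; this
module converts an exposure description (concentration, media geometry,
duration) into administered totals and scales them by the fraction to give
cellular dose time courses on every metric, plus the time-weighted dose
(AUC).  Polydisperse suspensions (e.g. a DLS size-class table) are handled
by solving each size class independently and summing -- particles are
non-interacting, so the PDE is linear in each class.

Conventions: the surface-area metric counts constituent monomer surface
(Np * pi d^2), not the smooth envelope of an agglomerate -- the biologically
argued dose is primary-particle surface.  Mass counts solid monomer mass
only; trapped medium is not particle mass.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AgglomerateSpec, Medium, ParticleSpec
from .transport import (
    SolverSettings,
    TransportSolution,
    build_problem,
    solve_transport,
)

CONCENTRATION_BASES = ("mass", "number")

#: fixed CSV column layout for written time courses
TIMECOURSE_COLUMNS = (
    "time_s",
    "fraction_delivered",
    "number_per_cm2",
    "sa_cm2_per_cm2",
    "mass_ug_per_cm2",
)


@dataclass(frozen=True)
class ExposureSetup:
    """An in vitro exposure: concentration, geometry, duration (all SI).

    Exactly one concentration basis is used: ``basis="mass"`` means
    ``concentration`` is kg/m^3 (note 1 ug/mL = 1e-3 kg/m^3),
    ``basis="number"`` means 1/m^3.  Geometry may be given as
    media_height + deposition_area, as media_volume + one of the two, or as
    all three (checked for consistency).
    """

    concentration: float
    basis: str
    duration: float
    media_height: float | None = None
    deposition_area: float | None = None
    media_volume: float | None = None

    def __post_init__(self) -> None:
        if self.basis not in CONCENTRATION_BASES:
            raise ValueError(f"basis must be one of {CONCENTRATION_BASES}")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        given = [
            v
            for v in (self.media_height, self.deposition_area, self.media_volume)
            if v is not None
        ]
        if any(v <= 0 for v in given):
            raise ValueError("geometry values must be positive")
        if self.media_volume is None:
            if self.media_height is None or self.deposition_area is None:
                raise ValueError(
                    "give media_volume, or media_height plus deposition_area"
                )
        elif self.media_height is not None and self.deposition_area is not None:
            implied = self.media_height * self.deposition_area
            if not math.isclose(implied, self.media_volume, rel_tol=1e-6):
                raise ValueError(
                    f"inconsistent geometry: height*area = {implied} but "
                    f"media_volume = {self.media_volume}"
                )
        elif self.media_height is None and self.deposition_area is None:
            raise ValueError(
                "media_volume alone is ambiguous; also give media_height or "
                "deposition_area"
            )

    @property
    def volume(self) -> float:
        if self.media_volume is not None:
            return self.media_volume
        return self.media_height * self.deposition_area

    @property
    def height(self) -> float:
        if self.media_height is not None:
            return self.media_height
        return self.media_volume / self.deposition_area

    @property
    def area(self) -> float:
        if self.deposition_area is not None:
            return self.deposition_area
        return self.media_volume / self.media_height


@dataclass(frozen=True)
class AdministeredTotals:
    """Total administered particle number, solid mass and monomer surface area.

    Absolute totals plus the same quantities per unit deposition area.
    """

    number: float
    mass: float
    surface_area: float
    area: float

    @property
    def number_per_area(self) -> float:
        return self.number / self.area

    @property
    def mass_per_area(self) -> float:
        return self.mass / self.area

    @property
    def surface_area_per_area(self) -> float:
        return self.surface_area / self.area


def _per_particle(particle: ParticleSpec | AgglomerateSpec) -> tuple[float, float]:
    """(solid mass, constituent surface area) of one particle/agglomerate."""
    if isinstance(particle, AgglomerateSpec):
        return particle.solid_mass, particle.constituent_surface_area
    return particle.density * particle.volume, particle.surface_area


def administered_totals(
    exposure: ExposureSetup, particle: ParticleSpec | AgglomerateSpec
) -> AdministeredTotals:
    """Convert the exposure concentration into total number/mass/surface area.

    Number <-> mass conversion goes through the solid volume: one monomer
    weighs rho_p pi d^3/6; an agglomerate weighs Np times that.
    """
    m1, sa1 = _per_particle(particle)
    volume = exposure.volume
    if exposure.basis == "number":
        number = exposure.concentration * volume
        mass = number * m1
    else:
        mass = exposure.concentration * volume
        number = mass / m1
    return AdministeredTotals(
        number=number,
        mass=mass,
        surface_area=number * sa1,
        area=exposure.area,
    )


@dataclass(frozen=True)
class DoseTimeCourse:
    """Delivered dose vs time on every metric, per deposition area (SI).

    ``auc`` maps metric name -> trapezoidal integral of the cumulative
    per-area dose over time, in metric * s (see :func:`dose_auc` for
    metric-hours).
    """

    times: np.ndarray
    fraction_delivered: np.ndarray
    number_per_area: np.ndarray
    surface_area_per_area: np.ndarray
    mass_per_area: np.ndarray
    auc: dict[str, float]
    totals: AdministeredTotals

    METRICS = ("fraction", "number", "surface_area", "mass")

    def metric(self, name: str) -> np.ndarray:
        series = {
            "fraction": self.fraction_delivered,
            "number": self.number_per_area,
            "surface_area": self.surface_area_per_area,
            "mass": self.mass_per_area,
        }
        try:
            return series[name]
        except KeyError:
            raise ValueError(f"unknown metric {name!r}; one of {self.METRICS}") from None

    def to_frame(self) -> pd.DataFrame:
        """Time course in the fixed lab-unit CSV layout."""
        return pd.DataFrame(
            {
                "time_s": self.times,
                "fraction_delivered": self.fraction_delivered,
                "number_per_cm2": self.number_per_area * 1e-4,
                "sa_cm2_per_cm2": self.surface_area_per_area,
                "mass_ug_per_cm2": self.mass_per_area * 1e9 * 1e-4,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        """JSON-serializable summary: administered totals and per-metric AUC."""
        return {
            "administered": {
                "number": self.totals.number,
                "mass_kg": self.totals.mass,
                "surface_area_m2": self.totals.surface_area,
                "deposition_area_m2": self.totals.area,
            },
            "final_fraction_delivered": float(self.fraction_delivered[-1]),
            "auc_metric_hours": {
                name: dose_auc(self, name) for name in self.METRICS
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def _auc_seconds(times: np.ndarray, series: np.ndarray) -> float:
    return float(np.trapezoid(series, times))


def delivered_dose(
    solution: TransportSolution,
    exposure: ExposureSetup,
    particle: ParticleSpec | AgglomerateSpec,
) -> DoseTimeCourse:
    """Combine a transport solution with an exposure into dose time courses.

    Every metric is the administered per-area total times the delivered
    fraction (exact proportionality for a monodisperse suspension).
    """
    if not math.isclose(
        solution.problem.media_height, exposure.height, rel_tol=1e-9
    ):
        raise ValueError(
            "transport solution and exposure disagree on media height: "
            f"{solution.problem.media_height} vs {exposure.height}"
        )
    totals = administered_totals(exposure, particle)
    f = solution.fraction_delivered
    times = solution.times
    number = totals.number_per_area * f
    sa = totals.surface_area_per_area * f
    mass = totals.mass_per_area * f
    auc = {
        "fraction": _auc_seconds(times, f),
        "number": _auc_seconds(times, number),
        "surface_area": _auc_seconds(times, sa),
        "mass": _auc_seconds(times, mass),
    }
    return DoseTimeCourse(
        times=times,
        fraction_delivered=f,
        number_per_area=number,
        surface_area_per_area=sa,
        mass_per_area=mass,
        auc=auc,
        totals=totals,
    )


def dose_auc(timecourse: DoseTimeCourse, metric: str) -> float:
    """Time-weighted cumulative dose: trapezoidal AUC in metric * hours."""
    times = timecourse.times
    if len(times) < 2:
        raise ValueError("need at least two time points for an AUC")
    return _auc_seconds(times, timecourse.metric(metric)) / 3600.0


@dataclass(frozen=True)
class SizeDistribution:
    """Discrete hydrodynamic size classes with number fractions.

    ``classes`` is a sequence of (diameter_m, number_fraction).  Fractions
    must be non-negative and sum to 1 (renormalized with a warning if the
    total is off by more than 1e-6).
    """

    classes: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("distribution needs at least one class")
        diameters = [d for d, _ in self.classes]
        fractions = [w for _, w in self.classes]
        if any(d <= 0 for d in diameters):
            raise ValueError("class diameters must be positive")
        if len(set(diameters)) != len(diameters):
            raise ValueError("class diameters must be unique")
        if any(w < 0 for w in fractions):
            raise ValueError("number fractions must be non-negative")
        total = sum(fractions)
        if total <= 0:
            raise ValueError("number fractions must not all be zero")
        if abs(total - 1.0) > 1e-6:
            warnings.warn(
                f"number fractions sum to {total:.6g}; renormalizing",
                UserWarning,
                stacklevel=2,
            )
            object.__setattr__(
                self,
                "classes",
                tuple((d, w / total) for d, w in self.classes),
            )

    @property
    def diameters(self) -> np.ndarray:
        return np.array([d for d, _ in self.classes])

    @property
    def number_fractions(self) -> np.ndarray:
        w = np.array([w for _, w in self.classes])
        return w / w.sum()

    def number_mean_diameter(self) -> float:
        return float(self.number_fractions @ self.diameters)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SizeDistribution":
        """Read a two-column table with header ``diameter_nm,number_fraction``."""
        frame = pd.read_csv(path)
        missing = {"diameter_nm", "number_fraction"} - set(frame.columns)
        if missing:
            raise ValueError(f"distribution CSV lacks columns: {sorted(missing)}")
        return cls(
            tuple(
                (row.diameter_nm * 1e-9, row.number_fraction)
                for row in frame.itertuples()
            )
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "diameter_nm": self.diameters * 1e9,
                "number_fraction": self.number_fractions,
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class PolydisperseResult:
    """Combined dose time course plus the per-class solves behind it."""

    timecourse: DoseTimeCourse
    class_specs: tuple[ParticleSpec | AgglomerateSpec, ...]
    class_solutions: tuple[TransportSolution, ...]
    mass_fractions: np.ndarray


def simulate_polydisperse(
    distribution: SizeDistribution,
    monomer: ParticleSpec,
    medium: Medium,
    exposure: ExposureSetup,
    fractal_dimension: float | None = None,
    packing_factor: float = 0.637,
    output_times: Sequence[float] | None = None,
    settings: SolverSettings | None = None,
    bottom_bc: str = "absorbing",
) -> PolydisperseResult:
    """Solve every size class independently and sum the delivered metrics.

    With ``fractal_dimension`` set, each class diameter is an agglomerate
    envelope diameter (>= the monomer diameter) and per-class solid mass
    scales as d_agg^DF; otherwise classes are solid spheres of the monomer
    material.  Class mass fractions are number fractions weighted by
    per-class solid mass.  The combined ``fraction_delivered`` is the
    mass-weighted mixture fraction.
    """
    if output_times is None:
        output_times = np.linspace(0.0, exposure.duration, 201)
    specs: list[ParticleSpec | AgglomerateSpec] = []
    for d in distribution.diameters:
        if fractal_dimension is None:
            specs.append(ParticleSpec(float(d), monomer.density, monomer.label))
        else:
            specs.append(
                AgglomerateSpec(
                    monomer=monomer,
                    agglomerate_diameter=float(d),
                    fractal_dimension=fractal_dimension,
                    packing_factor=packing_factor,
                )
            )

    nu = distribution.number_fractions
    per_mass = np.array([_per_particle(s)[0] for s in specs])
    per_sa = np.array([_per_particle(s)[1] for s in specs])
    mean_mass = float(nu @ per_mass)
    mass_fractions = nu * per_mass / mean_mass

    volume, area = exposure.volume, exposure.area
    if exposure.basis == "number":
        total_number = exposure.concentration * volume
        total_mass = total_number * mean_mass
    else:
        total_mass = exposure.concentration * volume
        total_number = total_mass / mean_mass
    totals = AdministeredTotals(
        number=total_number,
        mass=total_mass,
        surface_area=total_number * float(nu @ per_sa),
        area=area,
    )

    solutions = []
    fractions = []
    for spec in specs:
        problem = build_problem(
            spec, medium, exposure.height, exposure.duration, bottom_bc=bottom_bc
        )
        sol = solve_transport(problem, output_times=output_times, settings=settings)
        solutions.append(sol)
        fractions.append(sol.fraction_delivered)
    f_matrix = np.array(fractions)  # (n_classes, n_times)
    times = solutions[0].times

    number = (totals.number / area) * (nu @ f_matrix)
    mass = (totals.mass / area) * (mass_fractions @ f_matrix)
    sa_weights = nu * per_sa / float(nu @ per_sa)
    sa = (totals.surface_area / area) * (sa_weights @ f_matrix)
    combined_fraction = mass_fractions @ f_matrix

    auc = {
        "fraction": _auc_seconds(times, combined_fraction),
        "number": _auc_seconds(times, number),
        "surface_area": _auc_seconds(times, sa),
        "mass": _auc_seconds(times, mass),
    }
    timecourse = DoseTimeCourse(
        times=times,
        fraction_delivered=combined_fraction,
        number_per_area=number,
        surface_area_per_area=sa,
        mass_per_area=mass,
        auc=auc,
        totals=totals,
    )
    return PolydisperseResult(
        timecourse=timecourse,
        class_specs=tuple(specs),
        class_solutions=tuple(solutions),
        mass_fractions=mass_fractions,
    )
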