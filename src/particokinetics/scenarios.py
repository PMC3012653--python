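"""Built-in scenario fixtures and parameter sweeps.

Every published-style simulation the package reproduces is expressed here
as a named, parameter-exact :class:`Scenario` built from the data table in
``data/scenarios.yaml``:

* ``polystyrene_table1`` -- transport of 24-1100 nm carboxylated
  polystyrene beads to a microscopy counting field over 500 s;
* ``silica_lison`` -- 6-h delivery of 34.8 nm amorphous silica across five
  media heights, constant-concentration and constant-mass designs;
* ``iron_oxide_df_scan`` -- 8-h mass delivery of a polydisperse iron-oxide
  agglomerate suspension across plausible fractal dimensions;
* ``generalization_sweeps`` -- 24-h size x density AUC grid, media-height
  sweep, and agglomeration-state (monomers-per-agglomerate) sweep.

The iron-oxide DLS class table is not published; a lognormal stand-in
pinned to the printed mean/SD is generated by
:func:`synthetic_distribution` (clearly synthetic, deterministic per seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

from .core import (
    AgglomerateSpec,
    Medium,
    ParticleSpec,
    agglomerate_diameter_for_count,
    reynolds_number,
    transport_coefficients,
)
from .dosimetry import (
    DoseTimeCourse,
    ExposureSetup,
    PolydisperseResult,
    SizeDistribution,
    delivered_dose,
    dose_auc,
    simulate_polydisperse,
)
from .transport import SolverSettings, build_problem, solve_transport


def _load_params() -> dict:
    text = resources.files("particokinetics.data").joinpath("scenarios.yaml").read_text()
    return yaml.safe_load(text)


PARAMS = _load_params()


def default_medium() -> Medium:
    p = PARAMS["default_medium"]
    return Medium(
        temperature=p["temperature_K"],
        viscosity=p["viscosity_mPa_s"] * 1e-3,
        density=p["density_g_mL"] * 1e3,
    )


def material_density(name: str) -> float:
    return PARAMS["materials"][name]["density_g_cm3"] * 1e3


@dataclass(frozen=True)
class Scenario:
    """A runnable fixture: particle(s) + medium + exposure (+ expectations).

    ``expected`` holds published reference values (with their provenance
    described in the key names) for display; they are never fed back into
    the computation.
    """

    name: str
    particle: ParticleSpec | AgglomerateSpec | None
    medium: Medium
    exposure: ExposureSetup
    distribution: SizeDistribution | None = None
    monomer: ParticleSpec | None = None
    fractal_dimension: float | None = None
    packing_factor: float = 0.637
    expected: dict = field(default_factory=dict)

    def run(
        self,
        settings: SolverSettings | None = None,
        output_times: Sequence[float] | None = None,
    ) -> DoseTimeCourse:
        """Run the full pipeline and return the dose time course."""
        if self.distribution is not None:
            return simulate_polydisperse(
                self.distribution,
                self.monomer,
                self.medium,
                self.exposure,
                fractal_dimension=self.fractal_dimension,
                packing_factor=self.packing_factor,
                output_times=output_times,
                settings=settings,
            ).timecourse
        problem = build_problem(
            self.particle, self.medium, self.exposure.height, self.exposure.duration
        )
        solution = solve_transport(problem, output_times=output_times, settings=settings)
        return delivered_dose(solution, self.exposure, self.particle)

    def derived_quantities(self) -> dict[str, float]:
        """Transport coefficients for logging/reporting (monodisperse only)."""
        if self.particle is None:
            return {}
        d, v = transport_coefficients(self.particle, self.medium)
        re = reynolds_number(self.particle.diameter, v, self.medium)
        alpha = (
            d / (v * self.exposure.height) if abs(v) > 1e-15 else math.inf
        )
        return {"diffusivity": d, "velocity": v, "alpha": alpha, "reynolds": re}


def polystyrene_table1() -> list[Scenario]:
    """Five monodisperse polystyrene transport-rate scenarios (500 s)."""
    p = PARAMS["polystyrene_table1"]
    medium = default_medium()
    density = material_density(p["material"])
    scenarios = []
    for d_nm in p["diameters_nm"]:
        exposure = ExposureSetup(
            concentration=p["concentration_particles_per_mL"] * 1e6,
            basis="number",
            duration=p["duration_s"],
            media_height=p["media_height_cm"] * 1e-2,
            deposition_area=p["counting_area_cm2"] * 1e-4,
        )
        scenarios.append(
            Scenario(
                name=f"polystyrene_{d_nm}nm",
                particle=ParticleSpec(d_nm * 1e-9, density, f"polystyrene {d_nm} nm"),
                medium=medium,
                exposure=exposure,
                expected={
                    "simulated_count": p["expected_counts"]["simulated"][d_nm],
                    "observed_counts": p["expected_counts"]["observed"][d_nm],
                    "oracle_consistent": d_nm in p["oracle_consistent_nm"],
                },
            )
        )
    return scenarios


def silica_lison() -> list[Scenario]:
    """Ten 6-h silica scenarios: 5 media heights x 2 exposure designs."""
    p = PARAMS["silica_lison"]
    base = default_medium()
    medium = Medium(base.temperature, p["viscosity_mPa_s"] * 1e-3, base.density)
    density = material_density(p["material"])
    particle = ParticleSpec(
        p["hydrodynamic_diameter_nm"] * 1e-9, density, "amorphous silica"
    )
    area = p["well_area_cm2"] * 1e-4
    duration = p["duration_h"] * 3600.0
    scenarios = []
    for h_mm in p["media_heights_mm"]:
        height = h_mm * 1e-3
        scenarios.append(
            Scenario(
                name=f"silica_const_conc_{h_mm}mm",
                particle=particle,
                medium=medium,
                exposure=ExposureSetup(
                    concentration=p["constant_concentration_ug_mL"] * 1e-3,
                    basis="mass",
                    duration=duration,
                    media_height=height,
                    deposition_area=area,
                ),
            )
        )
        mass_kg = p["constant_mass_ug"] * 1e-9
        scenarios.append(
            Scenario(
                name=f"silica_const_mass_{h_mm}mm",
                particle=particle,
                medium=medium,
                exposure=ExposureSetup(
                    concentration=mass_kg / (height * area),
                    basis="mass",
                    duration=duration,
                    media_height=height,
                    deposition_area=area,
                ),
                expected={"administered_mass_kg": mass_kg},
            )
        )
    return scenarios


def synthetic_distribution(
    mean: float, sd: float, n_classes: int, seed: int = 0
) -> SizeDistribution:
    """Synthetic lognormal size-class table (stand-in for a DLS histogram).

    Draws a large seeded sample from the lognormal with the requested
    arithmetic mean and SD, bins it into ``n_classes`` equal-width bins in
    log-diameter between the 1st and 99th percentiles, and returns
    class-mean diameters with number fractions.  Deterministic for a given
    seed; ``sd=0`` collapses to a single class at the mean.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if n_classes < 1:
        raise ValueError("need at least one class")
    if sd == 0 or n_classes == 1:
        return SizeDistribution(((mean, 1.0),))
    sigma2 = math.log1p((sd / mean) ** 2)
    sigma = math.sqrt(sigma2)
    mu = math.log(mean) - sigma2 / 2.0
    rng = np.random.default_rng(seed)
    sample = rng.lognormal(mu, sigma, size=100_000)
    lo, hi = np.quantile(sample, [0.01, 0.99])
    sample = sample[(sample >= lo) & (sample <= hi)]
    edges = np.geomspace(lo, hi, n_classes + 1)
    idx = np.clip(np.digitize(sample, edges) - 1, 0, n_classes - 1)
    classes = []
    for k in range(n_classes):
        members = sample[idx == k]
        if members.size == 0:
            continue
        classes.append((float(members.mean()), members.size / sample.size))
    return SizeDistribution(tuple(classes))


def iron_oxide_distribution() -> SizeDistribution:
    """The five-class agglomerate stand-in pinned to the printed mean/SD."""
    p = PARAMS["iron_oxide_agglomerates"]
    return synthetic_distribution(
        p["agglomerate_mean_nm"] * 1e-9,
        p["agglomerate_sd_nm"] * 1e-9,
        p["n_classes"],
        seed=p["distribution_seed"],
    )


def iron_oxide_df_scan(
    df_values: Iterable[float] | None = None,
) -> list[Scenario]:
    """Polydisperse iron-oxide scenarios, one per fractal dimension."""
    p = PARAMS["iron_oxide_agglomerates"]
    if df_values is None:
        df_values = p["fractal_dimensions"]
    df_values = list(df_values)
    if any(not 1.0 < df <= 3.0 for df in df_values):
        raise ValueError("fractal dimensions must lie in (1, 3]")
    medium = default_medium()
    monomer = ParticleSpec(
        p["monomer_diameter_nm"] * 1e-9,
        material_density(p["material"]),
        "iron oxide",
    )
    distribution = iron_oxide_distribution()
    height = p["media_height_mm"] * 1e-3
    volume = p["media_volume_mL"] * 1e-6
    scenarios = []
    for df in df_values:
        scenarios.append(
            Scenario(
                name=f"iron_oxide_df_{df}",
                particle=None,
                medium=medium,
                exposure=ExposureSetup(
                    concentration=p["concentration_ug_mL"] * 1e-3,
                    basis="mass",
                    duration=p["duration_h"] * 3600.0,
                    media_height=height,
                    deposition_area=volume / height,
                ),
                distribution=distribution,
                monomer=monomer,
                fractal_dimension=df,
                packing_factor=p["packing_factor"],
            )
        )
    return scenarios


def _generalization_exposure(p: dict, height: float | None = None) -> ExposureSetup:
    volume = p["media_volume_mL"] * 1e-6
    height = height if height is not None else p["media_height_mm"] * 1e-3
    return ExposureSetup(
        concentration=p["concentration_ug_mL"] * 1e-3,
        basis="mass",
        duration=p["duration_h"] * 3600.0,
        media_height=height,
        deposition_area=volume / height,
    )


def size_density_grid() -> list[Scenario]:
    """24-h AUC grid across particle size and material density."""
    p = PARAMS["generalization"]
    medium = default_medium()
    scenarios = []
    for material, props in PARAMS["materials"].items():
        for d_nm in p["sweep_diameters_nm"]:
            scenarios.append(
                Scenario(
                    name=f"grid_{material}_{d_nm}nm",
                    particle=ParticleSpec(
                        d_nm * 1e-9, props["density_g_cm3"] * 1e3, material
                    ),
                    medium=medium,
                    exposure=_generalization_exposure(p),
                )
            )
    return scenarios


def media_height_sweep() -> list[Scenario]:
    """24-h TiO2 delivered fraction vs media height."""
    p = PARAMS["generalization"]
    medium = default_medium()
    density = material_density(p["height_sweep_material"])
    scenarios = []
    for d_nm in p["height_sweep_diameters_nm"]:
        for h_mm in p["height_sweep_mm"]:
            scenarios.append(
                Scenario(
                    name=f"height_TiO2_{d_nm}nm_{h_mm}mm",
                    particle=ParticleSpec(d_nm * 1e-9, density, "TiO2"),
                    medium=medium,
                    exposure=_generalization_exposure(p, height=h_mm * 1e-3),
                )
            )
    return scenarios


def agglomeration_state_sweep() -> list[Scenario]:
    """24-h delivered fraction vs monomers-per-agglomerate at two DF values.

    Np = 1 is the bare monomer (a solid sphere); for Np > 1 the envelope
    diameter follows from inverting the fractal particle-count relation.
    """
    p = PARAMS["generalization"]
    medium = default_medium()
    monomer = ParticleSpec(
        p["agglomeration_monomer_nm"] * 1e-9,
        material_density(p["agglomeration_material"]),
        "Fe2O3",
    )
    scenarios = []
    for df in p["agglomeration_fractal_dimensions"]:
        for count in p["agglomeration_counts"]:
            if count == 1:
                particle: ParticleSpec | AgglomerateSpec = monomer
            else:
                particle = AgglomerateSpec(
                    monomer=monomer,
                    agglomerate_diameter=agglomerate_diameter_for_count(
                        monomer, count, df
                    ),
                    fractal_dimension=df,
                )
            scenarios.append(
                Scenario(
                    name=f"agglomeration_df{df}_np{count}",
                    particle=particle,
                    medium=medium,
                    exposure=_generalization_exposure(p),
                    expected={"particle_count": count, "fractal_dimension": df},
                )
            )
    return scenarios


def generalization_sweeps() -> dict[str, list[Scenario]]:
    """All three generalization grids keyed by name."""
    return {
        "size_density_grid": size_density_grid(),
        "media_height_sweep": media_height_sweep(),
        "agglomeration_state_sweep": agglomeration_state_sweep(),
    }


SCENARIO_REGISTRY = {
    "polystyrene_table1": polystyrene_table1,
    "silica_lison": silica_lison,
    "iron_oxide_df_scan": iron_oxide_df_scan,
    "size_density_grid": size_density_grid,
    "media_height_sweep": media_height_sweep,
    "agglomeration_state_sweep": agglomeration_state_sweep,
}


def get_scenarios(name: str) -> list[Scenario]:
    try:
        factory = SCENARIO_REGISTRY[name]
    except KeyError:
        known = ", ".join(sorted(SCENARIO_REGISTRY))
        raise KeyError(f"unknown scenario {name!r}; known: {known}") from None
    return factory()
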