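"""Run configuration: YAML/JSON parsing, schema validation, SI conversion.

A run config describes one simulation in lab units::

    particle:
      diameter_nm: 100
      density_g_cm3: 1.05
      # optional agglomerate block:
      agglomerate: {agg_diameter_nm: 900, fractal_dimension: 2.3, packing_factor: 0.637}
    medium:
      temperature_C: 37
      viscosity_mPa_s: 0.69
      density_g_mL: 1.0
      serum_percent: 0        # optional; 10% serum raises viscosity 5%
    setup:
      media_height_mm: 3.1    # or volume_mL + well_area_cm2
      concentration: {value: 10, units: ug_per_mL}   # or particles_per_mL
      duration_h: 24
      bottom_bc: absorbing
    solver: {cells: 400, refinement: 50, rtol: 1e-7, atol: 1e-9}
    output: {n_times: 201}

Unknown keys anywhere are rejected; the concentration unit tag is
mandatory (a bare number is exactly the dose-metric ambiguity this format
exists to prevent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from .core import AgglomerateSpec, Medium, ParticleSpec
from .dosimetry import ExposureSetup
from .transport import BOTTOM_BCS, SolverSettings


class ConfigError(ValueError):
    """A config file failed schema validation; message names the field."""


_CONCENTRATION_UNITS = {
    "ug_per_mL": ("mass", 1e-3),
    "particles_per_mL": ("number", 1e6),
}

#: viscosity increase per percent serum (10% serum -> +5%)
SERUM_VISCOSITY_SLOPE = 0.005


def _require(block: dict, name: str, key: str):
    if key not in block:
        raise ConfigError(f"{name}: missing required key {key!r}")
    return block[key]


def _check_keys(block: dict, name: str, allowed: set[str]) -> None:
    if not isinstance(block, dict):
        raise ConfigError(f"{name}: expected a mapping, got {type(block).__name__}")
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"{name}: unknown keys {sorted(unknown)}")


def _positive(value, name: str) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError):
        raise ConfigError(f"{name}: expected a number, got {value!r}") from None
    if not value > 0 or not math.isfinite(value):
        raise ConfigError(f"{name}: must be a positive finite number, got {value}")
    return value


@dataclass(frozen=True)
class RunConfig:
    """Validated simulation configuration with SI-converted domain objects."""

    particle: ParticleSpec | AgglomerateSpec
    medium: Medium
    exposure: ExposureSetup
    bottom_bc: str
    solver: SolverSettings
    n_times: int
    label: str = ""


def _parse_particle(block: dict) -> ParticleSpec | AgglomerateSpec:
    _check_keys(
        block, "particle", {"diameter_nm", "density_g_cm3", "label", "agglomerate"}
    )
    monomer = ParticleSpec(
        diameter=_positive(_require(block, "particle", "diameter_nm"), "diameter_nm")
        * 1e-9,
        density=_positive(
            _require(block, "particle", "density_g_cm3"), "density_g_cm3"
        )
        * 1e3,
        label=str(block.get("label", "")),
    )
    agg = block.get("agglomerate")
    if agg is None:
        return monomer
    _check_keys(
        agg,
        "particle.agglomerate",
        {"agg_diameter_nm", "fractal_dimension", "packing_factor"},
    )
    try:
        return AgglomerateSpec(
            monomer=monomer,
            agglomerate_diameter=_positive(
                _require(agg, "particle.agglomerate", "agg_diameter_nm"),
                "agg_diameter_nm",
            )
            * 1e-9,
            fractal_dimension=_positive(
                _require(agg, "particle.agglomerate", "fractal_dimension"),
                "fractal_dimension",
            ),
            packing_factor=_positive(
                agg.get("packing_factor", 0.637), "packing_factor"
            ),
        )
    except ValueError as exc:
        raise ConfigError(f"particle.agglomerate: {exc}") from None


def _parse_medium(block: dict) -> Medium:
    _check_keys(
        block,
        "medium",
        {"temperature_C", "temperature_K", "viscosity_mPa_s", "density_g_mL",
         "serum_percent"},
    )
    if "temperature_K" in block:
        if "temperature_C" in block:
            raise ConfigError("medium: give temperature_C or temperature_K, not both")
        temperature = _positive(block["temperature_K"], "temperature_K")
    else:
        temperature = float(_require(block, "medium", "temperature_C")) + 273.15
    viscosity = _positive(
        _require(block, "medium", "viscosity_mPa_s"), "viscosity_mPa_s"
    ) * 1e-3
    serum = float(block.get("serum_percent", 0.0))
    if serum < 0 or serum > 100:
        raise ConfigError(f"medium.serum_percent: must be in [0, 100], got {serum}")
    viscosity *= 1.0 + SERUM_VISCOSITY_SLOPE * serum
    return Medium(
        temperature=temperature,
        viscosity=viscosity,
        density=_positive(_require(block, "medium", "density_g_mL"), "density_g_mL")
        * 1e3,
    )


def _parse_setup(block: dict) -> tuple[ExposureSetup, str]:
    _check_keys(
        block,
        "setup",
        {"media_height_mm", "volume_mL", "well_area_cm2", "concentration",
         "duration_h", "bottom_bc"},
    )
    conc = _require(block, "setup", "concentration")
    _check_keys(conc, "setup.concentration", {"value", "units"})
    units = _require(conc, "setup.concentration", "units")
    if units not in _CONCENTRATION_UNITS:
        raise ConfigError(
            f"setup.concentration.units: {units!r} not in "
            f"{sorted(_CONCENTRATION_UNITS)} (the unit tag is mandatory)"
        )
    basis, scale = _CONCENTRATION_UNITS[units]
    value = _positive(_require(conc, "setup.concentration", "value"), "concentration")

    height = block.get("media_height_mm")
    volume = block.get("volume_mL")
    area = block.get("well_area_cm2")
    kwargs: dict = {}
    if height is not None:
        kwargs["media_height"] = _positive(height, "media_height_mm") * 1e-3
    if volume is not None:
        kwargs["media_volume"] = _positive(volume, "volume_mL") * 1e-6
    if area is not None:
        kwargs["deposition_area"] = _positive(area, "well_area_cm2") * 1e-4
    if "media_height" not in kwargs and not (
        "media_volume" in kwargs and "deposition_area" in kwargs
    ):
        raise ConfigError(
            "setup: give media_height_mm (optionally with well_area_cm2) or "
            "volume_mL plus well_area_cm2"
        )
    if "media_height" in kwargs and "deposition_area" not in kwargs:
        # height alone fixes the transport problem; fractions need no area,
        # per-area metrics use a nominal 1 cm2 field
        kwargs["deposition_area"] = 1e-4

    duration = _positive(_require(block, "setup", "duration_h"), "duration_h") * 3600.0
    bc = block.get("bottom_bc", "absorbing")
    if bc not in BOTTOM_BCS:
        raise ConfigError(f"setup.bottom_bc: {bc!r} not in {BOTTOM_BCS}")
    try:
        exposure = ExposureSetup(
            concentration=value * scale, basis=basis, duration=duration, **kwargs
        )
    except ValueError as exc:
        raise ConfigError(f"setup: {exc}") from None
    return exposure, bc


def _parse_solver(block: dict | None) -> SolverSettings:
    if block is None:
        return SolverSettings()
    _check_keys(block, "solver", {"cells", "refinement", "rtol", "atol"})
    try:
        return SolverSettings(
            n_cells=int(block.get("cells", 400)),
            refinement=float(block.get("refinement", 50.0)),
            rtol=float(block.get("rtol", 1e-7)),
            atol=float(block.get("atol", 1e-9)),
        )
    except ValueError as exc:
        raise ConfigError(f"solver: {exc}") from None


def _parse_output(block: dict | None) -> int:
    if block is None:
        return 201
    _check_keys(block, "output", {"n_times"})
    n_times = int(block.get("n_times", 201))
    if n_times < 2:
        raise ConfigError("output.n_times: need at least 2 output times")
    return n_times


def parse_config(raw: dict, label: str = "") -> RunConfig:
    _check_keys(raw, "config", {"particle", "medium", "setup", "solver", "output"})
    particle = _parse_particle(_require(raw, "config", "particle"))
    medium = _parse_medium(_require(raw, "config", "medium"))
    exposure, bottom_bc = _parse_setup(_require(raw, "config", "setup"))
    return RunConfig(
        particle=particle,
        medium=medium,
        exposure=exposure,
        bottom_bc=bottom_bc,
        solver=_parse_solver(raw.get("solver")),
        n_times=_parse_output(raw.get("output")),
        label=label,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not parseable as YAML/JSON: {exc}") from None
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return parse_config(raw, label=path.stem)
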