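"""Run configuration: a flat YAML file tying every stage's parameters together.

All defaults are the simulator's standard operating point: 25 beams/m^2
(0.2 m spacing) from 100 m, 1.36 m mesh vertex spacing, species optics
(rho 0.25/0.17, tau 0.15/0.20, refraction index 0.5) and the calibrated
clear-sky atmosphere.  CLI flags override file values, which override
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .mesh import MeshResolution
from .scene import BROADLEAF, CONIFER
from .solar import AtmosphericParams
from .flux import OpticalProperties

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Validated bundle of site, schedule, atmosphere, optics and sampling."""

    latitude: float = 32.076
    longitude: float = 118.812
    days: list[int] = field(default_factory=lambda: [166])
    hours: list[float] = field(default_factory=lambda: [12.0])
    beam_spacing: float = 0.2
    source_height: float = 100.0
    mesh_spacing: float = 1.36
    seed: int = 0
    atmosphere: AtmosphericParams = field(default_factory=AtmosphericParams)
    optics: OpticalProperties = field(default_factory=OpticalProperties)

    def __post_init__(self) -> None:
        if self.beam_spacing <= 0 or self.mesh_spacing <= 0:
            raise ValueError("spacings must be positive")
        if self.source_height <= 0:
            raise ValueError("source_height must be positive")
        if not self.days or not self.hours:
            raise ValueError("schedule must be nonempty")

    @property
    def resolution(self) -> MeshResolution:
        return MeshResolution(target_vertex_spacing=self.mesh_spacing)

    def to_dict(self) -> dict:
        a, o = self.atmosphere, self.optics
        return {
            "latitude": self.latitude, "longitude": self.longitude,
            "days": list(self.days), "hours": list(self.hours),
            "beam_spacing": self.beam_spacing,
            "source_height": self.source_height,
            "mesh_spacing": self.mesh_spacing, "seed": self.seed,
            "ozone_cm": a.ozone_cm, "water_cm": a.water_cm,
            "visibility_km": a.visibility_km,
            "ground_albedo": a.ground_albedo,
            "omega_o": a.single_scattering_albedo,
            "forward_fraction": a.forward_scatter_fraction,
            "urban_factor": a.aerosol_urban_factor,
            "solar_constant": a.solar_constant,
            "rho_conifer": o.reflectance[CONIFER],
            "rho_broadleaf": o.reflectance[BROADLEAF],
            "tau_conifer": o.transmittance[CONIFER],
            "tau_broadleaf": o.transmittance[BROADLEAF],
            "refraction_index": o.refraction_index,
            "attribute_to": o.attribute_to,
        }


def _from_flat(d: dict) -> RunConfig:
    atmos = AtmosphericParams(
        solar_constant=d.get("solar_constant", 1367.0),
        ozone_cm=d.get("ozone_cm", AtmosphericParams.ozone_cm),
        water_cm=d.get("water_cm", AtmosphericParams.water_cm),
        visibility_km=d.get("visibility_km", AtmosphericParams.visibility_km),
        ground_albedo=d.get("ground_albedo", AtmosphericParams.ground_albedo),
        single_scattering_albedo=d.get("omega_o", 0.9),
        forward_scatter_fraction=d.get("forward_fraction", 0.84),
        aerosol_urban_factor=d.get("urban_factor", 0.79),
    )
    optics = OpticalProperties(
        reflectance={CONIFER: d.get("rho_conifer", 0.25),
                     BROADLEAF: d.get("rho_broadleaf", 0.17)},
        transmittance={CONIFER: d.get("tau_conifer", 0.15),
                       BROADLEAF: d.get("tau_broadleaf", 0.20)},
        refraction_index=d.get("refraction_index", 0.5),
        attribute_to=d.get("attribute_to", "parent"),
    )
    return RunConfig(
        latitude=d.get("latitude", 32.076),
        longitude=d.get("longitude", 118.812),
        days=list(d.get("days", [166])),
        hours=list(d.get("hours", [12.0])),
        beam_spacing=d.get("beam_spacing", 0.2),
        source_height=d.get("source_height", 100.0),
        mesh_spacing=d.get("mesh_spacing", 1.36),
        seed=int(d.get("seed", 0)),
        atmosphere=atmos, optics=optics,
    )


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a flat YAML config; keyword overrides win over file values."""
    d: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must hold a flat key/value mapping")
        d.update(loaded)
    d.update({k: v for k, v in overrides.items() if v is not None})
    return _from_flat(d)
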