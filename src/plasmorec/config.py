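"""Runtime configuration for the sensor pipeline.

All physically meaningful defaults live here so that every entry point (the
library, the CLI and the validation suite) sees the same study conditions.
A TOML file with the documented dotted keys (``gold.eps_inf``,
``fiber.core_radius_um``, ``ray.length_mm``, ...) overrides individual
fields; everything else keeps its default.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from typing import Optional

from .materials import (
    DrudeLorentzParams,
    GOLD_ELECTRON_DENSITY,
    VIAL_GOLD,
)

__all__ = ["ChargeConfig", "FiberConfig", "RayConfig", "MeshConfig", "SolverConfig", "SensorConfig", "load_config"]


@dataclass(frozen=True)
class ChargeConfig:
    """Electrode double-layer model mapping potential to excess charge.

    The double-layer capacitance and charged-layer thickness calibrate the
    voltage response; both sit inside documented electrode physics
    (C in 5-50 uF/cm^2, d of order the electrolyte screening length).
    Defaults: the canonical 20 uF/cm^2 double layer and d = 0.8 nm, the
    Debye length of physiological (150 mM) saline.

    ``localization`` selects how the excess electron density enters the
    film's dispersion:

    ``filmwide`` (default)
        The density change evaluated in the double layer
        (``dN = C V / (e d)``) modifies the plasma frequency of the whole
        film — the uniform-field treatment under which the sensor was
        conceived.
    ``surface_layer``
        Charge-conserving: the same ``dN`` is confined to an explicit
        sub-layer of thickness ``d`` at the gold/buffer interface.
    ``uniform_film``
        Charge-conserving: the excess charge is spread through the whole
        film (``dN = C V / (e t)``).

    ``sign_convention=-1`` means a positive gold potential depletes
    electrons.
    """

    capacitance_per_area: float = 0.2      # F/m^2 (20 uF/cm^2)
    layer_thickness: float = 0.8e-9        # m (Debye length, 1X PBS)
    sign_convention: int = -1
    N: float = GOLD_ELECTRON_DENSITY
    localization: str = "filmwide"


@dataclass(frozen=True)
class FiberConfig:
    design: str = "half_clad_removed"      # full_clad_removed | half_clad_removed | half_core_removed
    core_radius: float = 5e-6              # m
    gold_thickness: float = 50e-9          # m
    cladding_thickness: float = 2.5e-6     # m
    na: float = 0.37


@dataclass(frozen=True)
class RayConfig:
    """Geometric-optics transmission model of the multimode sensing region.

    The default sensing length is the neuron-contact scale (50 um): with a
    10 um core a guided ray then strikes the gold about once, which keeps
    the plasmon dip from saturating.  ``mode_power`` launch weights rays by
    sin(theta)cos(theta) (diffuse-source meridional distribution),
    suppressing the near-grazing rays a uniform-angle launch over-counts.
    """

    sensing_length: float = 50e-6          # m
    n_angles: int = 64
    polarization: str = "unpolarized"      # or "p"
    angular_distribution: str = "mode_power"  # or "uniform_angle"
    theta_max_deg: float = 89.5


@dataclass(frozen=True)
class MeshConfig:
    min_cells_in_film: int = 5
    window_factor: float = 4.0             # window side = factor * core radius
    points_per_wavelength: float = 4.0     # coarse-grid sampling of lambda/n
    volume_averaging: bool = True


@dataclass(frozen=True)
class SolverConfig:
    n_modes: int = 30
    tol: float = 0.0                       # ARPACK default when 0
    n_eff_guess: Optional[complex] = None
    max_grid: int = 400                    # refuse meshes beyond max_grid^2 cells


@dataclass(frozen=True)
class SensorConfig:
    gold: DrudeLorentzParams = VIAL_GOLD
    charge: ChargeConfig = field(default_factory=ChargeConfig)
    fiber: FiberConfig = field(default_factory=FiberConfig)
    ray: RayConfig = field(default_factory=RayConfig)
    mesh: MeshConfig = field(default_factory=MeshConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    buffer_n: float = 1.334
    coupling_factor: float = 1.0           # neuron-to-electrode potential transfer


def _replace_known(obj, table: dict, mapping: dict):
    kwargs = {}
    for key, attr in mapping.items():
        if key in table:
            kwargs[attr] = table[key]
    return replace(obj, **kwargs) if kwargs else obj


def load_config(path: Optional[str] = None, base: Optional[SensorConfig] = None) -> SensorConfig:
    """Load a :class:`SensorConfig`, overriding defaults from a TOML file."""
    cfg = base or SensorConfig()
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)

    if "gold" in doc:
        g = doc["gold"]
        gold = DrudeLorentzParams(
            eps_inf=g.get("eps_inf", cfg.gold.eps_inf),
            omega_D=g.get("omega_D", cfg.gold.omega_D),
            gamma_D=g.get("gamma_D", cfg.gold.gamma_D),
            omega_L=g.get("omega_L", cfg.gold.omega_L),
            gamma_L=g.get("gamma_L", cfg.gold.gamma_L),
            delta_eps=g.get("delta_eps", cfg.gold.delta_eps),
        )
        cfg = replace(cfg, gold=gold)
    if "charge" in doc:
        cfg = replace(cfg, charge=_replace_known(cfg.charge, doc["charge"], {
            "capacitance_per_area": "capacitance_per_area",
            "layer_thickness": "layer_thickness",
            "sign_convention": "sign_convention",
            "N": "N",
            "localization": "localization",
        }))
    if "fiber" in doc:
        f = doc["fiber"]
        fiber = cfg.fiber
        if "design" in f:
            fiber = replace(fiber, design=f["design"])
        if "core_radius_um" in f:
            fiber = replace(fiber, core_radius=f["core_radius_um"] * 1e-6)
        if "gold_nm" in f:
            fiber = replace(fiber, gold_thickness=f["gold_nm"] * 1e-9)
        if "cladding_um" in f:
            fiber = replace(fiber, cladding_thickness=f["cladding_um"] * 1e-6)
        if "na" in f:
            fiber = replace(fiber, na=f["na"])
        cfg = replace(cfg, fiber=fiber)
    if "ray" in doc:
        r = doc["ray"]
        ray = cfg.ray
        if "length_mm" in r:
            ray = replace(ray, sensing_length=r["length_mm"] * 1e-3)
        ray = _replace_known(ray, r, {
            "n_angles": "n_angles",
            "polarization": "polarization",
            "angular_distribution": "angular_distribution",
            "theta_max_deg": "theta_max_deg",
        })
        cfg = replace(cfg, ray=ray)
    if "mesh" in doc:
        cfg = replace(cfg, mesh=_replace_known(cfg.mesh, doc["mesh"], {
            "min_cells_in_film": "min_cells_in_film",
            "window_factor": "window_factor",
            "points_per_wavelength": "points_per_wavelength",
            "volume_averaging": "volume_averaging",
        }))
    if "solver" in doc:
        cfg = replace(cfg, solver=_replace_known(cfg.solver, doc["solver"], {
            "n_modes": "n_modes",
            "tol": "tol",
            "guess": "n_eff_guess",
            "max_grid": "max_grid",
        }))
    if "buffer" in doc and "n" in doc["buffer"]:
        cfg = replace(cfg, buffer_n=doc["buffer"]["n"])
    if "coupling_factor" in doc:
        cfg = replace(cfg, coupling_factor=doc["coupling_factor"])
    return cfg
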