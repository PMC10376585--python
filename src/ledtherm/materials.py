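"""Layered tissue geometry and material properties.

The skin is modelled as a stack of horizontal layers (epidermis, dermis,
subcutaneous fat), each with its own thermal properties (density rho,
specific heat c_p, conductivity k), Pennes blood-perfusion rate omega_b, and
near-infrared optical coefficients (absorption mu_a and reduced scattering
mu_s' at 850 nm).  A homogeneous agar phantom used for bench validation is
expressed as a single-layer stack with perfusion and metabolism switched off.

Conventions: z = 0 at the top (air-facing) surface, increasing into the
tissue.  All quantities are SI internally; optical coefficients are stored
in 1/m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

# Stefan-Boltzmann constant, W/m^2/K^4
SIGMA_SB = 5.670374419e-8

#: Aliases accepted in override keys / config files for MaterialProps fields.
_FIELD_ALIASES = {
    "density": "density",
    "rho": "density",
    "specific_heat": "specific_heat",
    "cp": "specific_heat",
    "c_p": "specific_heat",
    "conductivity": "conductivity",
    "k": "conductivity",
    "perfusion_rate": "perfusion_rate",
    "omega_b": "perfusion_rate",
    "w_b": "perfusion_rate",
    "absorption_coeff": "absorption_coeff",
    "mu_a": "absorption_coeff",
    "reduced_scattering_coeff": "reduced_scattering_coeff",
    "mu_s_prime": "reduced_scattering_coeff",
    "musp": "reduced_scattering_coeff",
}


@dataclass(frozen=True)
class MaterialProps:
    """Thermal + optical properties of one homogeneous material.

    Units: density kg/m^3, specific_heat J/kg/K, conductivity W/m/K,
    perfusion_rate 1/s, absorption_coeff and reduced_scattering_coeff 1/m.
    """

    density: float
    specific_heat: float
    conductivity: float
    perfusion_rate: float = 0.0
    absorption_coeff: float = 0.0
    reduced_scattering_coeff: float = 0.0

    def __post_init__(self):
        for name in ("density", "specific_heat", "conductivity"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"MaterialProps.{name} must be strictly positive")
        for name in ("perfusion_rate", "absorption_coeff", "reduced_scattering_coeff"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"MaterialProps.{name} must be non-negative")


@dataclass(frozen=True)
class LayerSpec:
    """One horizontal layer: a name, a thickness (m) and its material."""

    name: str
    thickness: float
    props: MaterialProps

    def __post_init__(self):
        if not self.thickness > 0:
            raise ConfigurationError(f"layer '{self.name}': thickness must be positive")


@dataclass(frozen=True)
class TissueStack:
    """Ordered layers (top first) plus the global Pennes blood/metabolic constants.

    arterial_temp is in kelvin; metabolic_heat in W/m^3 applies to every
    layer (zero for phantoms).
    """

    layers: tuple[LayerSpec, ...]
    blood_density: float = 1050.0
    blood_specific_heat: float = 3617.0
    arterial_temp: float = 310.0
    metabolic_heat: float = 368.0

    def __post_init__(self):
        if len(self.layers) == 0:
            raise ConfigurationError("TissueStack needs at least one layer")
        if not (self.blood_density > 0 and self.blood_specific_heat > 0):
            raise ConfigurationError("blood constants must be positive")
        if not (273.0 <= self.arterial_temp <= 320.0):
            raise ConfigurationError("arterial_temp outside plausible 273-320 K range")

    @property
    def total_depth(self) -> float:
        return float(sum(l.thickness for l in self.layers))

    @property
    def interfaces(self) -> np.ndarray:
        """Cumulative depths of layer bottoms, measured from the surface (m)."""
        return np.cumsum([l.thickness for l in self.layers])

    def layer_at(self, z: float) -> LayerSpec:
        """Layer containing depth ``z`` (m, 0 <= z <= total depth)."""
        if z < 0 or z > self.total_depth:
            raise ConfigurationError(f"depth {z} m outside stack (0..{self.total_depth} m)")
        for bottom, layer in zip(self.interfaces, self.layers):
            if z < bottom:
                return layer
        return self.layers[-1]

    def layer_named(self, name: str) -> LayerSpec:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise ConfigurationError(f"no layer named '{name}'")


# Table of default skin-layer properties (epidermis / dermis / subcutaneous
# fat) at 850 nm.  Optical coefficients converted from 1/cm to 1/m.
_SKIN_DEFAULTS = {
    "epidermis": dict(
        thickness=0.1e-3,
        density=1200.0, specific_heat=3950.0, conductivity=0.24,
        perfusion_rate=0.0, absorption_coeff=90.0, reduced_scattering_coeff=3000.0,
    ),
    "dermis": dict(
        thickness=1.9e-3,
        density=1090.0, specific_heat=3350.0, conductivity=0.42,
        perfusion_rate=0.002, absorption_coeff=95.0, reduced_scattering_coeff=2000.0,
    ),
    "subcutaneous_fat": dict(
        thickness=8.0e-3,
        density=1210.0, specific_heat=2240.0, conductivity=0.194,
        perfusion_rate=0.002, absorption_coeff=100.0, reduced_scattering_coeff=1800.0,
    ),
}

#: Agar phantom properties (2.6 % w/v agar gel at 850 nm).
_AGAR = dict(
    density=1050.0, specific_heat=4219.0, conductivity=0.66,
    perfusion_rate=0.0, absorption_coeff=40.0, reduced_scattering_coeff=530.0,
)


def build_skin_model(overrides: dict | None = None) -> TissueStack:
    """Three-layer skin stack with the default property table.

    ``overrides`` maps dotted keys to replacement values, e.g.
    ``{"dermis.k": 0.5, "epidermis.thickness": 8e-5, "metabolic_heat": 0}``.
    Field names accept the short aliases rho/cp/k/omega_b/mu_a/mu_s_prime.

    Layer thicknesses (epidermis 0.1 mm, dermis to a 2.0 mm depth, fat below)
    are declared modelling assumptions, not literature constants, and are
    echoed to the log so every run records them.
    """
    table = {name: dict(vals) for name, vals in _SKIN_DEFAULTS.items()}
    stack_kwargs = dict(
        blood_density=1050.0, blood_specific_heat=3617.0,
        arterial_temp=310.0, metabolic_heat=368.0,
    )
    for key, value in (overrides or {}).items():
        if "." in key:
            layer_name, _, fld = key.partition(".")
            if layer_name not in table:
                raise ConfigurationError(f"unknown layer '{layer_name}' in override '{key}'")
            if fld == "thickness":
                table[layer_name]["thickness"] = float(value)
            elif fld in _FIELD_ALIASES:
                table[layer_name][_FIELD_ALIASES[fld]] = float(value)
            else:
                raise ConfigurationError(f"unknown property '{fld}' in override '{key}'")
        elif key in stack_kwargs:
            stack_kwargs[key] = float(value)
        else:
            raise ConfigurationError(f"unknown override key '{key}'")

    layers = tuple(
        LayerSpec(name, vals.pop("thickness"), MaterialProps(**vals))
        for name, vals in ((n, dict(v)) for n, v in table.items())
    )
    stack = TissueStack(layers, **stack_kwargs)
    logger.info(
        "skin model: layer thicknesses %s (assumed, configurable); "
        "interfaces at %s mm depth",
        {l.name: f"{l.thickness*1e3:g} mm" for l in stack.layers},
        np.round(stack.interfaces[:-1] * 1e3, 3).tolist(),
    )
    return stack


def build_phantom_model(height: float = 0.009, config: dict | None = None) -> TissueStack:
    """Homogeneous agar-phantom stack of the given height (m).

    Perfusion and metabolic heat are zero: the phantom has no blood supply,
    so the Pennes sink/source terms are switched off.
    """
    if not height > 0:
        raise ConfigurationError("phantom height must be positive")
    props = dict(_AGAR)
    for key, value in (config or {}).items():
        if key in _FIELD_ALIASES:
            props[_FIELD_ALIASES[key]] = float(value)
        else:
            raise ConfigurationError(f"unknown phantom property '{key}'")
    layer = LayerSpec("agar", height, MaterialProps(**props))
    return TissueStack((layer,), metabolic_heat=0.0)


@dataclass
class PropertyArrays:
    """Per-voxel material properties rasterized on a grid.

    Because layers are horizontal slabs, every property varies only with z;
    arrays are stored as 1-D profiles over the nz cell centres and broadcast
    where a full 3-D view is needed.
    """

    density: np.ndarray
    specific_heat: np.ndarray
    conductivity: np.ndarray
    perfusion_rate: np.ndarray
    absorption_coeff: np.ndarray
    reduced_scattering_coeff: np.ndarray
    layer_index: np.ndarray
    stack: TissueStack = field(repr=False, default=None)

    @property
    def volumetric_heat_capacity(self) -> np.ndarray:
        """rho * c_p per cell, J/m^3/K."""
        return self.density * self.specific_heat

    @property
    def perfusion_coeff(self) -> np.ndarray:
        """rho_b * c_b * omega_b per cell, W/m^3/K (the Pennes sink coefficient)."""
        return self.stack.blood_density * self.stack.blood_specific_heat * self.perfusion_rate


def rasterize_properties(stack: TissueStack, grid) -> PropertyArrays:
    """Assign each grid cell the properties of the layer containing its centre."""
    z = grid.z_centers
    if grid.z_edges[-1] > stack.total_depth + 1e-12:
        raise ConfigurationError(
            f"grid depth {grid.z_edges[-1]:.4g} m exceeds stack depth {stack.total_depth:.4g} m"
        )
    idx = np.searchsorted(stack.interfaces, z, side="right")
    idx = np.minimum(idx, len(stack.layers) - 1)

    def profile(fld):
        vals = np.array([getattr(l.props, fld) for l in stack.layers])
        return vals[idx]

    return PropertyArrays(
        density=profile("density"),
        specific_heat=profile("specific_heat"),
        conductivity=profile("conductivity"),
        perfusion_rate=profile("perfusion_rate"),
        absorption_coeff=profile("absorption_coeff"),
        reduced_scattering_coeff=profile("reduced_scattering_coeff"),
        layer_index=idx,
        stack=stack,
    )


# ---------------------------------------------------------------------------
# plain-text serialization (units explicit in field names)

def stack_to_dict(stack: TissueStack) -> dict:
    return {
        "blood_density_kg_per_m3": stack.blood_density,
        "blood_specific_heat_J_per_kgK": stack.blood_specific_heat,
        "arterial_temp_K": stack.arterial_temp,
        "metabolic_heat_W_per_m3": stack.metabolic_heat,
        "layers": [
            {
                "name": l.name,
                "thickness_mm": l.thickness * 1e3,
                "density_kg_per_m3": l.props.density,
                "cp_J_per_kgK": l.props.specific_heat,
                "k_W_per_mK": l.props.conductivity,
                "omega_b_per_s": l.props.perfusion_rate,
                "mu_a_per_m": l.props.absorption_coeff,
                "mu_s_prime_per_m": l.props.reduced_scattering_coeff,
            }
            for l in stack.layers
        ],
    }


def stack_from_dict(d: dict) -> TissueStack:
    layers = tuple(
        LayerSpec(
            ld["name"],
            ld["thickness_mm"] * 1e-3,
            MaterialProps(
                density=ld["density_kg_per_m3"],
                specific_heat=ld["cp_J_per_kgK"],
                conductivity=ld["k_W_per_mK"],
                perfusion_rate=ld.get("omega_b_per_s", 0.0),
                absorption_coeff=ld.get("mu_a_per_m", 0.0),
                reduced_scattering_coeff=ld.get("mu_s_prime_per_m", 0.0),
            ),
        )
        for ld in d["layers"]
    )
    return TissueStack(
        layers,
        blood_density=d.get("blood_density_kg_per_m3", 1050.0),
        blood_specific_heat=d.get("blood_specific_heat_J_per_kgK", 3617.0),
        arterial_temp=d.get("arterial_temp_K", 310.0),
        metabolic_heat=d.get("metabolic_heat_W_per_m3", 368.0),
    )


def save_stack(stack: TissueStack, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(stack_to_dict(stack), fh, sort_keys=False)


def load_stack(path) -> TissueStack:
    with open(path) as fh:
        return stack_from_dict(yaml.safe_load(fh))
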