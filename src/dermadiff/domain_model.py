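"""Typed description of drugs, skin layers, patch reservoirs and scenarios.

The model treats transdermal delivery as transient Fickian diffusion through
a stack of homogeneous materials (patch reservoir, stratum corneum, viable
epidermis). Each material ``i`` carries a diffusion tensor ``D_i`` and a
dimensionless drug capacity ``K_i`` relating concentration to the continuous
drug potential, ``c_i = K_i * psi``. Ratios of capacities reproduce the
equilibrium partition coefficients that cause concentration jumps at layer
interfaces; the patch capacity is fixed at 1 by convention, which anchors
the scale of the potential variable.

All constants used by the named presets are the literature values for
fentanyl through human epidermis; geometry defaults describe a 40 mm square
reservoir (16 cm² active area) holding 6.4 mg of drug.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "DrugSpec",
    "MaterialProps",
    "LayerStack",
    "ReservoirSpec",
    "PartitionCoefficient",
    "MeshControls",
    "ScenarioConfig",
    "FENTANYL",
    "BODY_SITES",
    "preset",
    "preset_names",
    "initial_reservoir_mass",
    "sc_thickness_from_age",
    "partition_coefficient",
    "series_resistance_flux",
]

MATERIAL_LABELS = ("patch", "stratum_corneum", "viable_epidermis", "lumped_epidermis")


@dataclass(frozen=True)
class DrugSpec:
    """A drug molecule. ``log_kow`` is informational only and never enters
    any computation; transport is fully described by the per-layer D and K."""

    name: str
    molecular_weight: float  # Da
    log_kow: Optional[float] = None

    def __post_init__(self):
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")


FENTANYL = DrugSpec("fentanyl", 337.0, log_kow=3.5)


@dataclass(frozen=True)
class MaterialProps:
    """Transport properties of one material layer.

    Parameters
    ----------
    label : one of {patch, stratum_corneum, viable_epidermis, lumped_epidermis}
    thickness : m
    D_z : longitudinal (through-skin) diffusivity, m² s⁻¹
    D_xy : transverse diffusivity, m² s⁻¹ (equal to D_z for isotropic layers)
    K : dimensionless drug capacity, c = K * psi
    """

    label: str
    thickness: float
    D_z: float
    D_xy: float
    K: float

    def __post_init__(self):
        if self.label not in MATERIAL_LABELS:
            raise ValueError(f"unknown material label {self.label!r}")
        for name in ("thickness", "D_z", "D_xy", "K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.label}: {name} must be strictly positive")
        if self.label == "patch" and self.K != 1.0:
            raise ValueError("patch capacity is fixed at 1 by convention")

    @property
    def is_isotropic(self) -> bool:
        return self.D_z == self.D_xy

    @property
    def resistance_z(self) -> float:
        """Series diffusion resistance per unit area, d/(D_z*K) [s m⁻¹]."""
        return self.thickness / (self.D_z * self.K)


def isotropic(label: str, thickness: float, D: float, K: float) -> MaterialProps:
    return MaterialProps(label, thickness, D, D, K)


@dataclass(frozen=True)
class PartitionCoefficient:
    """Equilibrium concentration ratio across an interface, K_A/B = K_A / K_B."""

    numerator: str
    denominator: str
    value: float


def partition_coefficient(a: MaterialProps, b: MaterialProps) -> PartitionCoefficient:
    return PartitionCoefficient(a.label, b.label, a.K / b.K)


@dataclass(frozen=True)
class LayerStack:
    """Ordered layers from the top of the patch (z=0) down to the
    epidermis–dermis interface. At most one reservoir ("patch") layer, and
    it must sit on top; it is absent under the infinite-reservoir regime."""

    layers: tuple

    def __post_init__(self):
        if not self.layers:
            raise ValueError("stack must contain at least one layer")
        patches = [i for i, m in enumerate(self.layers) if m.label == "patch"]
        if len(patches) > 1 or (patches and patches[0] != 0):
            raise ValueError("exactly one reservoir layer allowed, at the top")

    @property
    def has_reservoir(self) -> bool:
        return self.layers[0].label == "patch"

    @property
    def skin_layers(self) -> tuple:
        return self.layers[1:] if self.has_reservoir else self.layers

    @property
    def total_thickness(self) -> float:
        return sum(m.thickness for m in self.layers)

    @property
    def skin_thickness(self) -> float:
        return sum(m.thickness for m in self.skin_layers)

    def get(self, label: str) -> MaterialProps:
        for m in self.layers:
            if m.label == label:
                return m
        raise KeyError(label)

    def without_reservoir(self) -> "LayerStack":
        return LayerStack(self.skin_layers)


@dataclass(frozen=True)
class ReservoirSpec:
    """Drug reservoir geometry and loading.

    ``finite`` reservoirs are meshed as a depletable layer; ``infinite``
    reservoirs are replaced by a constant-potential (Dirichlet) surrogate at
    the patch–skin interface and hold no defined mass.
    """

    width: float  # L_pt, square side, m
    thickness: float  # d_pt, m
    initial_concentration: float  # c_ini, kg m⁻³
    regime: str = "finite"

    def __post_init__(self):
        if self.regime not in ("finite", "infinite"):
            raise ValueError("regime must be 'finite' or 'infinite'")
        if self.width <= 0 or self.thickness <= 0:
            raise ValueError("reservoir dimensions must be positive")
        if self.initial_concentration < 0:
            raise ValueError("initial concentration must be non-negative")

    @property
    def area(self) -> float:
        """Active contact area L_pt² [m²], full square (not quarter)."""
        return self.width**2


def initial_reservoir_mass(spec: ReservoirSpec) -> float:
    """Initial drug load of a finite reservoir, in mg.

    m = c_ini * L_pt² * d_pt. Undefined for the infinite regime.
    """
    if spec.regime != "finite":
        raise ValueError("initial mass is undefined for an infinite reservoir")
    return spec.initial_concentration * spec.area * spec.thickness * 1e6


AGE_RANGE = (18.0, 70.0)


def sc_thickness_from_age(age: float) -> float:
    """Dorsal-forearm stratum corneum thickness [m] as a linear function of
    age in years: d_sc = (0.125*A + 11.8) µm.

    The underlying cohort spans 18–70 years; evaluation outside that range
    is allowed but warns.
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    if not (AGE_RANGE[0] <= age <= AGE_RANGE[1]) and age != 0:
        warnings.warn(
            f"age {age} outside the 18-70 y calibration range of the "
            "thickness correlation",
            stacklevel=2,
        )
    return (0.125 * age + 11.8) * 1e-6


@dataclass(frozen=True)
class MeshControls:
    """Spatial discretization controls.

    ``cells_per_layer`` is the base cell count of each meshed layer before
    refinement; ``refinement`` doubles counts per level (used for Richardson
    studies). ``grading_ratio`` is the geometric growth factor away from
    material interfaces (1D) and away from the footprint edge (multi-D).
    """

    cells_per_layer: int = 40
    refinement: int = 0
    grading_ratio: float = 1.2

    def __post_init__(self):
        if self.cells_per_layer < 2:
            raise ValueError("need at least 2 cells per layer")
        if self.grading_ratio < 1.0:
            raise ValueError("grading ratio must be >= 1")


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one simulation case: the single entry point
    for every study configuration."""

    stack: LayerStack
    reservoir: ReservoirSpec
    drug: DrugSpec = FENTANYL
    dimensionality: str = "1D"  # "1D" or "multi_D"
    lateral_margin: Optional[float] = None  # m; default 20*(skin thickness)
    removal_time_h: Optional[float] = None
    horizon_h: float = 240.0
    max_time_step_s: float = 600.0
    mesh: MeshControls = field(default_factory=MeshControls)
    name: str = "custom"

    def __post_init__(self):
        if self.dimensionality not in ("1D", "multi_D"):
            raise ValueError("dimensionality must be '1D' or 'multi_D'")
        if self.horizon_h <= 0 or self.max_time_step_s <= 0:
            raise ValueError("horizon and max time step must be positive")
        if self.removal_time_h is not None:
            if self.reservoir.regime == "infinite":
                raise ValueError("patch removal is undefined for an infinite reservoir")
            if not 0 < self.removal_time_h < self.horizon_h:
                raise ValueError("removal time must lie inside the horizon")
        if self.reservoir.regime == "finite" and not self.stack.has_reservoir:
            raise ValueError("finite regime requires a reservoir layer in the stack")
        if self.reservoir.regime == "infinite" and self.stack.has_reservoir:
            raise ValueError("infinite regime replaces the reservoir layer by a boundary condition")

    @property
    def margin(self) -> float:
        """Lateral skin extension beyond the reservoir footprint [m]."""
        if self.lateral_margin is not None:
            return self.lateral_margin
        return 20.0 * self.stack.skin_thickness

    @property
    def surface_potential(self) -> float:
        """Potential at the top of the stack: c_ini / K_pt (K_pt = 1)."""
        return self.reservoir.initial_concentration / 1.0


# ---------------------------------------------------------------------------
# Preset catalogue
# ---------------------------------------------------------------------------

# Base-case transport constants (parametric study).
_D_PT = 1.0e-13
_D_SC_Z = 7.2e-15
_D_SC_XY = 1.05e-12
_D_VEP = 2.0e-11
_K_SC = 0.14
_K_VEP = 0.00084  # = 0.14 * 0.006
_D_SC_BASE = 15e-6
_D_VEP_BASE = 70e-6

_L_PT = 40e-3
_D_PATCH = 50e-6
_C_INI = 80.0

#: mean (sd) sublayer thicknesses [m] by anatomical site
BODY_SITES = {
    "forearm_dorsal": {"d_sc": (18.3e-6, 4.9e-6), "d_vep": (56.6e-6, 11.5e-6)},
    "shoulder": {"d_sc": (11.0e-6, 2.2e-6), "d_vep": (70.3e-6, 13.6e-6)},
    "buttock": {"d_sc": (14.9e-6, 3.4e-6), "d_vep": (81.5e-6, 15.7e-6)},
    "all_sites": {"d_sc": (14.8e-6, 4.8e-6), "d_vep": (69.9e-6, 17.0e-6)},
}

_QUANTILES = {"mean": 0.0, "minus2sd": -2.0, "plus2sd": 2.0}


def _patch_layer(thickness=_D_PATCH) -> MaterialProps:
    return isotropic("patch", thickness, _D_PT, 1.0)


def _sc_layer(thickness=_D_SC_BASE) -> MaterialProps:
    return MaterialProps("stratum_corneum", thickness, _D_SC_Z, _D_SC_XY, _K_SC)


def _vep_layer(thickness=_D_VEP_BASE) -> MaterialProps:
    return isotropic("viable_epidermis", thickness, _D_VEP, _K_VEP)


def _finite_config(d_sc, d_vep, name, **kw) -> ScenarioConfig:
    stack = LayerStack((_patch_layer(), _sc_layer(d_sc), _vep_layer(d_vep)))
    res = ReservoirSpec(_L_PT, _D_PATCH, _C_INI, "finite")
    return ScenarioConfig(stack=stack, reservoir=res, name=name, **kw)


def preset_names():
    return [
        "base_case",
        "validation_60",
        "validation_80",
        "infinite",
        "removal_72h",
        "body_site",
        "age",
        "reservoir_sweep",
    ]


def preset(
    name: str,
    *,
    site: str = "forearm_dorsal",
    quantile: str = "mean",
    years: float = 18.0,
    L_pt: float = _L_PT,
    regime: str = "infinite",
) -> ScenarioConfig:
    """Return a fully populated :class:`ScenarioConfig` for a named study case.

    Recognized names: ``base_case``, ``validation_60``, ``validation_80``,
    ``infinite``, ``removal_72h``, ``body_site`` (with ``site`` and
    ``quantile``), ``age`` (with ``years``), ``reservoir_sweep`` (with
    ``L_pt`` and ``regime``).
    """
    if name == "base_case":
        return _finite_config(_D_SC_BASE, _D_VEP_BASE, "base_case")

    if name in ("validation_60", "validation_80"):
        c_ini = 60.0 if name == "validation_60" else 80.0
        stack = LayerStack(
            (
                _patch_layer(50.8e-6),
                isotropic("lumped_epidermis", 50.8e-6, 3.0e-14, 0.14),
            )
        )
        res = ReservoirSpec(_L_PT, 50.8e-6, c_ini, "finite")
        return ScenarioConfig(stack=stack, reservoir=res, name=name)

    if name == "infinite":
        stack = LayerStack((_sc_layer(), _vep_layer()))
        res = ReservoirSpec(_L_PT, _D_PATCH, _C_INI, "infinite")
        return ScenarioConfig(stack=stack, reservoir=res, name=name)

    if name == "removal_72h":
        return _finite_config(
            _D_SC_BASE, _D_VEP_BASE, "removal_72h", removal_time_h=72.0
        )

    if name == "body_site":
        if site not in BODY_SITES:
            raise ValueError(f"unknown body site {site!r}")
        if quantile not in _QUANTILES:
            raise ValueError(f"unknown quantile {quantile!r}")
        z = _QUANTILES[quantile]
        d_sc = BODY_SITES[site]["d_sc"][0] + z * BODY_SITES[site]["d_sc"][1]
        d_vep = BODY_SITES[site]["d_vep"][0] + z * BODY_SITES[site]["d_vep"][1]
        return _finite_config(d_sc, d_vep, f"body_site_{site}_{quantile}")

    if name == "age":
        d_sc = sc_thickness_from_age(years)
        return _finite_config(d_sc, _D_VEP_BASE, f"age_{years:g}y")

    if name == "reservoir_sweep":
        if regime == "infinite":
            stack = LayerStack((_sc_layer(), _vep_layer()))
            res = ReservoirSpec(L_pt, _D_PATCH, _C_INI, "infinite")
        else:
            stack = LayerStack((_patch_layer(), _sc_layer(), _vep_layer()))
            res = ReservoirSpec(L_pt, _D_PATCH, _C_INI, "finite")
        return ScenarioConfig(
            stack=stack,
            reservoir=res,
            dimensionality="multi_D",
            lateral_margin=1.7e-3,
            name=f"reservoir_{L_pt*1e6:g}um_{regime}",
        )

    raise ValueError(f"unknown preset {name!r}")


def series_resistance_flux(stack: LayerStack, psi_top: float) -> float:
    """Steady unidirectional flux [kg m⁻² s⁻¹] through the skin layers for a
    fixed surface potential: psi_top / sum(d_i / (D_z,i * K_i)).

    Closed form used as the independent cross-check for the steady solvers.
    """
    R = sum(m.resistance_z for m in stack.skin_layers)
    return psi_top / R


def with_replaced_layer(config: ScenarioConfig, label: str, **changes) -> ScenarioConfig:
    """Return a config whose layer ``label`` has fields replaced (re-meshed
    geometry; used by the sensitivity scan and thickness studies)."""
    layers = tuple(
        replace(m, **changes) if m.label == label else m for m in config.stack.layers
    )
    return replace(config, stack=LayerStack(layers))
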