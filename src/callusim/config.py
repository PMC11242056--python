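"""Configuration objects for fracture-healing scenarios.

All geometric quantities are in millimetres, forces in newtons, moduli in
megapascals, rates in day^-1 and strains dimensionless.  A scenario is fully
described by three blocks -- the fracture/fixation geometry
(:class:`ScenarioConfig`), the tissue material constants
(:class:`MaterialTable`) and the mechano-regulation rule constants
(:class:`FuzzyRuleSet`) -- which round-trip through a YAML file with the same
three top-level keys plus an ``output`` block.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "ConfigurationError",
    "ScenarioConfig",
    "MaterialTable",
    "FuzzyRuleSet",
    "OutputOptions",
    "SimulationConfig",
    "TISSUES",
    "bundled_config_path",
    "load_bundled_config",
    "list_bundled_configs",
]

#: Tissue phases tracked per cell, in canonical order.
TISSUES = ("lamellar", "woven", "cartilage", "fibrous")


class ConfigurationError(ValueError):
    """Raised when a configuration violates a geometric or physical constraint."""


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ConfigurationError(message)


@dataclass
class ScenarioConfig:
    """Idealized fracture scenario: hollow diaphysis, intramedullary nail,
    fracture gap and periosteal callus (healing) domain.

    The z axis is the bone's longitudinal axis; +x is anterior and +y medial
    (right-side convention).  Fragment 0 is proximal (loaded end), fragment 1
    distal (fixed end), fragment 2 an optional interposed wedge.
    """

    bone_type: str = "tibia"
    outer_diameter: float = 26.0
    cortical_thickness: float = 5.0
    canal_diameter: float = 12.0
    nail_diameter: float = 10.0
    segment_length: float = 48.0
    gap_width: float = 2.0
    fracture_kind: str = "transverse"
    #: tilt of the fracture plane from transverse, degrees (oblique only)
    oblique_angle: float = 30.0
    #: azimuth of the tilt direction, degrees from +x (oblique only)
    oblique_azimuth: float = 0.0
    #: azimuthal extent of the interposed wedge fragment, degrees (wedge only)
    wedge_span: float = 120.0
    #: axial height of the interposed wedge fragment, mm (wedge only)
    wedge_height: float = 9.0
    #: azimuth of the wedge centre, degrees from +x; -90 = lateral (wedge only)
    wedge_center: float = -90.0
    #: outer diameter of the callus (healing) domain; default 1.4x outer_diameter
    callus_diameter: Optional[float] = None
    #: axial extent of the healing domain beyond the fracture zone;
    #: default max(1.5x gap_width, 2x voxel_size)
    axial_margin: Optional[float] = None
    voxel_size: float = 1.5
    body_weight: float = 750.0
    weight_bearing: float = 1.0
    days: int = 240
    #: reserved for optional initialisation noise; geometry is seed-independent
    seed: int = 0
    #: fragment id whose cells start avascular (models a devitalised fragment)
    devascularize_fragment: Optional[int] = None

    def __post_init__(self) -> None:
        _require(self.bone_type in ("tibia", "femur"),
                 f"bone_type must be 'tibia' or 'femur', got {self.bone_type!r}")
        _require(self.fracture_kind in ("transverse", "oblique", "wedge"),
                 f"fracture_kind must be transverse/oblique/wedge, got {self.fracture_kind!r}")
        _require(self.voxel_size > 0, "voxel_size > 0 is violated")
        _require(self.days >= 1, "days >= 1 is violated")
        _require(self.gap_width >= 0, "gap_width >= 0 is violated")
        _require(self.body_weight > 0, "body_weight > 0 is violated")
        _require(0.0 <= self.weight_bearing <= 1.0,
                 "weight_bearing in [0, 1] is violated")
        _require(self.nail_diameter <= self.canal_diameter,
                 "nail_diameter <= canal_diameter is violated")
        _require(self.canal_diameter < self.outer_diameter - 2 * self.cortical_thickness,
                 "canal_diameter < outer_diameter - 2*cortical_thickness is violated")
        if self.callus_diameter is None:
            self.callus_diameter = 1.4 * self.outer_diameter
        _require(self.callus_diameter >= self.outer_diameter,
                 "callus_diameter >= outer_diameter is violated")
        if self.axial_margin is None:
            self.axial_margin = max(1.5 * self.gap_width, 2 * self.voxel_size)
        _require(self.axial_margin >= 0, "axial_margin >= 0 is violated")
        if self.fracture_kind == "wedge":
            _require(0 < self.wedge_span < 360, "wedge_span in (0, 360) is violated")
            _require(self.wedge_height > 0, "wedge_height > 0 is violated")
        zone = self.fracture_zone_extent()
        _require(self.segment_length > zone + 2 * self.axial_margin + 2 * self.voxel_size,
                 "segment_length > fracture zone + margins is violated")

    def fracture_zone_extent(self) -> float:
        """Axial extent (mm) of the carved fracture zone."""
        if self.fracture_kind == "wedge":
            return self.wedge_height + 2 * self.gap_width
        if self.fracture_kind == "oblique":
            import math
            reach = self.outer_diameter * math.tan(math.radians(self.oblique_angle))
            return self.gap_width + reach
        return self.gap_width


@dataclass
class MaterialTable:
    """Isotropic linear-elastic constants per tissue phase and implant.

    Defaults follow the range commonly used in callus mechano-regulation
    models: mature (lamellar) bone 10 GPa, immature (woven) bone 4 GPa,
    fibrocartilage 10 MPa, fibrous connective tissue 3 MPa, titanium nail
    110 GPa.  ``e_interface`` is the modulus of the thin reamed canal layer
    between nail and endosteum; the nail is tied to the bone through it.
    """

    e_lamellar: float = 10000.0
    e_woven: float = 4000.0
    e_cartilage: float = 10.0
    e_fibrous: float = 3.0
    nu_lamellar: float = 0.3
    nu_woven: float = 0.3
    nu_cartilage: float = 0.3
    nu_fibrous: float = 0.3
    e_nail: float = 110000.0
    nu_nail: float = 0.3
    e_interface: float = 3000.0
    nu_interface: float = 0.3
    mixture_exponent: float = 1.0

    def __post_init__(self) -> None:
        for name in ("e_lamellar", "e_woven", "e_cartilage", "e_fibrous",
                     "e_nail", "e_interface"):
            _require(getattr(self, name) > 0, f"{name} > 0 is violated")
        for name in ("nu_lamellar", "nu_woven", "nu_cartilage", "nu_fibrous",
                     "nu_nail", "nu_interface"):
            nu = getattr(self, name)
            _require(0 < nu < 0.5, f"{name} in (0, 0.5) is violated")
        _require(self.mixture_exponent > 0, "mixture_exponent > 0 is violated")

    @property
    def tissue_moduli(self):
        return (self.e_lamellar, self.e_woven, self.e_cartilage, self.e_fibrous)

    @property
    def tissue_poisson(self):
        return (self.nu_lamellar, self.nu_woven, self.nu_cartilage, self.nu_fibrous)


@dataclass
class FuzzyRuleSet:
    """Breakpoints and daily rate constants of the mechano-regulation rules.

    Distortional (octahedral shear) strain is partitioned into five fuzzy
    categories -- understimulated / low / moderate / high / excessive -- by
    trapezoidal memberships whose transition bands are centred on the
    breakpoints with a relative width ``shoulder`` (membership 0.5 exactly at
    each breakpoint).  Dilatational strain is split into compressive /
    neutral / tensile about ``dil_compress`` (and its mirror on the tensile
    side).  The windows follow the strain-window hypothesis of tissue
    differentiation: bone forms directly at low distortional strain,
    cartilage under moderate strain with volumetric compression, and tissue
    is destroyed beyond the excessive threshold.
    """

    eta_min: float = 5e-4       # understimulation floor (distortional)
    low_hi: float = 0.05
    mid_hi: float = 0.15
    destroy_hi: float = 0.30
    dil_compress: float = -0.002
    shoulder: float = 0.2       # relative transition-band width

    k_woven: float = 0.03       # intramembranous: fibrous -> woven
    k_chondro: float = 0.05     # chondrogenesis: fibrous -> cartilage
    k_endo: float = 0.04        # endochondral: cartilage -> woven
    k_remodel: float = 0.02     # remodeling: woven -> lamellar
    k_resorb: float = 0.01      # atrophy under understimulation -> fibrous
    k_destroy: float = 0.10     # destruction under excessive strain -> fibrous

    v_rate: float = 0.3         # vascular front speed, mm/day
    gamma_angio: float = 0.06   # distortional strain above which angiogenesis stops
    v_min: float = 0.5          # minimum vascularity for ossification

    def __post_init__(self) -> None:
        _require(0 < self.eta_min < self.low_hi < self.mid_hi < self.destroy_hi,
                 "0 < eta_min < low_hi < mid_hi < destroy_hi is violated")
        _require(0 < self.shoulder < 1, "shoulder in (0, 1) is violated")
        _require(self.dil_compress < 0, "dil_compress < 0 is violated")
        for name in ("k_woven", "k_chondro", "k_endo", "k_remodel",
                     "k_resorb", "k_destroy"):
            _require(getattr(self, name) >= 0, f"{name} >= 0 is violated")
        _require(self.v_rate >= 0, "v_rate >= 0 is violated")
        _require(self.gamma_angio > 0, "gamma_angio > 0 is violated")
        _require(0 < self.v_min <= 1, "v_min in (0, 1] is violated")
        # transition bands must not overlap, or the memberships would not
        # form a partition of unity
        s = self.shoulder / 2.0
        bps = (self.eta_min, self.low_hi, self.mid_hi, self.destroy_hi)
        for lo, hi in zip(bps[:-1], bps[1:]):
            _require(lo * (1 + s) < hi * (1 - s),
                     "membership transition bands overlap; reduce shoulder or "
                     "spread the breakpoints")


@dataclass
class OutputOptions:
    """Artifact cadence and solver options for a run."""

    snapshot_every: int = 40       # VTK snapshot cadence in days (0 = off)
    write_vtk: bool = True
    render_every: int = 0          # projection-image cadence in days (0 = off)
    solver: str = "auto"           # auto | direct | cg
    solver_rtol: float = 1e-8
    log_every: int = 20
    stop_on_union: bool = False

    def __post_init__(self) -> None:
        _require(self.solver in ("auto", "direct", "cg"),
                 "solver must be auto/direct/cg")
        _require(self.solver_rtol > 0, "solver_rtol > 0 is violated")


@dataclass
class SimulationConfig:
    """Complete, self-contained description of one simulation run."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    materials: MaterialTable = field(default_factory=MaterialTable)
    rules: FuzzyRuleSet = field(default_factory=FuzzyRuleSet)
    output: OutputOptions = field(default_factory=OutputOptions)

    def to_dict(self) -> dict:
        return {
            "scenario": dataclasses.asdict(self.scenario),
            "materials": dataclasses.asdict(self.materials),
            "rules": dataclasses.asdict(self.rules),
            "output": dataclasses.asdict(self.output),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for name, typ in (("scenario", ScenarioConfig), ("materials", MaterialTable),
                          ("rules", FuzzyRuleSet), ("output", OutputOptions)):
            block = data.get(name, {})
            names = {f.name for f in dataclasses.fields(typ)}
            bad = set(block) - names
            if bad:
                raise ConfigurationError(
                    f"unknown keys in '{name}' section: {sorted(bad)}")
            kwargs[name] = typ(**block)
        return cls(**kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def digest(self) -> str:
        """Stable content hash of the configuration (for provenance)."""
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# bundled reference scenarios
# ---------------------------------------------------------------------------

_CONFIG_DIR = Path(__file__).parent / "configs"


def list_bundled_configs() -> list:
    """Names of the reference scenario configurations shipped with the
    package (usable with ``load_bundled_config`` or ``callusim simulate``)."""
    return sorted(p.stem for p in _CONFIG_DIR.glob("*.yaml"))


def bundled_config_path(name: str) -> Path:
    """Path of a bundled scenario configuration by name (without .yaml)."""
    path = _CONFIG_DIR / f"{name}.yaml"
    if not path.exists():
        raise ConfigurationError(
            f"no bundled config {name!r}; available: {list_bundled_configs()}")
    return path


def load_bundled_config(name: str) -> "SimulationConfig":
    """Load one of the scenario configurations shipped with the package."""
    return SimulationConfig.from_yaml(bundled_config_path(name))
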