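"""Voxelized fracture scenarios and their initial tissue state.

A scenario is a structured grid of cubic cells (spacing ``voxel_size``)
containing an idealized hollow-cylinder diaphysis, an intramedullary nail
bonded through a thin reamed interface layer, a fracture gap of configurable
morphology and a periosteal callus annulus ("healing domain") spanning the
fracture zone.  This parametric stand-in preserves the mechanical
determinants a healing simulation responds to -- gap size, nail fit and
fragment topology -- without requiring patient imaging.

Conventions (documented once, used everywhere): the z axis is longitudinal,
+x anterior, +y medial (right-side convention); cells are indexed 0-based
and classified by their centre point; fragment 0 is proximal (loaded, high
z), fragment 1 distal (fixed, low z), fragment 2 an interposed wedge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Dict, Optional, Tuple

import numpy as np

from .config import ConfigurationError, ScenarioConfig

__all__ = [
    "Region",
    "Quadrant",
    "VoxelModel",
    "TissueState",
    "build_scenario",
    "partition_quadrants",
    "initial_state",
    "build_solid_cylinder",
    "build_block",
]

log = logging.getLogger(__name__)


class Region(IntEnum):
    OUTSIDE = 0
    CORTICAL = 1
    CANCELLOUS = 2
    CANAL = 3        # reamed interface layer between nail and endosteum
    NAIL = 4
    HEALING = 5      # healing domain: gap tissue + periosteal callus annulus


class Quadrant(IntEnum):
    NONE = -1
    ANTERIOR = 0
    POSTERIOR = 1
    MEDIAL = 2
    LATERAL = 3


#: regions that carry load (participate in the elasticity solve)
STRUCTURAL_REGIONS = (Region.CORTICAL, Region.CANCELLOUS, Region.CANAL,
                      Region.NAIL, Region.HEALING)
#: regions whose tissue composition evolves
EVOLVING_REGIONS = (Region.CORTICAL, Region.CANCELLOUS, Region.HEALING)

QUADRANT_LETTERS = {Quadrant.ANTERIOR: "A", Quadrant.POSTERIOR: "P",
                    Quadrant.MEDIAL: "M", Quadrant.LATERAL: "L"}


@dataclass
class VoxelModel:
    """Labeled cell grid plus the boundary sets needed for the daily solve."""

    dims: Tuple[int, int, int]
    spacing: float
    region: np.ndarray            # (nx, ny, nz) uint8, Region codes
    fragment_id: np.ndarray       # (nx, ny, nz) int8; -1 for non-bone
    quadrant: np.ndarray          # (nx, ny, nz) int8; Quadrant codes
    #: global structured node ids of the fully fixed distal base
    fixed_base: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    #: patch name -> (node ids, area weights summing to 1)
    load_patches: Dict[str, Tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    #: cells carved out of bone by the fracture (the gap proper)
    gap_mask: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    #: axial bounds (mm) of the carved fracture zone
    zone_bounds: Tuple[float, float] = (0.0, 0.0)
    config: Optional[ScenarioConfig] = None

    # -- derived helpers -------------------------------------------------
    @property
    def node_dims(self) -> Tuple[int, int, int]:
        nx, ny, nz = self.dims
        return nx + 1, ny + 1, nz + 1

    @property
    def axis_center(self) -> Tuple[float, float]:
        nx, ny, _ = self.dims
        return nx * self.spacing / 2.0, ny * self.spacing / 2.0

    def cell_centers(self):
        """Coordinate arrays (1-D per axis) of cell centres, mm."""
        h = self.spacing
        nx, ny, nz = self.dims
        return ((np.arange(nx) + 0.5) * h, (np.arange(ny) + 0.5) * h,
                (np.arange(nz) + 0.5) * h)

    def node_id(self, ix, iy, iz):
        nxn, nyn, _ = self.node_dims
        return np.asarray(ix) + np.asarray(iy) * nxn + np.asarray(iz) * nxn * nyn

    def mask(self, *regions: Region) -> np.ndarray:
        m = np.zeros(self.dims, bool)
        for r in regions:
            m |= self.region == int(r)
        return m

    @property
    def structural_mask(self) -> np.ndarray:
        return self.mask(*STRUCTURAL_REGIONS)

    @property
    def evolving_mask(self) -> np.ndarray:
        return self.mask(*EVOLVING_REGIONS)

    @property
    def bone_mask(self) -> np.ndarray:
        return self.mask(Region.CORTICAL, Region.CANCELLOUS)

    def region_counts(self) -> Dict[str, int]:
        return {r.name.lower(): int(np.count_nonzero(self.region == int(r)))
                for r in Region}


@dataclass
class TissueState:
    """Per-cell tissue composition and vascularity for one simulated day.

    The four phase fractions sum to one on every evolving cell and are zero
    elsewhere; vascularity lies in [0, 1] and is monotone non-decreasing over
    the simulation.
    """

    day: int
    lamellar: np.ndarray
    woven: np.ndarray
    cartilage: np.ndarray
    fibrous: np.ndarray
    vascularity: np.ndarray

    def fractions(self):
        return (self.lamellar, self.woven, self.cartilage, self.fibrous)

    def total(self) -> np.ndarray:
        return self.lamellar + self.woven + self.cartilage + self.fibrous

    def bone_fraction(self) -> np.ndarray:
        """Mineralised (woven + lamellar) fraction per cell."""
        return self.lamellar + self.woven

    def copy(self) -> "TissueState":
        return TissueState(self.day, self.lamellar.copy(), self.woven.copy(),
                           self.cartilage.copy(), self.fibrous.copy(),
                           self.vascularity.copy())


# ---------------------------------------------------------------------------
# scenario construction
# ---------------------------------------------------------------------------

def _grid_dims(cfg: ScenarioConfig) -> Tuple[int, int, int]:
    h = cfg.voxel_size
    half = int(np.ceil(cfg.callus_diameter / 2.0 / h)) + 1
    n_xy = 2 * half                       # even: centre on a node plane
    nz = max(int(round(cfg.segment_length / h)), 3)
    return n_xy, n_xy, nz


def build_scenario(config: ScenarioConfig) -> VoxelModel:
    """Construct the voxel model for a scenario configuration.

    Cell counts of every region are deterministic functions of the
    configuration; no randomness is involved.
    """
    h = config.voxel_size
    nx, ny, nz = _grid_dims(config)
    xs, ys, zs = ((np.arange(nx) + 0.5) * h, (np.arange(ny) + 0.5) * h,
                  (np.arange(nz) + 0.5) * h)
    cx = nx * h / 2.0
    cy = ny * h / 2.0
    X = (xs - cx)[:, None, None]
    Y = (ys - cy)[None, :, None]
    Z = zs[None, None, :]
    R = np.sqrt(X ** 2 + Y ** 2) + 0 * Z          # broadcast to (nx, ny, nz)

    nail_r = config.nail_diameter / 2.0
    canal_r = config.canal_diameter / 2.0
    outer_r = config.outer_diameter / 2.0
    inner_cort_r = outer_r - config.cortical_thickness
    callus_r = config.callus_diameter / 2.0

    region = np.zeros((nx, ny, nz), np.uint8)
    region[R <= nail_r] = Region.NAIL
    region[(R > nail_r) & (R <= canal_r)] = Region.CANAL
    region[(R > canal_r) & (R <= inner_cort_r)] = Region.CANCELLOUS
    region[(R > inner_cort_r) & (R <= outer_r)] = Region.CORTICAL

    # ---- carve the fracture -------------------------------------------
    z_mid = round(nz / 2) * h                      # gap centred on a node plane
    bone = (region == Region.CORTICAL) | (region == Region.CANCELLOUS)
    fragment = np.full((nx, ny, nz), -1, np.int8)
    gap = np.zeros((nx, ny, nz), bool)

    if config.fracture_kind == "transverse":
        lo, hi = z_mid - config.gap_width / 2.0, z_mid + config.gap_width / 2.0
        band = (Z >= lo) & (Z < hi) & np.ones_like(R, bool)
        gap = band & bone
        fragment[bone & (Z + 0 * R >= z_mid)] = 0
        fragment[bone & (Z + 0 * R < z_mid)] = 1
        fragment[gap] = -1
        zone = (lo, hi)
    elif config.fracture_kind == "oblique":
        az = np.radians(config.oblique_azimuth)
        slope = np.tan(np.radians(config.oblique_angle))
        plane = z_mid + slope * (X * np.cos(az) + Y * np.sin(az))
        local = Z - plane
        band = (local >= -config.gap_width / 2.0) & (local < config.gap_width / 2.0)
        gap = band & bone
        fragment[bone & (local >= 0)] = 0
        fragment[bone & (local < 0)] = 1
        fragment[gap] = -1
        zone = (z_mid - config.fracture_zone_extent() / 2.0,
                z_mid + config.fracture_zone_extent() / 2.0)
    else:  # wedge
        half_h = config.wedge_height / 2.0
        band_lo, band_hi = z_mid - half_h, z_mid + half_h
        in_band = (Z >= band_lo) & (Z < band_hi) & np.ones_like(R, bool)
        ang = np.degrees(np.arctan2(Y, X)) + 0 * Z
        delta = (ang - config.wedge_center + 180.0) % 360.0 - 180.0
        in_span = np.abs(delta) <= config.wedge_span / 2.0
        gap_above = (Z >= band_hi) & (Z < band_hi + config.gap_width) & np.ones_like(R, bool)
        gap_below = (Z >= band_lo - config.gap_width) & (Z < band_lo) & np.ones_like(R, bool)
        gap = bone & (gap_above | gap_below | (in_band & ~in_span))
        wedge = bone & in_band & in_span
        fragment[bone & (Z + 0 * R >= band_hi + config.gap_width)] = 0
        fragment[bone & (Z + 0 * R < band_lo - config.gap_width)] = 1
        fragment[wedge] = 2
        fragment[gap] = -1
        zone = (band_lo - config.gap_width, band_hi + config.gap_width)

    region[gap] = Region.HEALING

    # canal-interface cells at gap level belong to the healing domain, so the
    # space between the fragments evolves tissue everywhere around the nail
    z_in_zone = (Z >= zone[0]) & (Z < zone[1]) & np.ones_like(R, bool)
    canal_gap = (region == Region.CANAL) & z_in_zone
    region[canal_gap] = Region.HEALING
    gap = gap | canal_gap

    # ---- periosteal callus annulus ------------------------------------
    m = config.axial_margin
    callus_band = (Z >= zone[0] - m) & (Z < zone[1] + m) & np.ones_like(R, bool)
    callus = callus_band & (R > outer_r) & (R <= callus_r)
    region[callus] = Region.HEALING

    model = VoxelModel(dims=(nx, ny, nz), spacing=h, region=region,
                       fragment_id=fragment,
                       quadrant=np.full((nx, ny, nz), int(Quadrant.NONE), np.int8),
                       gap_mask=gap, zone_bounds=zone, config=config)
    partition_quadrants(model)
    _attach_boundaries(model)
    _check_connectivity(model)
    return model


def partition_quadrants(model: VoxelModel) -> VoxelModel:
    """Assign every bone / healing-domain cell to one of four 90-degree
    azimuthal sectors centred on +x (anterior), -x (posterior), +y (medial)
    and -y (lateral) about the section centroid.

    Cells exactly on a 45-degree sector boundary are broken toward anterior
    first, then medial, then posterior.
    """
    nx, ny, nz = model.dims
    xs, ys, _ = model.cell_centers()
    cx, cy = model.axis_center
    X = (xs - cx)[:, None]
    Y = (ys - cy)[None, :]
    sector = np.full((nx, ny), int(Quadrant.NONE), np.int8)
    ant = (X > 0) & (np.abs(Y) <= X)
    med = ~ant & (Y > 0) & (np.abs(X) <= Y)
    post = ~ant & ~med & (X < 0) & (np.abs(Y) <= -X)
    lat = ~ant & ~med & ~post & (Y < 0)
    sector[ant] = Quadrant.ANTERIOR
    sector[med] = Quadrant.MEDIAL
    sector[post] = Quadrant.POSTERIOR
    sector[lat] = Quadrant.LATERAL

    labelled = model.mask(Region.CORTICAL, Region.CANCELLOUS, Region.HEALING)
    quadrant = np.full(model.dims, int(Quadrant.NONE), np.int8)
    quadrant[labelled] = np.broadcast_to(sector[:, :, None], model.dims)[labelled]
    if labelled.any() and (quadrant[labelled] == int(Quadrant.NONE)).any():
        # only possible for a cell exactly on the section centroid
        warnings.warn("degenerate cross-section: some labelled cells have no "
                      "quadrant and were skipped", RuntimeWarning)
    model.quadrant = quadrant
    return model


def _attach_boundaries(model: VoxelModel) -> None:
    """Compute the fixed distal base nodes and the proximal load patches."""
    nx, ny, nz = model.dims
    h = model.spacing
    struct = model.structural_mask
    loadable = model.mask(Region.CORTICAL, Region.CANCELLOUS, Region.CANAL,
                          Region.NAIL)

    # fixed base: all nodes of the bottom faces of structural cells at iz = 0
    ii, jj = np.nonzero(struct[:, :, 0])
    corners = []
    for di, dj in ((0, 0), (1, 0), (0, 1), (1, 1)):
        corners.append(model.node_id(ii + di, jj + dj, 0))
    model.fixed_base = np.unique(np.concatenate(corners)) if len(ii) else np.empty(0, np.int64)

    # load patches: top faces of loadable cells in the top layer, uniform
    # traction -> each face spreads its share equally over its 4 nodes
    ii, jj = np.nonzero(loadable[:, :, nz - 1])
    ys = (np.arange(ny) + 0.5) * h
    cy = ny * h / 2.0
    medial_cells = ys[jj] > cy
    patches = {}
    for name, sel in (("medial", medial_cells), ("lateral", ~medial_cells),
                      ("proximal", np.ones_like(medial_cells))):
        isel, jsel = ii[sel], jj[sel]
        if isel.size == 0:
            patches[name] = (np.empty(0, np.int64), np.empty(0))
            continue
        nodes = {}
        for di, dj in ((0, 0), (1, 0), (0, 1), (1, 1)):
            for nid in model.node_id(isel + di, jsel + dj, nz):
                nodes[nid] = nodes.get(nid, 0.0) + 0.25
        ids = np.fromiter(nodes.keys(), np.int64)
        w = np.fromiter(nodes.values(), float)
        order = np.argsort(ids)
        ids, w = ids[order], w[order]
        patches[name] = (ids, w / w.sum())
    model.load_patches = patches


def _check_connectivity(model: VoxelModel) -> None:
    from scipy import ndimage
    struct = model.structural_mask
    labels, n = ndimage.label(struct, structure=ndimage.generate_binary_structure(3, 1))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        log.warning("structural mesh has %d disconnected components "
                    "(sizes %s); the solve will reject floating parts", n, sizes)


def initial_state(model: VoxelModel,
                  devascularize_fragment: Optional[int] = None,
                  noise: float = 0.0,
                  seed: Optional[int] = None) -> TissueState:
    """Day-0 tissue state: intact bone is 100 % lamellar and fully
    vascularized; the healing domain is avascular fibrous connective tissue.

    ``devascularize_fragment`` zeroes the vascularity of one fragment's bone
    cells (still 100 % lamellar), modelling a devitalised interposed
    fragment.  ``noise`` adds optional uniform perturbation to the healing
    domain's initial vascularity (off by default; this is the only use of
    ``seed``).
    """
    if devascularize_fragment is None and model.config is not None:
        devascularize_fragment = model.config.devascularize_fragment
    shape = model.dims
    zeros = lambda: np.zeros(shape)
    state = TissueState(0, zeros(), zeros(), zeros(), zeros(), zeros())
    bone = model.bone_mask
    healing = model.mask(Region.HEALING)
    state.lamellar[bone] = 1.0
    state.vascularity[bone] = 1.0
    state.fibrous[healing] = 1.0
    if devascularize_fragment is not None:
        state.vascularity[bone & (model.fragment_id == devascularize_fragment)] = 0.0
    if noise > 0.0:
        rng = np.random.default_rng(seed)
        jitter = rng.uniform(0.0, noise, size=shape)
        state.vascularity[healing] = np.clip(jitter[healing], 0.0, 1.0)
    return state


# ---------------------------------------------------------------------------
# verification geometries
# ---------------------------------------------------------------------------

def build_solid_cylinder(diameter: float, length: float, voxel_size: float) -> VoxelModel:
    """Homogeneous solid cortical cylinder (for solver verification)."""
    h = voxel_size
    half = int(np.ceil(diameter / 2.0 / h)) + 1
    nx = ny = 2 * half
    nz = max(int(round(length / h)), 1)
    xs = (np.arange(nx) + 0.5) * h - nx * h / 2.0
    ys = (np.arange(ny) + 0.5) * h - ny * h / 2.0
    R = np.sqrt(xs[:, None] ** 2 + ys[None, :] ** 2)
    region = np.zeros((nx, ny, nz), np.uint8)
    region[np.broadcast_to((R <= diameter / 2.0)[:, :, None], region.shape)] = Region.CORTICAL
    model = VoxelModel(dims=(nx, ny, nz), spacing=h, region=region,
                       fragment_id=np.where(region > 0, 0, -1).astype(np.int8),
                       quadrant=np.full((nx, ny, nz), int(Quadrant.NONE), np.int8))
    partition_quadrants(model)
    _attach_boundaries(model)
    return model


def build_block(nx: int, ny: int, nz: int, voxel_size: float = 1.0) -> VoxelModel:
    """Homogeneous rectangular cortical block (for patch tests)."""
    region = np.full((nx, ny, nz), int(Region.CORTICAL), np.uint8)
    model = VoxelModel(dims=(nx, ny, nz), spacing=voxel_size, region=region,
                       fragment_id=np.zeros((nx, ny, nz), np.int8),
                       quadrant=np.full((nx, ny, nz), int(Quadrant.NONE), np.int8))
    partition_quadrants(model)
    _attach_boundaries(model)
    return model
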