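"""Cortical-bridging detection and union/non-union classification.

A quadrant is *bridged* on a given day when a face-connected (6-connected by
default) path of cells with lamellar fraction >= ``c_min`` runs from any
proximal-fragment cortical cell to any distal-fragment cortical cell, with
the path restricted to that quadrant's bone and healing-domain cells.  A
case is classified as *union* when at least three of the four quadrants are
bridged simultaneously within the simulated horizon; the first such day is
the consolidation day.

The module also derives interfragmentary metrics from the daily
displacement field: the peak distortional strain over the gap-level healing
cells, the mean relative displacement of the two fragments' gap faces, and
the angulation between the fragments' least-squares longitudinal axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .fem import StrainField, VoxelElasticity
from .geometry import (QUADRANT_LETTERS, Quadrant, Region, TissueState,
                       VoxelModel)

__all__ = ["BridgingReport", "is_bridged", "bridged_quadrants", "classify",
           "interfragmentary_metrics"]

#: default minimum lamellar fraction for a cell to count as bridging bone
C_MIN_DEFAULT = 0.5


def _structure(connectivity: int):
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def is_bridged(state: TissueState, model: VoxelModel, quadrant: Quadrant,
               c_min: float = C_MIN_DEFAULT, connectivity: int = 6) -> bool:
    """True iff a path of lamellar bone crosses the fracture in ``quadrant``.

    The search region is the quadrant's bone plus healing-domain (periosteal
    callus) cells; endpoints are cortical cells of fragments 0 and 1.
    """
    if not 0.0 < c_min <= 1.0:
        raise ValueError("c_min must lie in (0, 1]")
    search = model.mask(Region.CORTICAL, Region.CANCELLOUS, Region.HEALING)
    search &= model.quadrant == int(quadrant)
    search &= state.lamellar >= c_min
    if not search.any():
        return False
    labels, n = ndimage.label(search, structure=_structure(connectivity))
    cortical = model.region == int(Region.CORTICAL)
    src = np.unique(labels[search & cortical & (model.fragment_id == 0)])
    dst = np.unique(labels[search & cortical & (model.fragment_id == 1)])
    src = src[src > 0]
    dst = dst[dst > 0]
    return bool(np.intersect1d(src, dst, assume_unique=True).size)


def bridged_quadrants(state: TissueState, model: VoxelModel,
                      c_min: float = C_MIN_DEFAULT,
                      connectivity: int = 6) -> Dict[Quadrant, bool]:
    return {q: is_bridged(state, model, q, c_min, connectivity)
            for q in (Quadrant.ANTERIOR, Quadrant.POSTERIOR,
                      Quadrant.MEDIAL, Quadrant.LATERAL)}


@dataclass
class BridgingReport:
    """Per-day bridging flags, interfragmentary metrics and final verdict."""

    days: List[int] = field(default_factory=list)
    bridged: List[Dict[Quadrant, bool]] = field(default_factory=list)
    gap_strain_max: List[float] = field(default_factory=list)
    rel_disp_mm: List[float] = field(default_factory=list)
    angulation_deg: List[float] = field(default_factory=list)
    outcome: Optional[str] = None
    consolidation_day: Optional[int] = None

    def append(self, day: int, flags: Dict[Quadrant, bool],
               gap_strain: float, rel_disp: float, angulation: float) -> None:
        self.days.append(day)
        self.bridged.append(dict(flags))
        self.gap_strain_max.append(float(gap_strain))
        self.rel_disp_mm.append(float(rel_disp))
        self.angulation_deg.append(float(angulation))

    def n_bridged(self) -> List[int]:
        return [sum(f.values()) for f in self.bridged]

    def to_frame(self):
        import pandas as pd
        cols = {"day": self.days}
        for q, letter in QUADRANT_LETTERS.items():
            cols[f"bridged_{letter}"] = [int(f[q]) for f in self.bridged]
        cols["n_bridged"] = self.n_bridged()
        cols["gap_strain_max"] = self.gap_strain_max
        cols["rel_disp_mm"] = self.rel_disp_mm
        cols["angulation_deg"] = self.angulation_deg
        return pd.DataFrame(cols)


def classify(report: BridgingReport, horizon: int,
             min_quadrants: int = 3) -> BridgingReport:
    """Fill in ``outcome`` and ``consolidation_day`` from the daily timeline.

    Union requires at least ``min_quadrants`` quadrants bridged
    simultaneously on some day within the horizon (the stricter reading of
    the at-least-three-quadrants rule); the consolidation day is the first
    such day.
    """
    if not report.days:
        raise ValueError("empty bridging timeline")
    report.outcome = "non_union"
    report.consolidation_day = None
    for day, flags in zip(report.days, report.bridged):
        if day > horizon:
            continue
        if sum(flags.values()) >= min_quadrants:
            report.outcome = "union"
            report.consolidation_day = int(day)
            break
    return report


def _rigid_rotation(centres: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body rotation vector (radians) of a point cloud.

    Minimizes ``|t + omega x (x - c) - u|^2`` over translation ``t`` and
    rotation ``omega``; with ``c`` the centroid, the normal equations are
    ``(sum |r|^2 I - r r^T) omega = sum r x du``.
    """
    r = centres - centres.mean(axis=0)
    du = disp - disp.mean(axis=0)
    A = np.eye(3) * np.einsum("ij,ij->", r, r) - r.T @ r
    b = np.cross(r, du).sum(axis=0)
    return np.linalg.solve(A, b)


def interfragmentary_metrics(model: VoxelModel, fem: VoxelElasticity,
                             u: np.ndarray, strains: StrainField,
                             ) -> Tuple[float, float, float]:
    """(max gap distortional strain, mean relative fragment displacement in
    mm, angulation between the fragments in degrees).

    The relative displacement is the mean displacement of fragment 1's
    gap-face cells minus fragment 0's, reported as a vector norm.  The
    angulation is the transverse (out-of-axis) component of the relative
    rigid-body rotation between the two main fragments, each fitted to its
    displacement field by least squares -- i.e. how far the fragments tilt
    against each other under the daily load.
    """
    gap = model.gap_mask
    gap_strain = float(strains.distortional[gap].max()) if gap.any() else 0.0

    disp = _cell_displacements(model, fem, u)
    centres = _cell_centres(model)

    rel = 0.0
    faces = [_gap_face(model, frag) for frag in (0, 1)]
    if faces[0].any() and faces[1].any():
        d1 = disp[faces[1]].mean(axis=0)
        d0 = disp[faces[0]].mean(axis=0)
        rel = float(np.linalg.norm(d1 - d0))

    ang = 0.0
    m0 = model.fragment_id == 0
    m1 = model.fragment_id == 1
    if m0.sum() >= 3 and m1.sum() >= 3:
        w0 = _rigid_rotation(centres[m0], disp[m0])
        w1 = _rigid_rotation(centres[m1], disp[m1])
        tilt = (w1 - w0)[:2]                 # transverse components only
        ang = float(np.degrees(np.linalg.norm(tilt)))
    return gap_strain, rel, ang


def _gap_face(model: VoxelModel, fragment: int) -> np.ndarray:
    """Cells of ``fragment`` with a face neighbour inside the fracture gap."""
    frag = model.fragment_id == fragment
    gap = model.gap_mask
    near = np.zeros_like(gap)
    near[:, :, 1:] |= gap[:, :, :-1]
    near[:, :, :-1] |= gap[:, :, 1:]
    near[1:, :, :] |= gap[:-1, :, :]
    near[:-1, :, :] |= gap[1:, :, :]
    near[:, 1:, :] |= gap[:, :-1, :]
    near[:, :-1, :] |= gap[:, 1:, :]
    return frag & near


def _cell_centres(model: VoxelModel) -> np.ndarray:
    xs, ys, zs = model.cell_centers()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    return np.stack([X, Y, Z], axis=-1)


def _cell_displacements(model: VoxelModel, fem: VoxelElasticity,
                        u: np.ndarray) -> np.ndarray:
    """Mean of the 8 nodal displacements per cell, scattered to the grid."""
    ue = u.reshape(-1)[fem.edofs].reshape(fem.n_cells, 8, 3)
    cell_disp = ue.mean(axis=1)
    out = np.zeros(model.dims + (3,))
    out[fem.cells] = cell_disp
    return out
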