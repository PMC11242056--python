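"""Simulated radiograph projections.

A grayscale image is produced as the line integral, along the anteroposterior
(x) or mediolateral (y) axis, of a radiodensity proxy formed from the tissue
fractions, then linearly rescaled to 8 bits.  Rows run proximal (top) to
distal (bottom).
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .geometry import Region, TissueState, VoxelModel

__all__ = ["DENSITY_DEFAULTS", "density_field", "render_projection"]

#: relative radiodensity per tissue phase and for the implant
DENSITY_DEFAULTS: Dict[str, float] = {
    "lamellar": 1.0,
    "woven": 0.6,
    "cartilage": 0.1,
    "fibrous": 0.05,
    "nail": 2.0,
    "interface": 0.05,
}


def density_field(state: TissueState, model: VoxelModel,
                  densities: Optional[Dict[str, float]] = None) -> np.ndarray:
    rho = dict(DENSITY_DEFAULTS, **(densities or {}))
    out = (rho["lamellar"] * state.lamellar + rho["woven"] * state.woven
           + rho["cartilage"] * state.cartilage + rho["fibrous"] * state.fibrous)
    out[model.region == int(Region.NAIL)] = rho["nail"]
    out[model.region == int(Region.CANAL)] = rho["interface"]
    return out


def render_projection(state: TissueState, model: VoxelModel, axis: str = "ap",
                      densities: Optional[Dict[str, float]] = None) -> np.ndarray:
    """8-bit projection image; ``axis='ap'`` integrates along +x,
    ``'ml'`` along +y.  Returns an array of shape (nz, n_transverse)."""
    if axis not in ("ap", "ml"):
        raise ValueError("axis must be 'ap' or 'ml'")
    rho = density_field(state, model, densities)
    proj = rho.sum(axis=0) if axis == "ap" else rho.sum(axis=1)
    # proj is (n_transverse, nz); rows should run proximal -> distal
    img = proj.T[::-1, :] * model.spacing
    peak = img.max()
    if peak <= 0:
        return np.zeros(img.shape, np.uint8)
    return np.round(img / peak * 255.0).astype(np.uint8)


def save_image(img: np.ndarray, path) -> None:
    from PIL import Image
    Image.fromarray(img, mode="L").save(path)
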