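"""Fuzzification of the strain stimuli.

The distortional (octahedral shear) strain is partitioned into five
categories -- understimulated, low, moderate, high, excessive -- by a chain
of trapezoidal memberships.  Each transition band is centred on its
breakpoint with relative width ``rules.shoulder`` (so the two adjacent
memberships are exactly 0.5 at the breakpoint) and the memberships sum to
one at every strain value.  The dilatational strain is split the same way
into compressive / neutral / tensile about the compression threshold and
its mirror image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import FuzzyRuleSet
from .fem import StrainField

__all__ = ["StimulusSummary", "fuzzify", "distortional_memberships",
           "dilatational_memberships"]


def _ramp(x: np.ndarray, breakpoint: float, shoulder: float) -> np.ndarray:
    """0 -> 1 transition centred on ``breakpoint`` with relative width
    ``shoulder`` (band = [b(1-s/2), b(1+s/2)])."""
    half = 0.5 * shoulder * abs(breakpoint)
    return np.clip((x - (breakpoint - half)) / (2.0 * half), 0.0, 1.0)


def distortional_memberships(gamma: np.ndarray, rules: FuzzyRuleSet) -> dict:
    gamma = np.asarray(gamma, float)
    u0 = _ramp(gamma, rules.eta_min, rules.shoulder)
    u1 = _ramp(gamma, rules.low_hi, rules.shoulder)
    u2 = _ramp(gamma, rules.mid_hi, rules.shoulder)
    u3 = _ramp(gamma, rules.destroy_hi, rules.shoulder)
    return {
        "understimulated": 1.0 - u0,
        "low": u0 - u1,
        "moderate": u1 - u2,
        "high": u2 - u3,
        "excessive": u3,
    }


def dilatational_memberships(dil: np.ndarray, rules: FuzzyRuleSet) -> dict:
    dil = np.asarray(dil, float)
    thr = abs(rules.dil_compress)
    # compressive: full membership below the (negative) threshold
    c = 1.0 - _ramp(dil, rules.dil_compress, rules.shoulder)
    t = _ramp(dil, thr, rules.shoulder)
    return {"compressive": c, "neutral": 1.0 - c - t, "tensile": t}


@dataclass
class StimulusSummary:
    """Per-cell membership degrees of the strain categories (grid-shaped)."""

    understimulated: np.ndarray
    low: np.ndarray
    moderate: np.ndarray
    high: np.ndarray
    excessive: np.ndarray
    compressive: np.ndarray
    neutral: np.ndarray
    tensile: np.ndarray


def fuzzify(strains: StrainField, rules: FuzzyRuleSet) -> StimulusSummary:
    """Evaluate all memberships on the grid-shaped stimulus fields."""
    d = distortional_memberships(strains.distortional, rules)
    v = dilatational_memberships(strains.dilatational, rules)
    return StimulusSummary(**d, **v)
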