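"""Daily tissue-evolution update driven by the fuzzified strain stimuli.

The update is an explicit forward-Euler step with per-day rate constants:
each active rule transfers a rate- and activation-scaled share of its source
phase into its target phase (Mamdani-style inference: min for AND, additive
aggregation).  Transfers are capped so the four phase fractions remain in
[0, 1] and sum to one on every evolving cell.

Rules (activation in parentheses):

R1 intramembranous ossification  fibrous   -> woven     (low AND vascular)
R2 chondrogenesis                fibrous   -> cartilage  (moderate AND compressive)
R3 endochondral ossification     cartilage -> woven      ((low OR moderate) AND vascular)
R4 remodeling                    woven     -> lamellar   (low OR understimulated)
R5 atrophy                       woven, lamellar -> fibrous (understimulated;
                                 healing domain and interposed-fragment cells only)
R6 destruction                   woven, cartilage, lamellar -> fibrous (excessive)

Vascularity spreads as a front from vascularized neighbours at ``v_rate``
mm/day, is damped by excessive-strain membership, stops entirely above the
angiogenesis strain limit, and never decreases.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .config import FuzzyRuleSet, MaterialTable
from .fem import (LoadCase, StrainField, VoxelElasticity, compute_strains,
                  mixture_properties)
from .fuzzy import StimulusSummary, fuzzify
from .geometry import Region, TissueState, VoxelModel

__all__ = ["update_vascularity", "update_tissues", "step_day", "get_fem"]


def _neighbor_max(field: np.ndarray) -> np.ndarray:
    """Max of the six face neighbours (zero-padded at the domain boundary)."""
    out = np.zeros_like(field)
    np.maximum(out[1:, :, :], field[:-1, :, :], out=out[1:, :, :])
    np.maximum(out[:-1, :, :], field[1:, :, :], out=out[:-1, :, :])
    np.maximum(out[:, 1:, :], field[:, :-1, :], out=out[:, 1:, :])
    np.maximum(out[:, :-1, :], field[:, 1:, :], out=out[:, :-1, :])
    np.maximum(out[:, :, 1:], field[:, :, :-1], out=out[:, :, 1:])
    np.maximum(out[:, :, :-1], field[:, :, 1:], out=out[:, :, :-1])
    return out


def update_vascularity(state: TissueState, strains: StrainField,
                       rules: FuzzyRuleSet, model: VoxelModel) -> np.ndarray:
    """Next-day vascularity field (monotone non-decreasing, clamped to [0,1]).

    A cell gains ``(v_rate / spacing) * max(neighbour vascularity)``, damped
    by its excessive-strain membership and zeroed where the distortional
    strain exceeds the angiogenesis limit.
    """
    from .fuzzy import distortional_memberships
    evolving = model.evolving_mask
    supply = np.where(evolving, state.vascularity, 0.0)
    influx = _neighbor_max(supply)
    m_exc = distortional_memberships(strains.distortional, rules)["excessive"]
    growth = (rules.v_rate / model.spacing) * influx * (1.0 - m_exc)
    growth[strains.distortional > rules.gamma_angio] = 0.0
    v = np.where(evolving, np.minimum(1.0, state.vascularity + growth),
                 state.vascularity)
    return np.maximum(v, state.vascularity)


def update_tissues(state: TissueState, stimuli: StimulusSummary,
                   rules: FuzzyRuleSet, model: VoxelModel) -> TissueState:
    """Apply the six differentiation rules for one day on the evolving cells."""
    lam, wov, car, fib = (f.copy() for f in state.fractions())
    evolving = model.evolving_mask.astype(float)
    vascular = (state.vascularity >= rules.v_min).astype(float)
    # atrophy acts in the healing domain and on an interposed fragment, never
    # on the intact far-field cortex of the main fragments
    atrophy_scope = ((model.region == Region.HEALING)
                     | (model.fragment_id == 2)).astype(float)

    a1 = np.minimum(stimuli.low, vascular)
    a2 = np.minimum(stimuli.moderate, stimuli.compressive)
    a3 = np.minimum(np.maximum(stimuli.low, stimuli.moderate), vascular)
    a4 = np.maximum(stimuli.low, stimuli.understimulated)
    a5 = stimuli.understimulated * atrophy_scope
    a6 = stimuli.excessive

    # outflow rates per source phase (capped below so fractions stay in [0,1])
    def _cap(total_rate):
        return np.minimum(total_rate, 1.0)

    out_fib = _cap(rules.k_woven * a1 + rules.k_chondro * a2) * evolving
    out_car = _cap(rules.k_endo * a3 + rules.k_destroy * a6) * evolving
    out_wov = _cap(rules.k_remodel * a4 + rules.k_resorb * a5
                   + rules.k_destroy * a6) * evolving
    out_lam = _cap(rules.k_resorb * a5 + rules.k_destroy * a6) * evolving

    d_fib = out_fib * fib
    d_car = out_car * car
    d_wov = out_wov * wov
    d_lam = out_lam * lam

    with np.errstate(divide="ignore", invalid="ignore"):
        w1 = np.where(out_fib > 0, rules.k_woven * a1 / np.maximum(out_fib, 1e-300), 0.0)
        w3 = np.where(out_car > 0, rules.k_endo * a3 / np.maximum(out_car, 1e-300), 0.0)
        w4 = np.where(out_wov > 0, rules.k_remodel * a4 / np.maximum(out_wov, 1e-300), 0.0)

    to_wov = d_fib * w1 + d_car * w3                  # R1 + R3
    to_car = d_fib * (1.0 - w1)                       # R2
    to_lam = d_wov * w4                               # R4
    to_fib = d_wov * (1.0 - w4) + d_lam + d_car * (1.0 - w3)  # R5 + R6

    lam += to_lam - d_lam
    wov += to_wov - d_wov
    car += to_car - d_car
    fib += to_fib - d_fib

    np.clip(lam, 0.0, 1.0, out=lam)
    np.clip(wov, 0.0, 1.0, out=wov)
    np.clip(car, 0.0, 1.0, out=car)
    np.clip(fib, 0.0, 1.0, out=fib)
    return TissueState(state.day, lam, wov, car, fib, state.vascularity)


def get_fem(model: VoxelModel, solver: str = "auto",
            rtol: float = 1e-8) -> VoxelElasticity:
    """Cached elasticity assembler for a model (pattern built once)."""
    cached = getattr(model, "_fem_cache", None)
    if cached is None or cached.solver != solver or cached.rtol != rtol:
        cached = VoxelElasticity(model, solver=solver, rtol=rtol)
        model._fem_cache = cached
    return cached


def step_day(model: VoxelModel, state: TissueState, table: MaterialTable,
             rules: FuzzyRuleSet, loadcase: LoadCase,
             fem: Optional[VoxelElasticity] = None,
             ) -> Tuple[TissueState, StrainField]:
    """Advance the state by one day: solve elasticity at the daily peak load,
    fuzzify the strain stimuli, update vascularity, then tissue fractions."""
    if fem is None:
        fem = get_fem(model)
    E, nu = mixture_properties(state, table, model)
    K = fem.assemble(E, nu)
    f = fem.load_vector(loadcase)
    u = fem.solve(K, f)
    strains = compute_strains(model, fem, u)
    stimuli = fuzzify(strains, rules)
    new_vasc = update_vascularity(state, strains, rules, model)
    staged = TissueState(state.day, state.lamellar, state.woven,
                         state.cartilage, state.fibrous, new_vasc)
    new_state = update_tissues(staged, stimuli, rules, model)
    new_state.day = state.day + 1
    return new_state, strains
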