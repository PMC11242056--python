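import dataclasses

import numpy as np
import pytest

import callusim as cs
from callusim.dynamics import step_day, update_tissues, update_vascularity
from callusim.fem import StrainField
from callusim.fuzzy import StimulusSummary
from callusim.geometry import Region, TissueState, build_block

from oracles import update_tissues_loop


def _strains(model, dist=0.0, dil=0.0):
    d = np.full(model.dims, float(dist))
    v = np.full(model.dims, float(dil))
    return StrainField(cells=None, tensor=None, distortional=d, dilatational=v)


def _healing_block(n=3):
    model = build_block(n, n, n, 1.0)
    model.region[:] = int(Region.HEALING)
    model.fragment_id[:] = -1
    return model


def _stimuli(model, **kwargs):
    zero = np.zeros(model.dims)
    fields = dict(understimulated=zero, low=zero, moderate=zero, high=zero,
                  excessive=zero, compressive=zero, neutral=zero, tensile=zero)
    for k, v in kwargs.items():
        fields[k] = np.full(model.dims, float(v))
    return StimulusSummary(**fields)


def _state(model, lamellar=0.0, woven=0.0, cartilage=0.0, fibrous=0.0,
           vascularity=0.0):
    full = lambda v: np.full(model.dims, float(v))
    return TissueState(0, full(lamellar), full(woven), full(cartilage),
                       full(fibrous), full(vascularity))


# ---------------------------------------------------------------------------
# vascularity
# ---------------------------------------------------------------------------

def test_vascular_front_single_cell_gain(rules):
    model = _healing_block(3)
    st = _state(model, fibrous=1.0)
    st.vascularity[0, 0, 0] = 1.0
    v = update_vascularity(st, _strains(model), rules, model)
    # face neighbours of the seed gain v_rate/h * 1 = 0.3 at 1 mm voxels
    assert v[1, 0, 0] == pytest.approx(0.3)
    assert v[0, 1, 0] == pytest.approx(0.3)
    assert v[0, 0, 1] == pytest.approx(0.3)
    assert v[1, 1, 0] == pytest.approx(0.0)   # diagonal is not a face neighbour
    assert v[0, 0, 0] == pytest.approx(1.0)


def test_vascularity_blocked_above_angiogenesis_limit(rules):
    model = _healing_block(3)
    st = _state(model, fibrous=1.0)
    st.vascularity[0, 0, 0] = 1.0
    v = update_vascularity(st, _strains(model, dist=rules.gamma_angio * 1.01),
                           rules, model)
    untouched = v == st.vascularity
    assert untouched.all()


def test_vascularity_monotone_and_capped(rules, rng):
    model = _healing_block(4)
    st = _state(model, fibrous=1.0)
    st.vascularity[:] = rng.uniform(0, 1, model.dims)
    v = st.vascularity
    for _ in range(5):
        new = update_vascularity(
            TissueState(0, st.lamellar, st.woven, st.cartilage, st.fibrous, v),
            _strains(model, dist=0.001), cs.FuzzyRuleSet(), model)
        assert (new >= v - 1e-15).all()
        assert (new <= 1.0).all()
        v = new


# ---------------------------------------------------------------------------
# single-rule arithmetic
# ---------------------------------------------------------------------------

def test_intramembranous_rate(rules):
    model = _healing_block()
    st = _state(model, fibrous=1.0, vascularity=1.0)
    new = update_tissues(st, _stimuli(model, low=1.0), rules, model)
    assert new.woven.flat[0] == pytest.approx(rules.k_woven)        # 0.03
    assert new.fibrous.flat[0] == pytest.approx(1.0 - rules.k_woven)


def test_intramembranous_requires_vascularity(rules):
    model = _healing_block()
    st = _state(model, fibrous=1.0, vascularity=rules.v_min - 0.01)
    new = update_tissues(st, _stimuli(model, low=1.0), rules, model)
    assert new.woven.flat[0] == 0.0
    assert new.fibrous.flat[0] == 1.0


def test_chondrogenesis_needs_compression_not_vascularity(rules):
    model = _healing_block()
    st = _state(model, fibrous=1.0, vascularity=0.0)
    new = update_tissues(st, _stimuli(model, moderate=1.0, compressive=1.0),
                         rules, model)
    assert new.cartilage.flat[0] == pytest.approx(rules.k_chondro)  # 0.05
    no_comp = update_tissues(st, _stimuli(model, moderate=1.0), rules, model)
    assert no_comp.cartilage.flat[0] == 0.0


def test_endochondral_ossification(rules):
    model = _healing_block()
    st = _state(model, cartilage=1.0, vascularity=1.0)
    new = update_tissues(st, _stimuli(model, moderate=1.0), rules, model)
    assert new.woven.flat[0] == pytest.approx(rules.k_endo)


def test_remodeling_and_atrophy(rules):
    model = _healing_block()
    st = _state(model, woven=1.0, vascularity=1.0)
    new = update_tissues(st, _stimuli(model, low=1.0), rules, model)
    assert new.lamellar.flat[0] == pytest.approx(rules.k_remodel)
    st2 = _state(model, woven=0.5, lamellar=0.5, vascularity=1.0)
    atro = update_tissues(st2, _stimuli(model, understimulated=1.0), rules, model)
    # understimulation both remodels woven and resorbs both bone phases
    assert atro.lamellar.flat[0] == pytest.approx(
        0.5 + 0.5 * rules.k_remodel / (rules.k_remodel + rules.k_resorb)
        * (rules.k_remodel + rules.k_resorb) - 0.5 * rules.k_resorb)
    assert atro.fibrous.flat[0] > 0.0


def test_atrophy_spares_main_fragment_cortex(rules):
    model = build_block(3, 3, 3, 1.0)       # cortical, fragment 0
    st = _state(model, lamellar=1.0, vascularity=1.0)
    new = update_tissues(st, _stimuli(model, understimulated=1.0), rules, model)
    assert (new.lamellar == 1.0).all()
    model.fragment_id[:] = 2                # interposed fragment resorbs
    again = update_tissues(st, _stimuli(model, understimulated=1.0), rules, model)
    np.testing.assert_allclose(again.lamellar, 1.0 - rules.k_resorb)


def test_destruction_rate(rules):
    model = _healing_block()
    st = _state(model, woven=0.5, cartilage=0.5)
    new = update_tissues(st, _stimuli(model, excessive=1.0), rules, model)
    assert new.woven.flat[0] == pytest.approx(0.5 * (1 - rules.k_destroy))
    assert new.cartilage.flat[0] == pytest.approx(0.5 * (1 - rules.k_destroy))
    assert new.fibrous.flat[0] == pytest.approx(rules.k_destroy)


def test_zero_rates_are_a_fixed_point():
    rules = cs.FuzzyRuleSet(k_woven=0, k_chondro=0, k_endo=0, k_remodel=0,
                            k_resorb=0, k_destroy=0)
    model = _healing_block()
    st = _state(model, woven=0.25, cartilage=0.25, fibrous=0.5,
                vascularity=1.0)
    new = update_tissues(st, _stimuli(model, low=0.5, moderate=0.5,
                                      compressive=1.0), rules, model)
    for a, b in zip(st.fractions(), new.fractions()):
        np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# conservation and oracle agreement
# ---------------------------------------------------------------------------

def test_conservation_under_random_stimuli(rules, rng):
    from callusim.fuzzy import (dilatational_memberships,
                                distortional_memberships)
    model = _healing_block(5)
    raw = rng.dirichlet(np.ones(4), size=model.dims).transpose(3, 0, 1, 2)
    st = TissueState(0, raw[0], raw[1], raw[2], raw[3],
                     rng.uniform(0, 1, model.dims))
    dist = rng.uniform(0, 0.5, model.dims)
    dil = rng.uniform(-0.02, 0.02, model.dims)
    m = distortional_memberships(dist, rules)
    d = dilatational_memberships(dil, rules)
    stim = StimulusSummary(**m, **d)
    new = update_tissues(st, stim, rules, model)
    np.testing.assert_allclose(new.total(), 1.0, atol=1e-9)
    for f in new.fractions():
        assert (f >= 0).all() and (f <= 1).all()


def test_vectorized_update_matches_scalar_loop(rules, rng, small_tibia_model):
    model = small_tibia_model
    raw = rng.dirichlet(np.ones(4), size=model.dims).transpose(3, 0, 1, 2)
    st = TissueState(0, raw[0], raw[1], raw[2], raw[3],
                     rng.uniform(0, 1, model.dims))
    dist = rng.uniform(0, 0.4, model.dims)
    dil = rng.uniform(-0.01, 0.005, model.dims)
    from callusim.fuzzy import (dilatational_memberships,
                                distortional_memberships)
    stim = StimulusSummary(**distortional_memberships(dist, rules),
                           **dilatational_memberships(dil, rules))
    new = update_tissues(st, stim, rules, model)
    lam, wov, car, fib = update_tissues_loop(st, dist, dil, rules, model)
    np.testing.assert_allclose(new.lamellar, lam, atol=1e-10)
    np.testing.assert_allclose(new.woven, wov, atol=1e-10)
    np.testing.assert_allclose(new.cartilage, car, atol=1e-10)
    np.testing.assert_allclose(new.fibrous, fib, atol=1e-10)


# ---------------------------------------------------------------------------
# full daily step
# ---------------------------------------------------------------------------

def test_step_day_is_deterministic(small_tibia_model, materials, rules):
    lc = cs.build_load_case("tibia", 750.0, 1.0)

    def advance():
        st = cs.initial_state(small_tibia_model)
        for _ in range(3):
            st, strains = step_day(small_tibia_model, st, materials, rules, lc)
        return st, strains

    a, sa = advance()
    b, sb = advance()
    for fa, fb in zip(a.fractions(), b.fractions()):
        np.testing.assert_array_equal(fa, fb)
    np.testing.assert_array_equal(a.vascularity, b.vascularity)
    np.testing.assert_array_equal(sa.distortional, sb.distortional)


def test_unloaded_fracture_forms_no_bone(small_tibia_model, materials, rules):
    lc = cs.build_load_case("tibia", 750.0, 0.0)
    st = cs.initial_state(small_tibia_model)
    for _ in range(5):
        st, _ = step_day(small_tibia_model, st, materials, rules, lc)
    healing = small_tibia_model.mask(Region.HEALING)
    assert st.woven[healing].max() == 0.0
    assert st.cartilage[healing].max() == 0.0
    assert st.vascularity[healing].max() > 0.0   # the front still advances
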