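"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's vectorized/ndimage code paths:
flood fill is a hand-rolled breadth-first search and the tissue update is a
per-cell Python loop, so agreement with the package is a genuine check.
"""

from collections import deque

import numpy as np

from callusim.geometry import Region


def flood_fill_bridged(lamellar, region, quadrant, fragment_id, q, c_min):
    """Breadth-first search equivalent of ``callusim.is_bridged`` (6-conn)."""
    nx, ny, nz = lamellar.shape
    searchable = np.isin(region, (int(Region.CORTICAL), int(Region.CANCELLOUS),
                                  int(Region.HEALING)))
    searchable &= quadrant == int(q)
    searchable &= lamellar >= c_min
    sources = (searchable & (region == int(Region.CORTICAL))
               & (fragment_id == 0))
    targets = (searchable & (region == int(Region.CORTICAL))
               & (fragment_id == 1))
    if not sources.any() or not targets.any():
        return False
    seen = np.zeros_like(searchable)
    queue = deque(zip(*np.nonzero(sources)))
    for cell in queue:
        seen[cell] = True
    while queue:
        i, j, k = queue.popleft()
        if targets[i, j, k]:
            return True
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if (0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz
                    and searchable[ni, nj, nk] and not seen[ni, nj, nk]):
                seen[ni, nj, nk] = True
                queue.append((ni, nj, nk))
    return False


def _memberships_scalar(g, rules):
    def ramp(x, b):
        half = 0.5 * rules.shoulder * abs(b)
        return min(1.0, max(0.0, (x - (b - half)) / (2.0 * half)))

    u0 = ramp(g, rules.eta_min)
    u1 = ramp(g, rules.low_hi)
    u2 = ramp(g, rules.mid_hi)
    u3 = ramp(g, rules.destroy_hi)
    return {"understimulated": 1.0 - u0, "low": u0 - u1, "moderate": u1 - u2,
            "high": u2 - u3, "excessive": u3}


def _dil_memberships_scalar(d, rules):
    def ramp(x, b):
        half = 0.5 * rules.shoulder * abs(b)
        return min(1.0, max(0.0, (x - (b - half)) / (2.0 * half)))

    c = 1.0 - ramp(d, rules.dil_compress)
    t = ramp(d, abs(rules.dil_compress))
    return {"compressive": c, "neutral": 1.0 - c - t, "tensile": t}


def update_tissues_loop(state, distortional, dilatational, rules, model):
    """Per-cell scalar re-implementation of the six differentiation rules."""
    lam = state.lamellar.copy()
    wov = state.woven.copy()
    car = state.cartilage.copy()
    fib = state.fibrous.copy()
    evolving = model.evolving_mask
    for i, j, k in zip(*np.nonzero(evolving)):
        m = _memberships_scalar(float(distortional[i, j, k]), rules)
        dm = _dil_memberships_scalar(float(dilatational[i, j, k]), rules)
        vascular = 1.0 if state.vascularity[i, j, k] >= rules.v_min else 0.0
        in_scope = (model.region[i, j, k] == int(Region.HEALING)
                    or model.fragment_id[i, j, k] == 2)
        a1 = min(m["low"], vascular)
        a2 = min(m["moderate"], dm["compressive"])
        a3 = min(max(m["low"], m["moderate"]), vascular)
        a4 = max(m["low"], m["understimulated"])
        a5 = m["understimulated"] if in_scope else 0.0
        a6 = m["excessive"]

        out_fib = min(rules.k_woven * a1 + rules.k_chondro * a2, 1.0)
        out_car = min(rules.k_endo * a3 + rules.k_destroy * a6, 1.0)
        out_wov = min(rules.k_remodel * a4 + rules.k_resorb * a5
                      + rules.k_destroy * a6, 1.0)
        out_lam = min(rules.k_resorb * a5 + rules.k_destroy * a6, 1.0)

        d_fib = out_fib * fib[i, j, k]
        d_car = out_car * car[i, j, k]
        d_wov = out_wov * wov[i, j, k]
        d_lam = out_lam * lam[i, j, k]

        w1 = rules.k_woven * a1 / out_fib if out_fib > 0 else 0.0
        w3 = rules.k_endo * a3 / out_car if out_car > 0 else 0.0
        w4 = rules.k_remodel * a4 / out_wov if out_wov > 0 else 0.0

        lam[i, j, k] += d_wov * w4 - d_lam
        wov[i, j, k] += d_fib * w1 + d_car * w3 - d_wov
        car[i, j, k] += d_fib * (1.0 - w1) - d_car
        fib[i, j, k] += (d_wov * (1.0 - w4) + d_lam
                         + d_car * (1.0 - w3) - d_fib)
    for arr in (lam, wov, car, fib):
        np.clip(arr, 0.0, 1.0, out=arr)
    return lam, wov, car, fib
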