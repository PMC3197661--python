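"""Exhaustive path-enumeration oracle for tiny games.

A deliberately slow, loop-based recomputation of finite-horizon survival
values, independent of the vectorized solver: every cost/gain draw and
mortality branch is enumerated explicitly, states are walked one by one,
and the recursion follows the game's definition directly.  Only feasible
for S <= ~6 and a few periods.
"""

from __future__ import annotations

import math

import numpy as np


def _chop(x, S):
    return min(S, max(x, 0))


def _smooth(v_forage, v_rest, k):
    z = (v_rest - v_forage) / k
    z = max(-700.0, min(700.0, z))
    return 1.0 / (1.0 + math.exp(z))


def _mort(params, u_self, u_other):
    if u_self == "rest":
        return params.m_R
    return params.m_T if u_other == "forage" else params.m_A


def _draws(params, action):
    """All (state change before D, probability) pairs for one individual."""
    cost = params.cost_distribution(action)
    out = []
    if action == "forage":
        gain = params.gain_distribution()
        for c, pc in zip(cost.support, cost.mass):
            for g, pg in zip(gain.support, gain.mass):
                if pc * pg > 0:
                    out.append((int(g - c), pc * pg))
    else:
        for c, pc in zip(cost.support, cost.mass):
            if pc > 0:
                out.append((int(-c), pc))
    return out


def enumerate_game(params, candidate, n_steps, terminal="alive"):
    """Finite-horizon survival values and first-period policies by recursion.

    Returns a dict with W_dom, W_sub ((S, S), indexed [x_d-1, x_s-1]),
    V_dom, V_sub ((S,)), pol_dom, pol_sub, lone_pol_dom, lone_pol_sub —
    all at the earliest period, matching ``finite_horizon``.
    """
    S, k = params.S, params.k
    draws = {u: _draws(params, u) for u in ("rest", "forage")}

    if terminal == "alive":
        W = {t: None for t in range(n_steps + 1)}
        W_T = {(xd, xs): 1.0 for xd in range(1, S + 1) for xs in range(1, S + 1)}
        V_T = {x: 1.0 for x in range(1, S + 1)}
        W_term = {"dom": dict(W_T), "sub": dict(W_T)}
        V_term = {"dom": dict(V_T), "sub": dict(V_T)}
    elif terminal == "state":
        W_term = {
            "dom": {(xd, xs): xd / S for xd in range(1, S + 1) for xs in range(1, S + 1)},
            "sub": {(xd, xs): xs / S for xd in range(1, S + 1) for xs in range(1, S + 1)},
        }
        V_term = {typ: {x: x / S for x in range(1, S + 1)} for typ in ("dom", "sub")}
    else:
        raise ValueError(terminal)

    def lone_H(x, u, V_next):
        m = params.m_R if u == "rest" else params.m_A
        total = 0.0
        for delta, p in draws[u]:
            xn = _chop(x + delta, S)
            if xn >= 1:
                total += p * V_next[xn]
        return (1.0 - m) * total

    def pair_H(focal, xd, xs, ud, us, W_next, V_next):
        """H for the focal type given both actions; D hits the subordinate."""
        D = int(round(params.interference_cost(ud, us)))
        if focal == "dom":
            u_f, u_o = ud, us
            x_f, x_o = xd, xs
            d_f, d_o = 0, D
        else:
            u_f, u_o = us, ud
            x_f, x_o = xs, xd
            d_f, d_o = D, 0
        m_f = _mort(params, u_f, u_o)
        m_o = _mort(params, u_o, u_f)
        total = 0.0
        for delta_f, p_f in draws[u_f]:
            x_fn = _chop(x_f + delta_f - d_f, S)
            if x_fn == 0:
                continue  # focal starves: zero continuation
            cont_alive = 0.0
            for delta_o, p_o in draws[u_o]:
                x_on = _chop(x_o + delta_o - d_o, S)
                if x_on >= 1:
                    key = (x_fn, x_on) if focal == "dom" else (x_on, x_fn)
                    cont_alive += p_o * W_next[key]
                else:
                    cont_alive += p_o * V_next[x_fn]
            total += p_f * ((1.0 - m_o) * cont_alive + m_o * V_next[x_fn])
        return (1.0 - m_f) * total

    W = dict(W_term)
    V = dict(V_term)
    pol = {}
    lone_pol = {}
    for _ in range(n_steps):
        new_V, new_lone_pol = {}, {}
        for typ in ("dom", "sub"):
            vals, pols = {}, {}
            for x in range(1, S + 1):
                vF = lone_H(x, "forage", V[typ])
                vR = lone_H(x, "rest", V[typ])
                pF = _smooth(vF, vR, k)
                pols[x] = pF
                vals[x] = pF * vF + (1 - pF) * vR
            new_V[typ] = vals
            new_lone_pol[typ] = pols
        new_W, new_pol = {}, {}
        for typ in ("dom", "sub"):
            vals, pols = {}, {}
            for xd in range(1, S + 1):
                for xs in range(1, S + 1):
                    if typ == "dom":
                        p_opp = candidate.sub[xd - 1, xs - 1]
                        vF = (p_opp * pair_H("dom", xd, xs, "forage", "forage", W["dom"], V["dom"])
                              + (1 - p_opp) * pair_H("dom", xd, xs, "forage", "rest", W["dom"], V["dom"]))
                        vR = (p_opp * pair_H("dom", xd, xs, "rest", "forage", W["dom"], V["dom"])
                              + (1 - p_opp) * pair_H("dom", xd, xs, "rest", "rest", W["dom"], V["dom"]))
                    else:
                        p_opp = candidate.dom[xd - 1, xs - 1]
                        vF = (p_opp * pair_H("sub", xd, xs, "forage", "forage", W["sub"], V["sub"])
                              + (1 - p_opp) * pair_H("sub", xd, xs, "rest", "forage", W["sub"], V["sub"]))
                        vR = (p_opp * pair_H("sub", xd, xs, "forage", "rest", W["sub"], V["sub"])
                              + (1 - p_opp) * pair_H("sub", xd, xs, "rest", "rest", W["sub"], V["sub"]))
                    pF = _smooth(vF, vR, k)
                    pols[(xd, xs)] = pF
                    vals[(xd, xs)] = pF * vF + (1 - pF) * vR
            new_W[typ] = vals
            new_pol[typ] = pols
        W, V, pol, lone_pol = new_W, new_V, new_pol, new_lone_pol

    def as_matrix(d):
        out = np.zeros((S, S))
        for (xd, xs), v in d.items():
            out[xd - 1, xs - 1] = v
        return out

    def as_vector(d):
        out = np.zeros(S)
        for x, v in d.items():
            out[x - 1] = v
        return out

    return {
        "W_dom": as_matrix(W["dom"]), "W_sub": as_matrix(W["sub"]),
        "V_dom": as_vector(V["dom"]), "V_sub": as_vector(V["sub"]),
        "pol_dom": as_matrix(pol["dom"]), "pol_sub": as_matrix(pol["sub"]),
        "lone_pol_dom": as_vector(lone_pol["dom"]),
        "lone_pol_sub": as_vector(lone_pol["sub"]),
        "pair_H": pair_H, "lone_H": lone_H, "W": W, "V": V,
    }
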