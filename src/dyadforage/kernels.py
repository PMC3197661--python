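"""Precomputed per-period transition kernels.

Everything the backward induction and the forward Markov chain need about a
parameter set is a handful of (S, S+1) matrices: row x (alive state 1..S),
column x' (next state 0..S, 0 = starved).  Entry [x-1, x'] is the probability
that an individual at state x ends the period at state x' given the action
context, before predation is accounted for.  Predation probabilities are kept
separate because they multiply whole branches of the expectation.
"""

from __future__ import annotations

import numpy as np

from .params import DiscreteChangeDistribution, ModelParameters

ACTIONS = ("rest", "forage")


def convolve_changes(
    cost: DiscreteChangeDistribution,
    gain: DiscreteChangeDistribution | None,
    extra_cost: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the net state change -cost + gain - extra_cost.

    Returns ``(offsets, probs)`` with integer offsets.  ``extra_cost`` (the
    interference cost) is rounded to the nearest integer, matching the
    integer state grid; the factorial design only uses 0 or 1.
    """
    extra = int(round(extra_cost))
    if gain is None:
        offsets = -cost.support - extra
        return offsets, cost.mass.copy()
    # outer sum of -cost and +gain, aggregated by offset
    lo = int(-cost.support.max() + gain.support.min()) - extra
    hi = int(-cost.support.min() + gain.support.max()) - extra
    probs = np.zeros(hi - lo + 1)
    for c, pc in zip(cost.support, cost.mass):
        idx = (-c - extra + gain.support) - lo
        probs[idx] += pc * gain.mass
    return np.arange(lo, hi + 1), probs


def transition_matrix(S: int, offsets: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """(S, S+1) matrix of chopped transitions x -> clamp(x + offset, 0, S)."""
    T = np.zeros((S, S + 1))
    x = np.arange(1, S + 1)
    for off, p in zip(offsets, probs):
        if p == 0.0:
            continue
        xp = np.clip(x + off, 0, S)
        np.add.at(T, (x - 1, xp), p)
    return T


class Kernels:
    """All transition matrices and mortality lookups for one parameter set."""

    def __init__(self, params: ModelParameters):
        self.params = params
        S = params.S
        cost_R = params.cost_distribution("rest")
        cost_F = params.cost_distribution("forage")
        gain = params.gain_distribution()

        def tmat(cost, gain_, extra=0.0):
            return transition_matrix(S, *convolve_changes(cost, gain_, extra))

        #: dominant (and any lone individual): transition per own action
        self.plain = {"rest": tmat(cost_R, None), "forage": tmat(cost_F, gain)}
        #: subordinate while paired: transition per (dominant action, own action)
        self.sub = {}
        for u_d in ACTIONS:
            for u_s in ACTIONS:
                cost = cost_R if u_s == "rest" else cost_F
                gain_ = None if u_s == "rest" else gain
                D = params.interference_cost(u_d, u_s)
                self.sub[(u_d, u_s)] = tmat(cost, gain_, D)

        # cached views used in the backward-induction hot loop
        self.plain_alive = {u: np.ascontiguousarray(T[:, 1:]) for u, T in self.plain.items()}
        self.plain_aliveT = {u: np.ascontiguousarray(T[:, 1:].T) for u, T in self.plain.items()}
        self.plain_dead = {u: T[:, 0].copy() for u, T in self.plain.items()}
        self.sub_alive = {key: np.ascontiguousarray(T[:, 1:]) for key, T in self.sub.items()}
        self.sub_aliveT = {key: np.ascontiguousarray(T[:, 1:].T) for key, T in self.sub.items()}
        self.sub_dead = {key: T[:, 0].copy() for key, T in self.sub.items()}

    def mortality(self, u_focal: str, u_other: str) -> float:
        """Predation probability for the focal's action in the joint context."""
        p = self.params
        if u_focal == "rest":
            return p.m_R
        return p.m_T if u_other == "forage" else p.m_A

    def mortality_lone(self, u: str) -> float:
        p = self.params
        return p.m_R if u == "rest" else p.m_A

    def dom_matrix(self, u_d: str) -> np.ndarray:
        return self.plain[u_d]

    def sub_matrix(self, u_d: str, u_s: str) -> np.ndarray:
        return self.sub[(u_d, u_s)]
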