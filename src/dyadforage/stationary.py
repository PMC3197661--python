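"""Forward Markov-chain analysis of a converged strategy pair.

Given a converged policy, the pair's joint reserves (x_d, x_s) evolve as a
Markov chain on the alive states {1..S}^2.  Mass leaks out of the chain
through predation and starvation; the "stable population" is the
renormalized distribution conditioned on both pair members being alive,
found by forward iteration.  All temporal statistics below (behaviour
proportions, repeat probabilities, heaviest-individual sojourns) are
computed from this conditioned chain.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .kernels import ACTIONS, Kernels
from .params import ModelParameters
from .solver import ConvergenceError, PairPolicy

__all__ = [
    "PairStateDistribution",
    "BehaviourProportions",
    "pair_transition_operator",
    "stationary_distribution",
    "behaviour_proportions",
    "behaviour_repeat_stats",
    "heaviest_sojourn",
    "mean_reserves",
]

#: the four paired behaviours, as (dominant action, subordinate action)
ACTION_PAIRS = tuple(itertools.product(ACTIONS, ACTIONS))


@dataclasses.dataclass
class PairStateDistribution:
    """Probability mass over alive paired states, conditioned on both alive.

    ``mass[x_d-1, x_s-1]`` sums to 1.  ``residual`` is the L1 change of the
    final forward iteration; ``steps`` the number of iterations taken;
    ``survival_rate`` the per-period probability that a pair drawn from the
    distribution has both members alive one period later.
    """

    mass: np.ndarray
    residual: float = np.nan
    steps: int = 0
    survival_rate: float = np.nan

    def __post_init__(self):
        self.mass = np.asarray(self.mass, dtype=float)
        if np.any(self.mass < -1e-12):
            raise ValueError("distribution mass must be nonnegative")
        if abs(self.mass.sum() - 1.0) > 1e-10:
            raise ValueError(f"mass sums to {self.mass.sum()!r}, not 1")


@dataclasses.dataclass(frozen=True)
class BehaviourProportions:
    """Stationary proportions of the four paired behaviours (sum to 1)."""

    p_FF: float
    p_FR: float  # dominant forages, subordinate rests
    p_RF: float  # dominant rests, subordinate forages
    p_RR: float
    dom_forage: float = None  # marginal foraging proportions
    sub_forage: float = None

    def __post_init__(self):
        total = self.p_FF + self.p_FR + self.p_RF + self.p_RR
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"paired-behaviour proportions sum to {total!r}, not 1")
        if self.dom_forage is None:
            object.__setattr__(self, "dom_forage", self.p_FF + self.p_FR)
        if self.sub_forage is None:
            object.__setattr__(self, "sub_forage", self.p_FF + self.p_RF)


def _pair_weights(policy: PairPolicy) -> dict:
    """Joint action-pair probabilities per state, from the smoothed policy."""
    pd, ps = policy.dom, policy.sub
    return {
        ("forage", "forage"): pd * ps,
        ("forage", "rest"): pd * (1 - ps),
        ("rest", "forage"): (1 - pd) * ps,
        ("rest", "rest"): (1 - pd) * (1 - ps),
    }


def _step_masses(kern: Kernels, policy: PairPolicy, dist: np.ndarray):
    """One unnormalized forward step, resolved per action pair.

    Yields ``(pair, next_mass)`` where ``next_mass[x_d'-1, x_s'-1]`` is the
    surviving mass that played that action pair; summing over pairs gives
    the total surviving (sub-probability) mass.
    """
    weights = _pair_weights(policy)
    for pair in ACTION_PAIRS:
        u_d, u_s = pair
        surv = (1 - kern.mortality(u_d, u_s)) * (1 - kern.mortality(u_s, u_d))
        Ad = kern.plain_alive[u_d]           # [x_d, x_d']
        As = kern.sub_alive[(u_d, u_s)]      # [x_s, x_s']
        source = dist * weights[pair]
        yield pair, surv * (Ad.T @ source @ As)


def pair_transition_operator(policy: PairPolicy, params: ModelParameters) -> np.ndarray:
    """Dense one-period transition operator on alive paired states.

    Returns a (S^2, S^2) matrix T with column index the source state
    (x_d, x_s) flattened row-major and row index the destination; each
    column sums to the pair's joint survival probability from that state
    (the deficit is predation/starvation leakage).
    """
    kern = Kernels(params)
    S = params.S
    weights = _pair_weights(policy)
    T = np.zeros((S * S, S * S))
    for pair in ACTION_PAIRS:
        u_d, u_s = pair
        surv = (1 - kern.mortality(u_d, u_s)) * (1 - kern.mortality(u_s, u_d))
        Ad = kern.plain_alive[u_d]
        As = kern.sub_alive[(u_d, u_s)]
        # contribution[(xd',xs'),(xd,xs)] = surv * w[xd,xs] * Ad[xd,xd'] * As[xs,xs']
        block = surv * np.einsum("de,sf,ds->efds", Ad, As, weights[pair])
        T += block.reshape(S * S, S * S)
    return T


def stationary_distribution(
    policy: PairPolicy,
    params: ModelParameters,
    init: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 200_000,
    kern: Kernels | None = None,
) -> PairStateDistribution:
    """Stable conditioned distribution by renormalized forward iteration.

    Iterates ``d <- normalize(T d)`` from a uniform start (or ``init``)
    until the L1 change is below ``tol``; the normalization step conditions
    the population on pairs in which both members are still alive.
    """
    kern = kern or Kernels(params)
    S = params.S
    if init is None:
        d = np.full((S, S), 1.0 / (S * S))
    else:
        d = np.asarray(init, dtype=float)
        d = d / d.sum()
    residual = np.inf
    for step in range(1, max_iter + 1):
        nxt = np.zeros_like(d)
        for _, mass in _step_masses(kern, policy, d):
            nxt += mass
        total = nxt.sum()
        if total <= 0:
            raise ConvergenceError("all mass leaked out of the alive states")
        nxt /= total
        residual = float(np.abs(nxt - d).sum())
        d = nxt
        if residual < tol:
            return PairStateDistribution(d, residual, step, float(total))
    raise ConvergenceError(
        f"forward iteration did not converge within {max_iter} steps "
        f"(last L1 residual {residual:.3e})"
    )


def behaviour_proportions(policy: PairPolicy, dist: PairStateDistribution) -> BehaviourProportions:
    """Stationary proportions of the four paired behaviours.

    Expectations of the joint (error-smoothed) action probabilities under
    the conditioned stationary distribution; the marginal foraging
    proportion of each type follows by additivity.
    """
    weights = _pair_weights(policy)
    p = {pair: float((dist.mass * w).sum()) for pair, w in weights.items()}
    return BehaviourProportions(
        p_FF=p[("forage", "forage")],
        p_FR=p[("forage", "rest")],
        p_RF=p[("rest", "forage")],
        p_RR=p[("rest", "rest")],
    )


def mean_reserves(dist: PairStateDistribution) -> tuple[float, float]:
    """Mean energetic reserves (state units) of the dominant and subordinate."""
    S = dist.mass.shape[0]
    x = np.arange(1, S + 1)
    mean_d = float((dist.mass.sum(axis=1) * x).sum())
    mean_s = float((dist.mass.sum(axis=0) * x).sum())
    return mean_d, mean_s


def behaviour_repeat_stats(
    policy: PairPolicy,
    params: ModelParameters,
    dist: PairStateDistribution | None = None,
    max_horizon: int = 10_000,
    kern: Kernels | None = None,
) -> dict:
    """Behavioural repeatability under the stationary conditioned chain.

    Returns a dict with:

    ``repeat_dom`` / ``repeat_sub``
        probability that the type repeats its current behaviour in the next
        period (among pairs with both members surviving the step);
    ``half_change_time``
        the first horizon t at which the fraction of surviving pairs that
        have repeated their initial paired behaviour through all t
        consecutive periods drops to <= 0.5, linearly interpolated between
        integer horizons; ``inf`` if the fraction never crosses 0.5 within
        ``max_horizon`` periods.
    """
    kern = kern or Kernels(params)
    if dist is None:
        dist = stationary_distribution(policy, params, kern=kern)
    weights = _pair_weights(policy)

    # one-step repeat probabilities
    num = {"dom": 0.0, "sub": 0.0}
    denom = 0.0
    for (u_d, u_s), mass in _step_masses(kern, policy, dist.mass):
        denom += mass.sum()
        p_same_d = policy.dom if u_d == "forage" else 1 - policy.dom
        p_same_s = policy.sub if u_s == "forage" else 1 - policy.sub
        num["dom"] += float((mass * p_same_d).sum())
        num["sub"] += float((mass * p_same_s).sum())
    repeat_dom = num["dom"] / denom
    repeat_sub = num["sub"] / denom

    # persistence of the initial paired behaviour
    persist = {pair: dist.mass * weights[pair] for pair in ACTION_PAIRS}
    alive = dist.mass.copy()  # unconstrained surviving mass, same chain
    prev_frac = 1.0
    half_change = np.inf
    for t in range(1, max_horizon + 1):
        alive_next = np.zeros_like(alive)
        for _, mass in _step_masses(kern, policy, alive):
            alive_next += mass
        new_persist = {}
        for pair in ACTION_PAIRS:
            u_d, u_s = pair
            surv = (1 - kern.mortality(u_d, u_s)) * (1 - kern.mortality(u_s, u_d))
            Ad = kern.plain_alive[u_d]
            As = kern.sub_alive[(u_d, u_s)]
            moved = surv * (Ad.T @ persist[pair] @ As)
            # must choose the same action pair again at the new state
            new_persist[pair] = moved * weights[pair]
        persist = new_persist
        frac = sum(m.sum() for m in persist.values()) / alive_next.sum()
        alive = alive_next
        if frac <= 0.5:
            half_change = (t - 1) + (prev_frac - 0.5) / (prev_frac - frac)
            break
        prev_frac = frac
    return {
        "repeat_dom": float(repeat_dom),
        "repeat_sub": float(repeat_sub),
        "half_change_time": float(half_change),
    }


def heaviest_sojourn(
    policy: PairPolicy,
    params: ModelParameters,
    dist: PairStateDistribution | None = None,
    kern: Kernels | None = None,
) -> tuple[float, float]:
    """Mean consecutive periods each type remains the strictly heavier one.

    Run lengths of the events {x_d > x_s} and {x_s > x_d} under the
    stationary conditioned chain, by the renewal identity
    mean sojourn = pi(E) / (per-period flux out of E); exiting includes
    moving to a tie or reversal and the pair's death.  Returns
    ``(mean_dom, mean_sub)``; ``inf`` when the chain cannot leave the set.
    """
    kern = kern or Kernels(params)
    if dist is None:
        dist = stationary_distribution(policy, params, kern=kern)
    S = params.S
    x = np.arange(1, S + 1)
    masks = {
        "dom": x[:, None] > x[None, :],
        "sub": x[:, None] < x[None, :],
    }
    out = []
    for key in ("dom", "sub"):
        mask = masks[key]
        pi_E = float(dist.mass[mask].sum())
        if pi_E == 0.0:
            out.append(0.0)
            continue
        source = dist.mass * mask
        stayed = 0.0
        for _, mass in _step_masses(kern, policy, source):
            stayed += float(mass[mask].sum())
        flux_out = pi_E - stayed
        out.append(float(pi_E / flux_out) if flux_out > 1e-15 else np.inf)
    return out[0], out[1]
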