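"""Scalar behavioural summary statistics for one converged run.

All statistics are taken under the stationary conditioned distribution of
paired states: the four paired-behaviour proportions and each individual's
marginal foraging proportion, the behavioural synchrony coefficient, an
independence-of-action (S) statistic, behavioural repeatability, mean
reserves, and heaviest-individual sojourn times.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

from .params import COST_NAMES, ModelParameters
from .solver import ESSResult, PairPolicy
from .stationary import (
    BehaviourProportions,
    PairStateDistribution,
    behaviour_proportions,
    behaviour_repeat_stats,
    heaviest_sojourn,
    mean_reserves,
    stationary_distribution,
)

__all__ = ["SummaryRecord", "synchrony_coefficient", "s_statistic", "summarize_run"]


def synchrony_coefficient(p: BehaviourProportions) -> float:
    """Behavioural synchrony in [-1, 1].

    (p_RR * p_FF - p_RF * p_FR) / (p_RR * p_FF + p_RF * p_FR): +1 when the
    pair only ever acts together, -1 when it only ever alternates.  When
    both products are zero (one individual's behaviour is constant) the
    coefficient is undefined and NaN is returned rather than 0.
    """
    together = p.p_RR * p.p_FF
    apart = p.p_RF * p.p_FR
    denom = together + apart
    if denom <= 0.0:
        return float("nan")
    return (together - apart) / denom


def _marginal_state_policy_disagreement(
    own_policy: np.ndarray, dist_mass: np.ndarray, axis: int
) -> float:
    """Dist-weighted disagreement with the colleague-marginalized action.

    ``own_policy`` is indexed [x_d, x_s]; ``axis`` is the colleague's axis
    (1 when the focal is the dominant).  For each focal state the colleague
    is collapsed to its conditional-mean state; the statistic is the mass-
    weighted absolute difference between the action actually taken and the
    action taken against that collapsed state.
    """
    S = own_policy.shape[0]
    x = np.arange(1, S + 1)
    marg = dist_mass.sum(axis=axis)           # focal marginal
    joint = dist_mass if axis == 1 else dist_mass.T  # [focal, colleague]
    pol = own_policy if axis == 1 else own_policy.T
    overall_mean = float((dist_mass.sum(axis=1 - axis) * x).sum())
    with np.errstate(invalid="ignore"):
        cond_mean = (joint * x[None, :]).sum(axis=1) / marg
    cond_mean = np.where(marg > 0, cond_mean, overall_mean)
    ref_idx = np.clip(np.rint(cond_mean).astype(int), 1, S) - 1
    ref = pol[np.arange(S), ref_idx]          # action vs collapsed colleague
    return float((joint * np.abs(pol - ref[:, None])).sum())


def s_statistic(
    policy: PairPolicy,
    dist: PairStateDistribution,
    method: Callable[[PairPolicy, PairStateDistribution], float] | None = None,
) -> float:
    """Degree to which optimal action depends on knowing the colleague's state.

    .. warning::
       This is a stand-in definition, not the statistic of the original
       independence-of-action reference (whose closed form is not restated
       here).  Default: the stationary-mass-weighted proportion of paired
       states at which the focal's smoothed action differs from the action
       it would take against the colleague-marginalized (conditional-mean)
       state, averaged over the two types.  0 means the policy ignores the
       colleague's state; larger values mean more state-interdependence.
       Quantitative comparison with published S values requires plugging the
       original formula in via ``method``.
    """
    if method is not None:
        return float(method(policy, dist))
    s_dom = _marginal_state_policy_disagreement(policy.dom, dist.mass, axis=1)
    s_sub = _marginal_state_policy_disagreement(policy.sub, dist.mass, axis=0)
    return 0.5 * (s_dom + s_sub)


@dataclasses.dataclass
class SummaryRecord:
    """One row of the sweep results table: all summary statistics of a run."""

    dom_forage: float
    sub_forage: float
    p_FF: float
    p_FR: float
    p_RF: float
    p_RR: float
    synchrony: float
    s_stat: float
    repeat_dom: float
    repeat_sub: float
    half_change_time: float
    reserves_dom: float
    reserves_sub: float
    heaviest_dom: float
    heaviest_sub: float
    D_dRsR: float
    D_dFsR: float
    D_dRsF: float
    D_dFsF: float
    set_id: int = -1
    seed: int = -1
    ess_iterations: int = 0
    ess_residual: float = np.nan
    br_residual: float = np.nan
    at_noise_floor: bool = False
    stationary_residual: float = np.nan
    failed: bool = False
    error: str = ""

    #: responses analysed by the factorial ANOVA, in reporting order
    RESPONSES = (
        "dom_forage", "sub_forage", "p_FF", "p_FR", "p_RF", "p_RR",
        "synchrony", "s_stat", "repeat_dom", "repeat_sub",
        "half_change_time", "reserves_dom", "reserves_sub",
        "heaviest_dom", "heaviest_sub",
    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize_run(
    ess: ESSResult,
    params: ModelParameters,
    dist: PairStateDistribution | None = None,
    set_id: int = -1,
    seed: int = -1,
) -> SummaryRecord:
    """Compute every summary statistic for one converged run."""
    policy = ess.policy
    if dist is None:
        dist = stationary_distribution(policy, params)
    props = behaviour_proportions(policy, dist)
    repeats = behaviour_repeat_stats(policy, params, dist=dist)
    res_d, res_s = mean_reserves(dist)
    heavy_d, heavy_s = heaviest_sojourn(policy, params, dist=dist)
    costs = dict(zip(COST_NAMES, params.costs_vector()))
    return SummaryRecord(
        dom_forage=props.dom_forage,
        sub_forage=props.sub_forage,
        p_FF=props.p_FF,
        p_FR=props.p_FR,
        p_RF=props.p_RF,
        p_RR=props.p_RR,
        synchrony=synchrony_coefficient(props),
        s_stat=s_statistic(policy, dist),
        repeat_dom=repeats["repeat_dom"],
        repeat_sub=repeats["repeat_sub"],
        half_change_time=repeats["half_change_time"],
        reserves_dom=res_d,
        reserves_sub=res_s,
        heaviest_dom=heavy_d,
        heaviest_sub=heavy_s,
        set_id=set_id,
        seed=seed,
        ess_iterations=ess.iterations,
        ess_residual=ess.residual,
        br_residual=ess.br_residual,
        at_noise_floor=ess.at_noise_floor,
        stationary_residual=dist.residual,
        **costs,
    )
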