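"""Tiny, exactly analysable games for verification and demonstration.

Each profile builds a game small enough (S in {3, 4, 5}, point-mass or
two-point cost/gain distributions) that its backward induction can be
checked by hand or by exhaustive path enumeration, together with the
qualitative features its converged policy must show.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .params import ModelParameters

__all__ = ["ToyFixture", "make_toy_fixture", "PROFILES"]


@dataclasses.dataclass(frozen=True)
class ToyFixture:
    """A small game plus the properties its solution must satisfy.

    ``expectations`` maps a short property name to the value or predicate
    description used by the test-suite; ``notes`` explains the construction.
    """

    name: str
    params: ModelParameters
    horizon: int
    expectations: dict
    notes: str


def _base_toy(**over) -> ModelParameters:
    defaults = dict(
        S=4, c_max=2, g_max=3,
        m_A=0.1, m_T=0.05, m_R=0.01,
        nu=2.0, mu_F=1.0, mu_R=1.0,
        psi=0.0, sigma_F=0.0, sigma_R=0.0,
        k=1e-7, lam=0.2,
    )
    defaults.update(over)
    return ModelParameters(**defaults)


def make_toy_fixture(profile: str, seed: int = 0) -> ToyFixture:
    """Build one of the named toy games.

    Profiles
    --------
    ``no-predation``
        All predation risks 0; foraging has strictly positive net gain.
        Resting forever starves, so at low reserves the converged policy
        must forage (probability ~1).
    ``certain-death-foraging``
        m_A = m_T = 1: any forager is predated this period.  Wherever
        resting cannot starve the individual this period, the policy must
        rest.
    ``enumerable-3state``
        S = 3, deterministic cost 1, two-point gain {0, 2}, two periods:
        small enough for exhaustive enumeration of every path; reference
        values are computed by the independent oracle in the test-suite.
    """
    rng = np.random.default_rng(seed)
    if profile == "no-predation":
        params = _base_toy(m_A=0.0, m_T=0.0, m_R=0.0, nu=2.0, mu_F=1.0, mu_R=1.0)
        return ToyFixture(
            profile, params, horizon=6,
            expectations={"forage_at_low_states": True},
            notes="Without predation the only death is starvation; any state "
                  "from which resting risks hitting 0 must forage.",
        )
    if profile == "certain-death-foraging":
        params = _base_toy(m_A=1.0, m_T=1.0, m_R=0.0, S=5, c_max=1,
                           nu=2.0, mu_F=1.0, mu_R=1.0)
        return ToyFixture(
            profile, params, horizon=1,
            expectations={"rest_where_safe": True},
            notes="Foraging is certain predation; resting costs 1 per period, "
                  "so for the 1-period problem every state x >= 2 must rest "
                  "(longer horizons drain all states to ties at value 0).",
        )
    if profile == "enumerable-3state":
        params = _base_toy(
            S=3, c_max=1, g_max=2,
            m_A=float(rng.uniform(0.05, 0.3)),
            m_T=float(rng.uniform(0.02, 0.05)),
            m_R=float(rng.uniform(0.0, 0.02)),
            nu=1.0, mu_F=1.0, mu_R=1.0,
            psi=1.0,  # two-point-ish gain after discretization
        )
        return ToyFixture(
            profile, params, horizon=2,
            expectations={"oracle": "exhaustive path enumeration"},
            notes="Reference H values / policies come from the brute-force "
                  "oracle shipped with the test-suite.",
        )
    raise ValueError(f"unknown fixture profile {profile!r}")


PROFILES = ("no-predation", "certain-death-foraging", "enumerable-3state")
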