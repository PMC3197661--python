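"""Model parameters and discretized cost/gain distributions.

The model tracks integer energetic reserves ("state units") for a pair of
foragers.  Per-period energetic costs and gains are integer-valued random
variables obtained by discretizing normal distributions onto integer bins;
all other parameters are scalars.  A full parameter set can be written down
directly or derived from six uniform(0, 1) draws using the published
generation formulas (see :func:`derive_parameters`).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
from scipy.stats import norm

__all__ = [
    "COST_NAMES",
    "TABLE_DEFAULTS",
    "ParameterError",
    "DiscreteChangeDistribution",
    "ModelParameters",
    "derive_parameters",
    "discretize_normal",
]

#: Canonical ordering of the four interference costs. ``D_dUsV`` is the extra
#: energetic cost paid by the subordinate when the dominant conducts action U
#: (R = rest, F = forage) and the subordinate conducts action V.
COST_NAMES = ("D_dRsR", "D_dFsR", "D_dRsF", "D_dFsF")

#: Fixed scalar values used for model exploration (state units unless noted).
TABLE_DEFAULTS: Mapping[str, float] = {
    "S": 40,
    "c_max": 4,
    "g_max": 6,
    "k": 1e-7,
    "lam": 0.1,
    "psi": math.sqrt(0.5),
    "sigma_F": math.sqrt(0.5),
    "sigma_R": math.sqrt(0.5),
}


class ParameterError(ValueError):
    """Raised when a parameter set violates the model's invariants."""


@dataclasses.dataclass(frozen=True)
class DiscreteChangeDistribution:
    """A probability distribution over integer state changes.

    Attributes
    ----------
    support : ndarray of int
        Ordered integer values (state units).
    mass : ndarray of float
        Probability attached to each support value; nonnegative, sums to 1.
    """

    support: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=int)
        mass = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "mass", mass)
        if support.shape != mass.shape or support.ndim != 1:
            raise ParameterError("support and mass must be 1-D and aligned")
        if np.any(mass < 0):
            raise ParameterError("probability mass must be nonnegative")
        if abs(mass.sum() - 1.0) > 1e-12:
            raise ParameterError(f"mass sums to {mass.sum()!r}, not 1")

    def mean(self) -> float:
        return float(self.support @ self.mass)

    def point(self) -> int | None:
        """The support value carrying all mass, or None if not degenerate."""
        idx = np.flatnonzero(self.mass > 0)
        return int(self.support[idx[0]]) if idx.size == 1 else None


def discretize_normal(mean: float, sd: float, lo: int, hi: int) -> DiscreteChangeDistribution:
    """Discretize a normal distribution onto the integers ``lo..hi``.

    Each integer v receives the normal CDF increment over [v - 1/2, v + 1/2];
    the tails below ``lo`` and above ``hi`` are folded into the end bins, and
    the result is renormalized to sum to exactly 1.  With ``sd == 0`` the
    distribution degenerates to a point mass at ``mean`` rounded to the
    nearest in-range integer.
    """
    if hi < lo:
        raise ParameterError(f"empty support: hi={hi} < lo={lo}")
    support = np.arange(lo, hi + 1)
    if sd < 0:
        raise ParameterError("sd must be nonnegative")
    if sd == 0:
        mass = np.zeros(support.size)
        target = int(np.clip(np.rint(mean), lo, hi))
        mass[target - lo] = 1.0
        return DiscreteChangeDistribution(support, mass)
    edges = np.concatenate(([-np.inf], support[:-1] + 0.5, [np.inf]))
    cdf = norm.cdf(edges, loc=mean, scale=sd)
    mass = np.diff(cdf)
    mass = mass / mass.sum()
    return DiscreteChangeDistribution(support, mass)


@dataclasses.dataclass(frozen=True)
class ModelParameters:
    """All scalars defining one run of the dyadic foraging game.

    Energetic state lives on the integers 0..S; state 0 is death by
    starvation.  ``m_R``, ``m_T`` and ``m_A`` are per-period predation
    probabilities for resting, foraging together and foraging alone
    (``m_R <= m_T <= m_A``).  Costs/gains are discretized normals with the
    means and s.d.s below, clamped to [0, c_max] and [0, g_max].  The four
    ``D_dUsV`` terms are extra costs paid by the subordinate only, per
    realized action pair.  ``k`` is the decision-error temperature and
    ``lam`` the damping weight placed on a freshly computed best response
    during ESS iteration.
    """

    # predation risks (per period probabilities)
    m_A: float = math.exp(-12.5)
    m_T: float = math.exp(-12.5) * 0.75
    m_R: float = math.exp(-12.5) * 0.75 * 0.75
    # energetics (state units); defaults are the midpoint draws r_i = 0.5
    nu: float = 3.0
    mu_F: float = 1.5
    mu_R: float = 0.75
    psi: float = TABLE_DEFAULTS["psi"]
    sigma_F: float = TABLE_DEFAULTS["sigma_F"]
    sigma_R: float = TABLE_DEFAULTS["sigma_R"]
    # state-space bounds
    S: int = 40
    c_max: int = 4
    g_max: int = 6
    # interference costs paid by the subordinate
    D_dRsR: float = 0.0
    D_dFsR: float = 0.0
    D_dRsF: float = 0.0
    D_dFsF: float = 0.0
    # solver controls
    k: float = TABLE_DEFAULTS["k"]
    lam: float = TABLE_DEFAULTS["lam"]
    tol_backward: float = 1e-9
    tol_ess: float = 1e-8
    max_backward: int = 10_000
    max_ess: int = 5_000

    def __post_init__(self) -> None:
        problems = []
        if not (self.S >= 2 and float(self.S).is_integer()):
            problems.append(f"S must be an integer >= 2, got {self.S}")
        if not (0 <= self.m_R <= self.m_T <= self.m_A <= 1):
            problems.append(
                f"need 0 <= m_R <= m_T <= m_A <= 1, got "
                f"m_R={self.m_R}, m_T={self.m_T}, m_A={self.m_A}"
            )
        if not (0 < self.mu_R <= self.mu_F):
            problems.append(f"need 0 < mu_R <= mu_F, got mu_R={self.mu_R}, mu_F={self.mu_F}")
        if not (self.mu_F <= self.nu):
            problems.append(f"need mu_F <= nu, got mu_F={self.mu_F}, nu={self.nu}")
        if not (1 <= self.nu <= self.g_max):
            problems.append(f"need 1 <= nu <= g_max, got nu={self.nu}")
        if min(self.sigma_F, self.sigma_R, self.psi) < 0:
            problems.append("s.d. parameters must be nonnegative")
        if self.c_max < 1 or self.g_max < 1:
            problems.append("c_max and g_max must be >= 1")
        for name in COST_NAMES:
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if not (0 < self.lam <= 1):
            problems.append(f"need 0 < lam <= 1, got lam={self.lam}")
        if not (self.k > 0):
            problems.append(f"need k > 0, got k={self.k}")
        if problems:
            raise ParameterError("; ".join(problems))

    # -- derived distributions ------------------------------------------------

    def cost_distribution(self, action: str) -> DiscreteChangeDistribution:
        """Per-period energetic cost distribution for 'rest' or 'forage'."""
        if action == "forage":
            return discretize_normal(self.mu_F, self.sigma_F, 0, self.c_max)
        if action == "rest":
            return discretize_normal(self.mu_R, self.sigma_R, 0, self.c_max)
        raise ValueError(f"unknown action {action!r}")

    def gain_distribution(self) -> DiscreteChangeDistribution:
        """Per-period energetic gain distribution while foraging."""
        return discretize_normal(self.nu, self.psi, 0, self.g_max)

    def interference_cost(self, u_dom: str, u_sub: str) -> float:
        """Extra subordinate cost D_dUsV for the realized action pair."""
        key = f"D_d{'F' if u_dom == 'forage' else 'R'}s{'F' if u_sub == 'forage' else 'R'}"
        return getattr(self, key)

    def costs_vector(self) -> tuple[float, float, float, float]:
        return tuple(getattr(self, name) for name in COST_NAMES)

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def derive_parameters(
    r1: float,
    r2: float,
    r3: float,
    r4: float,
    r5: float,
    r6: float,
    **fixed,
) -> ModelParameters:
    """Build a :class:`ModelParameters` from six uniform(0, 1) draws.

    The published generation formulas are::

        m_A  = exp(-25 r1)          nu   = 4 r6 + 1
        m_T  = m_A (1 - r3^2)       mu_F = r4 * nu
        m_R  = m_T (1 - r2^2)       mu_R = r5 * mu_F

    which force the predation-risk ordering ``m_R <= m_T <= m_A`` and the
    cost ordering ``mu_R <= mu_F <= nu``.  Any remaining field (state-space
    bounds, s.d.s, interference costs, solver controls) can be overridden via
    keyword arguments; otherwise the exploration defaults apply.
    """
    draws = {"r1": r1, "r2": r2, "r3": r3, "r4": r4, "r5": r5, "r6": r6}
    for name, value in draws.items():
        if not (0.0 < value < 1.0):
            raise ParameterError(f"draw {name}={value!r} is outside the open interval (0, 1)")
    m_A = math.exp(-25.0 * r1)
    m_T = m_A * (1.0 - r3**2)
    m_R = m_T * (1.0 - r2**2)
    nu = 4.0 * r6 + 1.0
    mu_F = r4 * nu
    mu_R = r5 * mu_F
    return ModelParameters(
        m_A=m_A, m_T=m_T, m_R=m_R, nu=nu, mu_F=mu_F, mu_R=mu_R, **fixed
    )
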