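import numpy as np
import pytest

from dyadforage import (
    ModelParameters,
    PairPolicy,
    behaviour_proportions,
    behaviour_repeat_stats,
    heaviest_sojourn,
    mean_reserves,
    pair_transition_operator,
    stationary_distribution,
)
from dyadforage.kernels import Kernels
from dyadforage.stationary import ACTION_PAIRS, PairStateDistribution, _step_masses


@pytest.fixture(scope="module")
def immortal_params():
    """No predation, near-zero costs: resting pairs never move or die."""
    return ModelParameters(S=3, c_max=1, g_max=2, m_A=0.0, m_T=0.0, m_R=0.0,
                           nu=2.0, mu_F=2e-4, mu_R=1e-4, psi=0.0,
                           sigma_F=0.0, sigma_R=0.0)


def rest_policy(S):
    return PairPolicy(np.zeros((S, S)), np.zeros((S, S)), np.zeros(S), np.zeros(S))


def forage_policy(S):
    return PairPolicy(np.ones((S, S)), np.ones((S, S)), np.ones(S), np.ones(S))


class TestTransitionOperator:
    def test_identity_for_immortal_resters(self, immortal_params):
        T = pair_transition_operator(rest_policy(3), immortal_params)
        np.testing.assert_allclose(T, np.eye(9), atol=1e-14)

    def test_columns_conserve_mass(self, random_params_s20, solved_s20):
        T = pair_transition_operator(solved_s20.policy, random_params_s20)
        col_alive = T.sum(axis=0)
        assert np.all(col_alive <= 1 + 1e-12)
        # leakage is exactly mortality + starvation per source state
        assert np.all(col_alive >= 0)

    def test_three_state_toy_matches_hand_built_table(self):
        """Deterministic rest cost 1, forage net +1, forage-only policy."""
        p = ModelParameters(S=3, c_max=1, g_max=2, m_A=0.2, m_T=0.1, m_R=0.01,
                            nu=2.0, mu_F=1.0, mu_R=1.0, psi=0.0,
                            sigma_F=0.0, sigma_R=0.0)
        T = pair_transition_operator(forage_policy(3), p)
        surv = (1 - 0.1) ** 2  # both forage together
        expected = np.zeros((9, 9))
        up = {1: 2, 2: 3, 3: 3}  # x -> chop(x + 1, 3)
        for xd in (1, 2, 3):
            for xs in (1, 2, 3):
                src = (xd - 1) * 3 + (xs - 1)
                dst = (up[xd] - 1) * 3 + (up[xs] - 1)
                expected[dst, src] = surv
        np.testing.assert_allclose(T, expected, atol=1e-14)


class TestStationaryDistribution:
    def test_absorbing_cycle_gets_all_mass(self, immortal_params):
        # forage: net +2 capped at S: everything drifts to (3, 3) and stays
        dist = stationary_distribution(forage_policy(3), immortal_params)
        assert dist.mass[2, 2] == pytest.approx(1.0, abs=1e-9)

    def test_fixed_point_property(self, random_params_s20, solved_s20):
        dist = stationary_distribution(solved_s20.policy, random_params_s20)
        T = pair_transition_operator(solved_s20.policy, random_params_s20)
        moved = T @ dist.mass.ravel()
        moved /= moved.sum()
        assert np.abs(moved - dist.mass.ravel()).sum() < 1e-8

    def test_matches_eigenvector_oracle(self):
        p = ModelParameters(S=6, c_max=2, g_max=3, m_A=0.1, m_T=0.05, m_R=0.01,
                            nu=2.0, mu_F=1.0, mu_R=0.5)
        rng = np.random.default_rng(2)
        policy = PairPolicy(rng.uniform(size=(6, 6)), rng.uniform(size=(6, 6)),
                            rng.uniform(size=6), rng.uniform(size=6))
        dist = stationary_distribution(policy, p)
        T = pair_transition_operator(policy, p)
        w, v = np.linalg.eig(T)
        lead = np.argmax(w.real)
        vec = np.abs(v[:, lead].real)
        vec /= vec.sum()
        np.testing.assert_allclose(dist.mass.ravel(), vec, atol=1e-8)

    def test_symmetric_when_costs_zero(self, random_params_s20, solved_s20):
        dist = stationary_distribution(solved_s20.policy, random_params_s20)
        np.testing.assert_allclose(dist.mass, dist.mass.T, atol=1e-7)


class TestBehaviourProportions:
    def test_all_forage(self, immortal_params):
        dist = stationary_distribution(forage_policy(3), immortal_params)
        props = behaviour_proportions(forage_policy(3), dist)
        assert props.p_FF == pytest.approx(1.0)
        assert props.p_FR == props.p_RF == props.p_RR == pytest.approx(0.0)

    def test_marginal_additivity_and_sum(self, random_params_s20, solved_s20):
        dist = stationary_distribution(solved_s20.policy, random_params_s20)
        props = behaviour_proportions(solved_s20.policy, dist)
        total = props.p_FF + props.p_FR + props.p_RF + props.p_RR
        assert total == pytest.approx(1.0, abs=1e-10)
        assert props.dom_forage == pytest.approx(props.p_FF + props.p_FR)
        assert props.sub_forage == pytest.approx(props.p_FF + props.p_RF)

    def test_mixed_toy_policy_matches_hand_sum(self):
        mass = np.array([[0.25, 0.25], [0.25, 0.25]])
        dist = PairStateDistribution(mass)
        pol = PairPolicy(np.array([[1.0, 0.0], [1.0, 1.0]]),
                         np.array([[0.5, 0.5], [0.0, 1.0]]),
                         np.zeros(2), np.zeros(2))
        props = behaviour_proportions(pol, dist)
        # p_FF = sum over states of 0.25 * pd * ps
        assert props.p_FF == pytest.approx(0.25 * (1 * 0.5 + 0 * 0.5 + 1 * 0 + 1 * 1))
        assert props.dom_forage == pytest.approx(0.25 * 3)


class TestMeanReserves:
    def test_point_mass(self):
        mass = np.zeros((20, 20))
        mass[19, 9] = 1.0
        assert mean_reserves(PairStateDistribution(mass)) == (20.0, 10.0)

    def test_symmetric_distribution_equal_means(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(size=(5, 5))
        m = m + m.T
        m /= m.sum()
        d, s = mean_reserves(PairStateDistribution(m))
        assert d == pytest.approx(s)


class TestRepeatStats:
    def test_deterministic_resters_repeat_forever(self, immortal_params):
        stats = behaviour_repeat_stats(rest_policy(3), immortal_params,
                                       max_horizon=50)
        assert stats["repeat_dom"] == pytest.approx(1.0)
        assert stats["repeat_sub"] == pytest.approx(1.0)
        assert np.isinf(stats["half_change_time"])

    def test_iid_equiprobable_actions_halve_each_period(self, immortal_params):
        # forage prob 1/2 everywhere, no mortality, so each pair repeats its
        # initial action pair with probability 1/4 each period; the pair-
        # persistence curve crosses 0.5 inside the first period
        policy = PairPolicy.uniform(3)
        stats = behaviour_repeat_stats(policy, immortal_params, max_horizon=50)
        # individual repeat probability is 1/2 by construction
        assert stats["repeat_dom"] == pytest.approx(0.5, abs=1e-9)
        # persistence after t periods is 4^-t: crossing interpolated between
        # p0 = 1 and p1 = 1/4 at t = 2/3
        assert stats["half_change_time"] == pytest.approx((1 - 0.5) / (1 - 0.25))

    def test_monte_carlo_oracle(self, random_params_s20, solved_s20):
        params, policy = random_params_s20, solved_s20.policy
        dist = stationary_distribution(policy, params)
        stats = behaviour_repeat_stats(policy, params, dist=dist)
        rng = np.random.default_rng(123)
        n = 60_000
        kern = Kernels(params)
        # sample initial states from the stationary distribution
        flat = dist.mass.ravel()
        idx = rng.choice(flat.size, size=n, p=flat / flat.sum())
        xd, xs = np.divmod(idx, params.S)
        repeats = {"dom": 0, "sub": 0}
        survivors = 0
        for i in range(n):
            pd = policy.dom[xd[i], xs[i]]
            ps = policy.sub[xd[i], xs[i]]
            u_d = "forage" if rng.random() < pd else "rest"
            u_s = "forage" if rng.random() < ps else "rest"
            if rng.random() < kern.mortality(u_d, u_s) or \
               rng.random() < kern.mortality(u_s, u_d):
                continue
            rowd = kern.plain[u_d][xd[i]]
            rows = kern.sub[(u_d, u_s)][xs[i]]
            nd = rng.choice(params.S + 1, p=rowd)
            ns = rng.choice(params.S + 1, p=rows)
            if nd == 0 or ns == 0:
                continue
            survivors += 1
            pd2 = policy.dom[nd - 1, ns - 1]
            ps2 = policy.sub[nd - 1, ns - 1]
            u_d2 = "forage" if rng.random() < pd2 else "rest"
            u_s2 = "forage" if rng.random() < ps2 else "rest"
            repeats["dom"] += u_d2 == u_d
            repeats["sub"] += u_s2 == u_s
        for typ, key in (("dom", "repeat_dom"), ("sub", "repeat_sub")):
            p_hat = repeats[typ] / survivors
            se = np.sqrt(p_hat * (1 - p_hat) / survivors)
            assert stats[key] == pytest.approx(p_hat, abs=max(3 * se, 1e-3))


class TestHeaviestSojourn:
    def test_frozen_heavier_state_never_ends(self, immortal_params):
        # resting pairs with zero cost never move; mass frozen at x_d > x_s
        mass = np.zeros((3, 3))
        mass[2, 0] = 1.0
        dist = PairStateDistribution(mass)
        heavy_d, heavy_s = heaviest_sojourn(rest_policy(3), immortal_params,
                                            dist=dist)
        assert np.isinf(heavy_d)
        assert heavy_s == 0.0  # subordinate is never the heavier one

    def test_memoryless_exit_is_geometric(self):
        """Exits from the heavier-dominant set are memoryless here, so the
        mean run length must be 1 / (per-period leave probability)."""
        # S = 2: dominant at 2, sub at 1 is the only x_d > x_s state; resting
        # costs are a two-point {0, 1} draw, so the pair leaves the set (by a
        # move or the subordinate starving) with a fixed per-period chance.
        p = ModelParameters(S=2, c_max=1, g_max=1, m_A=0.0, m_T=0.0, m_R=0.0,
                            nu=1.0, mu_F=0.5, mu_R=0.5, psi=0.0,
                            sigma_F=0.0, sigma_R=0.3)
        policy = rest_policy(2)
        kern = Kernels(p)
        mass = np.zeros((2, 2))
        mass[1, 0] = 1.0
        dist = PairStateDistribution(mass)
        stay = 0.0
        for _, moved in _step_masses(kern, policy, dist.mass):
            stay += moved[1, 0]
        assert 0.0 < stay < 1.0  # genuinely two-point cost draw
        heavy_d, _ = heaviest_sojourn(policy, p, dist=dist)
        assert heavy_d == pytest.approx(1.0 / (1.0 - stay))

    def test_monte_carlo_oracle(self, random_params_s20, solved_s20):
        params, policy = random_params_s20, solved_s20.policy
        dist = stationary_distribution(policy, params)
        heavy_d, heavy_s = heaviest_sojourn(policy, params, dist=dist)
        rng = np.random.default_rng(99)
        kern = Kernels(params)
        flat = dist.mass.ravel()
        probs = flat / flat.sum()

        def draw_state():
            i = rng.choice(flat.size, p=probs)
            return i // params.S + 1, i % params.S + 1

        runs = []
        current = 0
        xd, xs = draw_state()
        for _ in range(60_000):
            in_set = xd > xs
            if in_set:
                current += 1
            pd = policy.dom[xd - 1, xs - 1]
            ps = policy.sub[xd - 1, xs - 1]
            u_d = "forage" if rng.random() < pd else "rest"
            u_s = "forage" if rng.random() < ps else "rest"
            dead = (rng.random() < kern.mortality(u_d, u_s)
                    or rng.random() < kern.mortality(u_s, u_d))
            if not dead:
                nd = rng.choice(params.S + 1, p=kern.plain[u_d][xd - 1])
                ns = rng.choice(params.S + 1, p=kern.sub[(u_d, u_s)][xs - 1])
                dead = nd == 0 or ns == 0
            if dead:
                if current > 0:
                    runs.append(current)
                    current = 0
                xd, xs = draw_state()  # replacement pair keeps population stable
                continue
            xd, xs = nd, ns
            if current > 0 and not (xd > xs):
                runs.append(current)
                current = 0
        runs = np.array(runs)
        se = runs.std() / np.sqrt(len(runs))
        assert heavy_d == pytest.approx(runs.mean(), abs=max(3 * se, 0.05))
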