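"""Engine: softmax, state inference, expected free energy, deep inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from mpmath import mp

from stroopeffort.engine import (LevelLink, LevelModel, bayesian_model_average,
                                 efe_decomposition, expected_free_energy,
                                 infer_states, model_from_dict, model_to_dict,
                                 policy_posterior, predict_outcomes,
                                 run_deep_inference, softmax, ambiguity)
from .conftest import enumerate_posterior, random_level_model


# ---------------------------------------------------------------------------
# softmax
# ---------------------------------------------------------------------------

class TestSoftmax:
    def test_symmetry(self):
        assert np.allclose(softmax([0.0, 0.0]), [0.5, 0.5])

    def test_habit_prior_85_15(self):
        # potentials +-0.85 give the 85/15 word-reading habit
        p = softmax([0.85, -0.85])
        assert p[0] == pytest.approx(0.8455, abs=1e-3)
        assert p[1] == pytest.approx(0.1545, abs=1e-3)

    def test_matches_high_precision_oracle(self):
        # arbitrary-precision evaluation of exp/renormalise
        mp.dps = 50
        pots, prec = (2.0, 0.0, -2.0), 0.25
        es = [mp.e ** (prec * x) for x in pots]
        Z = sum(es)
        expected = np.array([float(x / Z) for x in es])
        assert np.allclose(softmax(pots, precision=prec), expected, atol=1e-15)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            softmax([np.inf, 0.0])
        with pytest.raises(ValueError):
            softmax([np.nan, 0.0])

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=6),
           st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance_and_normalisation(self, pots, shift):
        a = softmax(pots)
        b = softmax([p + shift for p in pots])
        assert np.allclose(a, b, atol=1e-12)
        assert a.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(a >= 0)

    def test_stable_for_large_magnitudes(self):
        p = softmax([1000.0, 0.0])
        assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# state inference
# ---------------------------------------------------------------------------

class TestInferStates:
    def test_identity_likelihood_gives_one_hot(self):
        A = [np.eye(3)]
        B = [np.eye(3)[None]]
        m = LevelModel(A=A, B=B, C=[np.zeros(3)], D=[np.full(3, 1 / 3)],
                       E=np.zeros(1), policies=np.zeros((1, 1, 1), int), T=1)
        traj = infer_states(m, [(2,)])
        assert np.allclose(traj.s[0][0][0], [0, 0, 1], atol=1e-12)

    def test_prior_propagation_without_observations(self):
        rng = np.random.default_rng(5)
        m = random_level_model(rng, n_states=(3,), n_outcomes=(3,), T=2,
                               n_actions=(1,), n_policies=1)
        traj = infer_states(m, [])
        expected = m.B[0][0] @ m.D[0]
        assert np.allclose(traj.s[0][0][1], expected, atol=1e-12)
        assert np.allclose(traj.s[0][0][0], m.D[0], atol=1e-12)

    def test_matches_enumeration_two_state_two_step(self, rng):
        m = random_level_model(rng, n_states=(2,), n_outcomes=(3,), T=2,
                               n_actions=(2,), n_policies=2)
        obs = [(1,), (2,)]
        for p in range(2):
            traj = infer_states(m, obs, policy=p)
            exact = enumerate_posterior(m, obs, p)
            assert np.allclose(traj.s[p if False else 0][0], exact, atol=1e-3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_multi_factor(self, seed):
        # randomised models with 2 factors, coupled likelihoods, 3 steps
        rng = np.random.default_rng(seed)
        m = random_level_model(rng, n_states=(2, 3), n_outcomes=(2, 4), T=3,
                               n_actions=(1, 2))
        obs = [(int(rng.integers(2)), int(rng.integers(4))) for _ in range(2)]
        traj = infer_states(m, obs, policy=1)
        exact = enumerate_posterior(m, obs, 1)
        for f in range(2):
            marg = exact.sum(axis=2 - f)
            assert np.allclose(np.stack([traj.s[0][f][t] for t in range(3)]),
                               marg, atol=1e-3)

    def test_posteriors_normalised_and_flow_recorded(self, rng):
        m = random_level_model(rng)
        traj = infer_states(m, [(0, 1)], policy=0)
        for f in range(m.n_factors):
            assert np.allclose(traj.s[0][f].sum(axis=1), 1.0, atol=1e-9)
        assert traj.v_trace and traj.v_trace[0].shape[0] >= 1
        assert traj.epsilon is not None

    def test_rejects_invalid_observation(self, rng):
        m = random_level_model(rng)
        with pytest.raises(ValueError):
            infer_states(m, [(99, 0)])


# ---------------------------------------------------------------------------
# outcome prediction & ambiguity
# ---------------------------------------------------------------------------

class TestPredictOutcomes:
    def test_deterministic_chain(self):
        A = [np.eye(2)]
        m = LevelModel(A=A, B=[np.eye(2)[None]], C=[np.zeros(2)],
                       D=[np.array([0.5, 0.5])], E=np.zeros(1),
                       policies=np.zeros((1, 1, 1), int), T=1)
        o = predict_outcomes(m, [np.array([1.0, 0.0])])[0]
        assert np.allclose(o, [1, 0])
        o = predict_outcomes(m, [np.array([0.5, 0.5])])[0]
        assert np.allclose(o, [0.5, 0.5])

    def test_matches_brute_force_sum(self, rng):
        m = random_level_model(rng, n_states=(2, 2), n_outcomes=(3,),
                               n_actions=(1, 1), T=1, n_policies=1)
        s = [rng.dirichlet([1, 1]), rng.dirichlet([1, 1])]
        o = predict_outcomes(m, s)[0]
        brute = np.zeros(3)
        for i in range(2):
            for j in range(2):
                brute += m.A[0][:, i, j] * s[0][i] * s[1][j]
        assert np.allclose(o, brute, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        m = random_level_model(rng)
        with pytest.raises(ValueError):
            predict_outcomes(m, [np.array([0.5, 0.5])])


class TestAmbiguity:
    def test_deterministic_likelihood_zero(self):
        m = LevelModel(A=[np.eye(4)], B=[np.eye(4)[None]], C=[np.zeros(4)],
                       D=[np.full(4, 0.25)], E=np.zeros(1),
                       policies=np.zeros((1, 1, 1), int), T=1)
        assert np.allclose(ambiguity(m), 0.0, atol=1e-12)

    def test_uniform_outcome_gives_log_K(self):
        K = 5
        A = [np.full((K, 2), 1 / K)]
        m = LevelModel(A=A, B=[np.eye(2)[None]], C=[np.zeros(K)],
                       D=[np.array([0.5, 0.5])], E=np.zeros(1),
                       policies=np.zeros((1, 1, 1), int), T=1)
        assert np.allclose(ambiguity(m), np.log(K), atol=1e-12)

    def test_matches_direct_entropy(self, rng):
        m = random_level_model(rng)
        H = ambiguity(m)
        direct = np.zeros(m.n_joint)
        for a in m.A_flat:
            direct -= np.sum(a * np.log(a), axis=0)
        assert np.allclose(H, direct, atol=1e-10)
        _, expec = ambiguity(m, [np.full(2, 0.5), np.full(3, 1 / 3)])
        assert expec >= 0


# ---------------------------------------------------------------------------
# expected free energy
# ---------------------------------------------------------------------------

class TestExpectedFreeEnergy:
    def _one_step(self, A, C, s):
        m = LevelModel(A=[A], B=[np.eye(A.shape[1])[None]], C=[C],
                       D=[s], E=np.zeros(1),
                       policies=np.zeros((1, 1, 1), int), T=1)
        traj = infer_states(m, [])
        return m, traj

    def test_zero_when_no_preferences_and_deterministic(self):
        m, traj = self._one_step(np.eye(2), np.zeros(2), np.array([1.0, 0.0]))
        assert expected_free_energy(m, traj, 0) == pytest.approx(0.0, abs=1e-9)

    def test_preferred_outcomes_lower_G(self):
        C = np.array([1.0, -1.0])
        m1, t1 = self._one_step(np.eye(2), C, np.array([1.0, 0.0]))
        m2, t2 = self._one_step(np.eye(2), C, np.array([0.0, 1.0]))
        assert expected_free_energy(m1, t1, 0) < expected_free_energy(m2, t2, 0)

    def test_matches_term_by_term_hand_evaluation(self, rng):
        A = np.array([[0.7, 0.2, 0.1], [0.3, 0.8, 0.9]])
        C = np.array([0.5, -0.5])
        s = np.array([0.2, 0.5, 0.3])
        m, traj = self._one_step(A, C, s)
        o = A @ s
        risk = float(o @ (np.log(o) - C))
        H = -np.sum(A * np.log(A), axis=0)
        expected = risk + float(H @ s)
        assert expected_free_energy(m, traj, 0) == pytest.approx(expected,
                                                                 abs=1e-10)


class TestEfeDecomposition:
    def test_independent_outcome_zero_mutual_information(self):
        A = np.tile(np.array([[0.3], [0.7]]), (1, 3))  # identical columns
        m = LevelModel(A=[A], B=[np.eye(3)[None]], C=[np.zeros(2)],
                       D=[np.full(3, 1 / 3)], E=np.zeros(1),
                       policies=np.zeros((1, 1, 1), int), T=1)
        traj = infer_states(m, [])
        _, mi = efe_decomposition(m, traj, 0)
        assert mi[0] == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_likelihood_flat_state_gives_log_K(self):
        K = 3
        m = LevelModel(A=[np.eye(K)], B=[np.eye(K)[None]], C=[np.zeros(K)],
                       D=[np.full(K, 1 / K)], E=np.zeros(1),
                       policies=np.zeros((1, 1, 1), int), T=1)
        traj = infer_states(m, [])
        _, mi = efe_decomposition(m, traj, 0)
        assert mi[0] == pytest.approx(np.log(K), abs=1e-6)

    @pytest.mark.parametrize("seed", range(25))
    def test_recombination_equals_expected_free_energy(self, seed):
        rng = np.random.default_rng(seed)
        m = random_level_model(rng, preferences=True)
        traj = infer_states(m, [(0, 1)], policy=0)
        G = expected_free_energy(m, traj, 0)
        pref, mi = efe_decomposition(m, traj, 0)
        assert G == pytest.approx(pref.sum() - mi.sum(), abs=1e-8)


# ---------------------------------------------------------------------------
# policy posterior and model averaging
# ---------------------------------------------------------------------------

class TestPolicyPosterior:
    def test_uniform_when_everything_flat(self):
        assert np.allclose(policy_posterior(np.zeros(3), np.zeros(3)), 1 / 3)

    def test_habit_only_when_G_constant(self):
        E = np.array([-0.85, 0.85])
        pi = policy_posterior(np.full(2, 7.3), E)
        assert np.allclose(pi, softmax(-E), atol=1e-12)
        assert pi[0] == pytest.approx(0.845, abs=1e-3)

    def test_mass_shifts_with_G(self):
        E = np.array([-0.85, 0.85])
        G = np.array([5.0, 0.0])
        pi = policy_posterior(G, E)
        direct = softmax(-(E + G))
        assert np.allclose(pi, direct, atol=1e-12)
        assert pi[1] > softmax(-E)[1]

    def test_shift_invariance(self, rng):
        G = rng.normal(size=4)
        E = rng.normal(size=4)
        base = policy_posterior(G, E)
        assert np.allclose(policy_posterior(G + 3.3, E), base, atol=1e-12)
        assert np.allclose(policy_posterior(G, E - 1.7), base, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            policy_posterior(np.zeros(2), np.zeros(3))


class TestBayesianModelAverage:
    def test_one_hot_returns_that_policy(self):
        posts = [[np.array([1.0, 0.0])], [np.array([0.2, 0.8])]]
        out = bayesian_model_average(np.array([0.0, 1.0]), posts)
        assert np.allclose(out[0], [0.2, 0.8])

    def test_convex_combination(self):
        posts = [[np.array([1.0, 0.0])], [np.array([0.0, 1.0])]]
        out = bayesian_model_average(np.array([0.3, 0.7]), posts)
        assert np.allclose(out[0], [0.3, 0.7], atol=1e-12)


# ---------------------------------------------------------------------------
# deep inference
# ---------------------------------------------------------------------------

def _toy_levels(seed=0, slow_T=2):
    rng = np.random.default_rng(seed)
    a = rng.random((2, 2)) + 0.2
    As = [a / a.sum(0, keepdims=True)]
    b = rng.random((2, 2, 2)) + 0.2
    Bs = [b / b.sum(1, keepdims=True)]
    slow = LevelModel(A=As, B=Bs, C=[np.zeros(2)], D=[rng.dirichlet([2, 2])],
                      E=np.zeros(2),
                      policies=np.array([[[0]] * slow_T, [[1]] * slow_T]),
                      T=slow_T)
    af = rng.random((2, 2)) + 0.2
    Af = [af / af.sum(0, keepdims=True)]
    bf = rng.random((1, 2, 2)) + 0.2
    Bf = [bf / bf.sum(1, keepdims=True)]
    fast = LevelModel(A=Af, B=Bf, C=[np.zeros(2)], D=[np.array([0.5, 0.5])],
                      E=np.zeros(1), policies=np.zeros((1, 1, 1), int), T=2)
    return slow, fast


class TestDeepInference:
    def test_uninformative_fast_evidence_leaves_prior(self):
        slow, fast = _toy_levels()
        # uniform fast likelihood => ascending message constant
        fast_flat = LevelModel(A=[np.full((2, 2), 0.5)], B=fast.B,
                               C=fast.C, D=fast.D, E=fast.E,
                               policies=fast.policies, T=2)
        link = LevelLink({0: 0})
        obs = [[(0,), (1,)], [(1,), (0,)]]
        traj, _ = run_deep_inference(slow, fast_flat, link, obs)
        prior = np.stack([slow.D[0], slow.B[0][0] @ slow.D[0]])
        assert np.allclose(traj.s[0][0], prior, atol=1e-9)

    def test_deterministic_chain_concentrates(self):
        # deterministic slow likelihood + one-hot fast evidence pins the slow state
        slow = LevelModel(A=[np.eye(2)], B=[np.eye(2)[None].repeat(1, 0)],
                          C=[np.zeros(2)], D=[np.array([0.5, 0.5])],
                          E=np.zeros(1), policies=np.zeros((1, 1, 1), int), T=1)
        fast = LevelModel(A=[np.eye(2)], B=[np.eye(2)[None]], C=[np.zeros(2)],
                          D=[np.array([0.5, 0.5])], E=np.zeros(1),
                          policies=np.zeros((1, 1, 1), int), T=1)
        link = LevelLink({0: 0})
        traj, _ = run_deep_inference(slow, fast, link, [[(1,)]])
        assert np.allclose(traj.s[0][0][0], [0, 1], atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_two_level_joint_enumeration(self, seed):
        slow, fast = _toy_levels(seed)
        link = LevelLink({0: 0})
        obs = [[(0,), (1,)], [(1,), (1,)]]
        traj, _ = run_deep_inference(slow, fast, link, obs)
        for pol in range(2):
            num = np.zeros((2, 2))
            for s1 in range(2):
                for s2 in range(2):
                    p = slow.D[0][s1] * slow.B[0][slow.policies[pol, 0, 0], s2, s1]
                    for t, s in enumerate((s1, s2)):
                        lt = 0.0
                        for i in range(2):
                            for j in range(2):
                                lt += (slow.A[0][i, s] * fast.B[0][0, j, i]
                                       * fast.A[0][obs[t][0][0], i]
                                       * fast.A[0][obs[t][1][0], j])
                        p *= lt
                    num[s1, s2] += p
            num /= num.sum()
            assert np.allclose(traj.s[pol][0][0], num.sum(1), atol=1e-9)
            assert np.allclose(traj.s[pol][0][1], num.sum(0), atol=1e-9)

    def test_link_cardinality_mismatch_rejected(self):
        slow, fast = _toy_levels()
        bad_fast = LevelModel(A=[np.eye(3)], B=[np.eye(3)[None]],
                              C=[np.zeros(3)], D=[np.full(3, 1 / 3)],
                              E=np.zeros(1), policies=np.zeros((1, 1, 1), int),
                              T=1)
        with pytest.raises(ValueError):
            run_deep_inference(slow, bad_fast, LevelLink({0: 0}), [[(0,)]])


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def test_model_round_trips_through_dict(rng):
    m = random_level_model(rng)
    m2 = model_from_dict(model_to_dict(m))
    for a, b in zip(m.A, m2.A):
        assert np.allclose(a, b)
    assert np.allclose(m.E, m2.E)
    assert np.array_equal(m.policies, m2.policies)
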