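import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comra.cmr import (
    A_MIN,
    CMRParams,
    NoItemsAvailable,
    context_input,
    drift_context,
    encode_list,
    init_agent,
    recall_item_update,
    retrieval_activations,
    sample_recall,
    simulate_individual_recall,
    stop_probability,
)
from comra.semantic import SemanticSpace

from conftest import orthogonal_space


class TestParams:
    def test_defaults_valid(self):
        CMRParams()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(beta_enc=1.5),
            dict(beta_rec=-0.1),
            dict(p_cue=2.0),
            dict(tau=0.0),
            dict(eps_d=-1.0),
            dict(s_sem=-0.5),
        ],
    )
    def test_bounds_enforced(self, kwargs):
        with pytest.raises(ValueError):
            CMRParams(**kwargs)

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            CMRParams.from_dict({"beta_enc": 0.5, "bogus": 1.0})

    def test_json_round_trip(self, tmp_path):
        p = CMRParams(beta_enc=0.33, p_cue=0.7)
        path = tmp_path / "params.json"
        p.to_json(path)
        assert CMRParams.from_json(path) == p


class TestInitAgent:
    def test_zero_semantic_scaling(self, desk_space):
        agent = init_agent(desk_space, CMRParams(s_sem=0.0))
        assert np.all(agent.m_cf == 0.0)

    def test_context_unit_norm(self, desk_space, params):
        agent = init_agent(desk_space, params)
        assert np.linalg.norm(agent.context) == pytest.approx(1.0, abs=1e-9)

    def test_context_orthogonal_to_items(self, desk_space, params):
        agent = init_agent(desk_space, params)
        assert np.allclose(agent.item_dirs @ agent.context, 0.0)

    def test_semantic_cross_activation_ratio(self):
        # items 0,1 at cosine 0.9; item 2 orthogonal to both
        v = np.array([[1.0, 0.0, 0.0], [0.9, np.sqrt(1 - 0.81), 0.0], [0.0, 0.0, 1.0]])
        space = SemanticSpace(items=("a", "b", "c"), vectors=v)
        agent = init_agent(space, CMRParams(s_sem=1.0))
        # context aligned with item 0's direction
        a = agent.m_cf @ agent.item_dirs[0]
        assert a[1] == pytest.approx(0.9, abs=1e-9)
        assert a[2] == pytest.approx(0.0, abs=1e-9)


class TestDrift:
    def test_beta_zero_identity(self, rng):
        c = rng.standard_normal(5)
        c /= np.linalg.norm(c)
        c_in = rng.standard_normal(5)
        c_in /= np.linalg.norm(c_in)
        assert np.allclose(drift_context(c, c_in, 0.0), c)

    def test_beta_one_orthogonal_replaces(self):
        c = np.array([1.0, 0.0])
        c_in = np.array([0.0, 1.0])
        assert np.allclose(drift_context(c, c_in, 1.0), c_in)

    def test_half_beta_orthogonal_closed_form(self):
        c = np.array([1.0, 0.0])
        c_in = np.array([0.0, 1.0])
        out = drift_context(c, c_in, 0.5)
        assert np.allclose(out, np.array([np.sqrt(0.75), 0.5]))
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_beta(self):
        with pytest.raises(ValueError):
            drift_context(np.array([1.0, 0.0]), np.array([0.0, 1.0]), 1.5)

    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0.0, 1.0),
        st.integers(2, 20),
    )
    @settings(max_examples=200, deadline=None)
    def test_norm_preserved(self, seed, beta, dim):
        rng = np.random.default_rng(seed)
        c = rng.standard_normal(dim)
        c /= np.linalg.norm(c)
        c_in = rng.standard_normal(dim)
        c_in /= np.linalg.norm(c_in)
        out = drift_context(c, c_in, beta)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-9)


class TestEncode:
    def test_zero_learning_rates(self, desk_space):
        p = CMRParams(gamma_fc=0.0, gamma_cf=0.0, s_sem=1.0)
        agent = init_agent(desk_space, p)
        m_fc0, m_cf0, c0 = agent.m_fc.copy(), agent.m_cf.copy(), agent.context.copy()
        encode_list(agent, np.arange(desk_space.n_items), p)
        assert np.array_equal(agent.m_fc, m_fc0)
        assert np.array_equal(agent.m_cf, m_cf0)
        assert not np.allclose(agent.context, c0)

    def test_no_primacy_equal_weights(self):
        space = orthogonal_space(3)
        p = CMRParams(phi_s=0.0, s_sem=0.0, beta_enc=0.0)
        agent = init_agent(space, p)
        encode_list(agent, [0, 1, 2], p)
        # with beta_enc=0 every item binds the same start context equally
        assert np.allclose(agent.m_cf[0], agent.m_cf[1])
        assert np.allclose(agent.m_cf[1], agent.m_cf[2])

    def test_primacy_boost_scales_first_position(self):
        space = orthogonal_space(3)
        p = CMRParams(phi_s=2.0, phi_d=100.0, s_sem=0.0, beta_enc=0.0)
        agent = init_agent(space, p)
        encode_list(agent, [0, 1, 2], p)
        assert np.allclose(agent.m_cf[0], 3.0 * agent.m_cf[1])

    def test_not_permutation_rejected(self, desk_space, params):
        agent = init_agent(desk_space, params)
        with pytest.raises(ValueError):
            encode_list(agent, [0, 0, 1], params)

    def test_two_item_orthogonal_closed_form(self):
        """Independent 2x2 algebra oracle for end-of-list activations."""
        beta = 0.5
        space = orthogonal_space(2)
        p = CMRParams(beta_enc=beta, gamma_cf=1.0, gamma_fc=0.3, s_sem=0.0, phi_s=0.0)
        agent = init_agent(space, p)
        encode_list(agent, [0, 1], p)
        a = retrieval_activations(agent)
        # oracle: c0 = start; item0 binds c0; c1 = sqrt(1-b^2) c0 + b e0;
        # item1 binds c1; c2 = sqrt(1-b^2) c1 + b e1 (all inputs orthogonal)
        r = np.sqrt(1 - beta**2)
        # a0 = c0 . c2 = r^2 ; a1 = c1 . c2 = r
        assert a[0] == pytest.approx(r**2, abs=1e-12)
        assert a[1] == pytest.approx(r, abs=1e-12)

    def test_recency_gradient_closed_form(self):
        """cos(end-of-list context, item input at position p) = b(1-b^2)^((L-p)/2)."""
        L, b = 6, 0.45
        space = orthogonal_space(L)
        p = CMRParams(beta_enc=b, s_sem=0.0, gamma_fc=0.0)
        agent = init_agent(space, p)
        order = np.arange(L)
        encode_list(agent, order, p)
        cosines = agent.item_dirs @ agent.context
        expected = np.array([b * (1 - b * b) ** ((L - k) / 2) for k in range(1, L + 1)])
        assert np.allclose(cosines, expected, atol=1e-10)
        assert np.all(np.diff(cosines) > 0)  # recency: later items closer


class TestRetrievalAndSampling:
    def test_floor_applied(self, desk_space):
        p = CMRParams(s_sem=0.0)
        agent = init_agent(desk_space, p)
        assert np.all(retrieval_activations(agent) == A_MIN)

    def test_argmax_alignment(self):
        space = orthogonal_space(1, extra_dim=1)
        p = CMRParams(s_sem=0.0, beta_enc=1.0)
        agent = init_agent(space, p)
        encode_list(agent, [0], p)
        agent.context = agent.m_cf[0] / np.linalg.norm(agent.m_cf[0])
        assert int(np.argmax(retrieval_activations(agent))) == 0

    def test_matches_direct_product(self, desk_space, params, rng):
        agent = init_agent(desk_space, params)
        encode_list(agent, rng.permutation(desk_space.n_items), params)
        direct = np.maximum(agent.m_cf @ agent.context, A_MIN)
        assert np.allclose(retrieval_activations(agent), direct)

    def test_equal_activations_symmetric(self, rng):
        a = np.array([0.7, 0.7])
        draws = [sample_recall(a, set(), 2.3, rng) for _ in range(10000)]
        freq = np.mean(np.array(draws) == 0)
        se = np.sqrt(0.25 / 10000)
        assert abs(freq - 0.5) < 3 * se

    def test_large_tau_argmax(self, rng):
        a = np.array([1.0, 2.0, 1.5])
        draws = [sample_recall(a, set(), 200.0, rng) for _ in range(200)]
        assert all(d == 1 for d in draws)

    def test_exact_normalization(self, rng):
        a = np.array([1.0, 2.0, 1.0])
        n = 50000
        draws = np.array([sample_recall(a, set(), 1.0, rng) for _ in range(n)])
        for item, p_true in [(0, 0.25), (1, 0.5), (2, 0.25)]:
            freq = np.mean(draws == item)
            se = np.sqrt(p_true * (1 - p_true) / n)
            assert abs(freq - p_true) < 3 * se

    def test_excluded_respected(self, rng):
        a = np.array([1.0, 1.0, 1.0])
        assert sample_recall(a, {0, 2}, 1.0, rng) == 1

    def test_all_excluded(self, rng):
        with pytest.raises(NoItemsAvailable):
            sample_recall(np.array([1.0]), {0}, 1.0, rng)


class TestStopProbability:
    def test_inverse_scaling(self):
        p1 = stop_probability(2, CMRParams(eps_d=1.0, theta_r=0.1))
        p2 = stop_probability(2, CMRParams(eps_d=2.0, theta_r=0.1))
        assert p1 == pytest.approx(2.0 * p2)

    def test_flat_hazard(self):
        p = CMRParams(eps_d=0.5, theta_r=0.0)
        assert stop_probability(0, p) == stop_probability(10, p)

    def test_cap_reached(self):
        assert stop_probability(0, CMRParams(eps_d=0.05, theta_r=0.0)) == 1.0
        assert stop_probability(7, CMRParams(eps_d=0.05, theta_r=0.0)) == 1.0

    def test_nondecreasing_in_position(self):
        p = CMRParams(eps_d=1.0, theta_r=0.2)
        vals = [stop_probability(k, p) for k in range(20)]
        assert np.all(np.diff(vals) >= 0)

    def test_negative_position_rejected(self, params):
        with pytest.raises(ValueError):
            stop_probability(-1, params)


class TestRecallUpdate:
    def test_beta_rec_zero(self, desk_space, rng):
        p = CMRParams(beta_rec=0.0)
        agent = init_agent(desk_space, p)
        encode_list(agent, rng.permutation(desk_space.n_items), p)
        c0 = agent.context.copy()
        recall_item_update(agent, 5, p)
        assert np.allclose(agent.context, c0)

    def test_cosine_strictly_increases(self, desk_space, params, rng):
        agent = init_agent(desk_space, params)
        encode_list(agent, rng.permutation(desk_space.n_items), params)
        item = 7
        before = float(np.dot(agent.context, context_input(agent, item)))
        recall_item_update(agent, item, params)
        after = float(np.dot(agent.context, context_input(agent, item)))
        assert after > before

    def test_repeated_updates_converge(self, desk_space, params, rng):
        agent = init_agent(desk_space, params)
        encode_list(agent, rng.permutation(desk_space.n_items), params)
        item = 2
        cosines = []
        for _ in range(40):
            recall_item_update(agent, item, params)
            cosines.append(float(np.dot(agent.context, context_input(agent, item))))
        assert np.all(np.diff(cosines) >= -1e-12)
        assert cosines[-1] == pytest.approx(1.0, abs=1e-6)

    def test_trajectory_bookkeeping(self, desk_space, params, rng):
        agent = init_agent(desk_space, params)
        encode_list(agent, rng.permutation(desk_space.n_items), params)
        for k in range(5):
            recall_item_update(agent, k, params)
        assert len(agent.context_trajectory) == 1 + 5


def _oracle_drift(c, c_in, beta):
    dot = float(c @ c_in)
    rho = np.sqrt(1 + beta**2 * (dot**2 - 1)) - beta * dot
    out = rho * c + beta * c_in
    return out / np.linalg.norm(out)


def _enumerate_sequences(agent, params, max_len):
    """Exact probability of every recall sequence of a tiny encoded agent."""
    n = agent.n_items
    cues = [agent.m_fc[:, i] / np.linalg.norm(agent.m_fc[:, i]) for i in range(n)]
    probs = {}

    def visit(seq, c, prob):
        pos = len(seq)
        p_stop = min(1.0, (0.05 / params.eps_d) * np.exp(params.theta_r * pos))
        if pos == max_len:
            probs[seq] = probs.get(seq, 0.0) + prob
            return
        probs[seq] = probs.get(seq, 0.0) + prob * p_stop
        a = np.maximum(agent.m_cf @ c, A_MIN)
        avail = [i for i in range(n) if i not in seq]
        w = a[avail] ** params.tau
        w = w / w.sum()
        for i, pi in zip(avail, w):
            visit(seq + (i,), _oracle_drift(c, cues[i], params.beta_rec), prob * (1 - p_stop) * pi)

    visit((), agent.context.copy(), 1.0)
    return probs


class TestIndividualRecall:
    def test_forced_immediate_stop(self, desk_space, rng):
        p = CMRParams(eps_d=0.05, theta_r=0.0)  # stop probability 1 everywhere
        agent = init_agent(desk_space, p)
        encode_list(agent, rng.permutation(desk_space.n_items), p)
        assert simulate_individual_recall(agent, p, rng) == []
        assert agent.stopped

    def test_exhaustive_recall(self, desk_space, rng):
        p = CMRParams(eps_d=1e9, theta_r=0.0)  # stop probability ~0
        agent = init_agent(desk_space, p)
        encode_list(agent, rng.permutation(desk_space.n_items), p)
        seq = simulate_individual_recall(agent, p, rng)
        assert sorted(seq) == list(range(desk_space.n_items))

    def test_no_duplicates_property(self, desk_space, params):
        rng = np.random.default_rng(77)
        for _ in range(50):
            agent = init_agent(desk_space, params)
            encode_list(agent, rng.permutation(desk_space.n_items), params)
            seq = simulate_individual_recall(agent, params, rng)
            assert len(seq) == len(set(seq))

    @pytest.mark.parametrize("list_len", [3, 4])
    def test_first_recall_matches_enumeration(self, list_len):
        p = CMRParams(eps_d=0.25, theta_r=0.0, tau=2.0, beta_rec=0.6)
        space = orthogonal_space(list_len)
        proto = init_agent(space, p)
        encode_list(proto, np.arange(list_len), p)
        exact = _enumerate_sequences(proto, p, list_len)
        first_exact = np.zeros(list_len)
        for seq, prob in exact.items():
            if seq:
                first_exact[seq[0]] += prob
        first_exact /= first_exact.sum()

        n_runs = 20000
        rng = np.random.default_rng(9)
        counts = np.zeros(list_len)
        n_nonempty = 0
        for _ in range(n_runs):
            agent = init_agent(space, p)
            encode_list(agent, np.arange(list_len), p)
            seq = simulate_individual_recall(agent, p, rng)
            if seq:
                counts[seq[0]] += 1
                n_nonempty += 1
        freq = counts / n_nonempty
        se = np.sqrt(first_exact * (1 - first_exact) / n_nonempty)
        assert np.all(np.abs(freq - first_exact) <= 3 * se + 1e-12)

    def test_sequence_distribution_matches_enumeration(self):
        p = CMRParams(eps_d=0.25, theta_r=0.0, tau=2.0, beta_rec=0.6)
        space = orthogonal_space(3)
        proto = init_agent(space, p)
        encode_list(proto, np.arange(3), p)
        exact = _enumerate_sequences(proto, p, 3)
        assert sum(exact.values()) == pytest.approx(1.0, abs=1e-10)

        n_runs = 20000
        rng = np.random.default_rng(11)
        counts: dict = {}
        for _ in range(n_runs):
            agent = init_agent(space, p)
            encode_list(agent, np.arange(3), p)
            seq = tuple(simulate_individual_recall(agent, p, rng))
            counts[seq] = counts.get(seq, 0) + 1
        for seq, prob in exact.items():
            freq = counts.get(seq, 0) / n_runs
            se = np.sqrt(prob * (1 - prob) / n_runs)
            assert abs(freq - prob) <= 3 * se + 1e-12

    def test_sampling_shifts_toward_just_recalled(self):
        """After recalling an item, the next-draw distribution favors items
        with closer study/semantic contexts (exact computation, 3-item toy)."""
        v = np.array([[1.0, 0.0, 0.0], [0.95, np.sqrt(1 - 0.95**2), 0.0], [0.0, 0.0, 1.0]])
        space = SemanticSpace(items=("a", "b", "c"), vectors=v)
        p = CMRParams(beta_enc=0.4, beta_rec=0.8, s_sem=1.0, tau=1.0)
        agent = init_agent(space, p)
        encode_list(agent, [2, 1, 0], p)  # item 0 studied last
        a_before = retrieval_activations(agent)
        p_before = a_before / a_before.sum()
        recall_item_update(agent, 0, p)
        a_after = retrieval_activations(agent)
        # relative preference for item 1 (semantically close to 0) over item 2
        assert a_after[1] / a_after[2] > a_before[1] / a_before[2]
        assert p_before[0] > 0  # sanity
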