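import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from gonogo import active_inference as ai
from gonogo.taskenv import CONTEXTS, GO, NOGO, Context, make_schedule


def params_with(base, **kw):
    return ai.AIParams(**{**base, **kw})


class TestStateSpace:
    def test_sixteen_states_twelve_reachable(self):
        assert ai.STATE_SPACE.n_states == 16
        assert ai.STATE_SPACE.n_reachable == 12

    def test_transitions_column_stochastic_and_block_diagonal(self):
        for B in (ai.B_GO, ai.B_NOGO):
            np.testing.assert_allclose(B.sum(axis=0), 1.0)
            for ci in range(4):
                for cj in range(4):
                    if ci != cj:
                        assert not B[ci * 4:(ci + 1) * 4, cj * 4:(cj + 1) * 4].any()

    def test_initial_state_reaches_optimal_outcome_at_08(self):
        sp = ai.STATE_SPACE
        j = sp.index("initial", Context.G2W)
        assert ai.B_GO[sp.index("win", Context.G2W), j] == pytest.approx(0.8)
        assert ai.B_NOGO[sp.index("win", Context.G2W), j] == pytest.approx(0.2)

    def test_outcome_states_absorbing(self):
        sp = ai.STATE_SPACE
        for kind, ctx in sp.states:
            if kind != "initial":
                j = sp.index(kind, ctx)
                assert ai.B_GO[j, j] == 1.0 and ai.B_NOGO[j, j] == 1.0


class TestContextPrior:
    def test_symmetric_beliefs_give_uniform_prior(self, ai_means):
        p = params_with(ai_means, p_W=0.5, p_go_W=0.5, p_nogo_AL=0.5)
        np.testing.assert_allclose(ai.context_prior(p), 0.25)

    def test_degenerate_prior_concentrates(self, ai_means):
        p = params_with(ai_means, p_W=1 - 1e-12, p_go_W=1 - 1e-12)
        d0 = ai.context_prior(p)
        assert d0[Context.G2W.index] == pytest.approx(1.0)

    def test_table_values_multiply(self, ai_means):
        d0 = ai.context_prior(ai.AIParams(**ai_means))
        assert d0[Context.G2W.index] == pytest.approx(0.5163 * 0.5211)
        assert d0.sum() == pytest.approx(1.0)


class TestPreferences:
    def test_flat_temperature_limit_follows_context_prior(self, ai_means):
        p = params_with(ai_means, c_tau=1e-9)
        c = ai.preferences(p)
        d0 = ai.context_prior(p)
        sp = ai.STATE_SPACE
        for ctx in CONTEXTS:
            kinds = ("win", "null") if ctx.is_win else ("null", "lose")
            mass = sum(c[sp.index(k, ctx)] for k in kinds)
            assert mass == pytest.approx(d0[ctx.index], rel=1e-6)

    def test_greedy_limit_prefers_win_states(self, ai_means):
        c = ai.preferences(params_with(ai_means, c_tau=30.0))
        sp = ai.STATE_SPACE
        win_mass = sum(c[sp.index("win", ctx)] for ctx in CONTEXTS if ctx.is_win)
        assert win_mass > 0.99

    def test_extreme_temperature_raises(self, ai_means):
        with pytest.raises(ValueError):
            ai.preferences(params_with(ai_means, c_tau=1e5))


class TestPolicyQuality:
    def test_worked_single_destination_terms(self):
        # the win-outcome contributions quoted for go vs no-go in G2W
        assert round(ai.kl_quality_term(0.8, 0.31), 2) == -0.76
        assert round(ai.kl_quality_term(0.8, 0.003), 2) == -4.47

    def test_entries_nonpositive(self, ai_means):
        q = ai.initial_state_quality(ai.AIParams(**ai_means))
        assert q.shape == (2, 4)
        assert np.all(q <= 0)

    def test_zero_divergence_when_prediction_matches_preference(self):
        B = np.zeros((2, 2))
        B[1, 0] = 1.0
        B[1, 1] = 1.0
        c = np.array([0.0, 1.0])
        q = ai.policy_quality(B, B, c)
        assert q[0, 0] == pytest.approx(0.0)

    def test_full_matrix_agrees_with_neg_kl(self, ai_means):
        p = ai.AIParams(**ai_means)
        c = ai.preferences(p)
        q = ai.policy_quality(ai.B_GO, ai.B_NOGO, c)
        sp = ai.STATE_SPACE
        j = sp.index("initial", Context.G2W)
        col = ai.B_GO[:, j]
        nz = col > 0
        kl = np.sum(col[nz] * (np.log(col[nz]) - np.log(c[nz])))
        assert q[1, j] == pytest.approx(-kl)


class TestPrecision:
    def test_gamma_equals_alpha_when_quality_vanishes(self):
        rng = np.random.default_rng(0)
        for alpha in 10 ** rng.uniform(-2, 2, size=100):
            gamma, _, _ = ai.infer_precision(np.zeros((2, 4)), np.full(4, 0.25), alpha)
            assert gamma == pytest.approx(alpha, abs=1e-9)

    def test_fixed_point_matches_root_finder(self):
        # oracle: gamma solves gamma * (1 - qbar(gamma)) = alpha with
        # qbar the softmax-weighted mean policy quality
        q = np.array([-4.47, -0.76])  # (nogo, go)
        s = np.array([1.0, 0.0, 0.0, 0.0])
        Q = np.zeros((2, 4))
        Q[:, 0] = q
        alpha = 1.627

        def qbar(g):
            w = np.exp(g * q - np.max(g * q))
            w /= w.sum()
            return float(w @ q)

        root = brentq(lambda g: g * (1 - qbar(g)) - alpha, 1e-9, alpha)
        gamma, pi_hat, _ = ai.infer_precision(Q, s, alpha)
        assert gamma == pytest.approx(root, abs=1e-5)
        # and the policy posterior is the plain softmax at that precision
        w = np.exp(gamma * q - np.max(gamma * q))
        np.testing.assert_allclose(pi_hat, w / w.sum(), atol=1e-6)

    @given(st.floats(0.05, 20.0))
    def test_monotone_in_alpha(self, alpha):
        Q = np.zeros((2, 4))
        Q[0, :] = -3.0
        Q[1, :] = -0.5
        s = np.full(4, 0.25)
        g1, _, _ = ai.infer_precision(Q, s, alpha)
        g2, _, _ = ai.infer_precision(Q, s, 2 * alpha)
        assert g2 > g1
        assert 0 < g1 <= alpha + 1e-12


class TestForgetting:
    def test_no_forgetting_keeps_stored(self):
        d = np.array([0.7, 0.1, 0.1, 0.1])
        d0 = np.full(4, 0.25)
        np.testing.assert_allclose(ai.forget(d, d0, 0.0, 5), d)

    def test_full_forgetting_resets_to_prior(self):
        d = np.array([0.7, 0.1, 0.1, 0.1])
        d0 = np.array([0.4, 0.3, 0.2, 0.1])
        np.testing.assert_allclose(ai.forget(d, d0, 1.0, 3), d0)

    def test_single_gap_is_convex_mix(self):
        d = np.array([0.7, 0.1, 0.1, 0.1])
        d0 = np.full(4, 0.25)
        f = 0.3
        np.testing.assert_allclose(ai.forget(d, d0, f, 1), (1 - f) * d + f * d0)

    def test_rejects_bad_gap(self):
        with pytest.raises(ValueError):
            ai.forget(np.full(4, 0.25), np.full(4, 0.25), 0.5, 0)


class TestContextPosterior:
    def test_win_outcome_excludes_loss_contexts(self):
        lik = ai.outcome_likelihoods()
        post = ai.update_context_posterior(np.full(4, 0.25), lik, GO, 1)
        assert post[Context.G2AL.index] == 0.0
        assert post[Context.NG2AL.index] == 0.0

    def test_bayes_odds_from_uniform(self):
        lik = ai.outcome_likelihoods()
        post = ai.update_context_posterior(np.full(4, 0.25), lik, GO, 1)
        odds = post[Context.G2W.index] / post[Context.NG2W.index]
        assert odds == pytest.approx(0.8 / 0.2)

    def test_repeated_evidence_converges_to_truth(self):
        # with f = 0 the chain posterior is a martingale that settles on
        # the generating context
        rng = np.random.default_rng(1)
        lik = ai.outcome_likelihoods()
        d = np.full(4, 0.25)
        for _ in range(100):
            out = 1 if rng.random() < 0.8 else 0
            d = ai.update_context_posterior(d, lik, GO, out)
        assert np.argmax(d) == Context.G2W.index
        assert d[Context.G2W.index] > 0.99

    def test_impossible_observation_raises(self):
        lik = ai.outcome_likelihoods()
        d = np.zeros(4)
        d[Context.G2AL.index] = 1.0
        with pytest.raises(ValueError):
            ai.update_context_posterior(d, lik, GO, 1)


class TestChoiceProb:
    def test_symmetric_quality_gives_half(self):
        Q = np.array([[-1.0, -2.0, -1.0, -2.0], [-2.0, -1.0, -2.0, -1.0]])
        assert ai.ai_choice_prob(Q, np.full(4, 0.25), 2.0) == pytest.approx(0.5)

    def test_zero_precision_gives_half(self, ai_means):
        Q = ai.initial_state_quality(ai.AIParams(**ai_means))
        assert ai.ai_choice_prob(Q, np.full(4, 0.25), 1e-12) == pytest.approx(0.5)

    def test_greedy_limit(self):
        Q = np.array([[-5.0] * 4, [-0.1] * 4])
        assert ai.ai_choice_prob(Q, np.full(4, 0.25), 50.0) > 0.999

    def test_matches_bruteforce_policy_posterior(self, ai_means):
        # enumeration of the two-policy softmax per state, mixed by belief
        p = ai.AIParams(**ai_means)
        Q = ai.initial_state_quality(p)
        rng = np.random.default_rng(2)
        for _ in range(25):
            s = rng.dirichlet(np.ones(4))
            gamma = float(10 ** rng.uniform(-2, 1))
            expected = 0.0
            for j in range(4):
                num = np.exp(gamma * Q[1, j])
                den = np.exp(gamma * Q[1, j]) + np.exp(gamma * Q[0, j])
                expected += s[j] * num / den
            assert ai.ai_choice_prob(Q, s, gamma) == pytest.approx(expected, abs=1e-12)


class TestSessionLoglik:
    def test_memoryless_symmetric_agent_is_constant(self, ai_means):
        p = params_with(ai_means, f=1 - 1e-12, p_W=0.5, p_go_W=0.5, p_nogo_AL=0.5)
        sess = ai.ai_simulate(make_schedule(10, 3), p, seed=3)
        ll, trace = ai.ai_session_loglik(sess, p, return_trace=True)
        np.testing.assert_allclose(trace["p_go"], 0.5, atol=1e-9)
        assert ll == pytest.approx(len(sess) * np.log(0.5))

    def test_matches_stepwise_reference(self, ai_session, ai_means):
        """Kernel vs a trial-by-trial loop over the public operations."""
        p = ai.AIParams(**ai_means)
        ll_fast, trace = ai.ai_session_loglik(ai_session, p, return_trace=True)
        d0 = ai.context_prior(p)
        qmat = ai.initial_state_quality(p)
        lik = ai.outcome_likelihoods()
        stored, last = {}, {}
        ll_ref = 0.0
        for i, t in enumerate(ai_session.trials):
            k = t.context.index
            d_t = d0.copy() if k not in stored else ai.forget(stored[k], d0, p.f, i - last[k])
            gamma, _, _ = ai.infer_precision(qmat, d_t, p.alpha)
            p_go = ai.ai_choice_prob(qmat, d_t, gamma)
            assert p_go == pytest.approx(trace["p_go"][i], abs=1e-10)
            assert gamma == pytest.approx(trace["gamma_hat"][i], abs=1e-8)
            ll_ref += np.log(p_go if t.action == GO else 1 - p_go)
            stored[k] = ai.update_context_posterior(d_t, lik, t.action, t.outcome)
            last[k] = i
        assert ll_fast == pytest.approx(ll_ref, abs=1e-8)

    def test_beliefs_stay_on_simplex(self, ai_session, ai_means):
        _, trace = ai.ai_session_loglik(
            ai_session, ai.AIParams(**ai_means), return_trace=True
        )
        beliefs = trace[[f"belief_{c.name}" for c in CONTEXTS]].to_numpy()
        assert np.all(beliefs >= 0)
        np.testing.assert_allclose(beliefs.sum(axis=1), 1.0, atol=1e-12)

    def test_generating_alpha_beats_shrunk_alpha(self, ai_means):
        gen = params_with(ai_means, alpha=3.0, f=0.2)
        low = params_with(ai_means, alpha=0.3, f=0.2)
        rng = np.random.default_rng(4)
        diffs = []
        for _ in range(100):
            sess = ai.ai_simulate(make_schedule(36, rng), gen, rng)
            arr = sess.to_arrays()
            diffs.append(
                ai.ai_session_loglik(arr, gen)[0] - ai.ai_session_loglik(arr, low)[0]
            )
        assert np.mean(diffs) > 0

    def test_precision_grows_with_consistent_feedback(self, ai_means):
        # deterministic feedback lets beliefs concentrate, so gamma_hat
        # should rise on average from early to late within-chain trials
        p = params_with(ai_means, f=0.2)
        rng = np.random.default_rng(5)
        early, late = [], []
        for _ in range(20):
            sched = make_schedule(36, rng)
            sess = ai.ai_simulate(sched, p, rng, feedback_validity=1.0)
            _, trace = ai.ai_session_loglik(sess, p, return_trace=True)
            tw = sess.to_arrays().t_within
            early.append(trace["gamma_hat"][tw < 5].mean())
            late.append(trace["gamma_hat"][tw >= 30].mean())
        assert np.mean(late) > np.mean(early)


class TestSimulate:
    def test_reproducible(self, ai_means):
        p = ai.AIParams(**ai_means)
        sched = make_schedule(10, 6)
        assert ai.ai_simulate(sched, p, seed=7).trials == ai.ai_simulate(sched, p, seed=7).trials

    def test_tiny_alpha_is_chance(self, ai_means):
        p = params_with(ai_means, alpha=1e-6)
        sess = ai.ai_simulate(make_schedule(36, 8), p, seed=9)
        p_go = np.mean([t.action == GO for t in sess.trials])
        assert abs(p_go - 0.5) < 3 * np.sqrt(0.25 / 144)

    def test_confident_accurate_agent_learns_within_chain(self, ai_means):
        p = params_with(ai_means, alpha=4.0, f=0.05, p_W=0.6, p_go_W=0.7, p_nogo_AL=0.7)
        rng = np.random.default_rng(10)
        correct_late = []
        correct_early = []
        for _ in range(15):
            sess = ai.ai_simulate(make_schedule(36, rng), p, rng)
            for t in sess.trials:
                hit = t.action == t.context.correct_action
                (correct_late if t.t_within >= 24 else correct_early).append(hit)
        assert np.mean(correct_late) > np.mean(correct_early)
        assert np.mean(correct_late) > 0.75
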