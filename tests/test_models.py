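import numpy as np
import pytest

from inferca import (MODEL_SPECS, LatentState, ParamVector, SessionConfig,
                     build_task_map, choice_probability, generate_session_plan,
                     is_nested, mb_person_value, session_loglik,
                     simulate_session, update_state)
from inferca import _core
from inferca.models import PARAM_NAMES, session_loglik_trace

from reference_model import handmade_session, reference_loglik

FULL = MODEL_SPECS["full"]
CROSS = MODEL_SPECS["RI_cross_CA"]
SUBS = ["pure_MB", "pure_MF", "no_presentation_MBCA", "no_position_MBCA",
        "no_format_MBCA", "additive_MBCA", "flipped_functional"]


def random_params(rng, cross=False):
    theta = np.zeros(13)
    theta[[0, 9]] = rng.uniform(-1, 1, 2)          # c_mf, pr
    theta[2:8] = rng.uniform(-1, 1, 6)             # c_mb
    theta[[1, 8, 10]] = rng.uniform(0, 1, 3)       # forgetting
    if cross:
        theta[11:13] = rng.uniform(-1, 1, 2)
    return ParamVector.from_array(theta)


class TestParamVector:
    def test_roundtrip_and_order(self):
        theta = np.arange(13) / 20.0
        pv = ParamVector.from_array(theta)
        assert np.allclose(pv.to_array(), theta)
        assert list(pv.to_dict()) == list(PARAM_NAMES)

    def test_forgetting_bounds_enforced(self):
        with pytest.raises(ValueError):
            ParamVector(0.1, 1.2, (0,) * 6, 0.1, 0.0, 0.1)

    def test_gain_lookup_by_format_and_position(self):
        pv = ParamVector(0, 0, (1, 2, 3, 4, 5, 6), 0, 0, 0)
        assert pv.c_mb_of(0, 1) == 1 and pv.c_mb_of(2, 2) == 6


class TestModelSpecs:
    def test_spec_family_and_nesting(self):
        assert set(MODEL_SPECS) == {"full", "RI_cross_CA", *SUBS}
        for name in SUBS:
            assert is_nested(MODEL_SPECS[name], FULL)
        assert is_nested(FULL, CROSS)
        assert not is_nested(FULL, FULL)
        assert not is_nested(CROSS, FULL)

    @pytest.mark.parametrize("name,expected", [
        ("full", 11), ("RI_cross_CA", 13), ("pure_MB", 9), ("pure_MF", 4),
        ("no_presentation_MBCA", 6), ("no_position_MBCA", 8),
        ("no_format_MBCA", 7), ("additive_MBCA", 9), ("flipped_functional", 7)])
    def test_free_parameter_counts(self, name, expected):
        assert MODEL_SPECS[name].n_free == expected

    def test_constraint_structure(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.0, 0.5, MODEL_SPECS["no_position_MBCA"].n_free)
        pv = MODEL_SPECS["no_position_MBCA"].expand(x)
        assert pv.c_mb[0] == pv.c_mb[1] and pv.c_mb[2] == pv.c_mb[3]
        x = rng.uniform(0.0, 0.5, MODEL_SPECS["additive_MBCA"].n_free)
        pv = MODEL_SPECS["additive_MBCA"].expand(x)
        # interaction-free: position effect identical across formats
        diffs = [pv.c_mb[1] - pv.c_mb[0], pv.c_mb[3] - pv.c_mb[2],
                 pv.c_mb[5] - pv.c_mb[4]]
        assert np.allclose(diffs, diffs[0])
        x = rng.uniform(0.0, 0.5, MODEL_SPECS["flipped_functional"].n_free)
        pv = MODEL_SPECS["flipped_functional"].expand(x)
        assert pv.c_mb[0] == pv.c_mb[2] == pv.c_mb[5]   # S1 = PI1 = RI2
        assert pv.c_mb[1] == pv.c_mb[3] == pv.c_mb[4]   # S2 = PI2 = RI1
        pv = MODEL_SPECS["pure_MF"].expand(np.array([0.4, 0.2, 0.1, 0.3]))
        assert pv.c_mb == (0.0,) * 6 and pv.f_mb == 0.0

    def test_free_from_full_inverts_expand(self):
        rng = np.random.default_rng(1)
        for spec in MODEL_SPECS.values():
            x = rng.uniform(0.05, 0.4, spec.n_free)
            assert np.allclose(spec.free_from_full(spec.expand(x)), x)


class TestChoice:
    def test_fresh_state_values_and_probability(self, task_map):
        state = LatentState()
        for p in range(4):
            assert mb_person_value(state, task_map, p) == 0.0
        assert choice_probability(state, task_map, (0, 1)) == (0.5, 0.5)

    def test_mb_value_additivity(self, task_map):
        state = LatentState()
        a, v = task_map.outcomes_of(2)
        state.q_mb[a], state.q_mb[v] = 0.3, 0.1
        assert mb_person_value(state, task_map, 2) == pytest.approx(0.4)

    def test_shared_outcome_moves_both_sharers_equally(self, task_map):
        state = LatentState()
        p1, p2 = task_map.persons_sharing(0)
        before = [mb_person_value(state, task_map, p) for p in (p1, p2)]
        state.q_mb[0] += 0.7
        after = [mb_person_value(state, task_map, p) for p in (p1, p2)]
        assert after[0] - before[0] == pytest.approx(after[1] - before[1])

    def test_softmax_identities(self, task_map):
        state = LatentState()
        state.q_mf[0], state.q_mf[1] = 1.4, 0.2
        p0, p1 = choice_probability(state, task_map, (0, 1))
        assert p0 + p1 == pytest.approx(1.0)
        assert p0 == pytest.approx(1 / (1 + np.exp(-1.2)))
        state.q_mf[:2] += 5.0   # shift invariance
        assert choice_probability(state, task_map, (0, 1)) == pytest.approx((p0, p1))


class TestUpdateState:
    def test_no_forgetting_double_reward(self, task_map):
        pv = ParamVector(0.3, 0.0, (0.2,) * 6, 0.0, 0.0, 0.0)
        sess = handmade_session()
        trial = sess.trial(0)._replace(reward1=1, reward2=1)
        new = update_state(LatentState(), pv, FULL, trial, task_map)
        assert new.q_mf[trial.chosen] == pytest.approx(2 * 0.3)

    def test_full_forgetting_clears_unrelated_outcomes(self, task_map):
        pv = ParamVector(0.0, 0.0, (0.2,) * 6, 1.0, 0.0, 0.0)
        state = LatentState()
        state.q_mb[:] = 0.9
        trial = handmade_session().trial(0)
        new = update_state(state, pv, FULL, trial, task_map)
        related = set(task_map.outcomes_of(trial.chosen))
        for o in set(range(4)) - related:
            assert new.q_mb[o] == 0.0

    def test_missing_choice_is_inert(self, task_map, plausible_params):
        sess = handmade_session()
        state = LatentState()
        state.q_mf[:] = 0.4
        new = update_state(state, plausible_params, FULL, sess.trial(5), task_map)
        assert np.array_equal(new.q_mf, state.q_mf)

    def test_cross_spec_with_zero_gains_matches_full(self, task_map):
        rng = np.random.default_rng(4)
        sess = handmade_session()
        for t in (2, 4, 7):   # RI trials
            pv = random_params(rng)
            state = LatentState()
            state.q_mb[:] = rng.normal(size=4)
            a = update_state(state, pv, FULL, sess.trial(t), task_map)
            b = update_state(state, pv, CROSS, sess.trial(t), task_map)
            assert np.allclose(a.q_mb, b.q_mb)


class TestSessionLoglik:
    def test_uniform_policy_value(self, full_session):
        pv = ParamVector(0, 0.2, (0,) * 6, 0.2, 0, 0.2)
        n_choices = int(np.sum(full_session.chosen >= 0))
        assert session_loglik(pv, FULL, full_session) == pytest.approx(
            n_choices * np.log(0.5))

    def test_matches_reference_transcription_on_handmade(self):
        sess = handmade_session()
        rng = np.random.default_rng(5)
        for cross in (False, True):
            spec = CROSS if cross else FULL
            pv = random_params(rng, cross=cross)
            assert session_loglik(pv, spec, sess) == pytest.approx(
                reference_loglik(pv.to_array(), cross, sess), abs=1e-10)

    @pytest.mark.parametrize("name", list(MODEL_SPECS))
    def test_matches_reference_on_simulated_sessions(self, name, session_factory):
        sess, _ = session_factory(100, config=SessionConfig(n_blocks=2))
        spec = MODEL_SPECS[name]
        rng = np.random.default_rng(6)
        x = rng.uniform(-0.5, 0.5, spec.n_free)
        for i, nm in enumerate(spec.free_names):
            if nm in ("f_mf", "f_mb", "f_p"):
                x[i] = rng.uniform(0, 1)
        assert session_loglik(x, spec, sess) == pytest.approx(
            reference_loglik(spec.expand_array(x), spec.uses_cross, sess),
            abs=1e-10)

    def test_trace_sums_to_loglik_and_skips_missing(self):
        sess = handmade_session()
        pv = random_params(np.random.default_rng(7))
        trace = session_loglik_trace(pv, FULL, sess)
        assert np.isnan(trace[5])
        assert np.nansum(trace) == pytest.approx(session_loglik(pv, FULL, sess))

    def test_nesting_loglik_equality(self, full_session):
        rng = np.random.default_rng(8)
        for name in SUBS:
            spec = MODEL_SPECS[name]
            x = rng.uniform(0.0, 0.4, spec.n_free)
            assert session_loglik(x, spec, full_session) == pytest.approx(
                session_loglik(spec.expand(x), FULL, full_session))

    def test_flipped_functional_equivalence_class(self, full_session):
        # with gains equal across formats AND positions these specs coincide
        c, f_mb = 0.3, 0.2
        base = dict(c_mf=0.4, f_mf=0.1, pr=0.2, f_p=0.3)
        pv = ParamVector(c_mb=(c,) * 6, f_mb=f_mb, **base)
        ref = session_loglik(pv, FULL, full_session)
        frees = {
            "no_presentation_MBCA": [0.4, 0.1, c, f_mb, 0.2, 0.3],
            "no_position_MBCA": [0.4, 0.1, c, c, c, f_mb, 0.2, 0.3],
            "no_format_MBCA": [0.4, 0.1, c, c, f_mb, 0.2, 0.3],
            "additive_MBCA": [0.4, 0.1, c, c, c, 0.0, f_mb, 0.2, 0.3],
            "flipped_functional": [0.4, 0.1, c, c, f_mb, 0.2, 0.3],
        }
        for name, x in frees.items():
            assert session_loglik(np.array(x), MODEL_SPECS[name],
                                  full_session) == pytest.approx(ref)

    def test_nonfinite_parameters_rejected(self, full_session):
        x = np.zeros(11)
        x[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            session_loglik(x, FULL, full_session)


class TestGradient:
    @pytest.mark.parametrize("cross", [False, True])
    def test_analytic_gradient_matches_finite_differences(self, cross, session_factory):
        sess, _ = session_factory(200, config=SessionConfig(n_blocks=2))
        arrs = _core.session_arrays(sess)
        rng = np.random.default_rng(9)
        theta = random_params(rng, cross=cross).to_array()
        _, grad = _core.nll_and_grad(theta, *arrs, cross)
        eps = 1e-6
        for i in range(13):
            tp, tm_ = theta.copy(), theta.copy()
            tp[i] += eps
            tm_[i] -= eps
            fd = (_core.nll_and_grad(tp, *arrs, cross)[0]
                  - _core.nll_and_grad(tm_, *arrs, cross)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(fd, abs=1e-4), PARAM_NAMES[i]


class TestSimulation:
    def test_deterministic_under_seed(self, task_map, plausible_params):
        plan = generate_session_plan(task_map, SessionConfig(n_blocks=2), seed=1)
        a = simulate_session(plausible_params, FULL, plan, seed=2)
        b = simulate_session(plausible_params, FULL, plan, seed=2)
        assert np.array_equal(a.chosen, b.chosen)
        assert np.array_equal(a.reward1, b.reward1)

    def test_pure_mf_choices_ignore_presentation_format(self, task_map):
        # relabeling which outcome was concealed cannot move a pure-MF agent
        pv = MODEL_SPECS["pure_MF"].expand(np.array([0.6, 0.2, 0.1, 0.3]))
        plan = generate_session_plan(task_map, SessionConfig(n_blocks=2), seed=3)
        alt = plan.copy_plan()
        alt.fmt = (alt.fmt + 1) % 3
        a = simulate_session(pv, MODEL_SPECS["pure_MF"], plan, seed=4)
        b = simulate_session(pv, MODEL_SPECS["pure_MF"], alt, seed=4)
        assert np.array_equal(a.chosen, b.chosen)

    def test_strong_mb_agent_generalizes_common_reward(self, task_map):
        # a rewarded shared outcome should lift choice of the other sharer
        from inferca.signatures import select_generalization_transitions
        pv = ParamVector(0.0, 0.0, (1.5,) * 6, 0.1, 0.0, 0.0)
        rows = []
        for seed in range(30):
            plan = generate_session_plan(task_map, SessionConfig(n_blocks=2), seed=seed)
            sess = simulate_session(pv, MODEL_SPECS["pure_MB"], plan, seed=1000 + seed)
            sess.participant_id = f"p{seed}"
            rows.append(sess)
        table = select_generalization_transitions(rows)
        effect = (table.loc[table.COMMON > 0, "GENERALIZE"].mean()
                  - table.loc[table.COMMON < 0, "GENERALIZE"].mean())
        assert effect > 0.1
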