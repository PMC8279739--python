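import numpy as np
import pandas as pd
import pytest

from inferca import (MODEL_SPECS, ParamVector, SessionConfig, SessionData,
                     build_task_map, generate_session_plan,
                     generate_synthetic_cohort, sample_plausible_params,
                     simulate_session)
from inferca.fitting import FitResult
from inferca import signatures as sig

FULL = MODEL_SPECS["full"]


def _manual_session(fmt, veg_first, left, right, chosen, reward1, reward2):
    """Single-block session on the seed-1 map: woman=(monkey,garlic),
    bearded_man=(monkey,carrot), child=(sheep,garlic), old_man=(sheep,carrot)."""
    tm = build_task_map(1)
    n = len(fmt)
    cfg = SessionConfig(n_blocks=1, trials_per_block=4)
    return SessionData(
        tm, cfg, np.full((1, 4), 0.5),
        block=np.zeros(n, dtype=int), left=np.array(left), right=np.array(right),
        fmt=np.array(fmt), veg_first=np.array(veg_first, dtype=bool),
        chosen=np.array(chosen), reward1=np.array(reward1),
        reward2=np.array(reward2), participant_id="manual")


WOMAN, BEARDED, CHILD, OLD = 0, 1, 2, 3


class TestWorkedExamples:
    def test_repetition_row_monkey_rewarded(self):
        # n: woman chosen, monkey (shared with bearded man) rewarded first;
        # n+1 offers woman vs bearded man and the woman is chosen again
        s = _manual_session(fmt=[0, 0], veg_first=[0, 0],
                            left=[WOMAN, WOMAN], right=[CHILD, BEARDED],
                            chosen=[WOMAN, WOMAN],
                            reward1=[1, 1], reward2=[0, 0])
        table = sig.select_repetition_transitions(s)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.REPEAT == 1 and row.COMMON == 0.5
        assert row.POSITION == 0.5 and row.PROSPECTIVE == 0 and row.RETROSPECTIVE == 0

    def test_generalization_row_bearded_man_after_monkey(self):
        # n: woman chosen (RI format), monkey rewarded; n+1 excludes the woman
        # but offers the bearded man, who shares the monkey -> generalization
        s = _manual_session(fmt=[2, 0], veg_first=[0, 0],
                            left=[WOMAN, BEARDED], right=[CHILD, OLD],
                            chosen=[WOMAN, BEARDED],
                            reward1=[1, 0], reward2=[0, 0])
        table = sig.select_generalization_transitions(s)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.GENERALIZE == 1 and row.COMMON == 0.5
        assert row.RETROSPECTIVE == 1 and row.POSITION == 0.5

    def test_cross_ca_row_hidden_garlic_reward(self):
        # RI trial n with garlic first (hidden) and rewarded, monkey second
        # (seen); the monkey is the common outcome on the generalization trial
        s = _manual_session(fmt=[2, 0], veg_first=[1, 0],
                            left=[WOMAN, BEARDED], right=[CHILD, OLD],
                            chosen=[WOMAN, BEARDED],
                            reward1=[1, 0], reward2=[0, 0])
        table = sig.select_cross_ca_transitions(s)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.GENERALIZE == 1 and row.NON_COMMON == 0.5
        # standard-format trials n are excluded
        s2 = _manual_session(fmt=[0, 0], veg_first=[1, 0],
                             left=[WOMAN, BEARDED], right=[CHILD, OLD],
                             chosen=[WOMAN, BEARDED],
                             reward1=[1, 0], reward2=[0, 0])
        assert sig.select_cross_ca_transitions(s2).empty
        # common-first variant selects the complementary transitions
        assert len(sig.select_cross_ca_transitions(s, common_position=1)) == 0

    def test_full_design_unique_outcome_coding(self):
        # trial n: woman chosen, outcomes monkey (first) + garlic; trial n+1
        # offers bearded man (left) vs old man (right): the monkey is unique
        # to the bearded man, garlic relates to neither
        s = _manual_session(fmt=[1, 0], veg_first=[0, 0],
                            left=[WOMAN, BEARDED], right=[CHILD, OLD],
                            chosen=[WOMAN, OLD],
                            reward1=[1, 0], reward2=[0, 0])
        row = sig.build_full_transition_design(s).iloc[0]
        # monkey rewarded and relates to the LEFT person -> MB_REW = -0.5
        assert row.MB_REW == -0.5
        assert row.POSITION == -0.5          # unique outcome came first
        assert row.PROSPECTIVE == 1
        assert row.PERS == 0                 # previous choice not on offer
        mf_cols = [c for c in row.index if "MF_REW" in c]
        assert all(row[c] == 0.0 for c in mf_cols)
        assert row.CHOOSE_R == 1


@pytest.fixture(scope="module")
def cohort():
    return [s for s, _ in generate_synthetic_cohort(
        6, sample_plausible_params, SessionConfig(n_blocks=3), seed=41)]


class TestDesignInvariants:
    def test_selectors_partition_transitions(self, cohort):
        rep = sig.select_repetition_transitions(cohort)
        gen = sig.select_generalization_transitions(cohort)
        total = sum(
            int(np.sum((s.block[1:] == s.block[:-1])
                       & (s.chosen[1:] >= 0) & (s.chosen[:-1] >= 0)))
            for s in cohort)
        assert len(rep) + len(gen) == total
        assert len(sig.build_full_transition_design(cohort)) == total

    def test_regressors_take_declared_values(self, cohort):
        rep = sig.select_repetition_transitions(cohort)
        gen = sig.select_generalization_transitions(cohort)
        full = sig.build_full_transition_design(cohort)
        for tab, resp in ((rep, "REPEAT"), (gen, "GENERALIZE")):
            assert set(tab[resp].unique()) <= {0, 1}
            assert set(tab.COMMON.unique()) <= {0.5, -0.5}
            assert set(tab.POSITION.unique()) <= {0.5, -0.5}
        assert set(full.MB_REW.unique()) <= {0.5, -0.5}
        assert set(full.PERS.unique()) <= {-1, 0, 1}
        mf_cols = [c for c in full.columns if "MF_REW" in c]
        assert all(set(full[c].unique()) <= {0.0, 0.5, -0.5} for c in mf_cols)
        # at most one format's MF pair is nonzero per row
        nz = sum((full[c] != 0).astype(int) for c in mf_cols)
        assert nz.max() <= 2
        pairs = np.stack([(full[mf_cols[2 * k]] != 0) | (full[mf_cols[2 * k + 1]] != 0)
                          for k in range(3)])
        assert pairs.sum(axis=0).max() <= 1
        # MF regressors all zero exactly when the previous choice is absent
        assert np.array_equal(nz == 0, full.PERS == 0)

    def test_display_side_flip_symmetry(self, cohort):
        base = sig.build_full_transition_design(cohort[0])
        flipped_session = cohort[0].copy_plan()
        flipped_session.left = cohort[0].right.copy()
        flipped_session.right = cohort[0].left.copy()
        flipped_session.chosen = cohort[0].chosen.copy()
        flipped_session.reward1 = cohort[0].reward1.copy()
        flipped_session.reward2 = cohort[0].reward2.copy()
        flip = sig.build_full_transition_design(flipped_session)
        assert np.array_equal(flip.CHOOSE_R, 1 - base.CHOOSE_R)
        assert np.array_equal(flip.MB_REW, -base.MB_REW)
        assert np.array_equal(flip.PERS, -base.PERS)
        for c in [c for c in base.columns if "MF_REW" in c]:
            assert np.array_equal(flip[c], -base[c])

    def test_transitions_never_cross_blocks(self, cohort):
        s = cohort[0]
        tpb = s.config.trials_per_block
        rep = sig.select_repetition_transitions(s)
        gen = sig.select_generalization_transitions(s)
        for tab in (rep, gen):
            assert not np.any((tab.trial.to_numpy() + 1) % tpb == 0)


class TestTwoStageModels:
    def test_single_participant_matches_plain_logistic(self, session_factory):
        import statsmodels.api as sm
        sess, _ = session_factory(50)
        table = sig.select_repetition_transitions(sess)
        res = sig.fit_mixed_logistic(table, "REPEAT", "COMMON + POSITION",
                                     ridge=1e8)
        from patsy import dmatrix
        X = np.asarray(dmatrix("COMMON + POSITION", table))
        ref = sm.Logit(table.REPEAT.to_numpy(), X).fit(disp=0)
        assert np.allclose(res.params.to_numpy(), ref.params, atol=1e-4)
        assert np.isnan(res.contrast("COMMON").p)  # no between-participant df

    def test_contrast_and_joint_against_known_coefficients(self):
        rng = np.random.default_rng(42)
        coefs = pd.DataFrame(
            rng.normal([1.0, 0.5, 0.0], 0.2, size=(40, 3)),
            columns=["Intercept", "A", "B"])
        res = sig.TwoStageResult(("Intercept", "A", "B"), coefs, "two_stage_linear")
        a = res.contrast("A")
        assert a.estimate == pytest.approx(coefs["A"].mean())
        assert a.p < 1e-6
        b = res.contrast("B")
        assert b.p > 0.01
        j = res.joint_test(["A", "B"])
        assert j.df == (2, 38) and j.p < 1e-6

    def test_composite_main_effect_weights(self):
        terms = ("Intercept", "COMMON", "COMMON:PROSPECTIVE", "COMMON:RETROSPECTIVE")
        coefs = pd.DataFrame(np.tile([0.0, 0.3, 0.6, -0.3], (10, 1)), columns=terms)
        coefs += np.random.default_rng(1).normal(0, 1e-6, coefs.shape)
        res = sig.TwoStageResult(terms, coefs, "two_stage_logistic")
        # (3*0.3 + 0.6 - 0.3) / 3 = 0.4
        assert res.composite_main_effect("COMMON").estimate == pytest.approx(0.4, abs=1e-4)

    def test_reward_effect_model_constant_effects(self):
        rows = []
        for p in range(4):
            for f in ("S", "PI", "RI"):
                for pos in (1, 2):
                    rows.append({"participant": f"p{p}", "format": f,
                                 "position": pos, "effect": 0.25, "n": 20})
        res = sig.reward_effect_model(pd.DataFrame(rows))
        assert res.params["Intercept"] == pytest.approx(0.25)
        non_intercept = res.params.drop("Intercept")
        assert np.allclose(non_intercept, 0.0, atol=1e-12)


class TestParameterModel:
    def _fits(self, c_mb_fn, n=12, seed=0):
        rng = np.random.default_rng(seed)
        fits = []
        for i in range(n):
            c = np.clip(c_mb_fn(rng), -4.9, 4.9)
            pv = ParamVector(0.4, 0.2, tuple(c), 0.15, 0.1, 0.3)
            fits.append(FitResult("full", FULL.free_from_full(pv), pv, -100.0,
                                  np.array([-100.0]), 1, np.array([True]), 0,
                                  f"p{i}"))
        return fits

    def test_identical_gains_give_zero_interactions(self):
        fits = self._fits(lambda rng: np.full(6, 0.3))
        res = sig.mbca_parameter_model(fits)["ca_model"]
        for term in ("POSITION", "POSITION:PROSPECTIVE", "POSITION:RETROSPECTIVE"):
            assert res.params[term] == pytest.approx(0.0, abs=1e-12)

    def test_ri_second_position_deficit_recovered_with_sign(self):
        delta = 0.3

        def gen(rng):
            base = rng.uniform(0.2, 0.5)
            c = np.full(6, base) + rng.normal(0, 0.02, 6)
            c[5] -= delta   # RI, second temporal position impaired
            return c

        out = sig.mbca_parameter_model(self._fits(gen, n=20, seed=3))
        ca = out["ca_model"]
        # temporal coding: impaired second position in RI only ->
        # positive POSITION:RETROSPECTIVE interaction
        t = ca.contrast("POSITION:RETROSPECTIVE")
        assert t.estimate > 0 and t.p < 0.01
        # functional coding flips RI: the deficit moves to position 1
        fn = out["functional_ca_model"].contrast("POSITION:RETROSPECTIVE")
        assert fn.estimate < 0
        imp = out["impairment"]
        assert imp["intercept"] == pytest.approx(delta, abs=0.1)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            sig.mbca_parameter_model(self._fits(lambda rng: np.full(6, 0.3), n=2))


class TestRTAnalysis:
    def _sessions_with_rt(self, rt_fn, n=6, seed=0):
        out = []
        for i in range(n):
            s, _ = _factory(seed * 100 + i)
            s.rt_ms = rt_fn(s, np.random.default_rng(i))
            out.append(s)
        return out

    def test_constant_rt_gives_intercept_only(self):
        sessions = self._sessions_with_rt(lambda s, rng: np.full(s.n_trials, 600.0))
        res = sig.rt_analysis(sessions)["model"]
        assert res.params["Intercept"] == pytest.approx(600.0)
        assert np.allclose(res.params.drop("Intercept"), 0.0, atol=1e-9)

    def test_first_block_trials_and_fast_trials_excluded(self):
        def rt_fn(s, rng):
            rt = np.full(s.n_trials, 600.0)
            rt[s.trial_in_block == 0] = 5000.0   # would shift the mean if kept
            rt[1] = 100.0                        # below the fast cutoff
            return rt

        sessions = self._sessions_with_rt(rt_fn)
        res = sig.rt_analysis(sessions)["model"]
        assert res.params["Intercept"] == pytest.approx(600.0)

    def test_injected_slowing_on_new_trials_after_ri(self):
        def rt_fn(s, rng):
            pair = np.minimum(s.left, s.right) * 4 + np.maximum(s.left, s.right)
            new = np.ones(s.n_trials, dtype=bool)
            new[1:] = pair[1:] != pair[:-1]
            prev_ri = np.zeros(s.n_trials, dtype=bool)
            prev_ri[1:] = s.fmt[:-1] == 2
            return (600.0 + 80.0 * new + 40.0 * (new & prev_ri)
                    + rng.normal(0, 5, s.n_trials))

        sessions = self._sessions_with_rt(rt_fn, n=10)
        res = sig.rt_analysis(sessions)["model"]
        assert res.contrast("TYPE").estimate == pytest.approx(80, abs=15)
        t = res.contrast("TYPE:RETROSPECTIVE")
        assert t.estimate == pytest.approx(40, abs=15) and t.p < 0.01


@pytest.fixture(scope="module")
def mf_cohort():
    pv = MODEL_SPECS["pure_MF"].expand(np.array([0.7, 0.2, 0.1, 0.3]))
    return [s for s, _ in generate_synthetic_cohort(
        10, lambda rng: pv, SessionConfig(n_blocks=4), seed=55,
        spec=MODEL_SPECS["pure_MF"])]


class TestBootstrapPower:
    def test_single_resample_power_is_binary(self, mf_cohort):
        out = sig.bootstrap_power(mf_cohort, "repetition_common", n_boot=1, seed=1)
        assert out["power"] in (0.0, 1.0)

    def test_power_monotone_in_cohort_size(self, mf_cohort):
        lo = sig.bootstrap_power(mf_cohort, "repetition_common", n_boot=300,
                                 seed=2, target_n=6)
        hi = sig.bootstrap_power(mf_cohort, "repetition_common", n_boot=300,
                                 seed=2, target_n=40)
        assert hi["power"] >= lo["power"]

    def test_unknown_analysis_rejected(self, mf_cohort):
        with pytest.raises(KeyError):
            sig.bootstrap_power(mf_cohort, "nope", n_boot=1)


def _factory(seed):
    rng_seed = np.random.SeedSequence(seed).generate_state(4)
    tm = build_task_map(int(rng_seed[0]))
    params = sample_plausible_params(np.random.default_rng(int(rng_seed[1])))
    plan = generate_session_plan(tm, SessionConfig(n_blocks=3), seed=int(rng_seed[2]))
    sess = simulate_session(params, FULL, plan, seed=int(rng_seed[3]))
    sess.participant_id = f"p{seed}"
    return sess, params
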