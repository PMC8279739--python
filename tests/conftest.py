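import numpy as np
import pytest

from inferca import (MODEL_SPECS, ParamVector, SessionConfig, build_task_map,
                     generate_session_plan, sample_plausible_params,
                     simulate_session)


@pytest.fixture(scope="session")
def task_map():
    return build_task_map(7)


@pytest.fixture(scope="session")
def small_config():
    return SessionConfig(n_blocks=3)


@pytest.fixture(scope="session")
def plausible_params():
    return ParamVector(c_mf=0.5, f_mf=0.2,
                       c_mb=(0.35, 0.3, 0.3, 0.25, 0.3, 0.15),
                       f_mb=0.15, pr=0.15, f_p=0.3)


@pytest.fixture(scope="session")
def full_session(task_map, plausible_params):
    """One default-schedule session simulated from the full model."""
    plan = generate_session_plan(task_map, SessionConfig(), seed=11)
    return simulate_session(plausible_params, MODEL_SPECS["full"], plan, seed=12)


@pytest.fixture(scope="session")
def session_factory():
    """Callable producing a simulated session for (seed, spec, params, config)."""

    def make(seed, spec_name="full", params=None, config=None, participant=None):
        config = config or SessionConfig(n_blocks=3)
        ss = np.random.SeedSequence(seed)
        s_map, s_par, s_plan, s_sim = ss.generate_state(4)
        tm = build_task_map(int(s_map))
        if params is None:
            params = sample_plausible_params(np.random.default_rng(int(s_par)))
        plan = generate_session_plan(tm, config, seed=int(s_plan))
        sess = simulate_session(params, MODEL_SPECS[spec_name], plan, seed=int(s_sim))
        sess.participant_id = participant or f"p{seed}"
        return sess, params

    return make
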