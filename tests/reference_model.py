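"""Independent straight-line transcription of the learning model.

Deliberately naive oracle for the likelihood: named dictionaries, explicit
per-trial arithmetic, no shared code with the package's fast kernels.  Used
to pin down `session_loglik` on hand-built and random sessions.
"""

import math

import numpy as np


def handmade_session():
    """A fully hand-specified 10-trial session (3 blocks of 4, truncated).

    Covers all three formats, both outcome orders, a mid-session block reset
    and one missing response.  Person/outcome indices refer to the map built
    from seed 1: woman=(monkey,garlic), bearded_man=(monkey,carrot),
    child=(sheep,garlic), old_man=(sheep,carrot); outcomes 0=monkey, 1=sheep,
    2=garlic, 3=carrot.
    """
    from inferca import SessionConfig, SessionData, build_task_map

    tm = build_task_map(1)
    cfg = SessionConfig(n_blocks=3, trials_per_block=4)
    reward_probs = np.array([[0.5, 0.4, 0.6, 0.3],
                             [0.7, 0.2, 0.5, 0.8],
                             [0.3, 0.6, 0.4, 0.5]])
    #            t:   0  1  2  3  4  5  6  7  8  9
    block = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2])
    left = np.array([0, 2, 1, 0, 3, 0, 2, 1, 0, 3])
    right = np.array([1, 0, 3, 2, 1, 1, 3, 3, 2, 2])
    fmt = np.array([0, 1, 2, 0, 2, 1, 0, 2, 1, 0])
    veg_first = np.array([0, 1, 0, 1, 1, 0, 0, 1, 0, 1], dtype=bool)
    chosen = np.array([0, 2, 3, 2, 1, -1, 2, 3, 0, 3])
    reward1 = np.array([1, 0, 1, 1, 0, -1, 1, 0, 0, 1])
    reward2 = np.array([0, 1, 1, 0, 1, -1, 0, 0, 1, 1])
    return SessionData(tm, cfg, reward_probs, block, left, right, fmt,
                       veg_first, chosen, reward1, reward2,
                       participant_id="handmade")


def reference_loglik(theta, uses_cross, session):
    """Log-likelihood of a session's choices; theta is the 13-entry full vector.

    theta: [c_mf, f_mf, cS1, cS2, cPI1, cPI2, cRI1, cRI2, f_mb, pr, f_p,
            c_cross_12, c_cross_21]
    """
    c_mf, f_mf = theta[0], theta[1]
    c_mb = {("S", 1): theta[2], ("S", 2): theta[3],
            ("PI", 1): theta[4], ("PI", 2): theta[5],
            ("RI", 1): theta[6], ("RI", 2): theta[7]}
    f_mb, pr, f_p = theta[8], theta[9], theta[10]
    cross_12, cross_21 = theta[11], theta[12]
    fmt_names = ("S", "PI", "RI")

    tm = session.task_map
    persons = list(range(4))
    outcomes = list(range(4))

    q_mf = {p: 0.0 for p in persons}
    q_mb = {o: 0.0 for o in outcomes}
    pers = {p: 0.0 for p in persons}

    loglik = 0.0
    prev_block = None
    for trial in session:
        if trial.block != prev_block:
            prev_block = trial.block
            q_mf = {p: 0.0 for p in persons}
            q_mb = {o: 0.0 for o in outcomes}
            pers = {p: 0.0 for p in persons}
        if trial.chosen < 0:
            continue

        def q_net(p):
            animal, veg = tm.outcomes_of(p)
            return q_mb[animal] + q_mb[veg] + q_mf[p] + pers[p]

        chosen = trial.chosen
        other = trial.left if chosen == trial.right else trial.right
        num = math.exp(q_net(chosen))
        den = math.exp(q_net(chosen)) + math.exp(q_net(other))
        loglik += math.log(num / den)

        r1 = 1.0 if trial.reward1 == 1 else -1.0
        r2 = 1.0 if trial.reward2 == 1 else -1.0
        r_total = r1 + r2

        # model-free update
        new_q_mf = {}
        for p in persons:
            if p == chosen:
                new_q_mf[p] = (1 - f_mf) * q_mf[p] + c_mf * r_total
            else:
                new_q_mf[p] = (1 - f_mf) * q_mf[p]
        q_mf = new_q_mf

        # model-based update
        animal, veg = tm.outcomes_of(chosen)
        first, second = (veg, animal) if trial.veg_first else (animal, veg)
        fmt = fmt_names[trial.fmt]
        new_q_mb = {}
        for o in outcomes:
            if o == first:
                v = (1 - f_mb) * q_mb[o] + c_mb[(fmt, 1)] * r1
                if uses_cross and fmt == "RI":
                    v += cross_21 * r2
            elif o == second:
                v = (1 - f_mb) * q_mb[o] + c_mb[(fmt, 2)] * r2
                if uses_cross and fmt == "RI":
                    v += cross_12 * r1
            else:
                v = (1 - f_mb) * q_mb[o]
            new_q_mb[o] = v
        q_mb = new_q_mb

        # perseveration update
        new_pers = {}
        for p in persons:
            new_pers[p] = (1 - f_p) * pers[p] + (pr if p == chosen else 0.0)
        pers = new_pers

    return loglik
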