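"""Numba kernels: likelihood + gradient, simulation, and a box-constrained fitter.

The canonical parameter vector ``theta`` has 13 entries:
0 c_mf, 1 f_mf, 2..7 c_mb (S1,S2,PI1,PI2,RI1,RI2), 8 f_mb, 9 pr, 10 f_p,
11 c_cross_12, 12 c_cross_21.

Gradients are exact forward sensitivities: every latent-value update is affine
in the state, so d(state)/d(theta) obeys the same cheap recursion.  The
sensitivities factor into three small blocks (Q_MF depends only on c_mf/f_mf,
Q_MB on the six gains, f_mb and the two cross gains, PERS on pr/f_p), which
keeps a full likelihood-plus-gradient pass at ~150 flops per trial.

The fitter is a projected L-BFGS (two-loop recursion, Armijo backtracking
onto the box).  It is deliberately hand-rolled and compiled: the bootstrap
model-comparison studies need hundreds of thousands of maximum-likelihood
fits, where per-call overhead of a Python optimizer dominates the actual
arithmetic.  Its optima are cross-checked against scipy's L-BFGS-B in the
test suite.
"""

import numpy as np
from numba import njit

N_PARAMS = 13
# theta indices for the local Q_MB sensitivity columns:
# cols 0..5 -> the six gains, 6 -> f_mb, 7 -> c_cross_12, 8 -> c_cross_21
_MB_COLS = np.array([2, 3, 4, 5, 6, 7, 8, 11, 12], dtype=np.int64)


def session_arrays(session):
    """Flatten a SessionData into the contiguous arrays the kernels consume."""
    o1, o2 = session.outcome_temporal()
    r1 = np.where(session.reward1 == 1, 1.0, -1.0)
    r2 = np.where(session.reward2 == 1, 1.0, -1.0)
    return (
        np.ascontiguousarray(session.block, dtype=np.int64),
        np.ascontiguousarray(session.chosen, dtype=np.int64),
        np.ascontiguousarray(o1, dtype=np.int64),
        np.ascontiguousarray(o2, dtype=np.int64),
        np.ascontiguousarray(r1, dtype=np.float64),
        np.ascontiguousarray(r2, dtype=np.float64),
        np.ascontiguousarray(session.fmt, dtype=np.int64),
        np.ascontiguousarray(session.left, dtype=np.int64),
        np.ascontiguousarray(session.right, dtype=np.int64),
        np.ascontiguousarray(session.task_map.person_outcomes, dtype=np.int64),
    )


@njit(cache=True)
def nll_and_grad(theta, block, chosen, o1, o2, r1, r2, fmt, left, right, pout,
                 use_cross):
    """Negative log-likelihood of the observed choices and its 13-gradient."""
    c_mf, f_mf = theta[0], theta[1]
    f_mb, pr, f_p = theta[8], theta[9], theta[10]

    q_mf = np.zeros(4)
    q_mb = np.zeros(4)
    pers = np.zeros(4)
    d_mf = np.zeros((4, 2))    # wrt (c_mf, f_mf)
    d_mb = np.zeros((4, 9))    # wrt (6 gains, f_mb, cr12, cr21)
    d_pers = np.zeros((4, 2))  # wrt (pr, f_p)

    nll = 0.0
    grad = np.zeros(N_PARAMS)
    cur_block = -1
    n = block.shape[0]
    for t in range(n):
        if block[t] != cur_block:
            cur_block = block[t]
            q_mf[:] = 0.0; q_mb[:] = 0.0; pers[:] = 0.0
            d_mf[:] = 0.0; d_mb[:] = 0.0; d_pers[:] = 0.0
        ch = chosen[t]
        if ch < 0:
            continue
        other = left[t] if ch == right[t] else right[t]

        ca0, ca1 = pout[ch, 0], pout[ch, 1]
        oa0, oa1 = pout[other, 0], pout[other, 1]
        d = (q_mf[ch] + q_mb[ca0] + q_mb[ca1] + pers[ch]
             - q_mf[other] - q_mb[oa0] - q_mb[oa1] - pers[other])
        if d >= 0.0:
            e = np.exp(-d)
            nll += np.log1p(e)
            w = e / (1.0 + e)         # sigma(-d)
        else:
            e = np.exp(d)
            nll += -d + np.log1p(e)
            w = 1.0 / (1.0 + e)
        # d(nll)/d(theta) = -w * d(d)/d(theta)
        grad[0] -= w * (d_mf[ch, 0] - d_mf[other, 0])
        grad[1] -= w * (d_mf[ch, 1] - d_mf[other, 1])
        for k in range(9):
            grad[_MB_COLS[k]] -= w * (d_mb[ca0, k] + d_mb[ca1, k]
                                      - d_mb[oa0, k] - d_mb[oa1, k])
        grad[9] -= w * (d_pers[ch, 0] - d_pers[other, 0])
        grad[10] -= w * (d_pers[ch, 1] - d_pers[other, 1])

        # ---- learning update (after the choice) ----
        rt = r1[t] + r2[t]
        for p in range(4):
            old = q_mf[p]
            d_mf[p, 0] *= (1.0 - f_mf)
            d_mf[p, 1] = (1.0 - f_mf) * d_mf[p, 1] - old
            q_mf[p] = (1.0 - f_mf) * old
        q_mf[ch] += c_mf * rt
        d_mf[ch, 0] += rt

        for o in range(4):
            old = q_mb[o]
            for k in range(9):
                d_mb[o, k] *= (1.0 - f_mb)
            d_mb[o, 6] -= old
            q_mb[o] = (1.0 - f_mb) * old
        a, b = o1[t], o2[t]
        g1 = 2 * fmt[t]
        g2 = g1 + 1
        q_mb[a] += theta[2 + g1] * r1[t]
        d_mb[a, g1] += r1[t]
        q_mb[b] += theta[2 + g2] * r2[t]
        d_mb[b, g2] += r2[t]
        if use_cross and fmt[t] == 2:
            q_mb[b] += theta[11] * r1[t]   # first reward -> second outcome
            d_mb[b, 7] += r1[t]
            q_mb[a] += theta[12] * r2[t]   # second reward -> first outcome
            d_mb[a, 8] += r2[t]

        for p in range(4):
            old = pers[p]
            d_pers[p, 0] *= (1.0 - f_p)
            d_pers[p, 1] = (1.0 - f_p) * d_pers[p, 1] - old
            pers[p] = (1.0 - f_p) * old
        pers[ch] += pr
        d_pers[ch, 0] += 1.0

    return nll, grad


@njit(cache=True)
def simulate_core(theta, use_cross, block, left, right, fmt, veg_first, pout,
                  reward_probs, u_choice, u_r1, u_r2):
    """Sample choices from the softmax policy and realize Bernoulli rewards."""
    c_mf, f_mf = theta[0], theta[1]
    f_mb, pr, f_p = theta[8], theta[9], theta[10]
    n = block.shape[0]
    chosen = np.empty(n, dtype=np.int64)
    rew1 = np.empty(n, dtype=np.int64)
    rew2 = np.empty(n, dtype=np.int64)
    q_mf = np.zeros(4)
    q_mb = np.zeros(4)
    pers = np.zeros(4)
    cur_block = -1
    for t in range(n):
        if block[t] != cur_block:
            cur_block = block[t]
            q_mf[:] = 0.0; q_mb[:] = 0.0; pers[:] = 0.0
        l, r = left[t], right[t]
        dlr = (q_mf[l] + q_mb[pout[l, 0]] + q_mb[pout[l, 1]] + pers[l]
               - q_mf[r] - q_mb[pout[r, 0]] - q_mb[pout[r, 1]] - pers[r])
        if dlr >= 0.0:
            p_left = 1.0 / (1.0 + np.exp(-dlr))
        else:
            e = np.exp(dlr)
            p_left = e / (1.0 + e)
        ch = l if u_choice[t] < p_left else r
        chosen[t] = ch

        if veg_first[t]:
            a, b = pout[ch, 1], pout[ch, 0]
        else:
            a, b = pout[ch, 0], pout[ch, 1]
        r1b = 1 if u_r1[t] < reward_probs[block[t], a] else 0
        r2b = 1 if u_r2[t] < reward_probs[block[t], b] else 0
        rew1[t] = r1b
        rew2[t] = r2b
        r1s = 1.0 if r1b == 1 else -1.0
        r2s = 1.0 if r2b == 1 else -1.0

        for p in range(4):
            q_mf[p] *= (1.0 - f_mf)
        q_mf[ch] += c_mf * (r1s + r2s)
        for o in range(4):
            q_mb[o] *= (1.0 - f_mb)
        g1 = 2 * fmt[t]
        q_mb[a] += theta[2 + g1] * r1s
        q_mb[b] += theta[2 + g1 + 1] * r2s
        if use_cross and fmt[t] == 2:
            q_mb[b] += theta[11] * r1s
            q_mb[a] += theta[12] * r2s
        for p in range(4):
            pers[p] *= (1.0 - f_p)
        pers[ch] += pr
    return chosen, rew1, rew2


@njit(cache=True)
def _eval(x, A, block, chosen, o1, o2, r1, r2, fmt, left, right, pout, use_cross):
    theta = A @ x
    f, g13 = nll_and_grad(theta, block, chosen, o1, o2, r1, r2, fmt, left,
                          right, pout, use_cross)
    return f, A.T @ g13


@njit(cache=True)
def _project(x, lb, ub):
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        v = x[i]
        if v < lb[i]:
            v = lb[i]
        elif v > ub[i]:
            v = ub[i]
        out[i] = v
    return out


@njit(cache=True)
def _pg_norm(x, g, lb, ub):
    """Max-norm of the gradient projected onto the feasible directions."""
    m = 0.0
    for i in range(x.shape[0]):
        gi = g[i]
        if x[i] <= lb[i] + 1e-12 and gi > 0.0:
            gi = 0.0
        elif x[i] >= ub[i] - 1e-12 and gi < 0.0:
            gi = 0.0
        if abs(gi) > m:
            m = abs(gi)
    return m


@njit(cache=True)
def _minimize_one(x0, lb, ub, A, block, chosen, o1, o2, r1, r2, fmt, left,
                  right, pout, use_cross, maxiter, gtol):
    """Projected L-BFGS from one start; returns (x, f, converged)."""
    k = x0.shape[0]
    m = 8
    S = np.zeros((m, k))
    Y = np.zeros((m, k))
    rho = np.zeros(m)
    n_pairs = 0
    head = 0

    x = _project(x0, lb, ub)
    f, g = _eval(x, A, block, chosen, o1, o2, r1, r2, fmt, left, right, pout,
                 use_cross)
    converged = False
    for _ in range(maxiter):
        if _pg_norm(x, g, lb, ub) < gtol:
            converged = True
            break
        # two-loop recursion for d = -H g
        q = g.copy()
        alphas = np.zeros(m)
        for j in range(n_pairs):
            idx = (head - 1 - j) % m
            alphas[idx] = rho[idx] * np.dot(S[idx], q)
            q -= alphas[idx] * Y[idx]
        if n_pairs > 0:
            last = (head - 1) % m
            gamma = np.dot(S[last], Y[last]) / max(np.dot(Y[last], Y[last]), 1e-300)
            q *= gamma
        for j in range(n_pairs - 1, -1, -1):
            idx = (head - 1 - j) % m
            beta = rho[idx] * np.dot(Y[idx], q)
            q += (alphas[idx] - beta) * S[idx]
        d = -q
        if np.dot(d, g) >= 0.0:   # not a descent direction; fall back
            d = -g

        # backtracking Armijo search along the projected arc
        step = 1.0
        accepted = False
        fn = f
        xn = x
        gn = g
        for _ls in range(25):
            xt = _project(x + step * d, lb, ub)
            delta = xt - x
            slope = np.dot(g, delta)
            if slope >= 0.0:
                norm = 0.0
                for i in range(k):
                    if abs(delta[i]) > norm:
                        norm = abs(delta[i])
                if norm < 1e-14:
                    break
                step *= 0.5
                continue
            ft, gt = _eval(xt, A, block, chosen, o1, o2, r1, r2, fmt, left,
                           right, pout, use_cross)
            if ft <= f + 1e-4 * slope:
                xn, fn, gn = xt, ft, gt
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # line search exhausted: at the arithmetic floor of the objective
            converged = _pg_norm(x, g, lb, ub) < max(1e-3, 10 * gtol)
            break

        s = xn - x
        y = gn - g
        sy = np.dot(s, y)
        if sy > 1e-12:
            S[head] = s
            Y[head] = y
            rho[head] = 1.0 / sy
            head = (head + 1) % m
            if n_pairs < m:
                n_pairs += 1
        small_step = True
        for i in range(k):
            if abs(s[i]) > 1e-12:
                small_step = False
                break
        if abs(f - fn) < 1e-12 * (1.0 + abs(f)) and small_step:
            x, f, g = xn, fn, gn
            converged = True
            break
        x, f, g = xn, fn, gn
    return x, f, converged


@njit(cache=True)
def fit_starts(x0s, lb, ub, A, block, chosen, o1, o2, r1, r2, fmt, left, right,
               pout, use_cross, maxiter, gtol):
    """Multi-start fit; returns (best x, per-start nll, per-start converged).

    Ties across starts are broken by first-found, so results are stable under
    a fixed start sequence.
    """
    ns, k = x0s.shape
    fs = np.empty(ns)
    conv = np.zeros(ns, dtype=np.bool_)
    best_x = np.zeros(k)
    best_f = np.inf
    for i in range(ns):
        x, f, c = _minimize_one(x0s[i], lb, ub, A, block, chosen, o1, o2, r1,
                                r2, fmt, left, right, pout, use_cross,
                                maxiter, gtol)
        fs[i] = f
        conv[i] = c
        if f < best_f:
            best_f = f
            best_x = x
    return best_x, fs, conv
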