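"""Reward-earnings simulations for pure model-based agents.

Earnings are standardized per session against two hypothetical agents on the
same trials: a guessing agent earning the *average* expected total reward of
the two offers and an oracle earning the *maximal* expected total reward.
Standardized earnings are (agent - guessing) / (oracle - guessing), so the
oracle scores 1 and guessing 0 in expectation.  The agent's own earnings are
its realized coins; the baselines are expectations under the generating
reward probabilities.

Two simulation studies use this scale: "yoked" agents that copy a fitted
participant's MBCA gains from one presentation format across all three
formats (quantifying the instrumental value of each format's credit
assignment), and a grid over the total retrospective-inference MBCA and the
fraction of it allocated to the first (inferred) outcome, which shows that
earnings are maximized at an even split and are symmetric in the fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fitting import FitResult
from .models import MODEL_SPECS, ParamVector, simulate_session
from .task import SessionConfig, SessionData, build_task_map, generate_session_plan

__all__ = [
    "baseline_earnings",
    "standardized_earnings",
    "policy_earnings",
    "yoked_format_agents",
    "grid_earnings",
    "argmax_fraction",
    "earnings_regression",
]

_PURE_MB = MODEL_SPECS["pure_MB"]


def _offer_sums(plan: SessionData) -> tuple[np.ndarray, np.ndarray]:
    po = plan.task_map.person_outcomes
    probs = plan.reward_probs[plan.block]          # (n, 4)
    left = probs[np.arange(plan.n_trials), po[plan.left, 0]] \
        + probs[np.arange(plan.n_trials), po[plan.left, 1]]
    right = probs[np.arange(plan.n_trials), po[plan.right, 0]] \
        + probs[np.arange(plan.n_trials), po[plan.right, 1]]
    return left, right


def baseline_earnings(plan: SessionData) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial expected points of the guessing and oracle agents.

    Guessing earns the mean of the two offered persons' expected total
    reward (sum of their two outcomes' probabilities); the oracle earns the
    max.  For two offers, oracle - guessing equals half the absolute
    difference of the two sums.
    """
    left, right = _offer_sums(plan)
    return 0.5 * (left + right), np.maximum(left, right)


def standardized_earnings(session: SessionData) -> float:
    """Standardized earnings of a filled session's realized choices."""
    if np.any(session.chosen < 0):
        raise ValueError("session has unfilled choices")
    guess, oracle = baseline_earnings(session)
    agent = (session.reward1 + session.reward2).mean()
    denom = oracle.mean() - guess.mean()
    if denom <= 0:
        raise ValueError("degenerate session: oracle does not beat guessing")
    return float((agent - guess.mean()) / denom)


def policy_earnings(plan: SessionData, policy: str, seed: int = 0) -> float:
    """Standardized earnings of a fixed policy ('oracle' or 'random') with
    realized coin draws."""
    rng = np.random.default_rng(seed)
    left, right = _offer_sums(plan)
    if policy == "oracle":
        chosen = np.where(left >= right, plan.left, plan.right)
    elif policy == "random":
        chosen = np.where(rng.random(plan.n_trials) < 0.5, plan.left, plan.right)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    po = plan.task_map.person_outcomes
    probs = plan.reward_probs[plan.block]
    idx = np.arange(plan.n_trials)
    p1 = probs[idx, po[chosen, 0]]
    p2 = probs[idx, po[chosen, 1]]
    agent = ((rng.random(plan.n_trials) < p1).astype(float)
             + (rng.random(plan.n_trials) < p2)).mean()
    guess, oracle = baseline_earnings(plan)
    return float((agent - guess.mean()) / (oracle.mean() - guess.mean()))


def _pure_mb_params(c_mb: Sequence[float], f_mb: float) -> ParamVector:
    return ParamVector(0.0, 0.0, tuple(c_mb), f_mb, 0.0, 0.0)


def _plans(n_sessions: int, config: SessionConfig, seed: int) -> list[SessionData]:
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_sessions):
        s_map, s_plan = child.generate_state(2)
        out.append(generate_session_plan(build_task_map(int(s_map)), config,
                                         seed=int(s_plan)))
    return out


def yoked_format_agents(fits: Sequence[FitResult], n_sessions: int = 1000,
                        config: SessionConfig = SessionConfig(),
                        seed: int = 0) -> pd.DataFrame:
    """Standardized earnings of format-yoked pure-MB agents.

    For each fitted participant, three agents copy the participant's MBCA
    gains from one format (S, PI or RI) across all three formats, keep the
    fitted MB forgetting rate and have no MF learning or perseveration.  All
    agents play the same ``n_sessions`` fresh synthetic sessions; per session
    the standardized earnings are averaged across the cohort, giving
    ``n_sessions`` repeated group-level measurements per regime.
    """
    plans = _plans(n_sessions, config, seed)
    regimes = {"S": (0, 1), "PI": (2, 3), "RI": (4, 5)}
    per_session = {name: np.zeros(n_sessions) for name in regimes}
    rng = np.random.default_rng(seed + 1)
    for s_idx, plan in enumerate(plans):
        for name, (i1, i2) in regimes.items():
            vals = []
            for fit in fits:
                c1, c2 = fit.params.c_mb[i1], fit.params.c_mb[i2]
                agent = _pure_mb_params((c1, c2) * 3, fit.params.f_mb)
                sim = simulate_session(agent, _PURE_MB, plan,
                                       seed=int(rng.integers(2**31)))
                vals.append(standardized_earnings(sim))
            per_session[name][s_idx] = np.mean(vals)
    rows = [{"regime": name, "mean": float(v.mean()),
             "sem": float(v.std(ddof=1) / np.sqrt(len(v))) if n_sessions > 1 else np.nan,
             "n_sessions": n_sessions}
            for name, v in per_session.items()]
    return pd.DataFrame(rows)


def grid_earnings(total_grid: Sequence[float] = tuple(np.round(np.arange(0.3, 3.01, 0.3), 10)),
                  fraction_grid: Sequence[float] = tuple(np.round(np.arange(0.0, 1.001, 0.05), 10)),
                  f_mb: float = 0.15, n_sims: int = 10_000,
                  config: SessionConfig = SessionConfig(), seed: int = 0,
                  return_sessions: bool = False):
    """Mean standardized earnings over a (total RI-MBCA, fraction) grid.

    For total t and fraction p the pure-MB agent uses gains t/2 in all S and
    PI slots, p*t for the first (inferred) and (1-p)*t for the second (seen)
    RI outcome.  All cells share the same ``n_sims`` session plans (common
    random numbers), which sharpens between-cell comparisons; ``mc_sem`` is
    the per-cell Monte-Carlo standard error across sessions.
    """
    total_grid = list(total_grid)
    fraction_grid = list(fraction_grid)
    if not total_grid or not fraction_grid:
        raise ValueError("grids must be non-empty")
    plans = _plans(n_sims, config, seed)
    rng = np.random.default_rng(seed + 1)
    cells = [(t, p) for t in total_grid for p in fraction_grid]
    raw = np.zeros((len(cells), n_sims))
    for ci, (t, p) in enumerate(cells):
        params = _pure_mb_params(
            (t / 2, t / 2, t / 2, t / 2, p * t, (1 - p) * t), f_mb)
        for s_idx, plan in enumerate(plans):
            sim = simulate_session(params, _PURE_MB, plan,
                                   seed=int(rng.integers(2**31)))
            raw[ci, s_idx] = standardized_earnings(sim)
    df = pd.DataFrame({
        "total": [c[0] for c in cells],
        "fraction": [c[1] for c in cells],
        "mean": raw.mean(axis=1),
        "mc_sem": raw.std(axis=1, ddof=1) / np.sqrt(n_sims),
        "n": n_sims,
    })
    return (df, raw) if return_sessions else df


def argmax_fraction(surface: pd.DataFrame, total: float,
                    raw: Optional[np.ndarray] = None) -> float:
    """Earnings-maximizing allocation fraction at a fixed total, with
    Monte-Carlo ties resolved toward the centre of the tied set.

    A grid point is tied with the maximum when its mean is within two
    combined standard errors (paired when the raw per-session matrix from
    ``grid_earnings(..., return_sessions=True)`` is supplied, since cells
    share sessions); the median tied fraction is returned, which favours the
    point whose neighbours are not significantly higher.
    """
    sel = surface[np.isclose(surface["total"], total)].reset_index()
    if sel.empty:
        raise ValueError(f"total {total} not on the surface")
    means = sel["mean"].to_numpy()
    best = int(np.argmax(means))
    if raw is not None:
        rows = raw[sel["index"].to_numpy()]
        diff = rows[best] - rows
        se = diff.std(axis=1, ddof=1) / np.sqrt(rows.shape[1])
        tied = (means[best] - means) <= 2 * np.where(se > 0, se, np.inf)
        tied[best] = True
    else:
        sems = sel["mc_sem"].to_numpy()
        tied = (means[best] - means) <= 2 * np.hypot(sems[best], sems)
    fractions = sel["fraction"].to_numpy()[tied]
    return float(np.median(fractions))


def earnings_regression(fits: Sequence[FitResult],
                        earnings: Sequence[float]) -> dict:
    """Robust regression of standardized earnings on MBCA level and asymmetry.

    Regressors: the mean of the six MBCA gains (overall level) and the mean
    over formats of |first - second position gain| (asymmetry).  Fitted by
    iteratively reweighted M-estimation (Huber weights).
    """
    if len(fits) != len(earnings):
        raise ValueError("one earnings value per fit required")
    if len(fits) < 3:
        raise ValueError("need at least 3 participants")
    c = np.array([f.params.c_mb for f in fits])
    level = c.mean(axis=1)
    asym = np.mean(np.abs(c[:, 0::2] - c[:, 1::2]), axis=1)
    X = sm.add_constant(np.column_stack([level, asym]))
    res = sm.RLM(np.asarray(earnings, dtype=float), X,
                 M=sm.robust.norms.HuberT()).fit()
    names = ["intercept", "mbca_level", "mbca_asymmetry"]
    return {
        "params": pd.Series(res.params, index=names),
        "bse": pd.Series(res.bse, index=names),
        "tvalues": pd.Series(res.tvalues, index=names),
        "pvalues": pd.Series(res.pvalues, index=names),
        "result": res,
    }
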