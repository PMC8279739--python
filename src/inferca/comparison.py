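"""Bootstrapped nested-model comparison (BGLRT) and recovery studies.

The generalized likelihood-ratio statistic 2*(loglik_full - loglik_sub) has
no usable asymptotic null here, so its null distribution is built by
parametric bootstrap: simulate the fitted sub-model on fresh trial plans
generated exactly as the experimental schedule, refit both models to each
synthetic session, and take the refitted improvements as the null sample.
The per-participant p value is the proportion of null statistics at least as
large as the empirical one (no continuity correction).  At the group level
the empirical statistics are summed over participants and compared against
resampled sums of per-participant null draws.

Every refit uses the same reduced-multistart procedure on both the empirical
and the bootstrap side; the full model is additionally warm-started from the
embedded sub-model solution, which guarantees a non-negative statistic and
preserves the bootstrap's exchangeability (the identical procedure is applied
to real and synthetic data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _core
from .fitting import FitResult, fit_participant
from .models import MB_GAIN_NAMES, MODEL_SPECS, ModelSpec, ParamVector, is_nested
from .task import SessionConfig, SessionData, TaskMap, build_task_map, generate_session_plan
from . import models as _models

__all__ = [
    "BGLRTResult",
    "GroupBGLRTResult",
    "bglrt_participant",
    "bglrt_group",
    "bglrt_type1_rate",
    "model_recovery_power",
    "parameter_recovery",
]


@dataclass
class BGLRTResult:
    participant_id: str
    sub_name: str
    full_name: str
    statistic: float            # empirical 2 * (loglik_full - loglik_sub)
    null_stats: np.ndarray      # bootstrap statistics (n_boot,)
    p: float                    # proportion of null >= empirical
    n_boot: int
    seed: int
    sub_fit: Optional[FitResult] = None
    full_fit: Optional[FitResult] = None


@dataclass
class GroupBGLRTResult:
    sub_name: str
    full_name: str
    statistic: float            # sum of participant statistics
    null_sums: np.ndarray
    p: float
    n_resample: int
    seed: int


# ---------------------------------------------------------------------------
# fast internal path: raw-array plans, simulation and fits (no dataclasses)
# ---------------------------------------------------------------------------

def _fast_plan(task_map: TaskMap, config: SessionConfig, rng: np.random.Generator):
    """Session-plan arrays with the experimental schedule, one shared stream."""
    nb, tpb = config.n_blocks, config.trials_per_block
    n = nb * tpb
    pairs = task_map.valid_pairs
    per_pair = tpb // 4
    pair_idx = np.empty(n, dtype=np.int64)
    base = np.repeat(np.arange(4), per_pair)
    for b in range(nb):
        pair_idx[b * tpb:(b + 1) * tpb] = rng.permutation(base)
    first, second = pairs[pair_idx, 0], pairs[pair_idx, 1]
    swap = rng.random(n) < 0.5
    left = np.where(swap, second, first)
    right = np.where(swap, first, second)
    fmt = rng.choice(3, size=n, p=np.asarray(config.format_probs))
    veg_first = rng.random(n) < 0.5
    probs = rng.uniform(config.reward_prob_low, config.reward_prob_high, (nb, 4))
    block = np.repeat(np.arange(nb), tpb)
    return block, left.astype(np.int64), right.astype(np.int64), \
        fmt.astype(np.int64), veg_first, probs


def _simulate_arrays(theta, use_cross, plan, pout, rng):
    block, left, right, fmt, veg_first, probs = plan
    n = block.shape[0]
    chosen, r1, r2 = _core.simulate_core(
        theta, use_cross, block, left, right, fmt, veg_first.astype(np.bool_),
        pout, probs, rng.random(n), rng.random(n), rng.random(n))
    o1 = np.where(veg_first, pout[chosen, 1], pout[chosen, 0])
    o2 = np.where(veg_first, pout[chosen, 0], pout[chosen, 1])
    r1s = np.where(r1 == 1, 1.0, -1.0)
    r2s = np.where(r2 == 1, 1.0, -1.0)
    return (block, chosen, o1.astype(np.int64), o2.astype(np.int64),
            r1s, r2s, fmt, left, right, pout)


def _neutral(spec: ModelSpec) -> np.ndarray:
    x = np.zeros(spec.n_free)
    for i, nm in enumerate(spec.free_names):
        if nm in ("f_mf", "f_mb", "f_p"):
            x[i] = 0.2
    return x


def _raw_fit(spec: ModelSpec, arrs, starts, gtol, maxiter):
    b = spec.bounds
    x, fs, _ = _core.fit_starts(
        np.ascontiguousarray(starts), b[:, 0].copy(), b[:, 1].copy(),
        np.ascontiguousarray(spec.expand_matrix), *arrs, spec.uses_cross,
        maxiter, gtol)
    return x, -float(np.min(fs))


def _fit_pair(sub: ModelSpec, full: ModelSpec, arrs, rng, n_starts, gtol, maxiter):
    """Fit sub then full (warm-started from the embedded sub solution)."""
    sub_starts = np.vstack([
        _neutral(sub)[None, :],
        rng.uniform(sub.bounds[:, 0], sub.bounds[:, 1], (max(n_starts - 1, 0), sub.n_free)),
    ])[:max(n_starts, 1)]
    xs, ll_sub = _raw_fit(sub, arrs, sub_starts, gtol, maxiter)
    warm = full.free_from_full(sub.expand(xs))
    full_starts = np.vstack([
        warm[None, :],
        _neutral(full)[None, :],
        rng.uniform(full.bounds[:, 0], full.bounds[:, 1], (max(n_starts - 1, 0), full.n_free)),
    ])[:max(n_starts, 1) + 1]
    xf, ll_full = _raw_fit(full, arrs, full_starts, gtol, maxiter)
    return xs, ll_sub, xf, ll_full


_BOOT_GTOL = 1e-5
_BOOT_MAXITER = 150


def bglrt_participant(session: SessionData, sub: ModelSpec, full: ModelSpec,
                      n_boot: int = 1001, n_starts: int = 20, seed: int = 0,
                      keep_fits: bool = True) -> BGLRTResult:
    """Parametric-bootstrap likelihood-ratio test for one participant.

    ``n_boot`` synthetic sessions are simulated from the sub-model at its ML
    parameters on novel trial plans generated with the experimental schedule,
    and both models are refitted to each with the same (reduced) multi-start
    procedure used on the empirical session.
    """
    if not is_nested(sub, full):
        raise ValueError(f"{sub.name} is not nested in {full.name}")
    rng = np.random.default_rng(seed)
    arrs = _core.session_arrays(session)
    pout = arrs[-1]
    xs, ll_sub, xf, ll_full = _fit_pair(sub, full, arrs, rng, n_starts,
                                        _BOOT_GTOL, _BOOT_MAXITER)
    stat = 2.0 * (ll_full - ll_sub)
    if stat < 0:
        warnings.warn(f"negative empirical statistic {stat:.2e} clamped to 0")
        stat = 0.0

    theta_sub = sub.expand_array(xs)
    null = np.empty(n_boot)
    for b in range(n_boot):
        plan = _fast_plan(session.task_map, session.config, rng)
        barrs = _simulate_arrays(theta_sub, sub.uses_cross, plan, pout, rng)
        _, lls, _, llf = _fit_pair(sub, full, barrs, rng, n_starts,
                                   _BOOT_GTOL, _BOOT_MAXITER)
        null[b] = max(2.0 * (llf - lls), 0.0)

    p = float(np.mean(null >= stat))
    res = BGLRTResult(session.participant_id, sub.name, full.name, stat, null,
                      p, n_boot, seed)
    if keep_fits:
        res.sub_fit = fit_result_from_raw(sub, xs, ll_sub, session, seed)
        res.full_fit = fit_result_from_raw(full, xf, ll_full, session, seed)
    return res


def fit_result_from_raw(spec: ModelSpec, x: np.ndarray, loglik: float,
                        session: SessionData, seed: int) -> FitResult:
    return FitResult(spec.name, x, spec.expand(x), loglik,
                     np.array([loglik]), 1, np.array([True]), seed,
                     session.participant_id)


def bglrt_group(results: Sequence[BGLRTResult], n_resample: int = 10_000,
                seed: int = 0) -> GroupBGLRTResult:
    """Group-level BGLRT: sum statistics, resample one null draw per participant."""
    if not results:
        raise ValueError("no participant results")
    sub = results[0].sub_name
    if any(r.sub_name != sub for r in results):
        raise ValueError("mixed sub-model results")
    rng = np.random.default_rng(seed)
    stat = float(sum(r.statistic for r in results))
    null_mat = np.stack([
        r.null_stats[rng.integers(0, len(r.null_stats), n_resample)]
        for r in results])
    null_sums = null_mat.sum(axis=0)
    p = float(np.mean(null_sums >= stat))
    return GroupBGLRTResult(sub, results[0].full_name, stat, null_sums, p,
                            n_resample, seed)


# ---------------------------------------------------------------------------
# cohort-level studies (type-I error, power, parameter recovery)
# ---------------------------------------------------------------------------

def _group_bglrt_once(gen_thetas: Sequence[np.ndarray], gen_use_cross: bool,
                      sub: ModelSpec, full: ModelSpec, config: SessionConfig,
                      n_boot: int, n_starts: int, n_resample: int,
                      rng: np.random.Generator) -> float:
    """One synthetic cohort -> group p value.  ``gen_thetas``: one full
    13-vector per participant for the generating model."""
    stats = []
    nulls = []
    for theta_gen in gen_thetas:
        task_map = build_task_map(int(rng.integers(2**31)))
        pout = np.ascontiguousarray(task_map.person_outcomes, dtype=np.int64)
        plan = _fast_plan(task_map, config, rng)
        arrs = _simulate_arrays(np.asarray(theta_gen, dtype=float),
                                gen_use_cross, plan, pout, rng)
        xs, lls, _, llf = _fit_pair(sub, full, arrs, rng, n_starts,
                                    _BOOT_GTOL, _BOOT_MAXITER)
        stats.append(max(2.0 * (llf - lls), 0.0))
        theta_sub = sub.expand_array(xs)
        null = np.empty(n_boot)
        for b in range(n_boot):
            bplan = _fast_plan(task_map, config, rng)
            barrs = _simulate_arrays(theta_sub, sub.uses_cross, bplan, pout, rng)
            _, blls, _, bllf = _fit_pair(sub, full, barrs, rng, n_starts,
                                         _BOOT_GTOL, _BOOT_MAXITER)
            null[b] = max(2.0 * (bllf - blls), 0.0)
        nulls.append(null)

    stat = float(np.sum(stats))
    idx = rng.integers(0, n_boot, (len(nulls), n_resample))
    null_sums = np.sum(np.stack([null[i] for null, i in zip(nulls, idx)]), axis=0)
    return float(np.mean(null_sums >= stat))


def bglrt_type1_rate(sub: ModelSpec, full: ModelSpec, sub_params: ParamVector,
                     n_participants: int = 10,
                     config: SessionConfig = SessionConfig(n_blocks=4),
                     n_cohorts: int = 200, n_boot: int = 99, n_starts: int = 1,
                     alpha: float = 0.05, n_resample: int = 2000,
                     seed: int = 0) -> dict:
    """Empirical type-I error of the group BGLRT under a true sub-model.

    Simulates ``n_cohorts`` cohorts from ``sub`` at fixed parameters and
    returns the fraction rejected at level ``alpha`` (rule: group p <= alpha).
    """
    if not is_nested(sub, full):
        raise ValueError(f"{sub.name} is not nested in {full.name}")
    rng = np.random.default_rng(seed)
    theta = sub_params.to_array() if isinstance(sub_params, ParamVector) \
        else sub.expand_array(sub_params)
    ps = np.empty(n_cohorts)
    for c in range(n_cohorts):
        ps[c] = _group_bglrt_once([theta] * n_participants, sub.uses_cross,
                                  sub, full, config, n_boot, n_starts,
                                  n_resample, rng)
    rate = float(np.mean(ps <= alpha))
    return {"rejection_rate": rate, "p_values": ps, "alpha": alpha,
            "n_cohorts": n_cohorts, "n_boot": n_boot,
            "n_participants": n_participants}


def model_recovery_power(cohort_params: Sequence[ParamVector],
                         subs: Sequence[str] = ("no_presentation_MBCA",),
                         n_sims: int = 20, alpha: float = 0.05, seed: int = 0,
                         config: SessionConfig = SessionConfig(),
                         full_name: str = "full", n_boot: int = 99,
                         n_starts: int = 1, n_resample: int = 2000) -> dict:
    """Power of the group BGLRT: cohorts simulated from the full model.

    Returns per-sub rejection frequency at level ``alpha``.
    """
    full = MODEL_SPECS[full_name]
    thetas = [p.to_array() for p in cohort_params]
    rng = np.random.default_rng(seed)
    out = {}
    for sub_name in subs:
        sub = MODEL_SPECS[sub_name]
        rejections = 0
        for _ in range(n_sims):
            p = _group_bglrt_once(thetas, full.uses_cross, sub, full, config,
                                  n_boot, n_starts, n_resample, rng)
            rejections += p <= alpha
        out[sub_name] = rejections / n_sims
    return out


def parameter_recovery(cohort: Sequence[tuple[SessionData, ParamVector]],
                       n_reps: int = 1, n_starts: int = 20,
                       seed: int = 0) -> dict:
    """Generating-vs-recovered correlations and error trade-offs for the six MBCA gains.

    For each cohort member and repetition, a fresh session is simulated from
    the generating parameters (same schedule as the member's session) and the
    full model refitted.  Returns Pearson r per MBCA gain over all
    participant x repetition datasets and the pairwise correlation matrix of
    estimation errors (generating minus recovered).
    """
    full = MODEL_SPECS["full"]
    rng = np.random.default_rng(seed)
    gen, rec = [], []
    for session, params in cohort:
        theta = params.to_array()
        for rep in range(n_reps):
            plan = generate_session_plan(session.task_map, session.config,
                                         seed=int(rng.integers(2**31)))
            plan.participant_id = session.participant_id
            sim = _models.simulate_session(params, full, plan,
                                           seed=int(rng.integers(2**31)))
            fit = fit_participant(sim, full, n_starts=n_starts,
                                  seed=int(rng.integers(2**31)))
            gen.append(theta[2:8])
            rec.append(fit.params.to_array()[2:8])
    gen = np.array(gen)
    rec = np.array(rec)
    r = np.full(6, np.nan)
    for j in range(6):
        if np.std(gen[:, j]) > 0 and np.std(rec[:, j]) > 0:
            r[j] = sps.pearsonr(gen[:, j], rec[:, j]).statistic
        else:
            warnings.warn(f"degenerate variance for {MB_GAIN_NAMES[j]}; r undefined")
    err = gen - rec
    with np.errstate(invalid="ignore"):
        err_corr = np.corrcoef(err.T)
    return {
        "pearson_r": pd.Series(r, index=list(MB_GAIN_NAMES)),
        "error_correlations": pd.DataFrame(err_corr, index=list(MB_GAIN_NAMES),
                                           columns=list(MB_GAIN_NAMES)),
        "generating": gen,
        "recovered": rec,
    }
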