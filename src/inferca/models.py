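"""Hybrid model-based / model-free value learning with format-specific credit assignment.

The model maintains three latent value sets, all reset to zero at each block
start: cached person values ``Q_MF`` (model-free), outcome values ``Q_MB``
(model-based; persons are valued at choice as the sum of their two outcomes'
values) and perseveration values ``PERS``.  After a choice with signed
rewards r in {+1, -1} (1 -> +1, 0 -> -1):

    Q_MF(chosen)      <- (1 - f_MF) Q_MF(chosen) + c_MF * (r1 + r2)
    Q_MF(not chosen)  <- (1 - f_MF) Q_MF(not chosen)
    Q_MB(outcome_k)   <- (1 - f_MB) Q_MB(outcome_k) + c_MB[format, k] * r_k
    Q_MB(unrelated)   <- (1 - f_MB) Q_MB(unrelated)
    PERS(person)      <- (1 - f_P) PERS(person) + pr * 1[person = chosen]

where k is the outcome's temporal position (1 = shown first) and c_MB carries
six gains, one per presentation format x position.  Choice is a softmax over
Q_net = Q_MB + Q_MF + PERS of the two offered persons; there is no inverse
temperature (its scale is absorbed by the gains).  The "RI cross CA"
extension lets each reward on retrospective-inference trials additionally
reinforce the *other* outcome via two extra gains; the full model is nested
in it at zero cross gains.

Seven nested sub-models ablate or constrain the six MBCA gains (see
``MODEL_SPECS``).  All constraint sets are linear, so each spec is a linear
map from its free-parameter vector to the canonical 13-entry full vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from . import _core
from .task import RI, SessionData, TaskMap, TrialView

__all__ = [
    "ParamVector",
    "LatentState",
    "ModelSpec",
    "MODEL_SPECS",
    "PARAM_NAMES",
    "MB_GAIN_NAMES",
    "is_nested",
    "mb_person_value",
    "choice_probability",
    "update_state",
    "session_loglik",
    "session_loglik_trace",
    "simulate_session",
]

#: Canonical order of the full parameter vector (length 13).
PARAM_NAMES = (
    "c_mf", "f_mf",
    "c_mb_S1", "c_mb_S2", "c_mb_PI1", "c_mb_PI2", "c_mb_RI1", "c_mb_RI2",
    "f_mb", "pr", "f_p",
    "c_cross_12", "c_cross_21",
)
MB_GAIN_NAMES = PARAM_NAMES[2:8]
_FORGETTING = {"f_mf", "f_mb", "f_p"}
#: Optimization box: forgetting rates in [0, 1], gains in [-5, 5].  The
#: exclusion rule presumes negative credit-assignment gains are representable.
GAIN_BOUNDS = (-5.0, 5.0)


@dataclass(frozen=True)
class ParamVector:
    """Full model parameters in canonical order.

    ``c_mb`` holds the six MBCA gains as (S1, S2, PI1, PI2, RI1, RI2) where
    the digit is the outcome's temporal position.  ``c_cross_12`` is the gain
    with which, on RI trials, the first reward reinforces the second outcome
    (and ``c_cross_21`` vice versa); both are zero except under the
    RI-cross-CA model.
    """

    c_mf: float
    f_mf: float
    c_mb: tuple[float, float, float, float, float, float]
    f_mb: float
    pr: float
    f_p: float
    c_cross_12: float = 0.0
    c_cross_21: float = 0.0

    def __post_init__(self):
        for name in _FORGETTING:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if len(self.c_mb) != 6:
            raise ValueError("c_mb must have 6 entries (S1,S2,PI1,PI2,RI1,RI2)")

    def to_array(self) -> np.ndarray:
        return np.array([self.c_mf, self.f_mf, *self.c_mb,
                         self.f_mb, self.pr, self.f_p,
                         self.c_cross_12, self.c_cross_21])

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "ParamVector":
        theta = np.asarray(theta, dtype=float)
        return cls(theta[0], theta[1], tuple(theta[2:8]),
                   theta[8], theta[9], theta[10], theta[11], theta[12])

    def to_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES, self.to_array()))

    @property
    def ca_params(self) -> np.ndarray:
        """The 7 credit-assignment gains (c_MF plus six c_MB)."""
        return np.array([self.c_mf, *self.c_mb])

    def c_mb_of(self, fmt: int, pos: int) -> float:
        """MBCA gain for presentation format (0=S,1=PI,2=RI) and position (1/2)."""
        return self.c_mb[2 * fmt + (pos - 1)]


@dataclass
class LatentState:
    """Per-person MF and perseveration values and per-outcome MB values."""

    q_mf: np.ndarray = field(default_factory=lambda: np.zeros(4))
    q_mb: np.ndarray = field(default_factory=lambda: np.zeros(4))
    pers: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def reset(self) -> None:
        self.q_mf[:] = 0.0
        self.q_mb[:] = 0.0
        self.pers[:] = 0.0

    def copy(self) -> "LatentState":
        return LatentState(self.q_mf.copy(), self.q_mb.copy(), self.pers.copy())


@dataclass(frozen=True)
class ModelSpec:
    """A named constraint set: linear map from free parameters to the full vector.

    ``expand_matrix`` is (13, k); ``expand(x) = ParamVector(expand_matrix @ x)``.
    All seven sub-models, the full model and the RI-cross-CA extension are
    expressible this way because every constraint is an equality, a zero or a
    sum of free parameters.
    """

    name: str
    free_names: tuple[str, ...]
    expand_matrix: np.ndarray

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    @property
    def uses_cross(self) -> bool:
        return bool(np.any(self.expand_matrix[11:13] != 0))

    @property
    def bounds(self) -> np.ndarray:
        """(k, 2) optimization box for the free parameters."""
        out = np.empty((self.n_free, 2))
        for i, name in enumerate(self.free_names):
            out[i] = (0.0, 1.0) if name in _FORGETTING else GAIN_BOUNDS
        return out

    def expand(self, free: np.ndarray) -> ParamVector:
        free = np.asarray(free, dtype=float)
        if free.shape != (self.n_free,):
            raise ValueError(
                f"{self.name} expects {self.n_free} free parameters, got {free.shape}")
        return ParamVector.from_array(self.expand_matrix @ free)

    def expand_array(self, free: np.ndarray) -> np.ndarray:
        return self.expand_matrix @ np.asarray(free, dtype=float)

    def free_from_full(self, params: ParamVector) -> np.ndarray:
        """Least-squares pullback of a full vector onto the free coordinates."""
        x, *_ = np.linalg.lstsq(self.expand_matrix, params.to_array(), rcond=None)
        return x


def _make_spec(name: str, mapping: dict[str, Sequence[int]]) -> ModelSpec:
    free = tuple(mapping)
    A = np.zeros((13, len(free)))
    for j, rows in enumerate(mapping.values()):
        for r in rows:
            A[r, j] = 1.0
    return ModelSpec(name, free, A)


# Row indices: 0 c_mf, 1 f_mf, 2..7 c_mb (S1,S2,PI1,PI2,RI1,RI2), 8 f_mb,
# 9 pr, 10 f_p, 11 c_cross_12, 12 c_cross_21.
MODEL_SPECS: dict[str, ModelSpec] = {
    spec.name: spec for spec in [
        _make_spec("full", {
            "c_mf": [0], "f_mf": [1],
            "c_mb_S1": [2], "c_mb_S2": [3], "c_mb_PI1": [4], "c_mb_PI2": [5],
            "c_mb_RI1": [6], "c_mb_RI2": [7],
            "f_mb": [8], "pr": [9], "f_p": [10]}),
        _make_spec("RI_cross_CA", {
            "c_mf": [0], "f_mf": [1],
            "c_mb_S1": [2], "c_mb_S2": [3], "c_mb_PI1": [4], "c_mb_PI2": [5],
            "c_mb_RI1": [6], "c_mb_RI2": [7],
            "f_mb": [8], "pr": [9], "f_p": [10],
            "c_cross_12": [11], "c_cross_21": [12]}),
        # pure MBCA: all MF parameters clamped to zero
        _make_spec("pure_MB", {
            "c_mb_S1": [2], "c_mb_S2": [3], "c_mb_PI1": [4], "c_mb_PI2": [5],
            "c_mb_RI1": [6], "c_mb_RI2": [7],
            "f_mb": [8], "pr": [9], "f_p": [10]}),
        # pure MFCA: all MB parameters clamped to zero
        _make_spec("pure_MF", {
            "c_mf": [0], "f_mf": [1], "pr": [9], "f_p": [10]}),
        # one MBCA gain shared across all formats and positions
        _make_spec("no_presentation_MBCA", {
            "c_mf": [0], "f_mf": [1], "c_mb": [2, 3, 4, 5, 6, 7],
            "f_mb": [8], "pr": [9], "f_p": [10]}),
        # per-format gain, equal across positions
        _make_spec("no_position_MBCA", {
            "c_mf": [0], "f_mf": [1],
            "c_mb_S": [2, 3], "c_mb_PI": [4, 5], "c_mb_RI": [6, 7],
            "f_mb": [8], "pr": [9], "f_p": [10]}),
        # per-position gain, equal across formats
        _make_spec("no_format_MBCA", {
            "c_mf": [0], "f_mf": [1], "c_mb_1": [2, 4, 6], "c_mb_2": [3, 5, 7],
            "f_mb": [8], "pr": [9], "f_p": [10]}),
        # additive format + position effects, no interaction:
        # c[format, pos] = c_format + c_pos2 * 1[pos = 2]
        _make_spec("additive_MBCA", {
            "c_mf": [0], "f_mf": [1],
            "c_mb_S": [2, 3], "c_mb_PI": [4, 5], "c_mb_RI": [6, 7],
            "c_mb_pos2": [3, 5, 7],
            "f_mb": [8], "pr": [9], "f_p": [10]}),
        # gains tied by functional (inference) order: on RI trials credit is
        # assigned to the temporally second outcome first, so RI positions flip
        _make_spec("flipped_functional", {
            "c_mf": [0], "f_mf": [1],
            "c_mb_fn1": [2, 4, 7], "c_mb_fn2": [3, 5, 6],
            "f_mb": [8], "pr": [9], "f_p": [10]}),
    ]
}

_SUB_MODELS = ("pure_MB", "pure_MF", "no_presentation_MBCA", "no_position_MBCA",
               "no_format_MBCA", "additive_MBCA", "flipped_functional")


def is_nested(sub: ModelSpec, full: ModelSpec) -> bool:
    """True iff ``sub``'s parameter set is a constrained version of ``full``'s."""
    if full.name == "RI_cross_CA":
        return sub.name != "RI_cross_CA"
    if full.name == "full":
        return sub.name in _SUB_MODELS
    return False


# ---------------------------------------------------------------------------
# Readable reference operations (the numba kernels in _core are the fast path
# and are checked against these in the test suite).
# ---------------------------------------------------------------------------

def mb_person_value(state: LatentState, task_map: TaskMap, person: int) -> float:
    """MB value of a person: sum of their two outcomes' Q_MB values."""
    a, v = task_map.outcomes_of(person)
    return float(state.q_mb[a] + state.q_mb[v])


def _q_net(state: LatentState, task_map: TaskMap, person: int) -> float:
    return (state.q_mf[person] + mb_person_value(state, task_map, person)
            + state.pers[person])


def choice_probability(state: LatentState, task_map: TaskMap,
                       offered_pair: tuple[int, int]) -> tuple[float, float]:
    """Softmax probabilities of choosing each person of the offered pair."""
    d = _q_net(state, task_map, offered_pair[0]) - _q_net(state, task_map, offered_pair[1])
    p0 = 1.0 / (1.0 + np.exp(-d)) if d >= 0 else np.exp(d) / (1.0 + np.exp(d))
    return float(p0), float(1.0 - p0)


def _signed(r: int) -> float:
    return 1.0 if r == 1 else -1.0


def update_state(state: LatentState, params: ParamVector, spec: ModelSpec,
                 trial: TrialView, task_map: TaskMap) -> LatentState:
    """Apply one trial's learning update; returns a new state.

    Trials with a missing choice trigger no learning and are returned
    unchanged.  On RI trials under the RI-cross-CA spec each reward also
    reinforces the other outcome through the cross gains.
    """
    if trial.chosen < 0:
        return state.copy()
    new = state.copy()
    ch = trial.chosen
    r1, r2 = _signed(trial.reward1), _signed(trial.reward2)

    # model-free system: chosen person reinforced by the summed signed reward
    new.q_mf *= (1.0 - params.f_mf)
    new.q_mf[ch] += params.c_mf * (r1 + r2)

    # model-based system: each of the chosen person's outcomes by its own reward
    a, v = task_map.outcomes_of(ch)
    o1, o2 = (v, a) if trial.veg_first else (a, v)
    new.q_mb *= (1.0 - params.f_mb)
    new.q_mb[o1] += params.c_mb_of(trial.fmt, 1) * r1
    new.q_mb[o2] += params.c_mb_of(trial.fmt, 2) * r2
    if spec.uses_cross and trial.fmt == RI:
        new.q_mb[o2] += params.c_cross_12 * r1
        new.q_mb[o1] += params.c_cross_21 * r2

    # progressive perseveration toward the chosen person
    new.pers *= (1.0 - params.f_p)
    new.pers[ch] += params.pr
    return new


def _as_theta(params: Union[ParamVector, np.ndarray, Sequence[float]],
              spec: ModelSpec) -> np.ndarray:
    if isinstance(params, ParamVector):
        return params.to_array()
    arr = np.asarray(params, dtype=float)
    if arr.shape == (13,):
        return arr
    return spec.expand_array(arr)


def session_loglik(params: Union[ParamVector, np.ndarray], spec: ModelSpec,
                   session: SessionData) -> float:
    """Log-likelihood of the session's observed choices under ``spec``.

    ``params`` may be a free vector for ``spec``, a full 13-vector or a
    :class:`ParamVector`.  Trials without a choice contribute nothing and
    trigger no update; latent values reset at block boundaries.
    """
    theta = _as_theta(params, spec)
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite parameters")
    arrs = _core.session_arrays(session)
    nll, _ = _core.nll_and_grad(theta, *arrs, spec.uses_cross)
    return -float(nll)


def session_loglik_trace(params: Union[ParamVector, np.ndarray], spec: ModelSpec,
                         session: SessionData) -> np.ndarray:
    """Per-trial log choice probabilities (NaN for missing choices).

    Straightforward Python recursion over :func:`update_state`; useful for
    debugging traces (exportable as CSV) and as a slow cross-check of
    :func:`session_loglik`.
    """
    theta = _as_theta(params, spec)
    pv = ParamVector.from_array(theta)
    state = LatentState()
    out = np.full(session.n_trials, np.nan)
    for t, trial in enumerate(session):
        if t == 0 or session.block[t] != session.block[t - 1]:
            state.reset()
        if trial.chosen < 0:
            continue
        pair = (trial.chosen, trial.left if trial.chosen == trial.right else trial.right)
        p_chosen, _ = choice_probability(state, session.task_map, pair)
        out[t] = np.log(p_chosen)
        state = update_state(state, pv, spec, trial, session.task_map)
    return out


def sample_plausible_params(rng: np.random.Generator) -> ParamVector:
    """Draw a plausible full-model parameter vector for synthetic cohorts.

    Ranges give clearly reward-sensitive but noisy agents, with MBCA-gain
    magnitudes on the scale typical of fitted participants (roughly 0.05-0.6)
    and moderate forgetting and perseveration:
    c_MF ~ U[0.2, 0.8], each c_MB ~ U[0.05, 0.6], f_MF/f_MB ~ U[0.05, 0.4],
    pr ~ U[0, 0.3], f_P ~ U[0.1, 0.6].
    """
    return ParamVector(
        c_mf=rng.uniform(0.2, 0.8),
        f_mf=rng.uniform(0.05, 0.4),
        c_mb=tuple(rng.uniform(0.05, 0.6, 6)),
        f_mb=rng.uniform(0.05, 0.4),
        pr=rng.uniform(0.0, 0.3),
        f_p=rng.uniform(0.1, 0.6))


def simulate_session(params: Union[ParamVector, np.ndarray], spec: ModelSpec,
                     plan: SessionData, seed: int) -> SessionData:
    """Simulate choices and rewards on a fresh plan; returns a filled copy.

    Choices are sampled from the softmax policy and rewards realized from the
    plan's per-block probabilities.  Deterministic given (params, plan, seed).
    """
    theta = _as_theta(params, spec)
    rng = np.random.default_rng(seed)
    n = plan.n_trials
    u_choice = rng.random(n)
    u_r1 = rng.random(n)
    u_r2 = rng.random(n)
    out = plan.copy_plan()
    chosen, r1, r2 = _core.simulate_core(
        theta, spec.uses_cross, out.block, out.left, out.right, out.fmt,
        out.veg_first.astype(np.bool_), out.task_map.person_outcomes,
        out.reward_probs, u_choice, u_r1, u_r2)
    out.chosen = chosen
    out.reward1 = r1
    out.reward2 = r2
    return out
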