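"""Dual-outcome bandit task: combinatorial structure and synthetic session plans.

The task offers choices between four "persons", each deterministically
associated with a unique (animal, vegetable) pair such that every animal and
every vegetable is shared by exactly two persons.  This bipartite structure
(the cognitive map) is what lets model-based credit assignment generalize
across persons who share an outcome.  On each trial two persons who share
exactly one outcome are offered; after a choice the chosen person's two
outcomes are revealed sequentially in random order, each rewarded by an
independent Bernoulli draw with a per-block probability.  Outcomes appear in
one of three presentation formats: standard (S, both outcomes visible),
prospective inference (PI, second outcome concealed) and retrospective
inference (RI, first outcome concealed); rewards are always visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "FORMATS",
    "S",
    "PI",
    "RI",
    "TaskMap",
    "SessionConfig",
    "SessionData",
    "TrialView",
    "RTModel",
    "build_task_map",
    "generate_session_plan",
    "realize_rewards",
    "generate_synthetic_cohort",
]

#: Presentation format codes, in canonical order.
FORMATS = ("S", "PI", "RI")
S, PI, RI = 0, 1, 2

_DEFAULT_ANIMALS = ("monkey", "sheep")
_DEFAULT_VEGETABLES = ("garlic", "carrot")
_DEFAULT_PERSONS = ("woman", "bearded_man", "child", "old_man")


class ConfigurationError(ValueError):
    """Raised when a session configuration violates the task's constraints."""


@dataclass(frozen=True)
class TaskMap:
    """The bipartite person <-> outcome map.

    Outcomes are indexed 0..3: indices 0-1 are animals, 2-3 vegetables.
    ``person_outcomes[p] = (animal_index, vegetable_index)`` gives the two
    outcomes of person ``p``.  Exactly 4 unordered person pairs share exactly
    one outcome (the valid choice pairs); the remaining 2 pairs share none.
    """

    persons: tuple[str, str, str, str]
    animals: tuple[str, str]
    vegetables: tuple[str, str]
    person_outcomes: np.ndarray  # (4, 2) int: [animal_idx, vegetable_idx]

    def __post_init__(self):
        po = np.asarray(self.person_outcomes, dtype=np.int64)
        object.__setattr__(self, "person_outcomes", po)
        if po.shape != (4, 2):
            raise ValueError("person_outcomes must be (4, 2)")
        pairs = {tuple(row) for row in po}
        if len(pairs) != 4:
            raise ValueError("each person must favor a unique outcome pair")
        counts = np.bincount(po.ravel(), minlength=4)
        if not np.all(counts == 2):
            raise ValueError("every outcome must be shared by exactly 2 persons")

    # -- derived structure -------------------------------------------------
    @property
    def outcome_names(self) -> tuple[str, str, str, str]:
        return (*self.animals, *self.vegetables)

    @property
    def preference(self) -> dict[str, tuple[str, str]]:
        names = self.outcome_names
        return {
            self.persons[p]: (names[self.person_outcomes[p, 0]],
                              names[self.person_outcomes[p, 1]])
            for p in range(4)
        }

    def shared_outcome(self, p1: int, p2: int) -> int:
        """Outcome index shared by persons ``p1`` and ``p2``, or -1 if none."""
        common = set(self.person_outcomes[p1]) & set(self.person_outcomes[p2])
        if len(common) > 1:
            raise ValueError("persons cannot share both outcomes")
        return common.pop() if common else -1

    @property
    def valid_pairs(self) -> np.ndarray:
        """(4, 2) array of unordered person pairs sharing exactly one outcome."""
        out = [
            (i, j)
            for i in range(4)
            for j in range(i + 1, 4)
            if self.shared_outcome(i, j) >= 0
        ]
        return np.array(out, dtype=np.int64)

    def persons_sharing(self, outcome: int) -> tuple[int, int]:
        who = np.where((self.person_outcomes == outcome).any(axis=1))[0]
        return int(who[0]), int(who[1])

    def outcomes_of(self, person: int) -> tuple[int, int]:
        if not 0 <= person < 4:
            raise ValueError(f"unknown person index {person}")
        return int(self.person_outcomes[person, 0]), int(self.person_outcomes[person, 1])


def build_task_map(seed: int,
                   persons: Sequence[str] = _DEFAULT_PERSONS,
                   animals: Sequence[str] = _DEFAULT_ANIMALS,
                   vegetables: Sequence[str] = _DEFAULT_VEGETABLES) -> TaskMap:
    """Randomly assign the 4 (animal, vegetable) combinations to the 4 persons.

    The person <-> outcome map is created anew per participant; the bipartite
    structure itself (every outcome shared by exactly two persons) is fixed by
    construction: the four persons receive the four combinations
    {animal 0/1} x {vegetable 0/1} in seed-shuffled order.
    """
    rng = np.random.default_rng(seed)
    combos = np.array([(a, v) for a in (0, 1) for v in (2, 3)], dtype=np.int64)
    rng.shuffle(combos, axis=0)
    return TaskMap(tuple(persons), tuple(animals), tuple(vegetables), combos)


@dataclass(frozen=True)
class SessionConfig:
    """Experimental schedule parameters.

    Defaults reproduce the experiment: 10 blocks of 36 trials, the four valid
    person pairs each offered 9 times per block in random order, the three
    presentation formats interleaved with equal probability, and per-block
    outcome reward probabilities drawn iid uniform on [0.2, 0.8].
    """

    n_blocks: int = 10
    trials_per_block: int = 36
    reward_prob_low: float = 0.2
    reward_prob_high: float = 0.8
    format_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    choice_deadline_s: float = 2.0  # metadata only; no deadline is simulated
    rng_seed: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "format_probs", tuple(self.format_probs))
        if self.trials_per_block % 4 != 0:
            raise ConfigurationError(
                f"trials_per_block={self.trials_per_block} must be divisible by 4 "
                "(equal allocation to the 4 valid pairs)")
        if abs(sum(self.format_probs)) - 1 > 1e-9 or not np.isclose(sum(self.format_probs), 1.0):
            raise ConfigurationError("format_probs must sum to 1")
        if not 0 <= self.reward_prob_low <= self.reward_prob_high <= 1:
            raise ConfigurationError("reward probability range invalid")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


class TrialView(NamedTuple):
    """Read-only view of one trial of a session."""

    block: int
    trial_in_block: int
    left: int
    right: int
    fmt: int            # 0=S, 1=PI, 2=RI
    veg_first: bool     # temporal order of the chosen person's outcomes
    chosen: int         # person index, or -1 if missing
    reward1: int        # binary reward of the temporally first outcome (-1 unset)
    reward2: int
    rt_ms: float

    @property
    def offered(self) -> tuple[int, int]:
        return (self.left, self.right)


@dataclass
class SessionData:
    """One participant's ordered trial records plus the generating schedule.

    Trial-wise arrays are column-oriented for speed; :meth:`trial` exposes a
    row view.  ``chosen`` is -1 for missing responses and ``reward1/2`` are -1
    until a choice is realized.  Outcome identities in temporal order are only
    defined after a choice (they belong to the chosen person).
    """

    task_map: TaskMap
    config: SessionConfig
    reward_probs: np.ndarray        # (n_blocks, 4) per-block outcome probabilities
    block: np.ndarray               # (n,) int
    left: np.ndarray                # (n,) person index shown on the left
    right: np.ndarray               # (n,) person index shown on the right
    fmt: np.ndarray                 # (n,) int in {0,1,2}
    veg_first: np.ndarray           # (n,) bool
    chosen: np.ndarray = None       # (n,) int, -1 = missing
    reward1: np.ndarray = None      # (n,) int binary, -1 = unset
    reward2: np.ndarray = None
    rt_ms: np.ndarray = None        # (n,) float, NaN = missing
    participant_id: str = "p0"
    seed: Optional[int] = None

    def __post_init__(self):
        n = len(self.block)
        if self.chosen is None:
            self.chosen = np.full(n, -1, dtype=np.int64)
        if self.reward1 is None:
            self.reward1 = np.full(n, -1, dtype=np.int64)
        if self.reward2 is None:
            self.reward2 = np.full(n, -1, dtype=np.int64)
        if self.rt_ms is None:
            self.rt_ms = np.full(n, np.nan)
        lo, hi = self.config.reward_prob_low, self.config.reward_prob_high
        if np.any(self.reward_probs < lo - 1e-12) or np.any(self.reward_probs > hi + 1e-12):
            raise ValueError("reward_probs outside configured range")

    @property
    def n_trials(self) -> int:
        return len(self.block)

    @property
    def trial_in_block(self) -> np.ndarray:
        return np.arange(self.n_trials) % self.config.trials_per_block

    def outcome_temporal(self) -> tuple[np.ndarray, np.ndarray]:
        """Outcome indices at temporal positions 1 and 2 (-1 where no choice)."""
        po = self.task_map.person_outcomes
        o1 = np.full(self.n_trials, -1, dtype=np.int64)
        o2 = np.full(self.n_trials, -1, dtype=np.int64)
        ok = self.chosen >= 0
        animal = po[self.chosen[ok], 0]
        veg = po[self.chosen[ok], 1]
        vf = self.veg_first[ok]
        o1[ok] = np.where(vf, veg, animal)
        o2[ok] = np.where(vf, animal, veg)
        return o1, o2

    def trial(self, t: int) -> TrialView:
        return TrialView(
            int(self.block[t]), int(t % self.config.trials_per_block),
            int(self.left[t]), int(self.right[t]), int(self.fmt[t]),
            bool(self.veg_first[t]), int(self.chosen[t]),
            int(self.reward1[t]), int(self.reward2[t]), float(self.rt_ms[t]))

    def __iter__(self):
        return (self.trial(t) for t in range(self.n_trials))

    def copy_plan(self) -> "SessionData":
        """A copy with choices/rewards/RTs cleared (a fresh plan)."""
        return SessionData(
            self.task_map, self.config, self.reward_probs.copy(),
            self.block.copy(), self.left.copy(), self.right.copy(),
            self.fmt.copy(), self.veg_first.copy(),
            participant_id=self.participant_id, seed=self.seed)


def generate_session_plan(task_map: TaskMap, config: SessionConfig,
                          seed: Optional[int] = None) -> SessionData:
    """Generate one session plan (offers, sides, formats, outcome order, probabilities).

    Choices and rewards are left unfilled.  A single session seed
    deterministically derives independent sub-streams for pair order, display
    sides, formats, outcome order and reward probabilities, so each component
    can be regenerated independently.
    """
    if seed is None:
        seed = config.rng_seed
    ss = np.random.SeedSequence(seed)
    rng_pairs, rng_sides, rng_fmt, rng_order, rng_prob = (
        np.random.default_rng(c) for c in ss.spawn(5))

    nb, tpb = config.n_blocks, config.trials_per_block
    n = nb * tpb
    pairs = task_map.valid_pairs  # (4, 2)

    pair_idx = np.empty(n, dtype=np.int64)
    per_pair = tpb // 4
    for b in range(nb):
        seq = np.repeat(np.arange(4), per_pair)
        rng_pairs.shuffle(seq)
        pair_idx[b * tpb:(b + 1) * tpb] = seq

    first = pairs[pair_idx, 0]
    second = pairs[pair_idx, 1]
    swap = rng_sides.random(n) < 0.5  # display side randomized uniformly
    left = np.where(swap, second, first)
    right = np.where(swap, first, second)

    fmt = rng_fmt.choice(3, size=n, p=np.asarray(config.format_probs))
    veg_first = rng_order.random(n) < 0.5
    reward_probs = rng_prob.uniform(config.reward_prob_low,
                                    config.reward_prob_high, size=(nb, 4))

    return SessionData(
        task_map, config, reward_probs,
        block=np.repeat(np.arange(nb), tpb), left=left, right=right,
        fmt=fmt.astype(np.int64), veg_first=veg_first, seed=seed)


def realize_rewards(plan: SessionData, chosen: int, trial: int,
                    rng: np.random.Generator) -> tuple[int, int]:
    """Draw the two binary rewards for ``chosen`` on ``trial``.

    Each reward is an independent Bernoulli draw with the block's probability
    for the outcome at the corresponding temporal position.
    """
    if chosen not in (plan.left[trial], plan.right[trial]):
        raise ValueError(
            f"person {chosen} not offered on trial {trial} "
            f"(offered: {plan.left[trial]}, {plan.right[trial]})")
    a, v = plan.task_map.outcomes_of(chosen)
    o1, o2 = (v, a) if plan.veg_first[trial] else (a, v)
    b = plan.block[trial]
    r1 = int(rng.random() < plan.reward_probs[b, o1])
    r2 = int(rng.random() < plan.reward_probs[b, o2])
    return r1, r2


@dataclass(frozen=True)
class RTModel:
    """Simple generator of reaction times for synthetic sessions.

    Real RTs carry the signature that new trials (offering a different pair
    than the previous trial) are slower than replica trials, most strongly
    after retrospective-inference trials.  The generator draws
    ``base + new_ms * 1[new] + ri_new_ms * 1[new and previous RI] + noise``
    truncated to [floor_ms, ceil_ms].  It emulates mean structure only, not
    full RT-distribution shape.
    """

    base_ms: float = 650.0
    new_ms: float = 80.0
    ri_new_ms: float = 20.0
    sd_ms: float = 150.0
    floor_ms: float = 120.0
    ceil_ms: float = 1990.0

    def draw(self, session: SessionData, rng: np.random.Generator) -> np.ndarray:
        n = session.n_trials
        mu = np.full(n, self.base_ms)
        pair_now = np.minimum(session.left, session.right) * 4 + np.maximum(session.left, session.right)
        same_block = np.zeros(n, dtype=bool)
        same_block[1:] = session.block[1:] == session.block[:-1]
        new = np.ones(n, dtype=bool)
        new[1:] = pair_now[1:] != pair_now[:-1]
        prev_ri = np.zeros(n, dtype=bool)
        prev_ri[1:] = session.fmt[:-1] == RI
        mu += self.new_ms * (new & same_block)
        mu += self.ri_new_ms * (new & same_block & prev_ri)
        rt = rng.normal(mu, self.sd_ms)
        return np.clip(rt, self.floor_ms, self.ceil_ms)


def generate_synthetic_cohort(
        n_participants: int,
        param_sampler: Callable[[np.random.Generator], "object"],
        config: SessionConfig = SessionConfig(),
        seed: int = 0,
        spec: Optional["object"] = None,
        rt_model: Optional[RTModel] = RTModel(),
) -> list[tuple[SessionData, "object"]]:
    """Simulate a cohort of full sessions with recorded generating parameters.

    For each participant a fresh task map is drawn (the person <-> outcome
    assignment was randomized anew per participant), a session plan is
    generated, parameters are drawn from ``param_sampler`` and choices are
    simulated from the hybrid model under ``spec`` (default: the full model).
    Returns ``[(session, generating ParamVector), ...]``.
    """
    from . import models  # deferred: models imports task types

    if spec is None:
        spec = models.MODEL_SPECS["full"]
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_participants)):
        s_map, s_par, s_plan, s_sim, s_rt = child.generate_state(5)
        task_map = build_task_map(int(s_map))
        params = param_sampler(np.random.default_rng(int(s_par)))
        plan = generate_session_plan(task_map, config, seed=int(s_plan))
        plan.participant_id = f"p{i:03d}"
        session = models.simulate_session(params, spec, plan, seed=int(s_sim))
        if rt_model is not None:
            session.rt_ms = rt_model.draw(session, np.random.default_rng(int(s_rt)))
        out.append((session, params))
    return out
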