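"""Model-agnostic trial-transition analyses and their regression designs.

Every consecutive pair of valid-choice trials within a block is classified by
whether the trial-n chosen person is offered again on trial n+1:

* repetition transitions (the previous choice is on offer) isolate model-free
  credit assignment: the outcome shared by the two offered persons cancels
  out of the model-based comparison, so an effect of its trial-n reward on
  choice repetition is an MFCA signature;
* generalization transitions (the previous choice is excluded) isolate
  model-based credit assignment: exactly one offered person shares an outcome
  with the previous choice, and an effect of that common outcome's trial-n
  reward on choosing this "generalization person" is an MBCA signature.

A full-transition design regresses the chosen display side on an MB regressor
built from the trial-n outcome that is unique to one offered person, plus six
format x position model-free reward regressors and a perseveration term.  A
cross-credit-assignment variant restricts generalization transitions to
retrospective-inference trials n and asks whether the *non-common* (hidden)
outcome's reward predicts generalization.

Regression designs follow the coding conventions of the corresponding
analyses: reward regressors are +0.5 / -0.5, format indicators are 0/1
dummies with the standard format as reference, and the serial-position
coding is per-analysis (+0.5 = first in the repetition/generalization and
parameter analyses; -0.5 = first in the full-transition design).

Mixed-effects models with participants as free-covariance random effects are
estimated by the two-stage summary-statistics method: the fixed-effects
design is fitted per participant (ridge-stabilized logistic regression for
binary responses, exact least squares for the saturated linear designs), and
population-level estimates and Wald/F contrast tests are computed across the
per-participant coefficient vectors, whose sample covariance is the
unrestricted random-effects covariance.  See docs/methods.md for the
rationale and the relation to joint-likelihood GLMMs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression

from .fitting import FitResult
from .task import RI, SessionData

__all__ = [
    "select_repetition_transitions",
    "select_generalization_transitions",
    "build_full_transition_design",
    "select_cross_ca_transitions",
    "TwoStageResult",
    "ContrastTest",
    "fit_mixed_logistic",
    "fit_twostage_linear",
    "common_reward_effects",
    "reward_effect_model",
    "mbca_parameter_model",
    "rt_analysis",
    "bootstrap_power",
]

_FMT_LABEL = ("S", "PI", "RI")

#: Formulas used by the named analyses (patsy syntax, intercept implied).
REPETITION_FORMULA = "COMMON * (PROSPECTIVE + RETROSPECTIVE) * POSITION"
GENERALIZATION_FORMULA = REPETITION_FORMULA
FULL_TRANSITION_FORMULA = (
    "MB_REW * (PROSPECTIVE + RETROSPECTIVE) * POSITION"
    " + MF_REW1 + MF_REW2 + PROSPECTIVE_MF_REW1 + PROSPECTIVE_MF_REW2"
    " + RETROSPECTIVE_MF_REW1 + RETROSPECTIVE_MF_REW2 + PERS")
CROSS_CA_FORMULA = "NON_COMMON"
REWARD_EFFECT_FORMULA = "POSITION * (PROSPECTIVE + RETROSPECTIVE)"
CA_PARAMETER_FORMULA = "POSITION * (PROSPECTIVE + RETROSPECTIVE)"
RT_FORMULA = "TYPE * (PROSPECTIVE + RETROSPECTIVE)"


# ---------------------------------------------------------------------------
# transition construction
# ---------------------------------------------------------------------------

def _iter_transitions(session: SessionData):
    """Yield per-transition dicts for consecutive valid-choice trial pairs.

    Transitions never cross block boundaries (latent values reset between
    blocks).  Each dict carries trial-n facts (format, outcomes in temporal
    order, binary rewards, chosen person) and trial-(n+1) facts (offered
    sides, chosen person).
    """
    tm = session.task_map
    o1, o2 = session.outcome_temporal()
    n = session.n_trials
    for t in range(n - 1):
        if session.block[t] != session.block[t + 1]:
            continue
        if session.chosen[t] < 0 or session.chosen[t + 1] < 0:
            continue
        yield {
            "t": t,
            "fmt_n": int(session.fmt[t]),
            "o1": int(o1[t]), "o2": int(o2[t]),
            "r1": int(session.reward1[t]), "r2": int(session.reward2[t]),
            "chosen_n": int(session.chosen[t]),
            "left": int(session.left[t + 1]), "right": int(session.right[t + 1]),
            "chosen_next": int(session.chosen[t + 1]),
        }


def _reward_of(tr: dict, outcome: int) -> int:
    """Binary trial-n reward of one of trial n's outcomes."""
    if outcome == tr["o1"]:
        return tr["r1"]
    if outcome == tr["o2"]:
        return tr["r2"]
    raise ValueError("outcome not presented on trial n")


def _position_of(tr: dict, outcome: int) -> int:
    """Temporal position (1 or 2) of an outcome on trial n."""
    return 1 if outcome == tr["o1"] else 2


def _fmt_dummies(fmt: int) -> tuple[int, int]:
    return int(fmt == 1), int(fmt == 2)


def select_repetition_transitions(sessions: Union[SessionData, Sequence[SessionData]]
                                  ) -> pd.DataFrame:
    """Transitions whose trial n+1 offers the previously chosen person.

    Columns: REPEAT (1 = chose the same person again), COMMON (+0.5 the
    offered pair's shared outcome was rewarded on trial n, -0.5 otherwise),
    POSITION (+0.5 that outcome came first on trial n), PROSPECTIVE /
    RETROSPECTIVE (trial-n format dummies), plus lowercase helper columns
    ``format`` and ``position`` for the effect tables.
    """
    rows = []
    for session in _as_list(sessions):
        tm = session.task_map
        for tr in _iter_transitions(session):
            if tr["chosen_n"] not in (tr["left"], tr["right"]):
                continue
            common = tm.shared_outcome(tr["left"], tr["right"])
            pos = _position_of(tr, common)
            pi, ri = _fmt_dummies(tr["fmt_n"])
            rows.append({
                "participant": session.participant_id,
                "trial": tr["t"],
                "REPEAT": int(tr["chosen_next"] == tr["chosen_n"]),
                "COMMON": 0.5 if _reward_of(tr, common) == 1 else -0.5,
                "POSITION": 0.5 if pos == 1 else -0.5,
                "PROSPECTIVE": pi, "RETROSPECTIVE": ri,
                "format": _FMT_LABEL[tr["fmt_n"]], "position": pos,
            })
    return pd.DataFrame(rows)


def _generalization_rows(session: SessionData):
    """Shared builder for generalization and cross-CA tables."""
    tm = session.task_map
    for tr in _iter_transitions(session):
        if tr["chosen_n"] in (tr["left"], tr["right"]):
            continue
        sharers = [p for p in (tr["left"], tr["right"])
                   if tm.shared_outcome(p, tr["chosen_n"]) >= 0]
        if len(sharers) != 1:  # impossible by task structure; guard anyway
            raise RuntimeError("expected exactly one generalization person")
        gen_person = sharers[0]
        common = tm.shared_outcome(gen_person, tr["chosen_n"])
        other_outcome = tr["o2"] if common == tr["o1"] else tr["o1"]
        yield tr, gen_person, common, other_outcome


def select_generalization_transitions(sessions: Union[SessionData, Sequence[SessionData]]
                                      ) -> pd.DataFrame:
    """Transitions whose trial n+1 excludes the previously chosen person.

    The generalization person is the unique offered person sharing one
    outcome with the previous choice; COMMON codes that shared outcome's
    trial-n reward and GENERALIZE whether the generalization person was
    chosen.  Coding conventions match the repetition table.
    """
    rows = []
    for session in _as_list(sessions):
        for tr, gen_person, common, _ in _generalization_rows(session):
            pos = _position_of(tr, common)
            pi, ri = _fmt_dummies(tr["fmt_n"])
            rows.append({
                "participant": session.participant_id,
                "trial": tr["t"],
                "GENERALIZE": int(tr["chosen_next"] == gen_person),
                "COMMON": 0.5 if _reward_of(tr, common) == 1 else -0.5,
                "POSITION": 0.5 if pos == 1 else -0.5,
                "PROSPECTIVE": pi, "RETROSPECTIVE": ri,
                "format": _FMT_LABEL[tr["fmt_n"]], "position": pos,
            })
    return pd.DataFrame(rows)


def select_cross_ca_transitions(sessions: Union[SessionData, Sequence[SessionData]],
                                common_position: int = 2) -> pd.DataFrame:
    """Generalization transitions restricted to retrospective-inference trials n.

    With ``common_position=2`` (the main analysis) the common outcome was the
    temporally second, *seen* outcome on the RI trial, and NON_COMMON codes
    the reward of the first, hidden outcome; ``common_position=1`` selects
    the complementary case.  A positive NON_COMMON effect on generalization
    is the footprint of cross-credit assignment (the hidden outcome's reward
    leaking onto the seen outcome's value).
    """
    if common_position not in (1, 2):
        raise ValueError("common_position must be 1 or 2")
    rows = []
    for session in _as_list(sessions):
        for tr, gen_person, common, other in _generalization_rows(session):
            if tr["fmt_n"] != RI or _position_of(tr, common) != common_position:
                continue
            rows.append({
                "participant": session.participant_id,
                "trial": tr["t"],
                "GENERALIZE": int(tr["chosen_next"] == gen_person),
                "NON_COMMON": 0.5 if _reward_of(tr, other) == 1 else -0.5,
            })
    return pd.DataFrame(rows)


def build_full_transition_design(sessions: Union[SessionData, Sequence[SessionData]]
                                 ) -> pd.DataFrame:
    """All-transition design regressing the chosen display side on MB and MF terms.

    Exactly one trial-n outcome (the "unique outcome") relates to exactly one
    of the persons offered on trial n+1; MB_REW is +0.5 iff that outcome
    supports the right-side person (related-and-rewarded on the right, or
    related-and-unrewarded on the left).  POSITION is the unique outcome's
    trial-n serial position coded -0.5 first / +0.5 second.  The six MF_REW
    regressors carry the trial-n rewards (+-0.5) in the two slots matching
    trial n's format, are zeroed when the previously chosen person is not on
    offer, and are sign-flipped when that person sits on the left; PERS is
    +1 / -1 / 0 for the previous choice offered right / left / not at all.
    """
    mf_names = ("MF_REW1", "MF_REW2", "PROSPECTIVE_MF_REW1", "PROSPECTIVE_MF_REW2",
                "RETROSPECTIVE_MF_REW1", "RETROSPECTIVE_MF_REW2")
    rows = []
    for session in _as_list(sessions):
        tm = session.task_map
        for tr in _iter_transitions(session):
            left, right = tr["left"], tr["right"]
            uniq = None
            for o in (tr["o1"], tr["o2"]):
                rel_l = o in tm.outcomes_of(left)
                rel_r = o in tm.outcomes_of(right)
                if rel_l != rel_r:
                    if uniq is not None:
                        raise RuntimeError("two unique outcomes cannot occur")
                    uniq = (o, rel_r)
            if uniq is None:  # impossible by task structure; guard anyway
                raise RuntimeError("expected exactly one unique outcome")
            o_uniq, relates_right = uniq
            rewarded = _reward_of(tr, o_uniq) == 1
            mb_rew = 0.5 if (relates_right == rewarded) else -0.5
            pi, ri = _fmt_dummies(tr["fmt_n"])

            row = {
                "participant": session.participant_id,
                "trial": tr["t"],
                "CHOOSE_R": int(tr["chosen_next"] == right),
                "MB_REW": mb_rew,
                "POSITION": -0.5 if _position_of(tr, o_uniq) == 1 else 0.5,
                "PROSPECTIVE": pi, "RETROSPECTIVE": ri,
                "PERS": 0, **{nm: 0.0 for nm in mf_names},
            }
            if tr["chosen_n"] in (left, right):
                on_right = tr["chosen_n"] == right
                row["PERS"] = 1 if on_right else -1
                sign = 1.0 if on_right else -1.0
                slot = 2 * tr["fmt_n"]
                row[mf_names[slot]] = sign * (0.5 if tr["r1"] == 1 else -0.5)
                row[mf_names[slot + 1]] = sign * (0.5 if tr["r2"] == 1 else -0.5)
            rows.append(row)
    return pd.DataFrame(rows)


def _as_list(sessions) -> list[SessionData]:
    return [sessions] if isinstance(sessions, SessionData) else list(sessions)


# ---------------------------------------------------------------------------
# two-stage mixed-effects estimation
# ---------------------------------------------------------------------------

@dataclass
class ContrastTest:
    estimate: float
    se: float
    statistic: float   # t (single contrast) or F (joint)
    df: tuple          # (df_num, df_den) for F, (df,) for t
    p: float


@dataclass
class TwoStageResult:
    """Population-level fixed effects from per-participant fits.

    ``coefs`` holds one fitted coefficient vector per participant; ``params``
    their mean (the fixed-effect estimate); ``cov_between`` the unrestricted
    between-participant covariance (the random-effects covariance plus
    estimation noise).  Contrast tests are Wald t/F tests across
    participants with n - 1 (t) or (q, n - q) (F) degrees of freedom.
    """

    terms: tuple[str, ...]
    coefs: pd.DataFrame              # participants x terms
    method: str

    def __post_init__(self):
        self._mean = self.coefs.mean(axis=0)
        self._cov = np.atleast_2d(np.cov(self.coefs.to_numpy().T, ddof=1)) \
            if self.n_participants > 1 else np.full((len(self.terms),) * 2, np.nan)

    @property
    def n_participants(self) -> int:
        return len(self.coefs)

    @property
    def params(self) -> pd.Series:
        return self._mean

    @property
    def cov_between(self) -> pd.DataFrame:
        return pd.DataFrame(self._cov, index=self.terms, columns=self.terms)

    def _vector(self, contrast: Union[dict, np.ndarray, str]) -> np.ndarray:
        if isinstance(contrast, str):
            contrast = {contrast: 1.0}
        if isinstance(contrast, dict):
            c = np.zeros(len(self.terms))
            for name, w in contrast.items():
                if name not in self.terms:
                    raise KeyError(f"unknown term {name!r}; have {self.terms}")
                c[self.terms.index(name)] = w
            return c
        return np.asarray(contrast, dtype=float)

    def contrast(self, contrast: Union[dict, np.ndarray, str]) -> ContrastTest:
        """Wald t test of a single linear combination of fixed effects."""
        c = self._vector(contrast)
        n = self.n_participants
        est = float(c @ self._mean.to_numpy())
        if n < 2:
            return ContrastTest(est, np.nan, np.nan, (n - 1,), np.nan)
        se = float(np.sqrt(c @ self._cov @ c / n))
        t = est / se if se > 0 else np.inf * np.sign(est)
        p = 2 * sps.t.sf(abs(t), n - 1)
        return ContrastTest(est, se, t, (n - 1,), float(p))

    def joint_test(self, contrasts: Sequence[Union[dict, np.ndarray, str]]
                   ) -> ContrastTest:
        """Hotelling F test that several contrasts are simultaneously zero."""
        C = np.stack([self._vector(c) for c in contrasts])
        q = C.shape[0]
        n = self.n_participants
        est = C @ self._mean.to_numpy()
        if n <= q:
            return ContrastTest(float(np.nan), np.nan, np.nan, (q, n - q), np.nan)
        V = C @ self._cov @ C.T / n
        t2 = float(est @ np.linalg.solve(V, est))
        f = t2 * (n - q) / (q * (n - 1))
        p = sps.f.sf(f, q, n - q)
        return ContrastTest(float(np.linalg.norm(est)), np.nan, f, (q, n - q),
                            float(p))

    def composite_main_effect(self, base: str) -> ContrastTest:
        """Main effect averaged over formats given dummy coding:
        (3 b_base + b_base:PROSPECTIVE + b_base:RETROSPECTIVE) / 3."""
        weights = {base: 1.0}
        for other in self.terms:
            parts = set(other.split(":"))
            if parts == {base, "PROSPECTIVE"} or parts == {base, "RETROSPECTIVE"}:
                weights[other] = 1 / 3
        return self.contrast(weights)

    def summary(self) -> pd.DataFrame:
        rows = {}
        for term in self.terms:
            t = self.contrast(term)
            rows[term] = {"estimate": t.estimate, "se": t.se,
                          "t": t.statistic, "df": t.df[0], "p": t.p}
        return pd.DataFrame(rows).T


def _split_design(table: pd.DataFrame, response: str, formula: str):
    X = np.asarray(dmatrix(formula, table, return_type="matrix"))
    terms = tuple(dmatrix(formula, table).design_info.column_names)
    y = table[response].to_numpy(dtype=float)
    groups = table["participant"].to_numpy()
    return X, y, groups, terms


def fit_mixed_logistic(table: pd.DataFrame, response: str, formula: str,
                       ridge: float = 100.0) -> TwoStageResult:
    """Logistic regression with participants as free-covariance random effects.

    Two-stage estimator: a ridge-stabilized logistic regression per
    participant (penalty 1/ridge keeps coefficients finite under separation,
    which small per-participant tables can produce), then across-participant
    Wald/F tests on the coefficient vectors.
    """
    if table.empty:
        raise ValueError("empty design table")
    X, y, groups, terms = _split_design(table, response, formula)
    coefs = {}
    for pid in pd.unique(groups):
        m = groups == pid
        if y[m].min() == y[m].max():
            # constant response: the intercept diverges without the penalty,
            # and all slope information is absent; keep the penalized fit
            warnings.warn(f"participant {pid}: constant response")
        clf = LogisticRegression(C=ridge, fit_intercept=False, max_iter=2000,
                                 tol=1e-10)
        clf.fit(X[m], y[m])
        coefs[pid] = clf.coef_[0]
    frame = pd.DataFrame.from_dict(coefs, orient="index", columns=terms)
    return TwoStageResult(terms, frame, "two_stage_logistic")


def fit_twostage_linear(table: pd.DataFrame, response: str, formula: str
                        ) -> TwoStageResult:
    """Linear counterpart of :func:`fit_mixed_logistic` (exact least squares).

    For the saturated per-participant designs used here (one observation per
    cell) the first stage is an exact linear transform of the cell values, so
    the across-participant tests coincide with the classical repeated-
    measures analysis of the mixed model.
    """
    if table.empty:
        raise ValueError("empty design table")
    X, y, groups, terms = _split_design(table, response, formula)
    coefs = {}
    for pid in pd.unique(groups):
        m = groups == pid
        if m.sum() < X.shape[1]:
            warnings.warn(f"participant {pid}: incomplete design; dropped")
            continue
        beta, *_ = np.linalg.lstsq(X[m], y[m], rcond=None)
        coefs[pid] = beta
    if not coefs:
        raise ValueError("no participant with a complete design")
    frame = pd.DataFrame.from_dict(coefs, orient="index", columns=terms)
    return TwoStageResult(terms, frame, "two_stage_linear")


# ---------------------------------------------------------------------------
# effect tables and parameter-level analyses
# ---------------------------------------------------------------------------

def common_reward_effects(table: pd.DataFrame, response: str) -> pd.DataFrame:
    """Per participant x format x position common-reward effect.

    The effect is P(response | common rewarded) - P(response | common
    unrewarded); each participant contributes six effects (3 formats x 2
    positions).  Cells without both reward and non-reward observations yield
    NaN.
    """
    def _one(g: pd.DataFrame) -> float:
        rew = g.loc[g["COMMON"] > 0, response]
        non = g.loc[g["COMMON"] < 0, response]
        if rew.empty or non.empty:
            return np.nan
        return rew.mean() - non.mean()

    out = (table.groupby(["participant", "format", "position"])
           .apply(_one, include_groups=False).rename("effect").reset_index())
    counts = (table.groupby(["participant", "format", "position"])
              .size().rename("n").reset_index())
    return out.merge(counts, on=["participant", "format", "position"])


def _effect_design(effects: pd.DataFrame) -> pd.DataFrame:
    t = effects.copy()
    t["POSITION"] = np.where(t["position"] == 1, 0.5, -0.5)
    t["PROSPECTIVE"] = (t["format"] == "PI").astype(int)
    t["RETROSPECTIVE"] = (t["format"] == "RI").astype(int)
    return t


def reward_effect_model(effects: pd.DataFrame) -> TwoStageResult:
    """Regress the six per-participant common-reward effects on format x position.

    Participants with missing cells are dropped with a warning (the saturated
    per-participant design needs all six effects).
    """
    t = _effect_design(effects.dropna(subset=["effect"]))
    full = t.groupby("participant").size()
    keep = full[full == 6].index
    dropped = set(t["participant"]) - set(keep)
    if dropped:
        warnings.warn(f"participants dropped for missing cells: {sorted(dropped)}")
    t = t[t["participant"].isin(keep)]
    return fit_twostage_linear(t, "effect", REWARD_EFFECT_FORMULA)


def _ca_table(fits: Sequence[FitResult], functional: bool) -> pd.DataFrame:
    rows = []
    for fit in fits:
        c = list(fit.params.c_mb)
        if functional:
            c[4], c[5] = c[5], c[4]  # flip the two RI gains
        for i, (fmt, pos) in enumerate([("S", 1), ("S", 2), ("PI", 1),
                                        ("PI", 2), ("RI", 1), ("RI", 2)]):
            rows.append({
                "participant": fit.participant_id, "CA": c[i],
                "POSITION": 0.5 if pos == 1 else -0.5,
                "PROSPECTIVE": int(fmt == "PI"),
                "RETROSPECTIVE": int(fmt == "RI"),
                "format": fmt, "position": pos,
            })
    return pd.DataFrame(rows)


def mbca_parameter_model(fits: Sequence[FitResult]) -> dict:
    """Mixed-model analyses of the six fitted MBCA gains.

    Returns the format x position model on the temporal-position coding
    (``ca_model``), its functional-position variant with the two RI gains
    flipped (``functional_ca_model``), and the retrospective-impairment
    analysis: per-participant standard-minus-RI differences for each
    position, their Pearson correlation, and the regression of the
    position-2 impairment on the position-1 impairment (a positive intercept
    is the baseline sparing of the hidden outcome).
    """
    if len(fits) < 3:
        raise ValueError("need at least 3 participants")
    ca_model = fit_twostage_linear(_ca_table(fits, False), "CA", CA_PARAMETER_FORMULA)
    fn_model = fit_twostage_linear(_ca_table(fits, True), "CA", CA_PARAMETER_FORMULA)

    c = np.array([f.params.c_mb for f in fits])
    imp1 = c[:, 0] - c[:, 4]   # S1 - RI1
    imp2 = c[:, 1] - c[:, 5]   # S2 - RI2
    n = len(fits)
    impairment = {"impairment_pos1": imp1, "impairment_pos2": imp2}
    if np.ptp(imp1) == 0 or np.ptp(imp2) == 0:
        warnings.warn("degenerate impairment variance; correlation undefined")
        impairment.update({k: np.nan for k in (
            "pearson_r", "pearson_p", "intercept", "intercept_t",
            "intercept_p", "slope")})
    else:
        pear = sps.pearsonr(imp1, imp2)
        lin = sps.linregress(imp1, imp2)
        # t test of the intercept from the standard OLS formulas
        resid = imp2 - (lin.intercept + lin.slope * imp1)
        s2 = resid @ resid / (n - 2)
        se_int = np.sqrt(s2 * (1 / n + imp1.mean() ** 2
                               / ((imp1 - imp1.mean()) ** 2).sum()))
        t_int = lin.intercept / se_int if se_int > 0 else np.inf
        impairment.update({
            "pearson_r": float(pear.statistic), "pearson_p": float(pear.pvalue),
            "intercept": float(lin.intercept), "intercept_t": float(t_int),
            "intercept_p": float(2 * sps.t.sf(abs(t_int), n - 2)),
            "slope": float(lin.slope),
        })
    return {
        "ca_model": ca_model,
        "functional_ca_model": fn_model,
        "impairment": impairment,
    }


# ---------------------------------------------------------------------------
# reaction-time analysis
# ---------------------------------------------------------------------------

def rt_analysis(sessions: Union[SessionData, Sequence[SessionData]],
                min_rt_ms: float = 250.0) -> dict:
    """Mean RT by previous-trial format and trial type (replica vs new).

    Drops trials faster than ``min_rt_ms`` and the first trial of each block
    (those follow a break), classifies each remaining trial by whether it
    offers the same person pair as its predecessor, and fits mean RT on
    TYPE (-0.5 replica / +0.5 new) crossed with the previous trial's format
    dummies.  Returns the per-participant cell means and the fitted model.
    """
    rows = []
    for session in _as_list(sessions):
        pair = np.minimum(session.left, session.right) * 4 \
            + np.maximum(session.left, session.right)
        tib = session.trial_in_block
        for t in range(session.n_trials):
            if tib[t] == 0:
                continue
            rt = session.rt_ms[t]
            if not np.isfinite(rt) or rt < min_rt_ms:
                continue
            rows.append({
                "participant": session.participant_id,
                "rt_ms": float(rt),
                "type": "replica" if pair[t] == pair[t - 1] else "new",
                "prev_format": _FMT_LABEL[session.fmt[t - 1]],
            })
    trials = pd.DataFrame(rows)
    if trials.empty:
        raise ValueError("no usable RT trials")
    cells = (trials.groupby(["participant", "prev_format", "type"])["rt_ms"]
             .mean().rename("mean_rt").reset_index())
    design = cells.copy()
    design["TYPE"] = np.where(design["type"] == "new", 0.5, -0.5)
    design["PROSPECTIVE"] = (design["prev_format"] == "PI").astype(int)
    design["RETROSPECTIVE"] = (design["prev_format"] == "RI").astype(int)
    full = design.groupby("participant").size()
    design = design[design["participant"].isin(full[full == 6].index)]
    model = fit_twostage_linear(design, "mean_rt", RT_FORMULA)
    return {"cell_means": cells, "model": model}


# ---------------------------------------------------------------------------
# bootstrap power over participants
# ---------------------------------------------------------------------------

def _focal_pvalue(result: TwoStageResult, analysis: str) -> float:
    if analysis in ("repetition_common", "generalization_common"):
        return result.composite_main_effect("COMMON").p
    if analysis == "generalization_triple":
        return result.joint_test(["COMMON:PROSPECTIVE:POSITION",
                                  "COMMON:RETROSPECTIVE:POSITION"]).p
    if analysis == "rt_interaction":
        return result.joint_test(["TYPE:PROSPECTIVE", "TYPE:RETROSPECTIVE"]).p
    if analysis == "parameter_interaction":
        return result.joint_test(["POSITION:PROSPECTIVE",
                                  "POSITION:RETROSPECTIVE"]).p
    raise KeyError(f"unknown analysis {analysis!r}")


def _base_result(sessions, analysis: str, fits) -> TwoStageResult:
    if analysis == "repetition_common":
        return fit_mixed_logistic(select_repetition_transitions(sessions),
                                  "REPEAT", REPETITION_FORMULA)
    if analysis in ("generalization_common", "generalization_triple"):
        return fit_mixed_logistic(select_generalization_transitions(sessions),
                                  "GENERALIZE", GENERALIZATION_FORMULA)
    if analysis == "rt_interaction":
        return rt_analysis(sessions)["model"]
    if analysis == "parameter_interaction":
        if fits is None:
            raise ValueError("parameter_interaction requires full-model fits")
        return mbca_parameter_model(fits)["ca_model"]
    raise KeyError(f"unknown analysis {analysis!r}")


def bootstrap_power(sessions: Sequence[SessionData], analysis: str,
                    n_boot: int = 1000, alpha: float = 0.05, seed: int = 0,
                    target_n: Optional[int] = None,
                    fits: Optional[Sequence[FitResult]] = None) -> dict:
    """Power of a named focal test under bootstrap resampling of participants.

    Participants are resampled with replacement (optionally up-sampled to
    ``target_n``) and the focal test rerun on each resample; power is the
    proportion of resamples significant at ``alpha``.  Because the two-stage
    estimator reduces each participant to a coefficient vector, resampling
    participants is exactly resampling rows of the first-stage coefficient
    matrix, which makes the bootstrap cheap.
    """
    base = _base_result(sessions, analysis, fits)
    rng = np.random.default_rng(seed)
    n = base.n_participants
    size = target_n if target_n is not None else n
    hits = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size)
        res = TwoStageResult(base.terms, base.coefs.iloc[idx].reset_index(drop=True),
                             base.method)
        hits += _focal_pvalue(res, analysis) <= alpha
    return {"power": hits / n_boot, "analysis": analysis, "alpha": alpha,
            "n_boot": n_boot, "n_participants": size,
            "base_p": _focal_pvalue(base, analysis)}
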