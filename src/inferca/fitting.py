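"""Per-participant maximum-likelihood estimation and the exclusion rule.

Each model spec is fitted by multi-start box-constrained optimization of the
session log-likelihood: starts are drawn uniformly over the parameter box
(forgetting rates on [0, 1], gains on [-5, 5]), plus one deterministic
"neutral" start with all gains at zero, and each start is refined with the
compiled projected L-BFGS in :mod:`inferca._core`.  The best start wins; ties
break first-found, so a fit is fully reproducible from its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _core
from .models import MODEL_SPECS, ModelSpec, ParamVector
from .task import SessionData

__all__ = ["FitResult", "FitError", "fit_participant", "exclude_participants"]

#: Default optimizer settings.  200 starts mirrors the fitting protocol at
#: full scale; bootstrap and recovery studies use far fewer (see their docs).
DEFAULT_N_STARTS = 200
DEFAULT_MAXITER = 400
DEFAULT_GTOL = 1e-6


class FitError(RuntimeError):
    """All optimization starts failed to converge."""


@dataclass
class FitResult:
    """Outcome of one participant x model maximum-likelihood fit."""

    spec_name: str
    free_params: np.ndarray      # best free-parameter vector
    params: ParamVector          # expanded full parameter vector
    loglik: float                # max log-likelihood over starts
    start_logliks: np.ndarray    # per-start log-likelihoods
    n_starts: int
    converged: np.ndarray        # per-start convergence flags
    seed: Optional[int]
    participant_id: str = ""

    @property
    def spec(self) -> ModelSpec:
        return MODEL_SPECS[self.spec_name]

    def to_dict(self) -> dict:
        return {
            "spec": self.spec_name,
            "participant": self.participant_id,
            "loglik": self.loglik,
            "free_params": dict(zip(self.spec.free_names, map(float, self.free_params))),
            "params": self.params.to_dict(),
            "n_starts": int(self.n_starts),
            "seed": self.seed,
        }


def _neutral_start(spec: ModelSpec) -> np.ndarray:
    """All gains 0, forgetting rates 0.2: a uniform-policy starting point."""
    x = np.zeros(spec.n_free)
    for i, name in enumerate(spec.free_names):
        if name in ("f_mf", "f_mb", "f_p"):
            x[i] = 0.2
    return x


def fit_participant(session: SessionData, spec: ModelSpec,
                    n_starts: int = DEFAULT_N_STARTS, seed: int = 0,
                    extra_starts: Optional[Sequence[np.ndarray]] = None,
                    maxiter: int = DEFAULT_MAXITER,
                    gtol: float = DEFAULT_GTOL) -> FitResult:
    """Maximum-likelihood fit of ``spec`` to one session.

    Parameters
    ----------
    n_starts
        Total number of random starts (the first is replaced by the
        deterministic neutral start).  The best log-likelihood is
        non-decreasing in ``n_starts`` under a fixed seed because the random
        start sequence is a prefix-stable stream.
    extra_starts
        Optional additional free-parameter vectors appended to the start list
        (e.g. a nested sub-model's solution when fitting the super-model).
    """
    if not np.any(session.chosen >= 0):
        raise ValueError("session has no valid choice trials")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")

    bounds = spec.bounds
    lb, ub = bounds[:, 0].copy(), bounds[:, 1].copy()
    rng = np.random.default_rng(seed)
    starts = rng.uniform(lb, ub, size=(n_starts, spec.n_free))
    starts[0] = _neutral_start(spec)
    if extra_starts is not None and len(extra_starts):
        starts = np.vstack([starts, np.asarray(extra_starts, dtype=float)])

    arrs = _core.session_arrays(session)
    best_x, fs, conv = _core.fit_starts(
        np.ascontiguousarray(starts), lb, ub,
        np.ascontiguousarray(spec.expand_matrix), *arrs, spec.uses_cross,
        maxiter, gtol)
    if not np.any(np.isfinite(fs)):
        raise FitError(
            f"no start produced a finite likelihood for {spec.name} "
            f"(participant {session.participant_id})")
    if not conv.any():
        warnings.warn(
            f"no start formally converged for {spec.name} "
            f"(participant {session.participant_id}); best value returned")
    return FitResult(
        spec_name=spec.name,
        free_params=best_x,
        params=spec.expand(best_x),
        loglik=-float(np.min(fs)),
        start_logliks=-fs,
        n_starts=len(starts),
        converged=conv,
        seed=seed,
        participant_id=session.participant_id)


def exclude_participants(fits: Sequence[FitResult]) -> tuple[list[FitResult], list[FitResult]]:
    """Apply the exclusion rule to full-model fits.

    A participant is excluded iff all 7 credit-assignment parameters (c_MF
    plus the six c_MB gains) are strictly negative — behaviour showing no
    incentive to earn reward.  Returns (kept, excluded).
    """
    kept, excluded = [], []
    for fit in fits:
        if fit.spec_name not in ("full", "RI_cross_CA"):
            raise ValueError("exclusion rule applies to full-model fits")
        if np.all(fit.params.ca_params < 0):
            excluded.append(fit)
        else:
            kept.append(fit)
    return kept, excluded
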