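"""Session serialization, run configuration and the end-to-end pipeline.

Sessions are stored as tidy CSV (one row per trial, 1-based block/trial
indices, person and outcome names rather than internal indices) with a JSON
sidecar holding everything the CSV cannot carry: the task map, the session
configuration, the per-block reward probabilities and the generating seed.
Every results bundle embeds the run configuration, its hash and the seeds, so
a rerun with the same configuration is reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import fit_participant, exclude_participants
from .models import MODEL_SPECS, ParamVector, sample_plausible_params
from .task import (FORMATS, SessionConfig, SessionData, TaskMap,
                   generate_synthetic_cohort)

__all__ = [
    "ParseError",
    "write_sessions",
    "read_sessions",
    "RunConfig",
    "run_pipeline",
]

_COLUMNS = ["participant", "block", "trial", "left_person", "right_person",
            "format", "first_outcome", "second_outcome", "chosen_person",
            "reward1", "reward2", "rt_ms"]


class ParseError(ValueError):
    """A session file violates the documented schema."""


def _session_frame(session: SessionData) -> pd.DataFrame:
    tm = session.task_map
    names = tm.outcome_names
    o1, o2 = session.outcome_temporal()
    chosen = session.chosen

    def _person(idx):
        return [tm.persons[i] if i >= 0 else "" for i in idx]

    def _outcome(idx):
        return [names[i] if i >= 0 else "" for i in idx]

    return pd.DataFrame({
        "participant": session.participant_id,
        "block": session.block + 1,
        "trial": session.trial_in_block + 1,
        "left_person": _person(session.left),
        "right_person": _person(session.right),
        "format": [FORMATS[f] for f in session.fmt],
        "first_outcome": _outcome(o1),
        "second_outcome": _outcome(o2),
        "chosen_person": _person(chosen),
        "reward1": np.where(chosen >= 0, session.reward1, np.nan),
        "reward2": np.where(chosen >= 0, session.reward2, np.nan),
        "rt_ms": session.rt_ms,
    })


def write_sessions(sessions: Sequence[SessionData], out_dir: Union[str, Path]
                   ) -> tuple[Path, Path]:
    """Write a cohort as ``sessions.csv`` plus ``sessions_meta.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "sessions.csv"
    meta_path = out_dir / "sessions_meta.json"
    pd.concat([_session_frame(s) for s in sessions], ignore_index=True) \
        .to_csv(csv_path, index=False)
    meta = {}
    for s in sessions:
        tm = s.task_map
        meta[s.participant_id] = {
            "persons": list(tm.persons),
            "animals": list(tm.animals),
            "vegetables": list(tm.vegetables),
            "preference": {p: list(v) for p, v in tm.preference.items()},
            "reward_probs": s.reward_probs.tolist(),
            "config": asdict(s.config),
            "seed": s.seed,
        }
    meta_path.write_text(json.dumps(meta, indent=1))
    return csv_path, meta_path


def _rebuild_task_map(m: dict) -> TaskMap:
    names = [*m["animals"], *m["vegetables"]]
    po = np.array([[names.index(o) for o in m["preference"][p]]
                   for p in m["persons"]])
    return TaskMap(tuple(m["persons"]), tuple(m["animals"]),
                   tuple(m["vegetables"]), po)


def read_sessions(path: Union[str, Path]) -> list[SessionData]:
    """Read a cohort written by :func:`write_sessions`, validating each row.

    Missing choices (empty ``chosen_person``) and missing RTs are accepted;
    a chosen person outside the offered pair or an unknown name is a
    :class:`ParseError` reporting the offending rows.
    """
    path = Path(path)
    csv_path = path / "sessions.csv" if path.is_dir() else path
    meta_path = csv_path.with_name("sessions_meta.json")
    if not meta_path.exists():
        raise ParseError(f"missing sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    frame = pd.read_csv(csv_path, dtype={"chosen_person": "string"},
                        keep_default_na=True)
    if "rt_ms" not in frame.columns:
        frame["rt_ms"] = np.nan
    missing = [c for c in _COLUMNS if c not in frame.columns and c != "rt_ms"]
    if missing:
        raise ParseError(f"missing columns: {missing}")

    sessions = []
    for pid, g in frame.groupby("participant", sort=False):
        if str(pid) not in meta:
            raise ParseError(f"participant {pid!r} absent from sidecar")
        m = meta[str(pid)]
        tm = _rebuild_task_map(m)
        cfg = SessionConfig(**m["config"])
        g = g.sort_values(["block", "trial"]).reset_index(drop=True)
        if len(g) != cfg.n_trials:
            raise ParseError(f"participant {pid!r}: expected {cfg.n_trials} "
                             f"rows, found {len(g)}")
        person_idx = {p: i for i, p in enumerate(tm.persons)}
        bad_rows = []

        def _lookup(col):
            out = np.empty(len(g), dtype=np.int64)
            for i, v in enumerate(g[col]):
                if pd.isna(v) or v == "":
                    out[i] = -1
                elif v in person_idx:
                    out[i] = person_idx[v]
                else:
                    bad_rows.append((i, col, v))
                    out[i] = -1
            return out

        left = _lookup("left_person")
        right = _lookup("right_person")
        chosen = _lookup("chosen_person")
        if np.any(left < 0) or np.any(right < 0):
            raise ParseError(f"participant {pid!r}: unreadable offers "
                             f"(rows {bad_rows[:5]})")
        off = (chosen >= 0) & (chosen != left) & (chosen != right)
        if np.any(off):
            raise ParseError(
                f"participant {pid!r}: chosen person not offered on rows "
                f"{np.where(off)[0][:10].tolist()}")
        if bad_rows:
            raise ParseError(f"participant {pid!r}: unknown names {bad_rows[:5]}")

        fmt = np.array([FORMATS.index(f) for f in g["format"]])
        # temporal outcome order: vegetable-first iff the first outcome is
        # a vegetable (only resolvable on choice trials; default False)
        veg_names = set(tm.vegetables)
        veg_first = np.array([
            (o in veg_names) if isinstance(o, str) and o else False
            for o in g["first_outcome"]])
        r1 = np.where(chosen >= 0, g["reward1"].fillna(-1).to_numpy(), -1)
        r2 = np.where(chosen >= 0, g["reward2"].fillna(-1).to_numpy(), -1)
        session = SessionData(
            tm, cfg, np.asarray(m["reward_probs"], dtype=float),
            block=g["block"].to_numpy() - 1, left=left, right=right,
            fmt=fmt, veg_first=veg_first, chosen=chosen,
            reward1=r1.astype(np.int64), reward2=r2.astype(np.int64),
            rt_ms=g["rt_ms"].to_numpy(dtype=float),
            participant_id=str(pid), seed=m.get("seed"))
        sessions.append(session)
    return sessions


@dataclass
class RunConfig:
    """Configuration of an end-to-end synthetic run."""

    n_participants: int = 5
    session: SessionConfig = field(default_factory=SessionConfig)
    model: str = "full"
    sub_model: str = "no_presentation_MBCA"
    n_starts: int = 20
    n_boot: int = 99
    n_resample: int = 2000
    alpha: float = 0.05
    n_earnings_sessions: int = 50
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("model", "sub_model"):
            if getattr(self, name) not in MODEL_SPECS:
                raise ValueError(f"unknown model name {getattr(self, name)!r}")
        if isinstance(self.session, dict):
            self.session = SessionConfig(**self.session)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @property
    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a cohort and run fits, comparison, signatures and earnings.

    Returns a provenance-stamped results bundle; deterministic stages are
    bit-identical under a repeated configuration.
    """
    from . import comparison, earnings, signatures  # deferred heavy imports

    bundle = {"config": asdict(config), "config_hash": config.hash,
              "seed": config.seed, "version": __version__}
    cohort = generate_synthetic_cohort(
        config.n_participants, sample_plausible_params, config.session,
        seed=config.seed, spec=MODEL_SPECS[config.model])
    sessions = [s for s, _ in cohort]
    if config.out_dir:
        write_sessions(sessions, config.out_dir)

    fits = [fit_participant(s, MODEL_SPECS[config.model],
                            n_starts=config.n_starts, seed=config.seed + i)
            for i, s in enumerate(sessions)]
    kept, excluded = exclude_participants(fits)
    bundle["fits"] = [f.to_dict() for f in fits]
    bundle["excluded"] = [f.participant_id for f in excluded]

    sub = MODEL_SPECS[config.sub_model]
    full = MODEL_SPECS[config.model]
    per_part = [comparison.bglrt_participant(
        s, sub, full, n_boot=config.n_boot, n_starts=config.n_starts,
        seed=config.seed + 1000 + i, keep_fits=False)
        for i, s in enumerate(sessions)]
    group = comparison.bglrt_group(per_part, n_resample=config.n_resample,
                                  seed=config.seed + 1)
    bundle["bglrt"] = {
        "sub": sub.name,
        "participant_p": [r.p for r in per_part],
        "group_p": group.p,
        "group_statistic": group.statistic,
    }

    rep = signatures.fit_mixed_logistic(
        signatures.select_repetition_transitions(sessions), "REPEAT",
        signatures.REPETITION_FORMULA)
    gen = signatures.fit_mixed_logistic(
        signatures.select_generalization_transitions(sessions), "GENERALIZE",
        signatures.GENERALIZATION_FORMULA)
    bundle["signatures"] = {
        "repetition_common": vars(rep.composite_main_effect("COMMON")),
        "generalization_common": vars(gen.composite_main_effect("COMMON")),
    }

    yoked = earnings.yoked_format_agents(
        kept if kept else fits, n_sessions=config.n_earnings_sessions,
        config=config.session, seed=config.seed + 2)
    bundle["earnings"] = yoked.to_dict(orient="records")

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(json.dumps(_jsonable(bundle), indent=1))
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
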