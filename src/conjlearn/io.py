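"""CSV/JSON serialization for schedules, sessions, and fit results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import task
from .task import EstimationBout, RewardSchedule, SessionRecord


def schedule_to_frame(schedule: RewardSchedule) -> pd.DataFrame:
    space = schedule.space
    rows = []
    for oid in range(task.N_STIMULI):
        i, j, k = space.instances(oid)
        rows.append(
            {"object_id": oid, "shape": i, "pattern": j, "color": k,
             "p_reward": schedule.p[oid]}
        )
    return pd.DataFrame(rows)


def save_schedule(schedule: RewardSchedule, path) -> None:
    path = Path(path)
    schedule_to_frame(schedule).to_csv(path, index=False)
    sidecar = {
        "informative_feature": int(schedule.informative_feature),
        "feature_marginals": schedule.feature_marginals.tolist(),
        "conjunction_marginals": schedule.conjunction_marginals.tolist(),
        "generalizability_feature": schedule.generalizability_feature,
        "generalizability_mixed": schedule.generalizability_mixed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_schedule(path) -> RewardSchedule:
    path = Path(path)
    df = pd.read_csv(path).sort_values("object_id")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    sched = RewardSchedule(
        p=df["p_reward"].to_numpy(),
        informative_feature=sidecar["informative_feature"],
    )
    sched.generalizability_feature = sidecar.get(
        "generalizability_feature", float("nan")
    )
    sched.generalizability_mixed = sidecar.get(
        "generalizability_mixed", float("nan")
    )
    return sched


def session_to_frame(session: SessionRecord) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial": np.arange(1, session.n_trials + 1),
            "left_id": session.left,
            "right_id": session.right,
            "chosen_side": session.chosen_side,
            "r_left": session.reward_left,
            "r_right": session.reward_right,
        }
    )


def save_session(session: SessionRecord, path) -> None:
    path = Path(path)
    session_to_frame(session).to_csv(path, index=False)
    bouts = [
        {
            "index": b.index,
            "after_trial": int(b.after_trial),
            "order": np.asarray(b.order).tolist(),
            "estimates": np.asarray(b.estimates).tolist(),
        }
        for b in session.bouts
    ]
    meta = {"rng_seed": session.rng_seed, "bouts": bouts}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_session(path, schedule: RewardSchedule | None = None) -> SessionRecord:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    bouts = [
        EstimationBout(
            index=b["index"],
            after_trial=b["after_trial"],
            order=np.asarray(b["order"], int),
            estimates=np.asarray(b["estimates"], float),
        )
        for b in meta["bouts"]
    ]
    return SessionRecord(
        left=df["left_id"].to_numpy(),
        right=df["right_id"].to_numpy(),
        reward_left=df["r_left"].to_numpy(),
        reward_right=df["r_right"].to_numpy(),
        chosen_side=df["chosen_side"].to_numpy(),
        bouts=bouts,
        rng_seed=meta["rng_seed"],
        schedule=schedule,
    )


def fit_to_dict(fit) -> dict:
    params = {
        name: (np.asarray(getattr(fit.params, "w_f")).tolist()
               if name == "w_f" else getattr(fit.params, name))
        for name in ("alpha_rew", "alpha_unr", "d", "w_o", "w_f", "w_c", "bias")
    }
    return {
        "model": fit.spec.key,
        "params": params,
        "negll": fit.negll,
        "k": fit.k,
        "aic": fit.aic,
        "bic": fit.bic,
        "converged": fit.converged,
        "n_restarts": fit.n_restarts,
    }
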