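"""Strategy-level reward-probability predictions and the generalizability index.

A learner can estimate the reward probability of a stimulus from different
component values: the stimulus's own assigned probability (object-based), the
average reward probabilities of its three feature instances (feature-based),
or the average probability of its informative-feature instance combined with
that of its informative-conjunction instance (mixed feature+conjunction).
Component probabilities are combined with the Bayes odds rule

    p = prod(p_i) / (prod(p_i) + prod(1 - p_i))

which is symmetric, fixes 0.5 when all components are 0.5, and is monotone
increasing in each component.

The generalizability index of a schedule under a strategy is the Spearman
rank correlation between the 27 assigned probabilities and the 27 predicted
ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .task import N_STIMULI, RewardSchedule

STRATEGIES = ("object", "feature", "conjunction", "mixed_fc")

_CLIP = 1e-6  # component probabilities are clipped to [_CLIP, 1-_CLIP]


@dataclass
class StrategyPrediction:
    strategy: str
    component_values: dict
    predicted: np.ndarray


def bayes_combine(probs) -> float:
    """Combine component probabilities with the Bayes odds rule.

    Components exactly at 0 and 1 simultaneously are contradictory and raise;
    otherwise components are clipped away from the boundaries where the rule
    is singular.
    """
    probs = np.asarray(probs, dtype=float)
    if np.any(probs == 0.0) and np.any(probs == 1.0):
        raise ValueError("contradictory components: both 0 and 1 present")
    probs = np.clip(probs, _CLIP, 1 - _CLIP)
    num = np.prod(probs)
    den = num + np.prod(1 - probs)
    return float(num / den)


def bayes_combine_arrays(*arrays) -> np.ndarray:
    """Vectorized Bayes odds combination of aligned probability arrays."""
    arrays = [np.clip(np.asarray(a, float), _CLIP, 1 - _CLIP) for a in arrays]
    num = np.ones_like(arrays[0])
    den = np.ones_like(arrays[0])
    for a in arrays:
        num = num * a
        den = den * (1 - a)
    return num / (num + den)


def feature_values(schedule: RewardSchedule) -> np.ndarray:
    """Average reward probability per feature id (9,), arithmetic averaging."""
    marg = schedule.feature_marginals  # (dim, instance)
    return marg.reshape(-1)


def conjunction_values(schedule: RewardSchedule) -> np.ndarray:
    """Average reward probability per conjunction id (27,)."""
    out = np.empty(27)
    for pair in range(3):
        out[9 * pair : 9 * (pair + 1)] = schedule.conjunction_marginal_matrix(
            pair
        ).reshape(-1)
    return out


def _lr_geometric_values(schedule: RewardSchedule, members_fn, n_ids):
    """Likelihood-ratio variant: geometric mean of member odds, mapped back
    to a probability.  Available for sensitivity checks; arithmetic averaging
    is the default everywhere."""
    p = np.clip(schedule.p, _CLIP, 1 - _CLIP)
    odds = p / (1 - p)
    vals = np.empty(n_ids)
    for fid in range(n_ids):
        members = members_fn(fid)
        g = np.exp(np.mean(np.log(odds[list(members)])))
        vals[fid] = g / (1 + g)
    return vals


def predict_all(
    schedule: RewardSchedule, strategy: str, marginalization: str = "average"
) -> StrategyPrediction:
    """Predicted reward probability of all 27 stimuli under a strategy.

    ``marginalization`` selects arithmetic probability averaging (default)
    or the geometric likelihood-ratio variant (``"lr"``).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    space = schedule.space
    if strategy == "object":
        return StrategyPrediction(
            strategy, {oid: schedule.p[oid] for oid in range(N_STIMULI)},
            schedule.p.copy(),
        )
    if marginalization == "average":
        fvals = feature_values(schedule)
        cvals = conjunction_values(schedule)
    elif marginalization == "lr":
        fvals = _lr_geometric_values(schedule, space.feature_members, 9)
        cvals = _lr_geometric_values(schedule, space.conjunction_members, 27)
    else:
        raise ValueError("marginalization must be 'average' or 'lr'")

    predicted = np.empty(N_STIMULI)
    components: dict = {}
    if strategy == "feature":
        for oid in range(N_STIMULI):
            fids = space.feature_ids(oid)
            predicted[oid] = bayes_combine([fvals[f] for f in fids])
        components = {f"F{f}": fvals[f] for f in range(9)}
    elif strategy == "conjunction":
        pair = schedule.informative_pair
        for oid in range(N_STIMULI):
            cid = space.conjunction_ids(oid)[pair]
            predicted[oid] = np.clip(cvals[cid], _CLIP, 1 - _CLIP)
        components = {f"C{c}": cvals[c] for c in range(9 * pair, 9 * pair + 9)}
    else:  # mixed_fc
        dim = schedule.informative_feature
        pair = schedule.informative_pair
        for oid in range(N_STIMULI):
            fid = space.feature_ids(oid)[dim]
            cid = space.conjunction_ids(oid)[pair]
            predicted[oid] = bayes_combine([fvals[fid], cvals[cid]])
        components = {
            **{f"F{f}": fvals[f] for f in range(3 * dim, 3 * dim + 3)},
            **{f"C{c}": cvals[c] for c in range(9 * pair, 9 * pair + 9)},
        }
    return StrategyPrediction(strategy, components, predicted)


def generalizability_index(
    schedule: RewardSchedule, strategy: str, marginalization: str = "average"
) -> float:
    """Spearman correlation between assigned and strategy-predicted probabilities."""
    predicted = predict_all(schedule, strategy, marginalization).predicted
    if np.ptp(schedule.p) == 0 or np.ptp(predicted) == 0:
        raise ValueError("generalizability undefined for constant vectors")
    rho, _ = stats.spearmanr(schedule.p, predicted)
    return float(rho)


def export_predictions(schedule: RewardSchedule, strategies=STRATEGIES):
    """Tidy DataFrame (object_id, strategy, predicted_p)."""
    import pandas as pd

    rows = []
    for s in strategies:
        pred = predict_all(schedule, s).predicted
        rows.extend(
            {"object_id": oid, "strategy": s, "predicted_p": pred[oid]}
            for oid in range(N_STIMULI)
        )
    return pd.DataFrame(rows)
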