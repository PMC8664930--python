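"""Trial-by-trial reinforcement-learning models of choice in the task.

The family covers four learning strategies — object-based, feature-based,
mixed feature+conjunction (three variants, differing in which feature is the
"learned" one), and mixed feature+object (three variants) — each available in
a chosen-update form (only the selected stimulus's components are updated), a
full-update form (the unchosen stimulus's components are also updated, using
its own reward feedback), and a chosen-update form with decay of all
non-updated values toward 0.5.  That 8 x 3 grid is the registry's default
24-model set.

Value updates use separate learning rates for rewarded and unrewarded trials:

    V <- V + alpha_rew * (1 - V)   after reward
    V <- V - alpha_unr * V         after no reward

and decayed values relax as ``V <- V - d * (V - 0.5)``.  Choice between the
two on-screen stimuli is a logistic function of weighted component-value
differences plus a left/right bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .task import (
    DIM_PAIRS,
    N_STIMULI,
    RewardSchedule,
    SessionRecord,
    generate_session,
)

FAMILIES = ("object", "feature", "fc1", "fc2", "fc3", "f1o", "f2o", "f3o")
UPDATE_MODES = ("chosen", "full")


@dataclass(frozen=True)
class RLModelSpec:
    family: str
    update_mode: str = "chosen"
    decay: bool = False

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.update_mode not in UPDATE_MODES:
            raise ValueError(f"unknown update mode {self.update_mode!r}")
        if self.decay and self.update_mode == "full":
            raise ValueError("decay variants are defined for chosen-update models")

    @property
    def key(self) -> str:
        k = f"{self.family}_{self.update_mode}"
        return k + "_decay" if self.decay else k

    @property
    def n_params(self) -> int:
        base = {"object": 4, "feature": 6}.get(self.family, 5)
        return base + (1 if self.decay else 0)

    @property
    def param_names(self) -> tuple:
        names = ["alpha_rew", "alpha_unr"]
        if self.decay:
            names.append("d")
        if self.family == "object":
            names.append("w_o")
        elif self.family == "feature":
            names.extend(["w_f0", "w_f1", "w_f2"])
        elif self.family.startswith("fc"):
            names.extend(["w_f", "w_c"])
        else:
            names.extend(["w_f", "w_o"])
        names.append("bias")
        return tuple(names)


def model_registry() -> list:
    """The default 24-model set: 8 families x {chosen, full, chosen+decay}."""
    specs = []
    for fam in FAMILIES:
        specs.append(RLModelSpec(fam, "chosen", False))
        specs.append(RLModelSpec(fam, "full", False))
        specs.append(RLModelSpec(fam, "chosen", True))
    return specs


#: machine-readable fitting bounds / sampling ranges per parameter kind
PARAM_BOUNDS = {
    "alpha_rew": (0.0, 1.0),
    "alpha_unr": (0.0, 1.0),
    "d": (0.0, 1.0),
    "w_o": (-np.inf, np.inf),
    "w_f": (-np.inf, np.inf),
    "w_c": (-np.inf, np.inf),
    "bias": (-np.inf, np.inf),
}


def spec_from_key(key: str) -> RLModelSpec:
    parts = key.split("_")
    decay = parts[-1] == "decay"
    if decay:
        parts = parts[:-1]
    family, mode = "_".join(parts[:-1]), parts[-1]
    return RLModelSpec(family, mode, decay)


@dataclass
class RLParams:
    alpha_rew: float = 0.3
    alpha_unr: float = 0.3
    d: float = 0.0
    w_o: float = 0.0
    w_f: object = 0.0  # scalar, or length-3 sequence for the feature family
    w_c: float = 0.0
    bias: float = 0.0

    def validate(self):
        for name in ("alpha_rew", "alpha_unr", "d"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class ValueState:
    """Component value estimates, all initialized to 0.5."""

    V_object: np.ndarray = field(default_factory=lambda: np.full(27, 0.5))
    V_feature: np.ndarray = field(default_factory=lambda: np.full(9, 0.5))
    V_conjunction: np.ndarray = field(default_factory=lambda: np.full(27, 0.5))

    def copy(self) -> "ValueState":
        return ValueState(
            self.V_object.copy(), self.V_feature.copy(), self.V_conjunction.copy()
        )


def _learned_dims(family: str, informative_feature: int):
    """(learned feature dim, learned conjunction pair index or None).

    Variant 1 learns the informative feature; variants 2 and 3 learn the
    second and first non-informative dimension respectively, paired (for F+C
    models) with the conjunction of the remaining two dimensions.
    """
    others = [d for d in range(3) if d != informative_feature]
    if family.startswith("fc"):
        variant = int(family[2])
    elif family.endswith("o") and family[0] == "f" and family[1] in "123":
        variant = int(family[1])
    else:
        variant = None
    if variant == 1:
        dim = informative_feature
    elif variant == 2:
        dim = others[1]
    elif variant == 3:
        dim = others[0]
    else:
        return None, None
    if family.startswith("fc"):
        pair_dims = tuple(sorted(d for d in range(3) if d != dim))
        return dim, DIM_PAIRS.index(pair_dims)
    return dim, None


class RLModel:
    """A model spec bound to a schedule (resolving learned dimensions)."""

    def __init__(self, spec: RLModelSpec, schedule: RewardSchedule):
        self.spec = spec
        self.schedule = schedule
        space = schedule.space
        self.feature_ids = np.array(
            [space.feature_ids(o) for o in range(N_STIMULI)]
        )  # (27, 3)
        self.conj_ids = np.array(
            [space.conjunction_ids(o) for o in range(N_STIMULI)]
        )  # (27, 3)
        self.learned_dim, self.learned_pair = _learned_dims(
            spec.family, schedule.informative_feature
        )

    # -- choice ----------------------------------------------------------
    def choice_logit(self, state: ValueState, s1: int, s2: int, params: RLParams):
        fam = self.spec.family
        if fam == "object":
            z = params.w_o * (state.V_object[s1] - state.V_object[s2])
        elif fam == "feature":
            w = np.broadcast_to(np.asarray(params.w_f, float), (3,))
            z = 0.0
            for dim in range(3):
                z += w[dim] * (
                    state.V_feature[self.feature_ids[s1, dim]]
                    - state.V_feature[self.feature_ids[s2, dim]]
                )
        elif fam.startswith("fc"):
            d, q = self.learned_dim, self.learned_pair
            z = params.w_f * (
                state.V_feature[self.feature_ids[s1, d]]
                - state.V_feature[self.feature_ids[s2, d]]
            ) + params.w_c * (
                state.V_conjunction[self.conj_ids[s1, q]]
                - state.V_conjunction[self.conj_ids[s2, q]]
            )
        else:  # f+o
            d = self.learned_dim
            z = params.w_f * (
                state.V_feature[self.feature_ids[s1, d]]
                - state.V_feature[self.feature_ids[s2, d]]
            ) + params.w_o * (state.V_object[s1] - state.V_object[s2])
        return z + params.bias

    def choice_prob(self, state, s1, s2, params) -> float:
        """P(choose s1) via the logistic function."""
        return 1.0 / (1.0 + math.exp(-self.choice_logit(state, s1, s2, params)))

    # -- learning --------------------------------------------------------
    def _updated_components(self, oid: int):
        """(array, index) pairs updated when stimulus ``oid`` gets feedback."""
        fam = self.spec.family
        if fam == "object":
            return [("V_object", oid)]
        if fam == "feature":
            return [("V_feature", f) for f in self.feature_ids[oid]]
        if fam.startswith("fc"):
            return [
                ("V_feature", self.feature_ids[oid, self.learned_dim]),
                ("V_conjunction", self.conj_ids[oid, self.learned_pair]),
            ]
        return [
            ("V_feature", self.feature_ids[oid, self.learned_dim]),
            ("V_object", oid),
        ]

    def _used_indices(self):
        """Entries each value array contributes to this family's predictions."""
        fam = self.spec.family
        used = {}
        if fam == "object":
            used["V_object"] = np.arange(27)
        elif fam == "feature":
            used["V_feature"] = np.arange(9)
        elif fam.startswith("fc"):
            d, q = self.learned_dim, self.learned_pair
            used["V_feature"] = np.arange(3 * d, 3 * d + 3)
            used["V_conjunction"] = np.arange(9 * q, 9 * q + 9)
        else:
            d = self.learned_dim
            used["V_feature"] = np.arange(3 * d, 3 * d + 3)
            used["V_object"] = np.arange(27)
        return used

    @staticmethod
    def _reinforce(arr, idx, reward, a_rew, a_unr):
        v = arr[idx]
        arr[idx] = v + a_rew * (1 - v) if reward else v - a_unr * v

    def update(
        self,
        state: ValueState,
        chosen: int,
        r_chosen: int,
        unchosen: int | None = None,
        r_unchosen: int | None = None,
        params: RLParams | None = None,
    ) -> ValueState:
        """Apply one trial's feedback (in place) and return the state."""
        a_rew, a_unr = params.alpha_rew, params.alpha_unr
        touched = []
        for arr_name, idx in self._updated_components(chosen):
            self._reinforce(getattr(state, arr_name), idx, r_chosen, a_rew, a_unr)
            touched.append((arr_name, idx))
        if self.spec.update_mode == "full" and unchosen is not None:
            for arr_name, idx in self._updated_components(unchosen):
                self._reinforce(
                    getattr(state, arr_name), idx, r_unchosen, a_rew, a_unr
                )
                touched.append((arr_name, idx))
        if self.spec.decay and params.d > 0:
            for arr_name, used in self._used_indices().items():
                arr = getattr(state, arr_name)
                mask = np.ones(arr.shape, bool)
                mask[:] = False
                mask[used] = True
                for t_arr, t_idx in touched:
                    if t_arr == arr_name:
                        mask[t_idx] = False
                arr[mask] -= params.d * (arr[mask] - 0.5)
        return state

    # -- latent stimulus estimates --------------------------------------
    def stimulus_estimates(self, state: ValueState) -> np.ndarray:
        """Per-stimulus reward-probability estimate implied by current values
        (Bayes odds combination of the family's components)."""
        from .strategies import bayes_combine_arrays

        fam = self.spec.family
        if fam == "object":
            return state.V_object.copy()
        if fam == "feature":
            comps = [state.V_feature[self.feature_ids[:, d]] for d in range(3)]
            return bayes_combine_arrays(*comps)
        if fam.startswith("fc"):
            d, q = self.learned_dim, self.learned_pair
            return bayes_combine_arrays(
                state.V_feature[self.feature_ids[:, d]],
                state.V_conjunction[self.conj_ids[:, q]],
            )
        d = self.learned_dim
        return bayes_combine_arrays(
            state.V_feature[self.feature_ids[:, d]], state.V_object
        )


def simulate_agent(
    schedule: RewardSchedule,
    spec: RLModelSpec,
    params: RLParams,
    seed: int,
    record_values: bool = False,
    session: SessionRecord | None = None,
) -> SessionRecord:
    """Simulate one agent through a full session.

    Choices are sampled from the model's logistic rule and values updated
    online; estimation bouts are filled with the agent's noiseless latent
    stimulus estimates.  If ``record_values`` is set, the per-trial latent
    estimates of all 27 stimuli are stored on ``session.value_trace``.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    if session is None:
        session = generate_session(schedule, seed)
    model = RLModel(spec, schedule)
    state = ValueState()
    bout_after = {b.after_trial: b for b in session.bouts}
    trace = np.empty((session.n_trials, N_STIMULI)) if record_values else None
    for t in range(session.n_trials):
        left, right = session.left[t], session.right[t]
        p_left = model.choice_prob(state, left, right, params)
        side = 0 if rng.random() < p_left else 1
        session.chosen_side[t] = side
        chosen = left if side == 0 else right
        unchosen = right if side == 0 else left
        r_cho = session.reward_left[t] if side == 0 else session.reward_right[t]
        r_unc = session.reward_right[t] if side == 0 else session.reward_left[t]
        model.update(state, chosen, r_cho, unchosen, r_unc, params)
        if record_values:
            trace[t] = model.stimulus_estimates(state)
        if (t + 1) in bout_after:
            bout_after[t + 1].estimates = model.stimulus_estimates(state)
    if record_values:
        session.value_trace = trace
    session.agent_spec = spec
    session.agent_params = replace(params)
    return session
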