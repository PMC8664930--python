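"""Stimulus space, reward schedules, and task sessions.

The task is a multi-dimensional probabilistic learning paradigm: 27 visual
stimuli are built from three feature dimensions (shape, pattern, color), each
with three instances.  On every choice trial two stimuli that differ in all
three features are shown; selecting a stimulus is rewarded with a fixed,
stimulus-specific probability, and reward is drawn independently for the
chosen and the unchosen stimulus.  Five bouts of estimation trials, in which
the reward probability of every stimulus is probed, are interleaved after
fixed trial positions.

The reward schedule has partial structure: one *informative feature* whose
instance-wise average reward probabilities differ (0.3/0.5/0.7 by default),
two non-informative features whose averages are flat, and an *informative
conjunction* (the pairing of the two non-informative dimensions) whose
instance-pair averages carry predictive value the individual features lack.
Object-level residuals on top of this structure make the schedule only
partially generalizable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

N_FEATURES = 3
N_INSTANCES = 3
N_STIMULI = N_INSTANCES**N_FEATURES  # 27
N_FEATURE_IDS = N_FEATURES * N_INSTANCES  # 9
N_CONJUNCTIONS = 27  # 3 dimension pairs x 9 instance pairs
N_TRIALS = 432
BOUT_POSITIONS = (86, 173, 259, 346, 432)  # estimation bout after these trials (1-based)

#: dimension pairs defining conjunction types, in canonical order
DIM_PAIRS = ((0, 1), (0, 2), (1, 2))

#: printed conjunction-marginal matrix of the default schedule (rows = instances
#: of the first non-informative dimension, cols = instances of the second)
DEFAULT_CONJUNCTION_MATRIX = np.array(
    [[0.63, 0.27, 0.63], [0.50, 0.50, 0.50], [0.37, 0.74, 0.37]]
)
DEFAULT_FEATURE_MARGINALS = np.array([0.3, 0.5, 0.7])


@dataclass(frozen=True)
class StimulusSpace:
    """The 3 x 3 x 3 lattice of stimuli with feature/conjunction indexing.

    Object ids enumerate stimuli canonically: ``id = 9*shape + 3*pattern +
    color`` (all indices 0-based).  Feature ids run 0..8 (``3*dim +
    instance``); conjunction ids run 0..26 (``9*pair + 3*a + b`` where
    ``pair`` indexes :data:`DIM_PAIRS` and ``a``, ``b`` are the instances of
    the pair's two dimensions).
    """

    n_features: int = N_FEATURES
    n_instances: int = N_INSTANCES
    stimuli: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if not self.stimuli:
            combos = tuple(
                itertools.product(range(self.n_instances), repeat=self.n_features)
            )
            object.__setattr__(self, "stimuli", combos)

    @property
    def n_stimuli(self) -> int:
        return self.n_instances**self.n_features

    def object_id(self, instances) -> int:
        i, j, k = instances
        return 9 * i + 3 * j + k

    def instances(self, object_id: int):
        return self.stimuli[object_id]

    def feature_ids(self, object_id: int):
        """The 3 feature ids (one per dimension) of a stimulus."""
        return tuple(
            3 * dim + inst for dim, inst in enumerate(self.stimuli[object_id])
        )

    def conjunction_id(self, pair_index: int, inst_a: int, inst_b: int) -> int:
        return 9 * pair_index + 3 * inst_a + inst_b

    def conjunction_ids(self, object_id: int):
        """The 3 conjunction ids (one per dimension pair) of a stimulus."""
        inst = self.stimuli[object_id]
        return tuple(
            self.conjunction_id(p, inst[a], inst[b])
            for p, (a, b) in enumerate(DIM_PAIRS)
        )

    def conjunction_members(self, conjunction_id: int):
        """Object ids of the 3 stimuli containing a given conjunction."""
        pair, rest = divmod(conjunction_id, 9)
        a, b = divmod(rest, 3)
        dims = DIM_PAIRS[pair]
        return tuple(
            oid
            for oid, inst in enumerate(self.stimuli)
            if inst[dims[0]] == a and inst[dims[1]] == b
        )

    def feature_members(self, feature_id: int):
        """Object ids of the 9 stimuli containing a given feature instance."""
        dim, inst = divmod(feature_id, 3)
        return tuple(
            oid for oid, s in enumerate(self.stimuli) if s[dim] == inst
        )

    def pair_index(self, dim_a: int, dim_b: int) -> int:
        return DIM_PAIRS.index(tuple(sorted((dim_a, dim_b))))

    def share_any_feature(self, oid_a: int, oid_b: int) -> bool:
        a, b = self.stimuli[oid_a], self.stimuli[oid_b]
        return any(x == y for x, y in zip(a, b))


def build_stimulus_space() -> StimulusSpace:
    """Canonical 27-stimulus space."""
    return StimulusSpace()


class InfeasibleScheduleError(ValueError):
    """Requested marginals force probabilities outside [0, 1]."""


@dataclass
class RewardSchedule:
    """27 assigned reward probabilities plus their marginal structure.

    Attributes
    ----------
    p : (27,) array of per-object reward probabilities.
    informative_feature : feature dimension whose marginals differ.
    feature_marginals : (3, 3) array, ``[dim, instance]`` average reward
        probability over the 9 stimuli containing that instance.
    conjunction_marginals : (3, 3) array over the instance pairs of the two
        non-informative dimensions (rows = first of the pair).
    generalizability_feature, generalizability_mixed : Spearman correlations
        between ``p`` and the feature-only / feature+conjunction predictions
        (see :mod:`conjlearn.strategies`).
    """

    p: np.ndarray
    informative_feature: int = 0
    space: StimulusSpace = field(default_factory=build_stimulus_space)
    generalizability_feature: float = float("nan")
    generalizability_mixed: float = float("nan")

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (N_STIMULI,):
            raise ValueError("schedule must assign exactly 27 probabilities")
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise InfeasibleScheduleError("probabilities must lie in [0, 1]")

    # -- marginals -------------------------------------------------------
    @property
    def cube(self) -> np.ndarray:
        return self.p.reshape(3, 3, 3)

    @property
    def feature_marginals(self) -> np.ndarray:
        out = np.empty((3, 3))
        for dim in range(3):
            axes = tuple(a for a in range(3) if a != dim)
            out[dim] = self.cube.mean(axis=axes)
        return out

    def conjunction_marginal_matrix(self, pair_index: int) -> np.ndarray:
        a, b = DIM_PAIRS[pair_index]
        other = ({0, 1, 2} - {a, b}).pop()
        return np.moveaxis(self.cube, (a, b), (0, 1)).mean(axis=2)

    @property
    def informative_pair(self) -> int:
        """Pair index of the informative conjunction (the two non-informative dims)."""
        dims = tuple(d for d in range(3) if d != self.informative_feature)
        return DIM_PAIRS.index(dims)

    @property
    def conjunction_marginals(self) -> np.ndarray:
        return self.conjunction_marginal_matrix(self.informative_pair)

    def better_stimulus(self, oid_a: int, oid_b: int) -> int:
        return oid_a if self.p[oid_a] >= self.p[oid_b] else oid_b


def _consistent_baseline(
    feature_marginals: np.ndarray, conjunction_matrix: np.ndarray
) -> np.ndarray:
    """Additive baseline cube with the requested marginals.

    ``base[i, j, k] = s_i + M[j, k] - g`` reproduces the informative-feature
    marginals ``s`` and the conjunction matrix ``M`` exactly provided both
    share the grand mean ``g``.
    """
    g = conjunction_matrix.mean()
    s = np.asarray(feature_marginals, float)
    if abs(s.mean() - g) > 1e-12:
        # absorb the (typically rounding-level) mean mismatch into the
        # informative marginals, spreading it evenly
        s = s + (g - s.mean())
    base = s[:, None, None] + conjunction_matrix[None, :, :] - g
    return base


def _nullspace_project(e: np.ndarray) -> np.ndarray:
    """Project a 3x3x3 residual onto the subspace with zero informative-feature
    and zero conjunction marginals (orthogonal projection; both constraint
    families share only the grand mean)."""
    m_conj = e.mean(axis=0)  # (3,3) over informative dim
    m_feat = e.mean(axis=(1, 2))  # (3,)
    g = e.mean()
    return e - m_conj[None, :, :] - m_feat[:, None, None] + g


def _orient_cube(base: np.ndarray, informative_feature: int) -> np.ndarray:
    """Move the informative dimension from axis 0 to its dimension index."""
    return np.moveaxis(base, 0, informative_feature)


def make_default_schedule(informative_feature: int = 0) -> RewardSchedule:
    """The experiment's reward schedule.

    Informative-feature marginals are the printed (0.3, 0.5, 0.7) up to the
    +1/900 shift forced by the grand mean of the printed conjunction matrix,
    the conjunction-marginal matrix is reproduced exactly, and a fixed
    object-level residual makes the schedule non-generalizable with a
    mixed feature+conjunction generalizability of ~0.86.
    """
    return generate_schedule(
        feature_marginals=DEFAULT_FEATURE_MARGINALS,
        conjunction_matrix=DEFAULT_CONJUNCTION_MATRIX,
        target_generalizability=0.86,
        seed=20211210,
        informative_feature=informative_feature,
    )


def generate_schedule(
    feature_marginals,
    conjunction_matrix,
    target_generalizability: float,
    seed: int,
    informative_feature: int = 0,
    max_tries: int = 200,
) -> RewardSchedule:
    """Construct a 27-value schedule with the requested marginal structure.

    The schedule is the additive consistent baseline plus a residual drawn in
    the null space of both marginalization operators, scaled so that the
    Spearman correlation between the schedule and its own mixed
    feature+conjunction predictions (the generalizability index) is as close
    as possible to ``target_generalizability``.  The achieved value is stored
    on the returned schedule rather than silently assumed.

    Raises
    ------
    InfeasibleScheduleError
        If the requested marginals force probabilities outside [0, 1].
    """
    from . import strategies  # local import to avoid cycle

    feature_marginals = np.asarray(feature_marginals, float)
    conjunction_matrix = np.asarray(conjunction_matrix, float)
    base = _consistent_baseline(feature_marginals, conjunction_matrix)
    if base.min() < -1e-12 or base.max() > 1 + 1e-12:
        raise InfeasibleScheduleError(
            "marginal combination forces probabilities outside [0, 1]"
        )
    base = np.clip(base, 0.0, 1.0)

    rng = np.random.default_rng(seed)

    def build(cube):
        p = _orient_cube(cube, informative_feature).reshape(-1)
        sched = RewardSchedule(
            p=p, informative_feature=informative_feature
        )
        sched.generalizability_feature = strategies.generalizability_index(
            sched, "feature"
        )
        sched.generalizability_mixed = strategies.generalizability_index(
            sched, "mixed_fc"
        )
        return sched

    if target_generalizability >= 1.0:
        return build(base)

    best = None
    for _ in range(max_tries):
        e = _nullspace_project(rng.standard_normal((3, 3, 3)))
        norm = np.linalg.norm(e)
        if norm < 1e-9:
            continue
        e /= norm
        # residual scale that keeps p inside [0,1]
        with np.errstate(divide="ignore"):
            pos_room = np.where(e > 0, (1 - base) / e, np.inf).min()
            neg_room = np.where(e < 0, -base / e, np.inf).min()
        lam_max = 0.999 * min(pos_room, neg_room)
        for lam in np.linspace(0.0, lam_max, 41):
            sched = build(np.clip(base + lam * e, 0.0, 1.0))
            err = abs(sched.generalizability_mixed - target_generalizability)
            if best is None or err < best[0]:
                best = (err, sched)
        if best[0] <= 0.02:
            break
    return best[1]


@dataclass
class EstimationBout:
    """One bout of estimation trials probing all 27 stimuli."""

    index: int
    after_trial: int
    order: np.ndarray  # probe order of object ids
    estimates: np.ndarray  # per-object estimate, indexed by object id (NaN until filled)


@dataclass
class SessionRecord:
    """Trial-level record of one task session.

    ``chosen_side`` is 0 (left) / 1 (right), -1 until an agent fills it.
    Rewards are pre-drawn independently per stimulus per trial
    (``reward_left``/``reward_right``) so the same session structure can be
    replayed by different agents; ``r_chosen``/``r_unchosen`` view them
    through the choices.
    """

    left: np.ndarray
    right: np.ndarray
    reward_left: np.ndarray
    reward_right: np.ndarray
    chosen_side: np.ndarray
    bouts: list
    rng_seed: int
    schedule: RewardSchedule | None = None

    @property
    def n_trials(self) -> int:
        return len(self.left)

    @property
    def chosen(self) -> np.ndarray:
        return np.where(self.chosen_side == 0, self.left, self.right)

    @property
    def unchosen(self) -> np.ndarray:
        return np.where(self.chosen_side == 0, self.right, self.left)

    @property
    def r_chosen(self) -> np.ndarray:
        return np.where(self.chosen_side == 0, self.reward_left, self.reward_right)

    @property
    def r_unchosen(self) -> np.ndarray:
        return np.where(self.chosen_side == 0, self.reward_right, self.reward_left)

    def better_chosen(self) -> np.ndarray:
        """Indicator of choosing the stimulus with the higher assigned probability."""
        p = self.schedule.p
        pl, pr = p[self.left], p[self.right]
        best_side = (pr > pl).astype(int)
        return (self.chosen_side == best_side).astype(float)


def generate_session(
    schedule: RewardSchedule,
    seed: int,
    n_trials: int = N_TRIALS,
    bout_positions=BOUT_POSITIONS,
) -> SessionRecord:
    """Generate the structure of one session (pairs, rewards, bout layout).

    Pairs are drawn uniformly from the admissible set (the two stimuli share
    no feature instance on any dimension), excluding an immediate repeat of
    the previous unordered pair.  Choices are left unfilled (-1).
    """
    rng = np.random.default_rng(seed)
    space = schedule.space
    admissible = [
        (a, b)
        for a in range(N_STIMULI)
        for b in range(a + 1, N_STIMULI)
        if not space.share_any_feature(a, b)
    ]
    admissible = np.array(admissible)
    left = np.empty(n_trials, dtype=int)
    right = np.empty(n_trials, dtype=int)
    prev = -1
    for t in range(n_trials):
        while True:
            idx = rng.integers(len(admissible))
            if idx != prev:
                break
        prev = idx
        a, b = admissible[idx]
        if rng.random() < 0.5:
            a, b = b, a
        left[t], right[t] = a, b
    reward_left = (rng.random(n_trials) < schedule.p[left]).astype(int)
    reward_right = (rng.random(n_trials) < schedule.p[right]).astype(int)
    bouts = [
        EstimationBout(
            index=i,
            after_trial=pos,
            order=rng.permutation(N_STIMULI),
            estimates=np.full(N_STIMULI, np.nan),
        )
        for i, pos in enumerate(bout_positions)
    ]
    return SessionRecord(
        left=left,
        right=right,
        reward_left=reward_left,
        reward_right=reward_right,
        chosen_side=np.full(n_trials, -1, dtype=int),
        bouts=bouts,
        rng_seed=int(seed),
        schedule=schedule,
    )


def quantize_estimates(estimates: np.ndarray) -> np.ndarray:
    """Quantize estimates to the 10 response keys (0.05, 0.15, ..., 0.95)."""
    levels = np.arange(0.05, 1.0, 0.1)
    idx = np.clip(np.round((np.asarray(estimates) - 0.05) / 0.1), 0, 9).astype(int)
    return levels[idx]
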