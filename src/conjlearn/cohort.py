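"""Synthetic cohorts of simulated participants with known generative models.

Every pipeline stage is testable without any external data: a cohort is a
list of simulated sessions, each generated by a known RL model with known
parameters, with estimation bouts filled from the agent's latent values plus
Gaussian noise and 10-level response quantization.  The default mixture
follows the observed strategy split (41 mixed feature+conjunction : 21
feature : 5 object out of 67 learners).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import rl, task
from .rl import RLModelSpec, RLParams
from .task import RewardSchedule, SessionRecord

DEFAULT_MIXTURE = (
    (RLModelSpec("fc1", "chosen", True), 41),
    (RLModelSpec("feature", "chosen", True), 21),
    (RLModelSpec("object", "chosen", True), 5),
)


@dataclass
class CohortSpec:
    n_agents: int = 67
    mixture: tuple = DEFAULT_MIXTURE
    estimate_noise_sd: float = 0.05
    quantize: bool = True
    seed: int = 0
    # parameter sampling (documented package defaults, not task constraints)
    alpha_beta: tuple = (2.0, 5.0)
    weight_lognorm: tuple = (np.log(5.0), 0.5)
    bias_sd: float = 0.2
    # decay d ~ Beta(1.2, 30): mean ~0.04/trial. A conjunction instance is
    # decayed on ~26 of every 27 trials, so much larger decay rates erase
    # conjunction knowledge and make a mixed strategy inexpressible.
    decay_beta: tuple = (1.2, 30.0)

    def label_counts(self):
        """Exact per-family counts for ``n_agents`` (largest-remainder split)."""
        weights = np.array([w for _, w in self.mixture], float)
        shares = weights / weights.sum() * self.n_agents
        counts = np.floor(shares).astype(int)
        rem = self.n_agents - counts.sum()
        order = np.argsort(-(shares - counts))
        counts[order[:rem]] += 1
        return counts


def sample_params(spec: CohortSpec, model_spec: RLModelSpec, rng) -> RLParams:
    a, b = spec.alpha_beta
    mu, sd = spec.weight_lognorm
    w = lambda: float(rng.lognormal(mu, sd))
    return RLParams(
        alpha_rew=float(rng.beta(a, b)),
        alpha_unr=float(rng.beta(a, b)),
        d=float(rng.beta(*spec.decay_beta)) if model_spec.decay else 0.0,
        w_o=w(),
        w_f=np.array([w(), w(), w()])
        if model_spec.family == "feature"
        else w(),
        w_c=w(),
        bias=float(rng.normal(0.0, spec.bias_sd)),
    )


@dataclass
class CohortMember:
    session: SessionRecord
    true_spec: RLModelSpec
    true_params: RLParams
    agent_id: int


def generate_cohort(
    spec: CohortSpec, schedule: RewardSchedule, record_values: bool = False
) -> list:
    """Simulate a full cohort; returns members with ground-truth labels.

    Estimation bouts hold the agent's latent estimates corrupted by additive
    Gaussian noise (sd ``estimate_noise_sd``), clipped to [0, 1], then
    quantized to the 10 response levels when ``quantize`` is set.
    """
    rng = np.random.default_rng(spec.seed)
    counts = spec.label_counts()
    members = []
    aid = 0
    for (model_spec, _), count in zip(spec.mixture, counts):
        for _ in range(count):
            params = sample_params(spec, model_spec, rng)
            agent_seed = int(rng.integers(2**31 - 1))
            session = rl.simulate_agent(
                schedule, model_spec, params, agent_seed,
                record_values=record_values,
            )
            for bout in session.bouts:
                est = bout.estimates
                if spec.estimate_noise_sd > 0:
                    est = np.clip(
                        est + rng.normal(0, spec.estimate_noise_sd, est.shape),
                        0.0, 1.0,
                    )
                if spec.quantize:
                    est = task.quantize_estimates(est)
                bout.estimates = est
            members.append(CohortMember(session, model_spec, params, aid))
            aid += 1
    return members


def generate_nonlearner(schedule: RewardSchedule, seed: int) -> SessionRecord:
    """A random-choice agent (no learning, no reward sensitivity).

    Its accuracy is binomial around chance, so the 0.55 exclusion rule drops
    it with probability ~0.977 (the one-sided 2-sigma tail of n = 400).
    """
    rng = np.random.default_rng(seed)
    session = task.generate_session(schedule, seed)
    session.chosen_side = rng.integers(0, 2, session.n_trials)
    for bout in session.bouts:
        bout.estimates = task.quantize_estimates(rng.random(task.N_STIMULI))
    return session
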