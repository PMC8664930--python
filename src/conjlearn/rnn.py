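"""Excitatory/inhibitory recurrent rate network with reward-dependent
three-factor Hebbian plasticity.

Architecture
------------
A rate network of ``N`` recurrent units (4:1 excitatory:inhibitory) receives
63 sensory inputs — 9 feature-, 27 conjunction-, and 27 object-identity
encoding populations, of which exactly 7 are active for any stimulus — and
reads out a scalar reward-probability estimate through the excitatory units.
Dynamics follow the first-order Euler discretization

    x_t = (1 - a) x_{t-1} + a (W_rec r_{t-1} + W_in u_t + b + noise),
    r_t = max(x_t, 0),      z_t = w_out . r_t + b_out,

with a = dt / tau.  Dale's constraint is enforced by storing non-negative
recurrent magnitudes multiplied by a fixed +/-1 column sign; input and output
weights are clipped non-negative and only excitatory units reach the output.

Each unit belongs to one of eight populations: {Exc, Inh} x {rr, fr, rf, ff},
where the first subscript letter marks plastic (f) vs. rigid (r) sensory
input and the second marks plastic recurrent connections (ownership is
post-synaptic: a connection is plastic iff its target unit is typed plastic
on that pathway).

Plasticity
----------
During the reward window T_R = [1.75, 2] s a modulator D = +1 (reward) or -1
(no reward) gates a Hebbian eligibility built from low-pass-filtered pre- and
post-synaptic rates,

    F(pre, post) = c_pre rbar_pre + c_post rbar_post + c_corr rbar_pre rbar_post,

with one (c_pre, c_post, c_corr) triple per sensory->E / sensory->I block and
one per recurrent E/I -> E/I block.  The eligibility integrates D x F over
T_R; the weights relax toward it with time constant tau_W = 0.1 s, which is
short against the inter-trial gap, so the accumulated increment is applied to
the plastic connections between trials (and re-clipped at zero).

Meta-training
-------------
Adam-SGD minimizes the time-averaged squared output error plus an L2 rate
penalty over sessions of trials with uniformly random reward probabilities.
Gradients are truncated per trial: each trial's loss is differentiated
through its own 100-step unroll with the trial-start weights treated as
constants, and the dependence of those weights on the naive weights
(identity) and on the Hebbian coefficients (the accumulated eligibility
integrals, which are linear in the coefficients for fixed rates) is added
analytically.  Every ``probe_interval`` iterations the network is evaluated
on the experiment's schedule and the best checkpoint retained; training
stops when the probe mean-squared estimation error reaches threshold.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from .task import N_STIMULI, RewardSchedule, build_stimulus_space

GROUP_TYPES = ("rr", "fr", "rf", "ff")
N_SENSORY = 63


def _lowpass(x: np.ndarray, lp: float) -> np.ndarray:
    """First-order low-pass filter along axis 0 (zero initial state):
    y_t = y_{t-1} + lp (x_t - y_{t-1})."""
    from scipy.signal import lfilter

    x0 = x.copy()
    x0[0] = 0.0  # the filter state starts at zero before the first step
    return lfilter([lp], [1.0, -(1.0 - lp)], x0, axis=0)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass
class RNNConfig:
    n_rec: int = 120
    exc_frac: float = 0.8  # 4:1 E:I ratio
    dt: float = 0.02
    tau: float = 0.1
    sigma_rec: float = 0.01
    sigma_in: float = 0.01
    trial_length: float = 2.0
    stim_window: tuple = (0.5, 1.5)
    choice_window: tuple = (1.0, 1.5)
    reward_window: tuple = (1.75, 2.0)
    tau_lowpass: float = 0.1
    tau_w: float = 0.1
    # variant switches
    plastic_input: bool = True
    plastic_recurrent: bool = True
    feedforward: bool = False
    output_bias: bool = True

    def __post_init__(self):
        if self.feedforward:
            self.exc_frac = 1.0
            self.plastic_recurrent = False
        if self.n_rec % 4:
            raise ValueError("n_rec must be divisible by 4")

    @property
    def alpha(self) -> float:
        return self.dt / self.tau

    @property
    def n_steps(self) -> int:
        return int(round(self.trial_length / self.dt))

    @property
    def n_exc(self) -> int:
        return int(round(self.n_rec * self.exc_frac))

    @property
    def n_inh(self) -> int:
        return self.n_rec - self.n_exc

    def window_steps(self, window) -> np.ndarray:
        """Step indices (1-based into the trial) whose time falls in [a, b)."""
        t = np.arange(1, self.n_steps + 1) * self.dt
        return np.nonzero((t >= window[0]) & (t < window[1] + 1e-9))[0] + 1


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    lr_decay_every: int | None = None  # halve-style step decay, optional
    lr_decay_factor: float = 0.5
    grad_clip: float | None = 200.0  # global-norm clip; inactive in the
    # normal regime, a rail against rare exploding-gradient sessions
    lambda_r: float = 0.01
    trials_per_session: int = 270
    probe_interval: int = 50
    probe_mse_threshold: float = 0.02
    max_iterations: int = 2000
    probe_trials: int = 270


def encode_stimulus(object_id: int, space=None) -> np.ndarray:
    """63-length indicator: 3 features, 3 conjunctions, 1 object id (7 ones)."""
    space = space or build_stimulus_space()
    s = np.zeros(N_SENSORY)
    for f in space.feature_ids(object_id):
        s[f] = 1.0
    for c in space.conjunction_ids(object_id):
        s[9 + c] = 1.0
    s[36 + object_id] = 1.0
    return s


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------
class EIRNN:
    """Network parameters, masks, and dynamics.

    Parameters are the *naive* quantities adjusted by SGD; within-session
    Hebbian plasticity acts on copies (``W_in_cur``/``W_rec_cur``) that are
    reset to the naive values at the start of every session.
    """

    def __init__(self, config: RNNConfig, seed: int = 0):
        self.config = config
        self.space = build_stimulus_space()
        rng = np.random.default_rng(seed)
        N, NE = config.n_rec, config.n_exc
        self.is_exc = np.zeros(N, bool)
        self.is_exc[:NE] = True
        self.sign = np.where(self.is_exc, 1.0, -1.0)
        # balanced typing: each quarter of the E block and of the I block
        self.group_type = np.empty(N, dtype=object)
        for block, idx in (("Exc", np.arange(NE)), ("Inh", np.arange(NE, N))):
            if len(idx) == 0:
                continue
            per = len(idx) // 4
            for g, gt in enumerate(GROUP_TYPES):
                sel = idx[g * per : (g + 1) * per] if g < 3 else idx[3 * per :]
                self.group_type[sel] = gt
        # plasticity masks (post-synaptic ownership)
        in_flex = np.isin(self.group_type, ("fr", "ff"))
        rec_flex = np.isin(self.group_type, ("rf", "ff"))
        self.plastic_in = np.zeros((N, N_SENSORY), bool)
        self.plastic_rec = np.zeros((N, N), bool)
        if config.plastic_input:
            self.plastic_in[in_flex, :] = True
        if config.plastic_recurrent:
            self.plastic_rec[rec_flex, :] = True
        self.lesion_mask = np.zeros((N, N), bool)

        # --- naive (trainable) parameters ---
        self.W_in0 = rng.uniform(0.0, 0.2, (N, N_SENSORY))
        scale_e = 2.0 / N
        scale_i = 8.0 / N
        mag = rng.uniform(0.0, 1.0, (N, N))
        mag[:, self.is_exc] *= scale_e
        mag[:, ~self.is_exc] *= scale_i
        if config.feedforward:
            mag[:] = 0.0
        self.W_rec0 = mag
        self.w_out = np.where(self.is_exc, rng.uniform(0.0, 0.1, N), 0.0)
        self.b_rec = np.full(N, 0.1)
        self.b_out = 0.0
        self.x0 = rng.uniform(0.0, 0.1, N)
        # Hebbian coefficient triples: sensory->{E, I} and E/I -> E/I
        self.c_in = np.zeros((2, 3))  # [post E=0/I=1, (pre, post, corr)]
        self.c_in[:, 2] = 0.1
        self.c_rec = np.zeros((2, 2, 3))  # [pre E/I, post E/I, term]

        # cached step indices
        cfg = config
        self._stim_step_arr = cfg.window_steps(cfg.stim_window)
        self._choice_steps = cfg.window_steps(cfg.choice_window)
        self._reward_step_arr = cfg.window_steps(cfg.reward_window)
        self._pre_steps = cfg.window_steps((0.0, cfg.stim_window[0]))
        self._stim_vectors = np.stack(
            [encode_stimulus(o, self.space) for o in range(N_STIMULI)]
        )
        self.reset_session()

    # -- bookkeeping -----------------------------------------------------
    def group_indices(self, name: str) -> np.ndarray:
        """Unit indices of e.g. 'Exc_fr'; 'Inh_f*' matches fr and ff."""
        block, gt = name.split("_")
        exc = block.lower().startswith("e")
        sel = self.is_exc == exc
        if gt == "f*":
            sel &= np.isin(self.group_type, ("fr", "ff"))
        elif gt == "*f":
            sel &= np.isin(self.group_type, ("rf", "ff"))
        elif gt != "*":
            sel &= self.group_type == gt
        return np.nonzero(sel)[0]

    def reset_session(self):
        """Reset plastic weights to the naive values (start of a session)."""
        self.W_in_cur = self.W_in0.copy()
        rec = self.W_rec0.copy()
        rec[self.lesion_mask] = 0.0
        self.W_rec_cur = rec

    def _effective_rec(self) -> np.ndarray:
        return self.W_rec_cur * self.sign[None, :]

    def _expand_c_in(self, term: int) -> np.ndarray:
        return np.where(self.is_exc, self.c_in[0, term], self.c_in[1, term])

    def _expand_c_rec(self, term: int) -> np.ndarray:
        pre = (~self.is_exc).astype(int)[None, :]
        post = (~self.is_exc).astype(int)[:, None]
        return self.c_rec[pre, post, term]

    # -- dynamics --------------------------------------------------------
    def run_trial(
        self,
        object_id: int,
        rng,
        noise: bool = True,
        cache: bool = False,
    ) -> dict:
        """Forward one 2-second trial; returns output trajectory, the mean
        estimate over the choice window, eligibility integrals, and (when
        ``cache`` is set) the state trajectories needed for backprop."""
        cfg = self.config
        N, S, a = cfg.n_rec, N_SENSORY, cfg.alpha
        steps = cfg.n_steps
        dt = cfg.dt
        lp = dt / cfg.tau_lowpass
        W_eff = self._effective_rec()
        # inputs are state-independent: build the full u trajectory and its
        # low-pass filter and drive contribution up front
        if noise:
            us = np.sqrt(2 * cfg.tau * cfg.sigma_in**2) * rng.standard_normal(
                (steps + 1, S)
            )
            noise_rec = np.sqrt(2 * a * cfg.sigma_rec**2) * rng.standard_normal(
                (steps + 1, N)
            )
        else:
            us = np.zeros((steps + 1, S))
            noise_rec = 0.0
        us[self._stim_step_arr] += self._stim_vectors[object_id]
        drive = a * (us @ self.W_in_cur.T + self.b_rec) + noise_rec
        ubars = _lowpass(us, lp)

        x = self.x0.copy()
        xs = np.empty((steps + 1, N))
        rs = np.empty((steps + 1, N))
        rbars = np.empty((steps + 1, N))
        xs[0] = x
        rs[0] = np.maximum(x, 0.0)
        rbars[0] = 0.0
        r = rs[0]
        rbar = rbars[0]
        for t in range(1, steps + 1):
            x = (1 - a) * x + a * (W_eff @ r) + drive[t]
            r = np.maximum(x, 0.0)
            rbar = rbar + lp * (r - rbar)
            xs[t], rs[t], rbars[t] = x, r, rbar
        z = rs @ self.w_out + self.b_out
        z[0] = float(self.w_out @ rs[0] + self.b_out)
        tr = self._reward_step_arr
        rb, ub = rbars[tr], ubars[tr]
        out = {
            "z": z,
            "estimate": float(z[self._choice_steps].mean()),
            "Su": dt * ub.sum(axis=0),
            "Sr": dt * rb.sum(axis=0),
            "Sur": dt * (rb.T @ ub),
            "Srr": dt * (rb.T @ rb),
        }
        if cache:
            out.update(xs=xs, rs=rs, us=us)
        return out

    def hebbian_update(self, trial: dict, reward: int) -> dict:
        """Apply the reward-gated Hebbian increment accumulated in a trial.

        ``D = +1`` on rewarded trials, ``-1`` otherwise, multiplies the
        eligibility integrals.  Returns the applied increments (before
        clipping) for logging.
        """
        D = 1.0 if reward else -1.0
        dW_in = D * (
            self._expand_c_in(0)[:, None] * trial["Su"][None, :]
            + self._expand_c_in(1)[:, None] * trial["Sr"][:, None]
            + self._expand_c_in(2)[:, None] * trial["Sur"]
        )
        dW_rec = D * (
            self._expand_c_rec(0) * trial["Sr"][None, :]
            + self._expand_c_rec(1) * trial["Sr"][:, None]
            + self._expand_c_rec(2) * trial["Srr"]
        )
        self.W_in_cur[self.plastic_in] += dW_in[self.plastic_in]
        np.clip(self.W_in_cur, 0.0, None, out=self.W_in_cur)
        rec_mask = self.plastic_rec & ~self.lesion_mask
        self.W_rec_cur[rec_mask] += dW_rec[rec_mask]
        np.clip(self.W_rec_cur, 0.0, None, out=self.W_rec_cur)
        self.W_rec_cur[self.lesion_mask] = 0.0
        return {"dW_in": dW_in, "dW_rec": dW_rec}

    # -- losses ----------------------------------------------------------
    def trial_loss(self, trial: dict, target_p: float, lambda_r: float):
        """Masked time-averaged squared error plus rate penalty, with the
        output-side gradients (dL/dz per step, rate-penalty factor)."""
        cfg = self.config
        z = trial["z"]
        mask_steps = np.concatenate([self._pre_steps, self._choice_steps])
        targets = np.concatenate(
            [np.zeros(len(self._pre_steps)),
             np.full(len(self._choice_steps), target_p)]
        )
        err = z[mask_steps] - targets
        L = float(np.mean(err**2))
        dz = np.zeros_like(z)
        dz[mask_steps] = 2 * err / len(mask_steps)
        rs = trial["rs"]
        R = float(np.mean(rs[1:] ** 2))
        return L, R, dz

    def backward_trial(self, trial: dict, dz: np.ndarray, lambda_r: float):
        """BPTT through one cached trial (trial-start weights constant)."""
        cfg = self.config
        a = cfg.alpha
        steps = cfg.n_steps
        xs, rs, us = trial["xs"], trial["rs"], trial["us"]
        W_eff = self._effective_rec()
        W_eff_T = W_eff.T.copy()
        N = cfg.n_rec
        pen = 2 * lambda_r / (N * steps)
        # direct (non-recurrent) dL/dr contribution, all steps at once
        G = np.outer(dz, self.w_out) + pen * rs
        pos = xs > 0
        dxs = np.empty((steps + 1, N))
        dx_next = np.zeros(N)
        for t in range(steps, 0, -1):
            g_r = G[t] + a * (W_eff_T @ dx_next)
            dx_next = g_r * pos[t] + (1 - a) * dx_next
            dxs[t] = dx_next
        gx0 = (a * (W_eff_T @ dx_next)) * pos[0] + (1 - a) * dx_next
        dxs[0] = 0.0
        gW_eff = a * (dxs[1:].T @ rs[:-1])
        gW_in = a * (dxs[1:].T @ us[1:])
        gb = a * dxs[1:].sum(axis=0)
        gw_out = (dz[1:] @ rs[1:]) * self.is_exc
        gb_out = float(dz[1:].sum())
        gW_rec = gW_eff * self.sign[None, :]
        return {
            "W_in0": gW_in,
            "W_rec0": gW_rec,
            "w_out": gw_out,
            "b_rec": gb,
            "b_out": gb_out,
            "x0": gx0,
        }


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------
class _Adam:
    def __init__(self, shapes, lr, beta1, beta2, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _coef_grads(net: EIRNN, gW_in, gW_rec, cum):
    """Gradient of a trial loss w.r.t. the Hebbian triples through the
    accumulated (linear-in-c) weight increments of earlier trials."""
    g_c_in = np.zeros((2, 3))
    g_c_rec = np.zeros((2, 2, 3))
    for post, exc in ((0, True), (1, False)):
        rows = (net.is_exc == exc) & net.plastic_in[:, 0]
        if not rows.any():
            continue
        sub = gW_in[rows]
        g_c_in[post, 0] = sub.sum(axis=0) @ cum["Su"]
        g_c_in[post, 1] = sub.sum(axis=1) @ cum["Sr"][rows]
        g_c_in[post, 2] = float(np.sum(sub * cum["Sur"][rows]))
    rec_rows = net.plastic_rec.any(axis=1)
    for pre_i, pre_exc in ((0, True), (1, False)):
        cols = net.is_exc == pre_exc
        for post_i, post_exc in ((0, True), (1, False)):
            rows = (net.is_exc == post_exc) & rec_rows
            if not rows.any():
                continue
            sub = gW_rec[np.ix_(rows, cols)]
            g_c_rec[pre_i, post_i, 0] = sub.sum(axis=0) @ cum["Sr"][cols]
            g_c_rec[pre_i, post_i, 1] = sub.sum(axis=1) @ cum["Sr"][rows]
            g_c_rec[pre_i, post_i, 2] = float(
                np.sum(sub * cum["Srr"][np.ix_(rows, cols)])
            )
    return g_c_in, g_c_rec


def run_training_session(
    net: EIRNN,
    probs: np.ndarray,
    rng,
    train_cfg: TrainingConfig,
    collect_grads: bool = True,
):
    """One session: fresh plastic weights, ``trials_per_session`` trials with
    Bernoulli rewards, per-trial truncated gradients accumulated."""
    cfg = net.config
    net.reset_session()
    n_trials = train_cfg.trials_per_session
    lam = train_cfg.lambda_r
    stims = rng.integers(0, N_STIMULI, n_trials)
    grads = None
    cum = {
        "Su": np.zeros(N_SENSORY),
        "Sr": np.zeros(cfg.n_rec),
        "Sur": np.zeros((cfg.n_rec, N_SENSORY)),
        "Srr": np.zeros((cfg.n_rec, cfg.n_rec)),
    }
    g_c_in = np.zeros((2, 3))
    g_c_rec = np.zeros((2, 2, 3))
    total_loss = 0.0
    for n in range(n_trials):
        oid = int(stims[n])
        trial = net.run_trial(oid, rng, cache=collect_grads)
        reward = int(rng.random() < probs[oid])
        L, R, dz = net.trial_loss(trial, probs[oid], lam)
        total_loss += L + lam * R
        if collect_grads:
            g = net.backward_trial(trial, dz, lam)
            if grads is None:
                grads = g
            else:
                for k in g:
                    grads[k] = grads[k] + g[k]
            gi, gr = _coef_grads(net, g["W_in0"], g["W_rec0"], cum)
            g_c_in += gi
            g_c_rec += gr
        D = 1.0 if reward else -1.0
        cum["Su"] += D * trial["Su"]
        cum["Sr"] += D * trial["Sr"]
        cum["Sur"] += D * trial["Sur"]
        cum["Srr"] += D * trial["Srr"]
        net.hebbian_update(trial, reward)
    total_loss /= n_trials
    if collect_grads:
        for k in grads:
            grads[k] = grads[k] / n_trials
        grads["c_in"] = g_c_in / n_trials
        grads["c_rec"] = g_c_rec / n_trials
    return total_loss, grads


def probe_mse(
    net: EIRNN,
    schedule: RewardSchedule,
    seed: int,
    n_trials: int | None = None,
) -> float:
    """Estimation error on the experiment schedule: run a session with
    plasticity, then sweep all 27 stimuli with plasticity frozen and return
    the mean squared error of the estimates."""
    rng = np.random.default_rng(seed)
    train_cfg = TrainingConfig()
    n_trials = n_trials or train_cfg.probe_trials
    net.reset_session()
    stims = rng.integers(0, N_STIMULI, n_trials)
    for oid in stims:
        trial = net.run_trial(int(oid), rng)
        reward = int(rng.random() < schedule.p[oid])
        net.hebbian_update(trial, reward)
    est = frozen_estimates(net, rng)
    return float(np.mean((est - schedule.p) ** 2))


def frozen_estimates(net: EIRNN, rng, n_reps: int = 1) -> np.ndarray:
    """Estimates for all 27 stimuli with plasticity frozen."""
    est = np.zeros(N_STIMULI)
    for _ in range(n_reps):
        for oid in range(N_STIMULI):
            est[oid] += net.run_trial(oid, rng)["estimate"]
    return est / n_reps


@dataclass
class TrainingLog:
    iterations: list = field(default_factory=list)
    losses: list = field(default_factory=list)
    probe_iterations: list = field(default_factory=list)
    probe_mses: list = field(default_factory=list)

    @property
    def best_probe(self) -> float:
        return min(self.probe_mses) if self.probe_mses else float("inf")


_PARAM_KEYS = ("W_in0", "W_rec0", "w_out", "b_rec", "b_out", "x0", "c_in", "c_rec")


def _get_params(net: EIRNN) -> dict:
    return {k: getattr(net, k) for k in _PARAM_KEYS}


def _project(net: EIRNN):
    np.clip(net.W_in0, 0.0, None, out=net.W_in0)
    np.clip(net.W_rec0, 0.0, None, out=net.W_rec0)
    np.clip(net.w_out, 0.0, None, out=net.w_out)
    net.w_out[~net.is_exc] = 0.0
    if not net.config.output_bias:
        net.b_out = 0.0
    if net.config.feedforward:
        net.W_rec0[:] = 0.0


def train(
    config: RNNConfig,
    train_cfg: TrainingConfig,
    probe_schedule: RewardSchedule,
    seed: int = 0,
) -> tuple:
    """Meta-train one network; returns (trained net at best probe, log)."""
    net = EIRNN(config, seed=seed)
    rng = np.random.default_rng(seed + 1_000_003)
    params = _get_params(net)
    opt = _Adam(
        {k: np.shape(v) for k, v in params.items()},
        train_cfg.learning_rate, train_cfg.beta1, train_cfg.beta2,
    )
    log = TrainingLog()
    best_state = None
    for it in range(train_cfg.max_iterations):
        if train_cfg.lr_decay_every:
            opt.lr = train_cfg.learning_rate * (
                train_cfg.lr_decay_factor ** (it // train_cfg.lr_decay_every)
            )
        probs = rng.random(N_STIMULI)
        loss, grads = run_training_session(net, probs, rng, train_cfg)
        gnorm = math.sqrt(
            sum(float(np.sum(np.asarray(grads[k]) ** 2)) for k in _PARAM_KEYS)
        )
        if not (math.isfinite(loss) and math.isfinite(gnorm)):
            log.iterations.append(it)
            log.losses.append(float("nan"))
            continue  # skip the update; best checkpoint is retained anyway
        if train_cfg.grad_clip and gnorm > train_cfg.grad_clip:
            scale = train_cfg.grad_clip / gnorm
            grads = {k: np.asarray(v) * scale if k in _PARAM_KEYS else v
                     for k, v in grads.items()}
        # scalar b_out handled via a 0-d view
        vals = {k: np.asarray(getattr(net, k), dtype=float) for k in _PARAM_KEYS}
        opt.step(vals, {k: np.asarray(grads[k]) for k in _PARAM_KEYS})
        for k in _PARAM_KEYS:
            setattr(net, k, vals[k] if vals[k].ndim else float(vals[k]))
        _project(net)
        log.iterations.append(it)
        log.losses.append(loss)
        if (it + 1) % train_cfg.probe_interval == 0 or it == 0:
            mse = probe_mse(net, probe_schedule, seed=seed + 7,
                            n_trials=train_cfg.probe_trials)
            log.probe_iterations.append(it)
            log.probe_mses.append(mse)
            if mse == min(log.probe_mses):
                best_state = copy.deepcopy(_get_params(net))
            if mse <= train_cfg.probe_mse_threshold:
                break
    if best_state is not None:
        for k, v in best_state.items():
            setattr(net, k, copy.deepcopy(v))
    net.reset_session()
    return net, log


# ---------------------------------------------------------------------------
# simulation of the experiment, lesions, variants, choice layer
# ---------------------------------------------------------------------------
def save_checkpoint(net: EIRNN, path) -> None:
    """Portable npz archive of the naive parameters and architecture."""
    cfg = net.config
    np.savez(
        path,
        **{k: np.asarray(getattr(net, k)) for k in _PARAM_KEYS},
        n_rec=cfg.n_rec,
        plastic_input=cfg.plastic_input,
        plastic_recurrent=cfg.plastic_recurrent,
        feedforward=cfg.feedforward,
        group_type=np.array([str(g) for g in net.group_type]),
        lesion_mask=net.lesion_mask,
    )


def load_checkpoint(path, seed: int = 0) -> EIRNN:
    with np.load(path, allow_pickle=False) as data:
        cfg = RNNConfig(
            n_rec=int(data["n_rec"]),
            plastic_input=bool(data["plastic_input"]),
            plastic_recurrent=bool(data["plastic_recurrent"]),
            feedforward=bool(data["feedforward"]),
        )
        net = EIRNN(cfg, seed=seed)
        for k in _PARAM_KEYS:
            v = data[k]
            setattr(net, k, float(v) if v.ndim == 0 else v.copy())
        net.group_type = np.array(
            [str(g) for g in data["group_type"]], dtype=object
        )
        net.lesion_mask = data["lesion_mask"].copy()
    net.reset_session()
    return net


@dataclass
class ExperimentResult:
    stimuli: np.ndarray  # per-trial presented object id
    rewards: np.ndarray
    estimates: np.ndarray  # per-trial mean output during the choice window
    probe_trials: np.ndarray  # trial indices after which probes ran
    probe_estimates: np.ndarray  # (n_probes, 27)
    W_in_log: np.ndarray  # (n_logs, N, 63) plastic input weights (float32)
    W_rec_log: np.ndarray
    log_trials: np.ndarray


def simulate_experiment(
    net: EIRNN,
    schedule: RewardSchedule,
    seed: int,
    n_trials: int = 432,
    probe_every: int = 27,
    log_every: int = 4,
) -> ExperimentResult:
    """Simulate the task with SGD stopped: single-stimulus trials on the
    experiment schedule, Hebbian plasticity only.  Stimuli are drawn as
    shuffled blocks of all 27 so presentation counts stay balanced."""
    rng = np.random.default_rng(seed)
    net.reset_session()
    order = np.concatenate(
        [rng.permutation(N_STIMULI) for _ in range(-(-n_trials // N_STIMULI))]
    )[:n_trials]
    rewards = np.zeros(n_trials, int)
    estimates = np.zeros(n_trials)
    probe_trials, probe_estimates = [], []
    W_in_log, W_rec_log, log_trials = [], [], []
    for t in range(n_trials):
        oid = int(order[t])
        trial = net.run_trial(oid, rng)
        reward = int(rng.random() < schedule.p[oid])
        estimates[t] = trial["estimate"]
        rewards[t] = reward
        net.hebbian_update(trial, reward)
        if (t + 1) % log_every == 0 or t == 0:
            W_in_log.append(net.W_in_cur.astype(np.float32).copy())
            W_rec_log.append(net.W_rec_cur.astype(np.float32).copy())
            log_trials.append(t)
        if (t + 1) % probe_every == 0:
            probe_trials.append(t + 1)
            probe_estimates.append(frozen_estimates(net, rng))
    return ExperimentResult(
        stimuli=order,
        rewards=rewards,
        estimates=estimates,
        probe_trials=np.array(probe_trials),
        probe_estimates=np.array(probe_estimates),
        W_in_log=np.array(W_in_log),
        W_rec_log=np.array(W_rec_log),
        log_trials=np.array(log_trials),
    )


def lesion(net: EIRNN, source: str, target: str) -> EIRNN:
    """Zero and freeze the recurrent block from ``source`` to ``target``
    population groups (e.g. ``lesion(net, 'Inh_f*', 'Exc_f*')``)."""
    out = copy.deepcopy(net)
    src = out.group_indices(source)
    tgt = out.group_indices(target)
    if len(src) == 0 or len(tgt) == 0:
        raise ValueError(f"unknown or empty group: {source!r} or {target!r}")
    out.lesion_mask[np.ix_(tgt, src)] = True
    out.reset_session()
    return out


def build_variant(kind: str, n_rec: int = 120, **kwargs) -> RNNConfig:
    """Configs for the alternative architectures."""
    if kind == "no_plastic_input":
        return RNNConfig(n_rec=n_rec, plastic_input=False, **kwargs)
    if kind == "no_plastic_recurrent":
        return RNNConfig(n_rec=n_rec, plastic_recurrent=False, **kwargs)
    if kind == "ffnn":
        return RNNConfig(n_rec=n_rec, feedforward=True, **kwargs)
    raise ValueError(f"unknown variant {kind!r}")


def choice_layer(est1: float, est2: float, gain: float = 10.0,
                 bias: float = 0.0) -> float:
    """Probability of choosing stimulus 1 from two output estimates."""
    return float(1.0 / (1.0 + np.exp(-(gain * (est1 - est2) + bias))))


def generate_choice_session(
    net: EIRNN, schedule: RewardSchedule, seed: int, gain: float = 10.0,
    n_trials: int = 432,
):
    """A fit-able 432-trial choice session from a trained network.

    Each trial pairs two stimuli; both are evaluated with plasticity frozen,
    a choice is drawn through the logistic decision layer, and the chosen
    stimulus is then presented with plasticity and its reward feedback.
    """
    from .task import generate_session

    rng = np.random.default_rng(seed)
    session = generate_session(schedule, seed, n_trials=n_trials)
    net.reset_session()
    for t in range(session.n_trials):
        left, right = int(session.left[t]), int(session.right[t])
        est_l = net.run_trial(left, rng)["estimate"]
        est_r = net.run_trial(right, rng)["estimate"]
        p_left = choice_layer(est_l, est_r, gain=gain)
        side = 0 if rng.random() < p_left else 1
        session.chosen_side[t] = side
        chosen = left if side == 0 else right
        trial = net.run_trial(chosen, rng)
        reward = (
            session.reward_left[t] if side == 0 else session.reward_right[t]
        )
        net.hebbian_update(trial, int(reward))
    for bout in session.bouts:
        bout.estimates = frozen_estimates(net, rng)
    return session
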