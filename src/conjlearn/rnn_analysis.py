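"""Post-hoc analyses of trained networks.

* Representational similarity analysis: the Euclidean dissimilarity of a
  population group's response to the 27 stimuli during the choice window is
  regressed on the dissimilarities of reward probabilities under the
  informative-feature, informative-conjunction, and object value codes; the
  standardized weights, normalized to sum to one, quantify which code the
  population carries.
* PCA of excitatory population trajectories, with a silhouette statistic of
  reward-probability tertiles as a separation measure.
* Naive-weight statistics: group-wise mean connection strengths at the end
  of meta-training, with Wilcoxon contrasts across networks and Holm
  adjustment.
* Value-dependent weight-change GLMs: each plastic sensory weight's
  trajectory over the simulated session is regressed on the value trace of
  the attribute its source population encodes (a simple RL agent with both
  learning rates 0.05); recurrent plastic weights are regressed on trial
  number.
* Differential response of network-generated choice sessions, reusing the
  behavioral statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .behavior import differential_response
from .rnn import EIRNN, ExperimentResult
from .task import N_STIMULI, RewardSchedule

SENSORY_CLASSES = ("feature", "conjunction", "object")
GROUPS = (
    "Exc_rr", "Exc_fr", "Exc_rf", "Exc_ff",
    "Inh_rr", "Inh_fr", "Inh_rf", "Inh_ff",
)


def sensory_slice(cls: str) -> slice:
    return {"feature": slice(0, 9), "conjunction": slice(9, 36),
            "object": slice(36, 63)}[cls]


# ---------------------------------------------------------------------------
# responses
# ---------------------------------------------------------------------------
def stimulus_responses(net: EIRNN, rng, n_reps: int = 2) -> np.ndarray:
    """(27, N) mean rates during the choice window, plasticity frozen."""
    cfg = net.config
    steps = net._choice_steps
    out = np.zeros((N_STIMULI, cfg.n_rec))
    for _ in range(n_reps):
        for oid in range(N_STIMULI):
            trial = net.run_trial(oid, rng, cache=True)
            out[oid] += trial["rs"][steps].mean(axis=0)
    return out / n_reps


def value_code_vectors(schedule: RewardSchedule) -> dict:
    """Per-stimulus value under the three codes used as RSA predictors."""
    from .behavior import strategy_regressors

    regs = strategy_regressors(schedule)
    return {"feature": regs["feature"], "conjunction": regs["conjunction"],
            "object": regs["object"]}


@dataclass
class RSAResult:
    weights: dict  # group -> {code: normalized weight}
    raw: dict = field(default_factory=dict)
    degenerate: dict = field(default_factory=dict)


def rsa(
    responses: np.ndarray,
    schedule: RewardSchedule,
    net: EIRNN,
    groups=GROUPS,
    metric: str = "euclidean",
) -> RSAResult:
    """Normalized GLM weights of the three value-code dissimilarity matrices
    for predicting each population group's response dissimilarity."""
    codes = value_code_vectors(schedule)
    predictors = {
        name: pdist(vals[:, None], metric=metric)
        for name, vals in codes.items()
    }
    X = np.column_stack([predictors[c] for c in SENSORY_CLASSES])
    weights, raw, degenerate = {}, {}, {}
    for g in groups:
        idx = net.group_indices(g)
        if len(idx) == 0:
            continue
        d = pdist(responses[:, idx], metric=metric)
        if np.ptp(d) < 1e-12:
            degenerate[g] = True
            weights[g] = {c: np.nan for c in SENSORY_CLASSES}
            continue
        degenerate[g] = False
        res = sm.OLS(d, sm.add_constant(X)).fit()
        std = np.abs(res.params[1:]) * X.std(axis=0) / d.std()
        total = std.sum()
        weights[g] = {
            c: float(w / total) if total > 0 else 0.0
            for c, w in zip(SENSORY_CLASSES, std)
        }
        raw[g] = dict(zip(SENSORY_CLASSES, res.params[1:]))
    return RSAResult(weights=weights, raw=raw, degenerate=degenerate)


def dissimilarity_matrix(vectors: np.ndarray, metric="euclidean") -> np.ndarray:
    """Square-form dissimilarity matrix (zero diagonal, symmetric)."""
    return squareform(pdist(vectors, metric=metric))


# ---------------------------------------------------------------------------
# PCA trajectories
# ---------------------------------------------------------------------------
@dataclass
class PCAResult:
    components: np.ndarray
    explained_variance_ratio: np.ndarray
    projected: np.ndarray  # (27, n_steps, 3)
    silhouette: float


def pca_trajectories(
    net: EIRNN,
    rng,
    schedule: RewardSchedule,
    n_components: int = 3,
    phase: str = "late",
) -> PCAResult:
    """PCA of excitatory rates over the trial; trajectories of all 27
    stimuli projected on the top components, plus the silhouette of
    reward-probability tertiles of the choice-window response.

    ``phase`` selects the weight state probed: ``"early"`` resets the
    plastic weights to their naive values (session start, before any reward
    feedback), ``"late"`` uses the network's current (post-session) plastic
    weights, ``"full"`` pools responses from both states.
    """
    import copy as _copy

    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    if phase not in ("early", "late", "full"):
        raise ValueError(f"unknown phase {phase!r}")
    nets = []
    if phase in ("early", "full"):
        fresh = _copy.deepcopy(net)
        fresh.reset_session()
        nets.append(fresh)
    if phase in ("late", "full"):
        nets.append(net)

    exc = np.nonzero(net.is_exc)[0]
    trajs = []
    for source in nets:
        for oid in range(N_STIMULI):
            trial = source.run_trial(oid, rng, cache=True)
            trajs.append(trial["rs"][1:, exc])
    schedule_p = np.tile(schedule.p, len(nets))
    data = np.stack(trajs)  # (27 * n_states, steps, n_exc)
    flat = data.reshape(-1, data.shape[-1])
    pca = PCA(n_components=n_components)
    proj = pca.fit_transform(flat).reshape(data.shape[0], data.shape[1], -1)
    resp = data[:, net._choice_steps - 1].mean(axis=1)
    tertiles = np.digitize(
        schedule_p, np.quantile(schedule_p, [1 / 3, 2 / 3]), right=True
    )
    resp_proj = pca.transform(resp)
    if len(np.unique(tertiles)) < 2 or np.allclose(resp_proj.std(axis=0), 0):
        sil = np.nan
    else:
        sil = float(silhouette_score(resp_proj, tertiles))
    return PCAResult(
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        projected=proj,
        silhouette=sil,
    )


# ---------------------------------------------------------------------------
# naive-weight statistics
# ---------------------------------------------------------------------------
def naive_weight_means(net: EIRNN) -> dict:
    """Group-wise mean naive weights of one network."""
    w_in = {}
    for cls in SENSORY_CLASSES:
        for g in GROUPS:
            idx = net.group_indices(g)
            if len(idx):
                w_in[(cls, g)] = float(
                    net.W_in0[np.ix_(idx, range(*sensory_slice(cls).indices(63)))].mean()
                )
    w_rec = {}
    for src in GROUPS:
        si = net.group_indices(src)
        for tgt in GROUPS:
            ti = net.group_indices(tgt)
            if len(si) and len(ti):
                w_rec[(src, tgt)] = float(net.W_rec0[np.ix_(ti, si)].mean())
    w_out = {
        g: float(net.w_out[net.group_indices(g)].mean())
        for g in GROUPS[:4]
        if len(net.group_indices(g))
    }
    return {"W_in": w_in, "W_rec": w_rec, "w_out": w_out}


def naive_weight_contrasts(nets: list) -> dict:
    """Across-network contrasts of naive weights with Holm adjustment.

    Returns per-contrast (median difference, adjusted p, per-net values).
    """
    from statsmodels.stats.multitest import multipletests

    means = [naive_weight_means(n) for n in nets]

    def diff(fn):
        return np.array([fn(m) for m in means])

    inh_f = ("Inh_fr", "Inh_ff")
    exc_f = ("Exc_fr", "Exc_ff")

    def mean_over(m, cls, groups):
        return np.mean([m["W_in"][(cls, g)] for g in groups])

    contrasts = {
        "feature_to_inh_f_vs_other": diff(
            lambda m: mean_over(m, "feature", inh_f)
            - np.mean([m["W_in"][("feature", g)]
                       for g in GROUPS if g not in inh_f])
        ),
        "object_to_exc_f_vs_other": diff(
            lambda m: mean_over(m, "object", exc_f)
            - np.mean([m["W_in"][("object", g)]
                       for g in GROUPS if g not in exc_f])
        ),
        "cross_ei_vs_within": diff(
            lambda m: np.mean(
                [m["W_rec"][(s, t)] for s in GROUPS for t in GROUPS
                 if s[0] != t[0]]
            )
            - np.mean(
                [m["W_rec"][(s, t)] for s in GROUPS for t in GROUPS
                 if s[0] == t[0]]
            )
        ),
        # compare within the same pre-synaptic sign class (I -> E blocks),
        # so E/I magnitude scales cannot masquerade as structure
        "inh_f_to_exc_f_vs_other_inh_to_exc": diff(
            lambda m: np.mean([m["W_rec"][(s, t)] for s in inh_f for t in exc_f])
            - np.mean(
                [m["W_rec"][(s, t)]
                 for s in GROUPS if s.startswith("Inh")
                 for t in GROUPS if t.startswith("Exc")
                 if not (s in inh_f and t in exc_f)]
            )
        ),
        "exc_f_out_vs_exc_r_out": diff(
            lambda m: np.mean([m["w_out"][g] for g in exc_f])
            - np.mean([m["w_out"][g] for g in ("Exc_rr", "Exc_rf")])
        ),
    }
    out = {}
    pvals, keys = [], []
    for key, vals in contrasts.items():
        if np.allclose(vals, 0):
            p = 1.0
        else:
            p = stats.wilcoxon(vals)[1] if len(vals) >= 5 else np.nan
        out[key] = {"median": float(np.median(vals)), "values": vals, "p": p}
        if np.isfinite(p):
            pvals.append(p)
            keys.append(key)
    if pvals:
        adj = multipletests(pvals, method="holm")[1]
        for k, p in zip(keys, adj):
            out[k]["p_adjusted"] = float(p)
    return out


# ---------------------------------------------------------------------------
# value-dependent weight-change GLMs
# ---------------------------------------------------------------------------
def attribute_value_traces(
    result: ExperimentResult, schedule: RewardSchedule, alpha: float = 0.05
) -> np.ndarray:
    """(n_trials, 63) value trace of each sensory attribute, learned by a
    simple RL agent (both learning rates = ``alpha``) from the session's
    single-stimulus reward sequence."""
    space = schedule.space
    n = len(result.stimuli)
    V = np.full(63, 0.5)
    traces = np.zeros((n, 63))
    for t in range(n):
        oid = int(result.stimuli[t])
        rew = int(result.rewards[t])
        idx = [f for f in space.feature_ids(oid)]
        idx += [9 + c for c in space.conjunction_ids(oid)]
        idx += [36 + oid]
        for i in idx:
            V[i] = V[i] + alpha * (1 - V[i]) if rew else V[i] - alpha * V[i]
        traces[t] = V
    return traces


@dataclass
class WeightChangeRates:
    input_slopes: dict  # (sensory class, group) -> mean standardized slope
    input_slopes_informative: dict  # restricted to informative attributes
    recurrent_slopes: dict  # (src group, tgt group) -> mean slope vs trial
    flagged_nonplastic: int = 0


def weight_change_glm(
    result: ExperimentResult,
    schedule: RewardSchedule,
    net: EIRNN,
    alpha: float = 0.05,
) -> WeightChangeRates:
    """Regression slopes of plastic weights on attribute value traces
    (sensory inputs) and on trial number (recurrent connections)."""
    traces = attribute_value_traces(result, schedule, alpha)
    log_t = result.log_trials
    W_in_log = result.W_in_log  # (n_logs, N, 63)
    x_by_sensor = traces[log_t]  # (n_logs, 63)
    n_logs = len(log_t)

    def slope(y, x):
        y = np.asarray(y, np.float64)
        sx = x.std()
        sy = y.std()
        if sy < 1e-6:  # constant up to float32 logging resolution
            return 0.0, True
        if sx < 1e-12:
            return 0.0, False
        b = np.polyfit(x, y, 1)[0]
        return float(b * sx / sy), False

    input_slopes: dict = {}
    input_inf: dict = {}
    flagged = 0
    dim = schedule.informative_feature
    pair = schedule.informative_pair
    inf_feature_ids = set(range(3 * dim, 3 * dim + 3))
    inf_conj_ids = set(range(9 + 9 * pair, 9 + 9 * pair + 9))
    for cls in SENSORY_CLASSES:
        sl = sensory_slice(cls)
        for g in GROUPS:
            idx = net.group_indices(g)
            if not len(idx) or not net.plastic_in[idx[0], 0]:
                continue
            slopes_all, slopes_inf = [], []
            for s_i in range(*sl.indices(63)):
                x = x_by_sensor[:, s_i]
                for j in idx:
                    b, flat = slope(W_in_log[:, j, s_i], x)
                    if flat:
                        flagged += 1
                        continue
                    slopes_all.append(b)
                    if (cls == "feature" and s_i in inf_feature_ids) or (
                        cls == "conjunction" and s_i in inf_conj_ids
                    ):
                        slopes_inf.append(b)
                    elif cls == "object":
                        slopes_inf.append(b)
            if slopes_all:
                input_slopes[(cls, g)] = float(np.mean(slopes_all))
            if slopes_inf:
                input_inf[(cls, g)] = float(np.mean(slopes_inf))

    recurrent_slopes: dict = {}
    W_rec_log = result.W_rec_log
    tt = log_t.astype(float)
    for src in GROUPS:
        si = net.group_indices(src)
        for tgt in GROUPS:
            ti = net.group_indices(tgt)
            if not len(si) or not len(ti):
                continue
            if not net.plastic_rec[ti[0], 0]:
                continue
            block = W_rec_log[:, np.ix_(ti, si)[0], np.ix_(ti, si)[1]].reshape(
                n_logs, -1
            )
            y = block.mean(axis=1)
            if y.std() < 1e-15:
                continue
            recurrent_slopes[(src, tgt)] = float(np.polyfit(tt, y, 1)[0])
    return WeightChangeRates(
        input_slopes=input_slopes,
        input_slopes_informative=input_inf,
        recurrent_slopes=recurrent_slopes,
        flagged_nonplastic=flagged,
    )


# ---------------------------------------------------------------------------
# differential response of network choices
# ---------------------------------------------------------------------------
def rnn_differential_response(session, schedule: RewardSchedule):
    """The behavioral differential-response statistic applied to a
    network-generated choice session."""
    return differential_response(session, schedule)
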