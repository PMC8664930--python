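"""Maximum-likelihood fitting and comparison of the RL model family.

Models are fit per session by minimizing the negative log likelihood of the
observed choices with a derivative-free simplex search (Nelder-Mead) from
multiple random starting points, with learning/decay rates optimized on a
logit-transformed unconstrained scale.  Goodness of fit is summarized by AIC
and BIC and by their per-trial decompositions

    AIC_p(t) = -2 LL(t) + 2k / N
    BIC_p(t) = -2 LL(t) + k ln(N) / N

whose trial sums equal AIC and BIC exactly.  Per-trial likelihoods are
floored at 1e-10 so unbounded logistic weights cannot produce -inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .rl import RLModel, RLModelSpec, RLParams
from .task import SessionRecord

LIK_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# fast per-session likelihood
# ---------------------------------------------------------------------------
def _session_arrays(model: RLModel, session: SessionRecord):
    """Precomputed per-trial integer indices for the fast likelihood loop."""
    left = session.left
    right = session.right
    d, q = model.learned_dim, model.learned_pair
    data = {
        "side": session.chosen_side.tolist(),
        "r_cho": session.r_chosen.tolist(),
        "r_unc": session.r_unchosen.tolist(),
        "left": left.tolist(),
        "right": right.tolist(),
        "fl": model.feature_ids[left].tolist(),
        "fr": model.feature_ids[right].tolist(),
    }
    if d is not None:
        data["fdl"] = model.feature_ids[left, d].tolist()
        data["fdr"] = model.feature_ids[right, d].tolist()
    if q is not None:
        data["cl"] = model.conj_ids[left, q].tolist()
        data["cr"] = model.conj_ids[right, q].tolist()
    return data


def _negll_factory(model: RLModel, session: SessionRecord):
    """Return ``negll(params: RLParams) -> (total, per_trial_LL)``.

    A hand-specialized scalar loop: orders of magnitude faster than going
    through the object-oriented update path, which matters when hundreds of
    sessions are fit with simplex restarts.
    """
    spec = model.spec
    fam = spec.family
    dat = _session_arrays(model, session)
    n = session.n_trials
    full = spec.update_mode == "full"
    decay_used = {}
    if spec.decay:
        decay_used = {k: v.tolist() for k, v in model._used_indices().items()}
    log = math.log
    exp = math.exp
    floor_ll = log(LIK_FLOOR)

    def negll(params: RLParams):
        a_r, a_u, dk, bias = params.alpha_rew, params.alpha_unr, params.d, params.bias
        Vo = [0.5] * 27
        Vf = [0.5] * 9
        Vc = [0.5] * 27
        per_ll = [0.0] * n
        side = dat["side"]
        r_cho, r_unc = dat["r_cho"], dat["r_unc"]
        left, right = dat["left"], dat["right"]
        if fam == "feature":
            wf = np.broadcast_to(np.asarray(params.w_f, float), (3,)).tolist()
            fl, fr = dat["fl"], dat["fr"]
        elif fam == "object":
            wo = params.w_o
        elif fam.startswith("fc"):
            wf1, wc = float(np.asarray(params.w_f).reshape(-1)[0]), params.w_c
            fdl, fdr = dat["fdl"], dat["fdr"]
            cl, cr = dat["cl"], dat["cr"]
        else:
            wf1, wo = float(np.asarray(params.w_f).reshape(-1)[0]), params.w_o
            fdl, fdr = dat["fdl"], dat["fdr"]
        total = 0.0
        for t in range(n):
            l, r = left[t], right[t]
            # logit of choosing the left stimulus
            if fam == "object":
                z = wo * (Vo[l] - Vo[r]) + bias
            elif fam == "feature":
                a, b = fl[t], fr[t]
                z = (
                    wf[0] * (Vf[a[0]] - Vf[b[0]])
                    + wf[1] * (Vf[a[1]] - Vf[b[1]])
                    + wf[2] * (Vf[a[2]] - Vf[b[2]])
                    + bias
                )
            elif fam.startswith("fc"):
                z = (
                    wf1 * (Vf[fdl[t]] - Vf[fdr[t]])
                    + wc * (Vc[cl[t]] - Vc[cr[t]])
                    + bias
                )
            else:
                z = wf1 * (Vf[fdl[t]] - Vf[fdr[t]]) + wo * (Vo[l] - Vo[r]) + bias
            if z > 35.0:
                p_left = 1.0
            elif z < -35.0:
                p_left = 0.0
            else:
                p_left = 1.0 / (1.0 + exp(-z))
            p = p_left if side[t] == 0 else 1.0 - p_left
            ll = log(p) if p > LIK_FLOOR else floor_ll
            per_ll[t] = ll
            total -= ll
            # updates
            cho = l if side[t] == 0 else r
            unc = r if side[t] == 0 else l
            updates = [(cho, r_cho[t])]
            if full:
                updates.append((unc, r_unc[t]))
            touched_o, touched_f, touched_c = [], [], []
            for oid, rew in updates:
                if fam == "object":
                    v = Vo[oid]
                    Vo[oid] = v + a_r * (1 - v) if rew else v - a_u * v
                    touched_o.append(oid)
                elif fam == "feature":
                    fo = fl[t] if oid == l else fr[t]
                    for fidx in fo:
                        v = Vf[fidx]
                        Vf[fidx] = v + a_r * (1 - v) if rew else v - a_u * v
                        touched_f.append(fidx)
                elif fam.startswith("fc"):
                    fidx = fdl[t] if oid == l else fdr[t]
                    cidx = cl[t] if oid == l else cr[t]
                    v = Vf[fidx]
                    Vf[fidx] = v + a_r * (1 - v) if rew else v - a_u * v
                    v = Vc[cidx]
                    Vc[cidx] = v + a_r * (1 - v) if rew else v - a_u * v
                    touched_f.append(fidx)
                    touched_c.append(cidx)
                else:
                    fidx = fdl[t] if oid == l else fdr[t]
                    v = Vf[fidx]
                    Vf[fidx] = v + a_r * (1 - v) if rew else v - a_u * v
                    v = Vo[oid]
                    Vo[oid] = v + a_r * (1 - v) if rew else v - a_u * v
                    touched_f.append(fidx)
                    touched_o.append(oid)
            if dk > 0.0 and decay_used:
                for arr_name, idxs in decay_used.items():
                    arr, touched = {
                        "V_object": (Vo, touched_o),
                        "V_feature": (Vf, touched_f),
                        "V_conjunction": (Vc, touched_c),
                    }[arr_name]
                    for i in idxs:
                        if i not in touched:
                            arr[i] -= dk * (arr[i] - 0.5)
        return total, per_ll

    return negll


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------
def _unpack(theta: np.ndarray, spec: RLModelSpec) -> RLParams:
    names = spec.param_names
    kw = {}
    i = 0
    for name in names:
        if name in ("alpha_rew", "alpha_unr", "d"):
            kw[name] = float(special.expit(theta[i]))
            i += 1
        elif name == "w_f0":
            kw["w_f"] = np.array(theta[i : i + 3])
            i += 3
        elif name in ("w_f1", "w_f2"):
            continue
        elif name == "w_f":
            kw["w_f"] = float(theta[i])
            i += 1
        else:
            kw[name] = float(theta[i])
            i += 1
    return RLParams(**kw)


def _random_start(spec: RLModelSpec, rng) -> np.ndarray:
    theta = []
    for name in spec.param_names:
        if name in ("alpha_rew", "alpha_unr", "d"):
            theta.append(special.logit(rng.uniform(0.05, 0.6)))
        elif name in ("w_f0", "w_f1", "w_f2", "w_f", "w_o", "w_c"):
            theta.append(rng.uniform(0.5, 10.0))
        else:  # bias
            theta.append(rng.normal(0.0, 0.5))
    return np.array(theta)


@dataclass
class FitResult:
    spec: RLModelSpec
    params: RLParams
    negll: float
    per_trial_ll: np.ndarray
    k: int
    n_trials: int
    n_restarts: int
    converged: bool
    seed: int
    restart_neglls: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def aic(self) -> float:
        return 2 * self.k + 2 * self.negll

    @property
    def bic(self) -> float:
        return self.k * math.log(self.n_trials) + 2 * self.negll

    @property
    def aic_per_trial(self) -> np.ndarray:
        return -2 * self.per_trial_ll + 2 * self.k / self.n_trials

    @property
    def bic_per_trial(self) -> np.ndarray:
        return (
            -2 * self.per_trial_ll
            + self.k * math.log(self.n_trials) / self.n_trials
        )


def fit_model(
    session: SessionRecord,
    spec: RLModelSpec,
    n_restarts: int = 10,
    seed: int = 0,
    maxfev: int | None = None,
) -> FitResult:
    """Fit one model to one session's choices by maximum likelihood."""
    if np.any(session.chosen_side < 0):
        raise ValueError("session has unfilled choices")
    model = RLModel(spec, session.schedule)
    negll_fn = _negll_factory(model, session)
    rng = np.random.default_rng(seed)

    def objective(theta):
        total, _ = negll_fn(_unpack(theta, spec))
        return total if math.isfinite(total) else 1e12

    best = None
    restart_vals = []
    converged = False
    options = {"xatol": 1e-4, "fatol": 1e-4}
    if maxfev is not None:
        options["maxfev"] = maxfev
    for _ in range(n_restarts):
        theta0 = _random_start(spec, rng)
        res = optimize.minimize(
            objective, theta0, method="Nelder-Mead", options=options
        )
        restart_vals.append(res.fun)
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success) or converged
    if best is None or not math.isfinite(best.fun):
        raise RuntimeError("all restarts failed to produce a finite likelihood")
    params = _unpack(best.x, spec)
    total, per_ll = negll_fn(params)
    return FitResult(
        spec=spec,
        params=params,
        negll=total,
        per_trial_ll=np.asarray(per_ll),
        k=spec.n_params,
        n_trials=session.n_trials,
        n_restarts=n_restarts,
        converged=converged,
        seed=seed,
        restart_neglls=np.asarray(restart_vals),
    )


def session_negll(session: SessionRecord, spec: RLModelSpec, params: RLParams):
    """Negative log likelihood of a session at fixed parameters."""
    model = RLModel(spec, session.schedule)
    total, per_ll = _negll_factory(model, session)(params)
    return total, np.asarray(per_ll)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------
def running_average(x: np.ndarray, window: int = 20) -> np.ndarray:
    """Moving-box running average (shrinking box at the edges)."""
    x = np.asarray(x, float)
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


@dataclass
class ModelComparison:
    fits: list
    ranking_aic: list
    ranking_bic: list

    @property
    def best(self) -> FitResult:
        return self.ranking_aic[0]

    def per_trial_difference(self, key_a: str, key_b: str, window: int = 20):
        """Smoothed AIC_p(key_a) - AIC_p(key_b) curve."""
        by_key = {f.spec.key: f for f in self.fits}
        diff = by_key[key_a].aic_per_trial - by_key[key_b].aic_per_trial
        return running_average(diff, window)

    def per_trial_frame(self, window: int = 20):
        """Tidy per-trial goodness-of-fit curves (one column per model),
        smoothed with the running-average box; ready for ``to_csv``."""
        import pandas as pd

        data = {"trial": np.arange(1, self.fits[0].n_trials + 1)}
        for f in self.fits:
            data[f"aic_p_{f.spec.key}"] = running_average(
                f.aic_per_trial, window
            )
            data[f"bic_p_{f.spec.key}"] = running_average(
                f.bic_per_trial, window
            )
        return pd.DataFrame(data)


def compare_models(fits: list) -> ModelComparison:
    if len({f.n_trials for f in fits}) != 1:
        raise ValueError("fits must come from the same session")
    return ModelComparison(
        fits=list(fits),
        ranking_aic=sorted(fits, key=lambda f: f.aic),
        ranking_bic=sorted(fits, key=lambda f: f.bic),
    )


# ---------------------------------------------------------------------------
# participant exclusion
# ---------------------------------------------------------------------------
EXCLUSION_SKIP = 32
EXCLUSION_WINDOW = 400
EXCLUSION_THRESHOLD = 0.5 + 2 * math.sqrt(0.25 / EXCLUSION_WINDOW)  # = 0.55


def exclusion_filter(session: SessionRecord) -> bool:
    """Keep/drop decision: True (keep) if mean accuracy over the 400 trials
    after the first 32 reaches 0.5 + 2*sem = 0.55."""
    if session.n_trials < EXCLUSION_SKIP + EXCLUSION_WINDOW:
        raise ValueError("session too short for the exclusion rule")
    acc = session.better_chosen()[EXCLUSION_SKIP : EXCLUSION_SKIP + EXCLUSION_WINDOW]
    return float(np.mean(acc)) >= EXCLUSION_THRESHOLD
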