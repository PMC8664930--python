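"""Strategy decomposition of reward-probability estimates and choice sequences.

Three complementary analyses:

* **Strategy GLMs** — separate linear regressions of the 27 per-stimulus
  estimates of a bout on the predictions of one strategy each (object,
  feature, mixed feature+conjunction), yielding an R-squared time course, and
  a single stepwise GLM (forward entry, backward removal) over three
  regressors (informative-feature
  value, informative-conjunction value, object value) whose standardized
  coefficients, normalized to sum to one over the entered terms, quantify the
  adopted strategy mix.

* **Exponential time-course fits** — y(t) = y_ss - (y_ss - y0) exp(-t / tau)
  fit to a weight trajectory, giving the time constant tau (in trials) at
  which a strategy weight approaches its asymptote.

* **Differential response** — a model-free statistic: the difference between
  the conditional probability of selecting a carrier of an attribute of the
  previously chosen stimulus after reward vs. after no reward.  A carrier
  shares exactly the tracked attribute with the previous choice; its
  on-screen alternative shares no feature with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize

from .strategies import predict_all
from .task import DIM_PAIRS, N_STIMULI, RewardSchedule, SessionRecord

STEPWISE_ALPHA = 0.05  # forward-entry F-test level
STEPWISE_ALPHA_REMOVE = 0.10  # backward-removal level


# ---------------------------------------------------------------------------
# strategy GLMs
# ---------------------------------------------------------------------------
@dataclass
class StrategyWeights:
    weights: dict  # regressor -> normalized weight in [0, 1]
    included: dict  # regressor -> bool (stepwise entry)
    r2: float
    r2_per_model: dict = field(default_factory=dict)
    delta_r2_object: float = float("nan")
    degenerate: bool = False


def strategy_regressors(schedule: RewardSchedule) -> dict:
    """The three stepwise regressors, each a 27-vector over stimuli."""
    space = schedule.space
    dim = schedule.informative_feature
    pair = schedule.informative_pair
    fvals = schedule.feature_marginals[dim]
    cmat = schedule.conjunction_marginals.reshape(-1)
    feat = np.array([fvals[space.instances(o)[dim]] for o in range(N_STIMULI)])
    a, b = DIM_PAIRS[pair]
    conj = np.array(
        [cmat[3 * space.instances(o)[a] + space.instances(o)[b]] for o in range(N_STIMULI)]
    )
    return {"feature": feat, "conjunction": conj, "object": schedule.p.copy()}


def fit_strategy_glms(estimates: np.ndarray, schedule: RewardSchedule) -> dict:
    """R-squared of three separate GLMs (object / feature / mixed F+C predictions
    plus intercept) for one bout's 27 estimates."""
    y = np.asarray(estimates, float)
    if np.ptp(y) < 1e-12:
        return {"object": np.nan, "feature": np.nan, "mixed_fc": np.nan,
                "degenerate": True}
    out = {"degenerate": False}
    for strat in ("object", "feature", "mixed_fc"):
        x = predict_all(schedule, strat).predicted
        res = sm.OLS(y, sm.add_constant(x)).fit()
        out[strat] = float(res.rsquared)
    return out


def _std_coefs(res, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    sx = X.std(axis=0, ddof=0)
    sy = y.std(ddof=0)
    return res.params[1:] * sx / sy


def stepwise_strategy_glm(
    estimates: np.ndarray, schedule: RewardSchedule, alpha: float = STEPWISE_ALPHA
) -> StrategyWeights:
    """Forward-stepwise GLM of one bout's estimates on the three strategy
    regressors; returns normalized standardized weights over entered terms
    and the R-squared gain from adding the object regressor last."""
    y = np.asarray(estimates, float)
    regs = strategy_regressors(schedule)
    names = list(regs)
    if np.ptp(y) < 1e-12:
        return StrategyWeights(
            weights={n: 0.0 for n in names},
            included={n: False for n in names},
            r2=np.nan,
            degenerate=True,
        )
    X_full = np.column_stack([regs[n] for n in names])
    cond = np.linalg.cond(np.column_stack([np.ones(len(y)), X_full]))
    entered: list = []
    remaining = list(names)
    alpha_remove = max(alpha, STEPWISE_ALPHA_REMOVE)
    for _ in range(10):  # forward entry + backward pruning until stable
        changed = False
        best = None
        for name in remaining:
            cols = entered + [name]
            X = sm.add_constant(np.column_stack([regs[c] for c in cols]))
            res = sm.OLS(y, X).fit()
            pval = res.pvalues[-1]
            if np.isfinite(pval) and (best is None or pval < best[0]):
                best = (pval, name)
        if best is not None and best[0] < alpha:
            entered.append(best[1])
            remaining.remove(best[1])
            changed = True
        # backward removal of terms that lost significance
        while len(entered) > 1:
            X = sm.add_constant(np.column_stack([regs[c] for c in entered]))
            pvals = sm.OLS(y, X).fit().pvalues[1:]
            pvals = np.where(np.isfinite(pvals), pvals, 1.0)
            worst = int(np.argmax(pvals))
            if pvals[worst] < alpha_remove:
                break
            remaining.append(entered.pop(worst))
            changed = True
        if entered:
            X = sm.add_constant(np.column_stack([regs[c] for c in entered]))
            if sm.OLS(y, X).fit().rsquared > 1 - 1e-10:
                break  # numerically perfect fit; further F-tests are 0/0
        if not changed:
            break
    weights = {n: 0.0 for n in names}
    r2 = 0.0
    if entered:
        X = np.column_stack([regs[c] for c in entered])
        res = sm.OLS(y, sm.add_constant(X)).fit()
        r2 = float(res.rsquared)
        std = np.abs(_std_coefs(res, X, y))
        total = std.sum()
        if total > 0:
            for name, w in zip(entered, std / total):
                weights[name] = float(w)
    # R2 gain of the object regressor beyond feature + conjunction
    X_fc = sm.add_constant(np.column_stack([regs["feature"], regs["conjunction"]]))
    r2_fc = sm.OLS(y, X_fc).fit().rsquared
    X_fco = sm.add_constant(X_full)
    r2_fco = sm.OLS(y, X_fco).fit().rsquared
    sw = StrategyWeights(
        weights=weights,
        included={n: n in entered for n in names},
        r2=r2,
        delta_r2_object=float(r2_fco - r2_fc),
    )
    sw.condition_number = float(cond)
    return sw


def coefficient_timecourse(estimate_series, schedule: RewardSchedule):
    """Unnormalized standardized coefficients of the three strategy
    regressors (full GLM, no selection) per time point.

    For time-constant comparisons of simulated learners this is preferable
    to the share-normalized stepwise weights: shares sum to one, so the
    dominant strategy's share *falls* as later strategies enter, making its
    rise time unidentifiable by construction.
    """
    regs = strategy_regressors(schedule)
    names = ("feature", "conjunction", "object")
    X = np.column_stack([regs[n] for n in names])
    sx = X.std(axis=0)
    out = {n: [] for n in names}
    for y in estimate_series:
        y = np.asarray(y, float)
        sy = max(y.std(), 1e-9)
        res = sm.OLS(y, sm.add_constant(X)).fit()
        std = res.params[1:] * sx / sy
        for n, b in zip(names, std):
            out[n].append(float(b))
    return {n: np.asarray(v) for n, v in out.items()}


#: sampling grid for latent-estimate trajectories: dense early (the feature
#: transient spans the first ~25 trials for slow learners), then every 27
TRAJECTORY_SAMPLE_TRIALS = np.array(
    [5, 10, 15, 20, 27, 40, 54, 81, 108, 135, 162, 189, 216, 243,
     270, 297, 324, 351, 378, 405, 432]
)


def strategy_weight_timecourse(bout_estimates, schedule: RewardSchedule):
    """Stepwise weights per bout.

    Parameters
    ----------
    bout_estimates : sequence of (27,) arrays, one per estimation bout.

    Returns
    -------
    dict of regressor -> array of per-bout normalized weights.
    """
    names = ("feature", "conjunction", "object")
    out = {n: [] for n in names}
    for est in bout_estimates:
        sw = stepwise_strategy_glm(est, schedule)
        for n in names:
            out[n].append(sw.weights[n])
    return {n: np.asarray(v) for n, v in out.items()}


# ---------------------------------------------------------------------------
# exponential time-course fit
# ---------------------------------------------------------------------------
@dataclass
class TimeCourseFit:
    y0: float
    y_ss: float
    tau: float
    residual: float
    degenerate: bool = False


def fit_exponential_timecourse(
    t: np.ndarray, y: np.ndarray, t_session: float = 432.0
) -> TimeCourseFit:
    """Least-squares fit of ``y(t) = y_ss - (y_ss - y0) exp(-t/tau)``.

    ``tau`` is bounded to (0, 10 * t_session].  A constant trajectory leaves
    tau unidentifiable and is flagged degenerate.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if len(t) < 4:
        raise ValueError("need at least 4 time points")
    if np.ptp(y) < 1e-10:
        return TimeCourseFit(y0=y[0], y_ss=y[0], tau=np.nan, residual=0.0,
                             degenerate=True)

    def f(tt, y0, yss, tau):
        return yss - (yss - y0) * np.exp(-tt / tau)

    lo, hi = float(y.min()), float(y.max())
    span = max(hi - lo, 1e-6)
    best = None
    for tau0 in (t_session / 20, t_session / 5, t_session):
        try:
            popt, _ = optimize.curve_fit(
                f,
                t,
                y,
                p0=[y[0], y[-1], tau0],
                bounds=([lo - 2 * span, lo - 2 * span, 1e-6],
                        [hi + 2 * span, hi + 2 * span, 10 * t_session]),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        resid = float(np.sum((f(t, *popt) - y) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        return TimeCourseFit(y0=np.nan, y_ss=np.nan, tau=np.nan,
                             residual=np.inf, degenerate=True)
    (y0, yss, tau), resid = best
    return TimeCourseFit(y0=float(y0), y_ss=float(yss), tau=float(tau),
                         residual=resid)


# ---------------------------------------------------------------------------
# group-level statistics (utilities for cohort summaries)
# ---------------------------------------------------------------------------
def signrank(values, mu: float = 0.0):
    """Wilcoxon signed-rank test of median ``mu``; returns (stat, p)."""
    from scipy import stats as _stats

    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    stat, p = _stats.wilcoxon(values - mu)
    return float(stat), float(p)


def cohens_d(values, mu: float = 0.0) -> float:
    """One-sample effect size (mean - mu) / sd."""
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    sd = values.std(ddof=1)
    return float((values.mean() - mu) / sd) if sd > 0 else np.nan


# ---------------------------------------------------------------------------
# differential response
# ---------------------------------------------------------------------------
@dataclass
class DifferentialResponse:
    informative_feature: float
    noninformative_features: float
    informative_conjunction: float
    noninformative_conjunctions: float
    per_attribute: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def defined(self, name: str) -> bool:
        return np.isfinite(self.per_attribute.get(name, np.nan))


def _attribute_carrier(space, stim, prev, kind, idx) -> bool:
    """Does ``stim`` carry exactly the tracked attribute of ``prev``?

    Feature kind: shares the tracked dimension's instance and no other
    feature.  Conjunction kind: shares both dimensions of the tracked pair
    and not the third.
    """
    s, p = space.instances(stim), space.instances(prev)
    if kind == "feature":
        return s[idx] == p[idx] and all(
            s[d] != p[d] for d in range(3) if d != idx
        )
    a, b = DIM_PAIRS[idx]
    c = ({0, 1, 2} - {a, b}).pop()
    return s[a] == p[a] and s[b] == p[b] and s[c] != p[c]


def differential_response(
    session: SessionRecord, schedule: RewardSchedule | None = None
) -> DifferentialResponse:
    """Reward-conditional re-selection statistic per tracked attribute.

    For each feature dimension and each conjunction pair: over trials where
    exactly one on-screen stimulus is a carrier of the previous choice's
    tracked attribute and the other shares no feature with the previous
    choice, compute P(select carrier | previous reward) - P(select carrier |
    previous no reward).  Cells without trials in one condition are NaN.
    """
    if session.n_trials < 2:
        raise ValueError("need at least 2 trials")
    schedule = schedule or session.schedule
    space = schedule.space
    chosen = session.chosen
    r_cho = session.r_chosen
    attrs = [("feature", d) for d in range(3)] + [
        ("conjunction", p) for p in range(3)
    ]
    sel: dict = {a: {0: [], 1: []} for a in attrs}
    for t in range(1, session.n_trials):
        prev, rew = chosen[t - 1], int(r_cho[t - 1])
        pair = (session.left[t], session.right[t])
        for kind, idx in attrs:
            carriers = [
                s for s in pair if _attribute_carrier(space, s, prev, kind, idx)
            ]
            if len(carriers) != 1:
                continue
            other = pair[1] if carriers[0] == pair[0] else pair[0]
            if space.share_any_feature(other, prev):
                continue
            sel[(kind, idx)][rew].append(int(chosen[t] == carriers[0]))

    per: dict = {}
    counts: dict = {}
    for a in attrs:
        n1, n0 = len(sel[a][1]), len(sel[a][0])
        counts[a] = (n1, n0)
        if n1 == 0 or n0 == 0:
            per[a] = np.nan
        else:
            per[a] = float(np.mean(sel[a][1]) - np.mean(sel[a][0]))

    inf_dim = schedule.informative_feature
    inf_pair = schedule.informative_pair
    noninf_dims = [d for d in range(3) if d != inf_dim]
    noninf_pairs = [p for p in range(3) if p != inf_pair]

    def _mean(keys):
        vals = [per[k] for k in keys if np.isfinite(per[k])]
        return float(np.mean(vals)) if vals else np.nan

    return DifferentialResponse(
        informative_feature=per[("feature", inf_dim)],
        noninformative_features=_mean([("feature", d) for d in noninf_dims]),
        informative_conjunction=per[("conjunction", inf_pair)],
        noninformative_conjunctions=_mean(
            [("conjunction", p) for p in noninf_pairs]
        ),
        per_attribute={f"{k}_{i}": v for (k, i), v in per.items()},
        counts={f"{k}_{i}": v for (k, i), v in counts.items()},
    )
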