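#!/usr/bin/env python
"""Train and analyze a cohort of E/I networks (the long-running study).

Runs the network suite at cohort scale: trains ``--n-nets`` networks,
simulates the experiment with each, and reports the cohort-level
properties — probe-MSE threshold attainment, end-of-session
estimate/probability Spearman correlation, strategy time-constant ordering
(tau feature < tau conjunction), the inhibitory/excitatory RSA opponency,
and the lesion double dissociation — as majority-of-nets statistics.

Expect hours at full scale; use ``--n-rec 40 --iterations 450
--trials-per-session 120`` for a reduced-scale pass.

    python scripts/rnn_cohort_study.py --n-nets 10 --seed 0 --out results/rnn_cohort.json
"""

from __future__ import annotations

import argparse
import json
import time
from pathlib import Path

import numpy as np
from scipy import stats

from conjlearn import behavior, rnn, rnn_analysis, task


def analyze_net(net, sched, seed):
    out = {}
    res = rnn.simulate_experiment(net, sched, seed=seed, n_trials=432)
    fe = res.probe_estimates[-1]
    out["spearman"] = float(stats.spearmanr(fe, sched.p)[0])
    w = behavior.coefficient_timecourse(list(res.probe_estimates), sched)
    tpts = res.probe_trials.astype(float)
    out["tau_feature"] = behavior.fit_exponential_timecourse(
        tpts, w["feature"]
    ).tau
    out["tau_conjunction"] = behavior.fit_exponential_timecourse(
        tpts, w["conjunction"]
    ).tau
    rng = np.random.default_rng(seed + 1)
    resp = rnn_analysis.stimulus_responses(net, rng, n_reps=2)
    rsa = rnn_analysis.rsa(resp, sched, net).weights
    out["rsa_feature_inh_minus_exc"] = float(
        np.mean([rsa["Inh_fr"]["feature"], rsa["Inh_ff"]["feature"]])
        - np.mean([rsa["Exc_fr"]["feature"], rsa["Exc_ff"]["feature"]])
    )
    out["rsa_object_exc_minus_inh"] = float(
        np.mean([rsa["Exc_fr"]["object"], rsa["Exc_ff"]["object"]])
        - np.mean([rsa["Inh_fr"]["object"], rsa["Inh_ff"]["object"]])
    )
    for label, src, tgt in (
        ("lesion_inh_to_exc", "Inh_f*", "Exc_f*"),
        ("lesion_exc_to_inh", "Exc_f*", "Inh_f*"),
    ):
        cut = rnn.lesion(net, src, tgt)
        res_l = rnn.simulate_experiment(cut, sched, seed=seed, n_trials=432)
        sw = behavior.stepwise_strategy_glm(res_l.probe_estimates[-1], sched)
        out[label] = sw.weights
    return out


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-nets", type=int, default=10)
    ap.add_argument("--n-rec", type=int, default=120)
    ap.add_argument("--iterations", type=int, default=2000)
    ap.add_argument("--trials-per-session", type=int, default=270)
    ap.add_argument("--learning-rate", type=float, default=1e-3)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/rnn_cohort.json"))
    args = ap.parse_args()

    sched = task.make_default_schedule()
    cfg = rnn.RNNConfig(n_rec=args.n_rec)
    tcfg = rnn.TrainingConfig(
        trials_per_session=args.trials_per_session,
        max_iterations=args.iterations,
        learning_rate=args.learning_rate,
        probe_interval=25,
        probe_trials=432,
        probe_mse_threshold=0.02,
    )
    nets = []
    for k in range(args.n_nets):
        t0 = time.time()
        net, log = rnn.train(cfg, tcfg, sched, seed=args.seed + k)
        rec = {"seed": args.seed + k, "best_probe_mse": log.best_probe,
               "iterations": len(log.losses),
               "train_seconds": round(time.time() - t0, 1)}
        rec.update(analyze_net(net, sched, seed=10_000 + k))
        nets.append(rec)
        print(json.dumps(rec, default=float), flush=True)

    def frac(fn):
        vals = [fn(n) for n in nets]
        return float(np.mean([v for v in vals if v is not None]))

    summary = {
        "n_nets": args.n_nets,
        "frac_probe_threshold": frac(
            lambda n: n["best_probe_mse"] <= tcfg.probe_mse_threshold
        ),
        "frac_spearman_gt_0.5": frac(lambda n: n["spearman"] > 0.5),
        "frac_tau_feature_lt_conjunction": frac(
            lambda n: n["tau_feature"] < n["tau_conjunction"]
        ),
        "median_tau_feature": float(np.median([n["tau_feature"] for n in nets])),
        "median_tau_conjunction": float(
            np.median([n["tau_conjunction"] for n in nets])
        ),
        "frac_rsa_feature_opponency": frac(
            lambda n: n["rsa_feature_inh_minus_exc"] > 0
        ),
        "frac_rsa_object_opponency": frac(
            lambda n: n["rsa_object_exc_minus_inh"] > 0
        ),
        "frac_lesion_object_dominant": frac(
            lambda n: n["lesion_inh_to_exc"]["object"]
            > n["lesion_inh_to_exc"]["feature"]
            + n["lesion_inh_to_exc"]["conjunction"]
        ),
        "frac_reverse_lesion_fc_preserved": frac(
            lambda n: n["lesion_exc_to_inh"]["feature"]
            + n["lesion_exc_to_inh"]["conjunction"]
            > n["lesion_exc_to_inh"]["object"]
        ),
    }
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps({"nets": nets, "summary": summary},
                                   indent=2, default=float))
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
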