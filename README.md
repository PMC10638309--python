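# selstop

Analysis toolkit for **response-selective stop-signal tasks** — experiments
in which a bimanual response must be *partially* cancelled: one hand stops
when a selective stop signal appears, the other continues. The package is
aimed at researchers in motor control and response inhibition who want to
model such tasks and analyse the accompanying surface EMG.

It provides, as one tested pipeline:

* **Task design** — trial schedules (dual-go / left-stop / right-stop,
  proactive cueing) and the 1-up/1-down SSD staircase that tracks 50% stop
  success.
* **The SIS race model** ("simultaneously inhibit and start") — on a stop
  trial the stop signal concurrently launches a *dual-stop* runner that
  races to cancel the bimanual response and a *selective go* runner that
  produces the continuing hand's response. Runner finish times are
  ex-Gaussian, T ~ N(μ, σ) + Exp(τ), summarized by the running time μ + τ.
  Trial simulation, the exact per-trial likelihood over stimulus × response
  categories (with go/stop trigger failures and wrong-hand errors), and the
  stop-wins probability P(SSD + T_stop < T_go) in closed form.
* **Hierarchical Bayesian fitting** — DE-MCMC (crossover) sampling of
  subject-level parameters under truncated-Normal group distributions, four
  model variants that fix or free each runner across reactive/proactive
  conditions, BPIC model comparison (BPIC = D̄ + 2p_D), and draw-wise
  running-time contrasts with 95% credible intervals.
* **EMG pipeline** — zero-phase 20–500 Hz Butterworth filtering, 10 Hz
  envelopes, single-threshold burst detection (baseline mean + 3 SD, 20 ms
  merge rule), RT-generating-burst and partial-burst classification under
  four timing/amplitude constraints, and **CancelTime** (partial-burst peak
  latency from the stop signal) — plus the censoring simulation showing why
  CancelTime is down-biased: a partial burst is only detectable when the
  stop runner beats the go runner by a 90–115 ms margin.
* **Synthetic data** — full studies (behaviour tables, latent race outcomes,
  raw two-channel EMG with planted-burst ground truth) so every stage is
  testable without any recording.

## Worked example

```python
import numpy as np
from selstop import (CensoringWindow, censoring_bias_sim, fit_hierarchical,
                     posterior_contrasts)
from selstop.sis import staircase_stop_run
from selstop.synth import (DesignConfig, default_group_truth,
                           generate_behaviour, sample_group)

# a synthetic cohort at the study's scale
cohort = sample_group(default_group_truth(), n_subjects=8, seed=11)
observed, latent, staircase = generate_behaviour(
    cohort, DesignConfig(n_trials_per_condition=288), seed=12)

print(round(staircase["stop_success"].mean(), 3))
# 0.516            <- the SSD staircase tracks ~50% stop success

res = censoring_bias_sim(cohort[0], CensoringWindow(), n=60_000,
                         rng=np.random.default_rng(5))
print({c: round(v["bias_ms"], 1) for c, v in res.items()})
# {'reactive': -2.7, 'proactive': -3.2}
#   <- the margin-censored mean stop finish is *faster* than the true mean
#      in both conditions: the CancelTime selection artifact

fit = fit_hierarchical(observed[["participant", "condition", "trial",
                                 "stimulus", "ssd_ms", "response", "rt_ms"]],
                       variant=1, seed=1)
res = posterior_contrasts(fit, [("dual_go", "proactive", +1),
                                ("dual_go", "reactive", -1)])
print(f"{res['median']:.1f} ms {res['ci95']}")
# 43.7 ms (38.9, 48.7)
#   <- the individual-level proactive-slowing contrast; this cohort's
#      realized mean slowing is 45.7 ms (drawn around the +30 ms hyper-mean
#      with 30 ms between-subject SD), squarely inside the interval
```

(The fit takes a few minutes on one CPU; numbers vary slightly with seeds.)

A command-line interface mirrors the library:

```bash
selstop simulate-design --condition proactive --n-trials 576 --seed 1 --out sched.csv
selstop synth --subjects 8 --trials 576 --seed 1 --out-dir study/
selstop fit --data study/behaviour.csv --variant 1 --seed 1 --out fit_v1.npz
selstop compare --fits fit_v1.npz --fits fit_v5.npz
selstop contrasts --fit fit_v1.npz --runner dual_go
```

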