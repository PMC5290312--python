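# circinfer

Circular-inference modelling of graded confidence in the Fisher task — a
beads-task variant used in computational psychiatry to measure how people
combine prior information with sensory evidence, and how that combination
breaks down in psychosis.

## The task and the models

On each trial a participant sees two baskets whose sizes encode a prior over
two lakes, then two lakes with anti-symmetric red-fish proportions, and
reports the confidence `c ∈ [0, 1]` that a red fish came from the right lake.
Everything is analysed on the log-odds scale:

- chance logit `L_c = log(c / (1 − c))`
- likelihood logit `L_s = log(P_R / (1 − P_R))` (red proportion in the right lake)
- prior logit `L_p = log(S_R / S_L)` (basket-size ratio)

Three nested models predict `L_c`:

| model | prediction | free parameters |
|---|---|---|
| simple Bayes | `L_c = L_s + L_p` | none |
| weighted Bayes | `L_c = F(L_s, w_s) + F(L_p, w_p)` | `w_s, w_p ∈ [0.5, 1]` |
| circular inference | `L_c = F(L_s + I, w_s) + F(L_p + I, w_p)` with `I = F(α_s L_s, w_s) + F(α_p L_p, w_p)` | `+ α_s, α_p ≥ 0` |

`F(L, w) = log[(w·e^L + 1 − w) / ((1 − w)·e^L + w)]` is the message a weighted
link of a binary causal chain applies to a log-odds input: belief propagation
on the three-node network fisher-preference → lake → display, with `w_s` and
`w_p` the trust placed in the sensory and prior links (verified in the test
suite against exhaustive enumeration over the chain's eight states). The loop
parameters `α_s` and `α_p` count how many times sensory evidence and prior are
redundantly reverberated ("over-counted") through the hierarchy; with
`α_s > 0` the slope of `L_c` in `L_s` at the origin exceeds 1, the signature
of the same evidence being counted more than once, and the behavioural
sigmoid characteristic of jumping to conclusions emerges.

The package provides:

- `circinfer.core` — the transforms, `F`, the three predictors, and an
  exact-enumeration oracle;
- `circinfer.synth` — a Fisher-task design generator (8 blocks × 30 trials,
  prior levels 0.1–0.9, likelihood levels 0–1, 50 fish per lake) and
  simulated responders with known parameters;
- `circinfer.fitting` — per-participant estimation by mean-squared error on
  the confidence scale (KL divergence as an alternative), multi-start bounded
  L-BFGS-B, ambiguous trials only;
- `circinfer.comparison` — Gaussian-approximation BIC
  (`n·ln σ² + k·ln n`) and random-effects group model selection
  (variational Dirichlet updates, Monte-Carlo exceedance probabilities);
- `circinfer.metrics` — model-free indices: absolute confidence
  `|(c − 0.5) × 2|`, sensory-evidence index `|2 P_R − 1|`, prior congruency,
  and jumping-to-conclusions descriptors;
- `circinfer.io` / `circinfer.cli` — CSV trial tables, YAML configs, and the
  `circinfer simulate|fit|compare|metrics|recover` command line.

## Worked example

Fit a simulated participant who over-counts sensory evidence:

```python
from circinfer import (
    DesignConfig, FitConfig, ModelParams, SimulatedParticipant,
    fit_participant, generate_design, predict_circular, simulate_responses,
)

truth = ModelParams.circular(w_s=0.9, w_p=0.75, alpha_s=1.8, alpha_p=0.6)
trials = generate_design(DesignConfig(seed=7))
responder = SimulatedParticipant(true_params=truth, response_noise_sd=0.05, seed=7)
responses = simulate_responses(trials, responder)

fit = fit_participant(trials, responses, variant="circular", config=FitConfig(seed=7))
p = fit.params
print(f"fitted: w_s={p.w_s:.3f} w_p={p.w_p:.3f} "
      f"alpha_s={p.alpha_s:.3f} alpha_p={p.alpha_p:.3f}")
print(f"mse={fit.objective_value:.5f} on {fit.n_trials_used} ambiguous trials")

h = 1e-6
slope = (predict_circular(h, 0.0, p) - predict_circular(-h, 0.0, p)) / (2 * h)
print(f"origin slope dL_c/dL_s = {slope:.2f}")
```

prints

```
fitted: w_s=0.901 w_p=0.740 alpha_s=1.848 alpha_p=0.723
mse=0.00190 on 197 ambiguous trials
origin slope dL_c/dL_s = 2.70
```

The generating weights and the ascending-loop count are recovered to within a
few hundredths from 240 noisy trials; the residual MSE matches the injected
motor noise (0.05² = 0.0025); and the fitted origin slope of 2.70 — well above
the Bayes-optimal 1 — is the over-counting signature. The same loop from the
shell:

```sh
circinfer recover --seed 1 --out results/recover
```

simulates a 25-participant cohort, fits all three variants, runs the group
comparison, and writes recovery statistics to `results/recover/summary.json`.

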