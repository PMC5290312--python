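# Methods

## Model

The Fisher task is interpreted through a three-node binary causal chain: the
fisher's lake preference `x_p` imperfectly determines the lake of origin
`x_c`, which imperfectly determines the sensory display `x_s`. Each link is a
binary symmetric channel with reliability `w_p` (prior link) and `w_s`
(sensory link): `P(x_c = right | x_p = right) = w_p`,
`P(x_s = right | x_c = right) = w_s`. Exact belief propagation on this chain
sends each source's log-odds through the saturating transform

    F(L, w) = log[(w·e^L + 1 − w) / ((1 − w)·e^L + w)]

and sums the messages at the middle node, giving the weighted-Bayes
prediction `L_c = F(L_s, w_s) + F(L_p, w_p)`. `F` is odd in `L`, the identity
at `w = 1`, identically zero at `w = 0.5`, and saturates at `±logit(w)`. The
implementation is pinned to first principles by an exhaustive-enumeration
oracle over the chain's 2×2×2 state space: the closed form and the oracle
agree to ≤ 1e−12 over a thousand random parameterizations in the test suite,
which guards the algebra against drift.

Circular inference adds reverberation: evidence re-entering the hierarchy is
wrongly treated as new. Each redundant pass sums another copy of the logit,
discounted by the link it traverses, so the over-counted contribution is
`I = F(α_s·L_s, w_s) + F(α_p·L_p, w_p)`, where `α_s` counts ascending
(sensory) loops and `α_p` descending (prior) loops. Because reverberation
travels both up and down the hierarchy, `I` corrupts both inputs equally:

    L_c = F(L_s + I, w_s) + F(L_p + I, w_p)

At `α_s = α_p = 0` this is exactly weighted Bayes; at unit weights weighted
Bayes is exactly simple Bayes (`L_c = L_s + L_p`) — the three models are
strictly nested, and the test suite asserts both reductions on a dense logit
grid. The behavioural signature of ascending loops is a local slope of `L_c`
in `L_s` exceeding 1 at the origin (at `w_s = 0.9, α_s = 1.8` the slope is
≈ 1.95): no setting of trust alone can produce a slope above 1, so slopes
above 1 indicate the same evidence counted more than once.

## Parameters

| parameter | range | default | meaning |
|---|---|---|---|
| `w_s`, `w_p` | [0.5, 1] | 1 | trust in the sensory / prior message. 0.5 is an uninformative link; values below 0.5 would mean a sign-flipping channel, which the generative story excludes. |
| `α_s`, `α_p` | ≥ 0 (fit box [0, 10]) | 0 | number of redundant reverberations of sensory / prior information. Dimensionless counts; the fitting box is finite because bounded optimization needs one, and because `F`'s saturation makes values beyond ~10 behaviourally indistinguishable at task logit ranges. The generator itself places no upper cap. |
| confidence clip | (1e−5, 1 − 1e−5) | — | reported `c` is rescaled into an open interval before any logit; a coarser (0.01, 0.99) band is exposed in `FitConfig` and reused as the extreme-rating threshold in the descriptive indices. |

## Synthetic data

The generator emulates the task design: 8 blocks × 30 trials (240 per
participant), prior levels {0.1, …, 0.9} realized as basket sizes out of a
10-unit total (level 0.8 → baskets 8 and 2), likelihood levels
{0, 0.1, …, 1} realized as red-fish counts out of 50 per lake
(`round(p·50)`, complement black, left lake anti-symmetric), with both factor
sequences balanced to within one trial per level, stratified within blocks,
and independently shuffled (this stratified random crossing keeps both
factors identifiable; whether the original procedure crossed all 9×11 cells
is not documented, so the crossing scheme is a package choice). The whole
sequence is a pure function of the seed.

Responders are forward samples of the model: predicted `L_c` mapped through
the logistic function, truncated Gaussian motor noise on the confidence scale
(default sd 0.05 — a response-noise term is required for a nondegenerate
fitting problem and 5% of the scale is a conservative motor-error magnitude),
and optional Gaussian jitter on the likelihood logit (sd 0.02) used to
reproduce the variance-driven behaviour of extreme over-counters, for whom
any tiny perturbation at zero net evidence lands the response at a scale
extremity. On unambiguous trials (`P_R ∈ {0, 1}`) simulated responders answer
at the scale end, as instructed participants do; those trials are excluded
from fitting.

What the generator does **not** emulate: reaction times, learning or fatigue
across blocks, lapses and anchoring on the response scale, and any
participant-specific reinterpretation of the basket-size-to-prior mapping.
Passing tests therefore demonstrate internal consistency of the estimation
machinery under the model's own assumptions, not validity on real
participants.

## Fitting

Per participant, parameters minimize the mean-squared distance between
predicted and reported confidence on ambiguous trials (mean Bernoulli KL
divergence available as an alternative; on clean data both recover the same
parameters). The optimizer is L-BFGS-B inside the parameter box, restarted
from a prefix of a fixed 64-point Latin-hypercube pool drawn per seed
(20 starts by default). Using a prefix of one pool rather than a fresh design
per `n_starts` makes the best-of-n objective exactly nonincreasing in n. Two
deterministic starts are appended: the nested special case (unit weights,
zero loops), and — for the circular variant — the fitted weighted solution,
so the richer model can never score worse than its special case and the
nesting inequality circular ≤ weighted ≤ simple holds structurally. Ties are
broken by the smaller parameter-vector norm. `F` is computed with
`logaddexp`, so arguments of order `α·L ≈ 100` stay finite.

## Model comparison

Fits are scored by BIC under a Gaussian residual approximation,
`BIC = n·ln σ² + k·ln n` with `σ² = SSE/n`; pooled scores use all trials and
`k` summed over participants (4/2/0 free parameters per participant for
circular / weighted / simple). A perfect fit returns −∞ with a warning. Group
level: per-participant log evidences are approximated as `−BIC/2` (the
standard bridge; the source method is agnostic about the evidence
approximation) and fed to random-effects model selection — variational
fixed-point updates of a Dirichlet over model frequencies (assignments
∝ `exp(log evidence + digamma terms)`, concentrations = prior + summed
assignments, iterated to 1e−6) with a uniform Dirichlet prior (`α₀ = 1`).
Exceedance probabilities are estimated by seeded Monte-Carlo draws from the
fitted Dirichlet (10⁶ by default), which remains valid for more than two
models, rather than by the two-model closed form.

## Numerical choices

- Extended-real likelihood logits are represented as `None` plus an
  ambiguity flag on the trial object rather than raw infinities, keeping
  downstream arithmetic total; boundary proportions map to scale extremities
  in simulation and are excluded from fitting.
- Side classifications (chosen vs Bayes-optimal) treat |logit sums| below
  1e−12 as undecided, absorbing round-off when prior and likelihood cancel.
- The prior-congruency index `(S_congruent − S_incongruent)/(S_c + S_i)` is
  divided by 0.8, the maximum attainable asymmetry under the default design
  (baskets 9:1 of a 10-unit total), mapping it onto [−1, 1]; the constant is
  configurable for other designs.
- Degenerate input: constant mid-scale responses drive both weights to the
  0.5 boundary with zero residual, the correct limit under the box.

## Known limitations

- **Loop-parameter identifiability.** The entire behavioural effect of
  `α_s` is the corruption term `F(α_s·L_s, w_s)`, which is bounded by
  `|logit(w_s)|` no matter how large `α_s` grows. For weights near 0.5 that
  bound (≈ 0.2 logits, ≲ 0.05 on the confidence scale near mid-scale) is
  comparable to motor noise, so the objective is nearly flat in the loop
  count; large `α` additionally saturates `F` at any weight. Consequently,
  when generating parameters are drawn uniformly over the full box, loop
  counts recover well only where the paired weight is informative: weights
  recover with r ≈ 0.999 and negligible bias, while `α_s` recovery at
  25 participants × 240 trials sits near r ≈ 0.85 with bias of order 0.5 —
  an information limit of the design, not an optimizer failure (noiseless
  data recover all four parameters to ≤ 1e−3). Inference about loop counts
  in participants with near-uninformative weights should be treated with
  caution.
- Fitted values for real participants are reproducible only in distribution,
  not bit-exactly, because optimizer, starts and bounds are package choices.
- The problem sizes used throughout (25 simulated participants, 240 trials,
  10⁵–10⁶ Dirichlet draws) are the package's standard study scale; all are
  configurable.
- Mixed-model inference on the behavioural indices, reaction-time analyses
  and clinical correlations are out of scope: the package exports the tables
  and leaves those to standard statistical tooling.
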