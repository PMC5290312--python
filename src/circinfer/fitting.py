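"""Per-participant parameter estimation for the nested confidence models.

Parameters are fit participant by participant by minimizing the mean-squared
distance between predicted and reported confidence on the chance scale,
restricted to trials with ambiguous sensory evidence (finite likelihood
logit). Mean-squared error on the confidence scale is the primary objective —
responses carry motor error even at the scale extremes — with a Bernoulli KL
divergence available as an alternative.

The objective surface is smooth but multimodal in the loop parameters, so the
optimizer is bounded L-BFGS-B restarted from Latin-hypercube draws over the
parameter box (plus the nested special case as a deterministic extra start,
which enforces the nesting inequality circular <= weighted <= simple up to
optimizer tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .core import ModelParams, TaskTrial, Variant, inv_logit, predict, ALPHA_MAX, W_MIN
from .synth import ResponseRecord

_START_POOL = 64

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "w_s": (W_MIN, 1.0),
    "w_p": (W_MIN, 1.0),
    "alpha_s": (0.0, ALPHA_MAX),
    "alpha_p": (0.0, ALPHA_MAX),
}


@dataclass(frozen=True)
class FitConfig:
    """Objective, rescaling and optimizer settings for one fit.

    ``c_clip`` rescales reported confidence into an open interval before any
    logit transform (default (1e-5, 1 - 1e-5); a coarser (0.01, 0.99) is a
    documented alternative). ``n_starts`` Latin-hypercube restarts guard
    against local minima in the loop parameters.
    """

    objective: str = "mse"
    c_clip: tuple[float, float] = (1e-5, 1.0 - 1e-5)
    n_starts: int = 20
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    seed: int = 0
    tolerance: float = 1e-10

    def __post_init__(self) -> None:
        if self.objective not in ("mse", "kl"):
            raise ValueError("objective must be 'mse' or 'kl'")
        lo, hi = self.c_clip
        if not 0.0 < lo < 0.5 < hi < 1.0:
            raise ValueError("c_clip must satisfy 0 < lower < 0.5 < upper < 1")
        if self.n_starts < 1:
            raise ValueError("n_starts must be positive")


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters with objective value and optimizer diagnostics."""

    params: ModelParams
    objective_value: float
    objective: str
    n_trials_used: int
    residuals: np.ndarray
    starts_tried: int
    converged: bool


def mse_objective(c_observed: np.ndarray, c_predicted: np.ndarray) -> float:
    """Mean squared difference on the confidence scale."""
    return float(np.mean((np.asarray(c_observed) - np.asarray(c_predicted)) ** 2))


def kl_objective(c_observed: np.ndarray, c_predicted: np.ndarray) -> float:
    """Mean Bernoulli KL divergence ``KL(c || c_hat)`` over trials.

    Both arguments must already be clipped into an open interval; zero iff
    the vectors agree pointwise.
    """
    c = np.asarray(c_observed, dtype=float)
    ch = np.asarray(c_predicted, dtype=float)
    kl = c * np.log(c / ch) + (1.0 - c) * np.log((1.0 - c) / (1.0 - ch))
    return float(np.mean(kl))


def _ambiguous_arrays(
    trials: list[TaskTrial], responses: list[ResponseRecord]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(trials) != len(responses):
        raise ValueError("trials and responses must be aligned (same length)")
    c_all = np.array([r.confidence for r in responses], dtype=float)
    if np.any(~np.isfinite(c_all)):
        bad = np.flatnonzero(~np.isfinite(c_all))
        raise ValueError(f"non-finite confidence at trial indices {bad.tolist()[:10]}")
    mask = np.array([t.is_ambiguous for t in trials])
    if not mask.any():
        raise ValueError("no ambiguous trials: the models are only fit where the likelihood logit is finite")
    L_s = np.array([t.likelihood_logit for t, m in zip(trials, mask) if m], dtype=float)
    L_p = np.array([t.prior_logit for t, m in zip(trials, mask) if m], dtype=float)
    return L_s, L_p, c_all[mask]


def _evaluate(
    x: np.ndarray,
    variant: Variant,
    L_s: np.ndarray,
    L_p: np.ndarray,
    c_obs: np.ndarray,
    config: FitConfig,
) -> float:
    params = ModelParams.from_vector(x, variant)
    c_hat = inv_logit(predict(L_s, L_p, params))
    if config.objective == "kl":
        c_hat = np.clip(c_hat, *config.c_clip)
        return kl_objective(c_obs, c_hat)
    return mse_objective(c_obs, c_hat)


def fit_participant(
    trials: list[TaskTrial],
    responses: list[ResponseRecord],
    variant: Variant = "circular",
    config: FitConfig | None = None,
) -> FitResult:
    """Fit one participant's responses with the requested model variant.

    Reported confidence is clipped into ``config.c_clip`` and the objective is
    evaluated on ambiguous trials only. ``simple`` has no free parameters and
    is evaluated directly; ``weighted`` and ``circular`` run multi-start
    bounded optimization, returning the best start (ties broken by the
    smaller parameter-vector norm). For the circular variant the fitted
    weighted solution is injected as an additional start so the richer model
    can never do worse than its special case.
    """
    config = config or FitConfig()
    L_s, L_p, c_obs = _ambiguous_arrays(trials, responses)
    c_obs = np.clip(c_obs, *config.c_clip)

    def objective_for(params: ModelParams) -> tuple[float, np.ndarray]:
        c_hat = inv_logit(predict(L_s, L_p, params))
        resid = c_obs - c_hat
        if config.objective == "kl":
            value = kl_objective(c_obs, np.clip(c_hat, *config.c_clip))
        else:
            value = float(np.mean(resid**2))
        return value, resid

    if variant == "simple":
        params = ModelParams.simple()
        value, resid = objective_for(params)
        return FitResult(params, value, config.objective, c_obs.size, resid, 0, True)

    names = ("w_s", "w_p", "alpha_s", "alpha_p") if variant == "circular" else ("w_s", "w_p")
    lo = np.array([config.bounds[n][0] for n in names])
    hi = np.array([config.bounds[n][1] for n in names])

    # draw a fixed-size pool and take a prefix: for a given seed the start sets
    # are nested in n_starts, so the best-of-n objective is nonincreasing in n
    sampler = qmc.LatinHypercube(d=len(names), seed=config.seed)
    pool = sampler.random(max(config.n_starts, _START_POOL))
    starts = [lo + (hi - lo) * row for row in pool[: config.n_starts]]
    starts.append(np.array([1.0, 1.0] + [0.0] * (len(names) - 2)))  # the nested special case
    if variant == "circular":
        sub = fit_participant(trials, responses, "weighted", config)
        starts.append(np.array([sub.params.w_s, sub.params.w_p, 0.0, 0.0]))

    best_x: np.ndarray | None = None
    best_val = np.inf
    converged = False
    for x0 in starts:
        res = minimize(
            _evaluate,
            x0,
            args=(variant, L_s, L_p, c_obs, config),
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"ftol": config.tolerance, "gtol": 1e-10},
        )
        better = res.fun < best_val - 1e-15 or (
            abs(res.fun - best_val) <= 1e-15
            and best_x is not None
            and np.linalg.norm(res.x) < np.linalg.norm(best_x)
        )
        if better or best_x is None:
            best_x, best_val = res.x, float(res.fun)
            converged = bool(res.success)

    params = ModelParams.from_vector(best_x, variant)
    value, resid = objective_for(params)
    return FitResult(params, value, config.objective, c_obs.size, resid, len(starts), converged)
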