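"""BIC scoring and random-effects group-level Bayesian model selection.

Model fits are scored with a Bayesian Information Criterion under a Gaussian
approximation to the response likelihood::

    BIC = n * ln(sigma^2) + k * ln(n)

where ``n`` is the number of data points, ``k`` the number of free parameters
and ``sigma^2`` the mean-squared difference between reported and predicted
confidence. Smaller is better. At the group level, per-participant log
evidences (approximated as ``-BIC/2``) feed a random-effects model-selection
scheme: model frequencies in the population follow a Dirichlet distribution
whose concentration parameters are estimated by fixed-point variational
updates, yielding expected posterior frequencies and exceedance probabilities
(the probability that each model is the most frequent one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, softmax


@dataclass(frozen=True)
class GroupComparison:
    """Group-level comparison across model variants.

    ``per_model_bic`` are pooled BIC totals; ``delta_bic`` is each model's BIC
    minus the best (lowest) one, so the winning model has delta 0.
    """

    model_names: tuple[str, ...]
    per_model_bic: dict[str, float]
    delta_bic: dict[str, float]
    dirichlet_alpha: dict[str, float]
    expected_freq: dict[str, float]
    exceedance_prob: dict[str, float]
    n_participants: int
    n_trials: int


def bic_score(sum_sq_error: float, n: int, k: int) -> float:
    """Gaussian-approximation BIC from a residual sum of squares.

    ``sigma^2 = sum_sq_error / n``. A perfect fit (zero residual variance)
    returns ``-inf`` with a warning rather than raising, since it genuinely
    dominates any finite score.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if k < 0:
        raise ValueError("k must be nonnegative")
    if sum_sq_error < 0:
        raise ValueError("sum_sq_error must be nonnegative")
    sigma2 = sum_sq_error / n
    if sigma2 == 0.0:
        warnings.warn("zero residual variance: BIC is -inf (perfect fit)", RuntimeWarning, stacklevel=2)
        return -np.inf
    return float(n * np.log(sigma2) + k * np.log(n))


def rfx_model_selection(
    log_evidences: np.ndarray,
    prior_alpha: float = 1.0,
    seed: int | None = None,
    n_samples: int = 1_000_000,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    model_names: tuple[str, ...] | None = None,
    n_trials: int = 0,
) -> GroupComparison:
    """Random-effects Bayesian model selection over a participants x models grid.

    Iterates the variational fixed point: posterior model assignments are
    proportional to ``exp(log_evidence + digamma(alpha_k) - digamma(sum alpha))``
    row-wise, and ``alpha = prior_alpha + summed assignments``, until the
    concentration vector changes by less than ``tol``. Exceedance
    probabilities are estimated by seeded Monte-Carlo sampling from the
    fitted Dirichlet (valid for any number of models).
    """
    ev = np.asarray(log_evidences, dtype=float)
    if ev.ndim != 2 or ev.shape[0] < 1 or ev.shape[1] < 2:
        raise ValueError("log_evidences must be (n_participants >= 1) x (n_models >= 2)")
    if np.any(~np.isfinite(ev)):
        raise ValueError("log evidences must be finite")
    if prior_alpha <= 0:
        raise ValueError("prior_alpha must be positive")
    n_sub, n_models = ev.shape
    names = model_names or tuple(f"model_{i}" for i in range(n_models))
    if len(names) != n_models:
        raise ValueError("model_names length must match the number of models")

    alpha = np.full(n_models, prior_alpha)
    for _ in range(max_iter):
        log_u = ev + digamma(alpha) - digamma(alpha.sum())
        u = softmax(log_u, axis=1)
        alpha_new = prior_alpha + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    expected = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    wins = np.bincount(np.argmax(draws, axis=1), minlength=n_models)
    exceedance = wins / n_samples

    # BIC totals are not known at this level; fill from -2 * evidence sums
    totals = {name: float(-2.0 * ev[:, j].sum()) for j, name in enumerate(names)}
    best = min(totals.values())
    return GroupComparison(
        model_names=tuple(names),
        per_model_bic=totals,
        delta_bic={name: totals[name] - best for name in names},
        dirichlet_alpha={name: float(alpha[j]) for j, name in enumerate(names)},
        expected_freq={name: float(expected[j]) for j, name in enumerate(names)},
        exceedance_prob={name: float(exceedance[j]) for j, name in enumerate(names)},
        n_participants=n_sub,
        n_trials=n_trials,
    )


def evidence_from_bic(bic: np.ndarray) -> np.ndarray:
    """Per-participant log model evidence approximated as ``-BIC / 2``."""
    return -0.5 * np.asarray(bic, dtype=float)


def compare_fits(
    sum_sq_errors: np.ndarray,
    n_trials_per_participant: np.ndarray,
    k_per_model: dict[str, int],
    prior_alpha: float = 1.0,
    seed: int | None = None,
    n_samples: int = 1_000_000,
) -> GroupComparison:
    """Full comparison from per-participant residual sums of squares.

    ``sum_sq_errors`` is participants x models (column order follows
    ``k_per_model``). Pooled BIC per model uses the grand totals (all trials
    combined, ``k`` summed over participants); the random-effects step uses
    per-participant BICs converted to approximate log evidences.
    """
    sse = np.asarray(sum_sq_errors, dtype=float)
    n_i = np.asarray(n_trials_per_participant, dtype=int)
    names = tuple(k_per_model)
    if sse.shape != (n_i.size, len(names)):
        raise ValueError("sum_sq_errors must be participants x models")

    n_total = int(n_i.sum())
    per_model_bic = {}
    for j, name in enumerate(names):
        k_total = k_per_model[name] * n_i.size
        per_model_bic[name] = bic_score(float(sse[:, j].sum()), n_total, k_total)

    per_sub_bic = np.empty_like(sse)
    for j, name in enumerate(names):
        for i in range(n_i.size):
            per_sub_bic[i, j] = bic_score(float(sse[i, j]), int(n_i[i]), k_per_model[name])
    result = rfx_model_selection(
        evidence_from_bic(per_sub_bic),
        prior_alpha=prior_alpha,
        seed=seed,
        n_samples=n_samples,
        model_names=names,
        n_trials=n_total,
    )
    best = min(per_model_bic.values())
    return GroupComparison(
        model_names=names,
        per_model_bic=per_model_bic,
        delta_bic={name: per_model_bic[name] - best for name in names},
        dirichlet_alpha=result.dirichlet_alpha,
        expected_freq=result.expected_freq,
        exceedance_prob=result.exceedance_prob,
        n_participants=n_i.size,
        n_trials=n_total,
    )
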