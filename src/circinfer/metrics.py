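"""Model-free behavioural indices and jumping-to-conclusions descriptors.

These summaries require no model fit. Per trial: absolute confidence
``|(c - 0.5) * 2|``, a bounded sensory-evidence index ``|2 P_R - 1|`` (0 at an
uninformative display, 1 on unambiguous trials), and a signed prior-congruency
index — the basket-size advantage of the lake favoured by the sensory
evidence, rescaled so the attainable range under the default design maps onto
[-1, 1] and set to 0 when the lake proportions are equal. Per participant:
the jumping-to-conclusions descriptors (mean +- sd of absolute confidence,
the number of extreme ratings, and choice quality against the ideal-observer
solution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import TaskTrial
from .synth import ResponseRecord

#: Maximum attainable |S_congruent - S_incongruent| / (S_c + S_i) under the
#: default design (basket sizes 1..9 in units of a 10-unit total): (9-1)/10.
DEFAULT_CONGRUENCY_SCALE = 0.8

#: Ratings at or beyond these bounds count as extreme (the coarse confidence
#: clip range used for descriptive analyses).
DEFAULT_EXTREME_BOUNDS = (0.01, 0.99)


@dataclass(frozen=True)
class TrialMetrics:
    absolute_confidence: float
    sensory_evidence_index: float
    prior_congruency: float
    chosen_side: str  # left | right | none
    bayes_optimal_side: str


def _side(value: float, tol: float = 1e-12) -> str:
    # tolerance absorbs round-off when the prior and likelihood logits cancel
    if value > tol:
        return "right"
    if value < -tol:
        return "left"
    return "none"


def compute_trial_metrics(
    trial: TaskTrial,
    response: ResponseRecord,
    congruency_scale: float = DEFAULT_CONGRUENCY_SCALE,
) -> TrialMetrics:
    """Model-free indices for one trial/response pair.

    ``chosen_side`` follows the sign of ``c - 0.5`` (none at exactly 0.5);
    ``bayes_optimal_side`` follows the sign of ``L_s + L_p``, with unambiguous
    sensory evidence dominating any finite prior.
    """
    c = response.confidence
    if trial.p_red_right == 0.5:
        congruency = 0.0
    else:
        congruent_right = trial.p_red_right > 0.5
        s_c = trial.basket_right if congruent_right else trial.basket_left
        s_i = trial.basket_left if congruent_right else trial.basket_right
        congruency = (s_c - s_i) / (s_c + s_i) / congruency_scale

    if trial.is_ambiguous:
        optimal = _side(trial.likelihood_logit + trial.prior_logit)
    else:
        optimal = "right" if trial.p_red_right > 0.5 else "left"

    return TrialMetrics(
        absolute_confidence=abs((c - 0.5) * 2.0),
        sensory_evidence_index=abs(2.0 * trial.p_red_right - 1.0),
        prior_congruency=congruency,
        chosen_side=_side(c - 0.5),
        bayes_optimal_side=optimal,
    )


def jtc_indices(
    trials: list[TaskTrial],
    responses: list[ResponseRecord],
    extreme_bounds: tuple[float, float] = DEFAULT_EXTREME_BOUNDS,
) -> dict[str, float]:
    """Jumping-to-conclusions descriptors for one participant.

    Returns the mean and s.d. of absolute confidence, the count of extreme
    ratings (confidence at or beyond ``extreme_bounds``), and choice quality:
    the proportion of trials on which the chosen side matches the
    ideal-observer side, excluding trials where either side is undecided.
    """
    if not trials:
        raise ValueError("trials must be nonempty")
    if len(trials) != len(responses):
        raise ValueError("trials and responses must be aligned")
    per_trial = [compute_trial_metrics(t, r) for t, r in zip(trials, responses)]
    abs_conf = np.array([m.absolute_confidence for m in per_trial])
    c = np.array([r.confidence for r in responses])
    lo, hi = extreme_bounds
    extreme = int(np.sum((c <= lo) | (c >= hi)))
    decided = [
        m for m in per_trial if m.chosen_side != "none" and m.bayes_optimal_side != "none"
    ]
    quality = (
        float(np.mean([m.chosen_side == m.bayes_optimal_side for m in decided]))
        if decided
        else math.nan
    )
    return {
        "mean_absolute_confidence": float(abs_conf.mean()),
        "sd_absolute_confidence": float(abs_conf.std(ddof=1)) if abs_conf.size > 1 else 0.0,
        "n_extreme_ratings": extreme,
        "choice_quality": quality,
        "n_trials": len(trials),
        "n_decided_trials": len(decided),
    }
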