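"""Logit transforms, message weighting and the nested confidence models.

The generative story is a three-node binary chain: the fisher's preference
``x_p`` imperfectly determines the lake of origin ``x_c``, which imperfectly
determines the sensory display ``x_s``. Each link carries a trust weight
(``w_p`` for the prior link, ``w_s`` for the sensory link). Belief propagation
on this chain sends each log-odds message through the saturating transform
:func:`F` before summation at the middle node.

Three nested predictors for the chance logit ``L_c`` are provided:

* :func:`predict_simple` — ``L_c = L_s + L_p`` (ideal observer),
* :func:`predict_weighted` — ``L_c = F(L_s, w_s) + F(L_p, w_p)``,
* :func:`predict_circular` — adds loop parameters ``alpha_s, alpha_p`` that
  reverberate (over-count) evidence: the corruption term
  ``I = F(alpha_s * L_s, w_s) + F(alpha_p * L_p, w_p)`` is added to both the
  bottom-up and top-down inputs before weighting.

:func:`exact_posterior_oracle` computes the weighted-Bayes posterior by
exhaustive enumeration over the 2x2x2 state space; it exists to pin the
closed-form message equations to first principles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Union

import numpy as np
from scipy.special import expit

ArrayLike = Union[float, np.ndarray]

#: Upper box bound on the loop parameters used throughout fitting. Loops are
#: counts of redundant reverberations; a finite box keeps optimization bounded.
ALPHA_MAX = 10.0

#: Lower box bound on trust weights. w = 0.5 is an uninformative link;
#: w < 0.5 would mean a sign-flipping channel, which the generative story
#: excludes.
W_MIN = 0.5

Variant = Literal["simple", "weighted", "circular"]
VARIANTS: tuple[str, ...] = ("simple", "weighted", "circular")


def logit(p: ArrayLike) -> ArrayLike:
    """Log-odds ``log(p / (1 - p))`` for ``p`` strictly inside (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("logit requires 0 < p < 1; use likelihood_logit for boundary proportions")
    out = np.log(p) - np.log1p(-p)
    return float(out) if out.ndim == 0 else out


def inv_logit(L: ArrayLike) -> ArrayLike:
    """Inverse of :func:`logit` (the logistic function); total on the extended reals."""
    out = expit(np.asarray(L, dtype=float))
    return float(out) if out.ndim == 0 else out


def prior_logit(basket_right: float, basket_left: float) -> float:
    """Prior log-odds ``log(S_R / S_L)`` from the two basket sizes.

    Antisymmetric under swapping the baskets. A 2:1 right:left ratio gives
    ``log(2)``.
    """
    if basket_right <= 0 or basket_left <= 0:
        raise ValueError("basket sizes must be strictly positive")
    return math.log(basket_right / basket_left)


def likelihood_logit(p_red_right: float) -> float:
    """Sensory log-odds ``log(P_R / (1 - P_R))`` of the right-lake red proportion.

    Returns ``+inf`` at ``P_R = 1`` and ``-inf`` at ``P_R = 0`` (unambiguous
    trials); callers should branch on :attr:`TaskTrial.is_ambiguous` before
    doing arithmetic with the result.
    """
    if not 0.0 <= p_red_right <= 1.0:
        raise ValueError(f"p_red_right must lie in [0, 1], got {p_red_right}")
    if p_red_right == 0.0:
        return -math.inf
    if p_red_right == 1.0:
        return math.inf
    return math.log(p_red_right / (1.0 - p_red_right))


@dataclass(frozen=True)
class TaskTrial:
    """One Fisher-task trial: basket-size prior and red-proportion likelihood.

    ``prior_logit`` and ``likelihood_logit`` are derived at construction;
    ``likelihood_logit`` is ``None`` on unambiguous trials (``P_R`` in {0, 1})
    so that downstream arithmetic stays total — consult :attr:`is_ambiguous`.
    """

    basket_left: float
    basket_right: float
    p_red_right: float
    prior_logit: float = field(init=False)
    likelihood_logit: float | None = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "prior_logit", prior_logit(self.basket_right, self.basket_left))
        ll = likelihood_logit(self.p_red_right)
        object.__setattr__(self, "likelihood_logit", ll if math.isfinite(ll) else None)

    @property
    def is_ambiguous(self) -> bool:
        """True iff ``0 < P_R < 1`` (finite sensory log-odds)."""
        return self.likelihood_logit is not None

    def mirrored(self) -> "TaskTrial":
        """The left/right mirror of this trial (both logits negate)."""
        return TaskTrial(
            basket_left=self.basket_right,
            basket_right=self.basket_left,
            p_red_right=1.0 - self.p_red_right,
        )


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the confidence models.

    ``w_s`` and ``w_p`` are the trust placed in the sensory and prior
    messages (0.5 = uninformative, 1 = full trust). ``alpha_s`` and
    ``alpha_p`` count redundant reverberations of the sensory evidence
    (ascending loops) and of the prior (descending loops). The ``variant``
    tag pins the nested special cases: ``simple`` forces unit weights and no
    loops, ``weighted`` forces no loops.
    """

    w_s: float = 1.0
    w_p: float = 1.0
    alpha_s: float = 0.0
    alpha_p: float = 0.0
    variant: Variant = "circular"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not (W_MIN <= self.w_s <= 1.0 and W_MIN <= self.w_p <= 1.0):
            raise ValueError("weights must lie in [0.5, 1]")
        if self.alpha_s < 0 or self.alpha_p < 0:
            raise ValueError("loop parameters must be nonnegative")
        if self.variant == "simple" and not (
            self.w_s == 1.0 and self.w_p == 1.0 and self.alpha_s == 0.0 and self.alpha_p == 0.0
        ):
            raise ValueError("variant 'simple' requires w_s = w_p = 1 and alpha_s = alpha_p = 0")
        if self.variant == "weighted" and not (self.alpha_s == 0.0 and self.alpha_p == 0.0):
            raise ValueError("variant 'weighted' requires alpha_s = alpha_p = 0")

    @classmethod
    def simple(cls) -> "ModelParams":
        return cls(variant="simple")

    @classmethod
    def weighted(cls, w_s: float, w_p: float) -> "ModelParams":
        return cls(w_s=w_s, w_p=w_p, variant="weighted")

    @classmethod
    def circular(cls, w_s: float, w_p: float, alpha_s: float, alpha_p: float) -> "ModelParams":
        return cls(w_s=w_s, w_p=w_p, alpha_s=alpha_s, alpha_p=alpha_p, variant="circular")

    @property
    def free_names(self) -> tuple[str, ...]:
        """Names of the free parameters of this variant, in fitting order."""
        if self.variant == "simple":
            return ()
        if self.variant == "weighted":
            return ("w_s", "w_p")
        return ("w_s", "w_p", "alpha_s", "alpha_p")

    @property
    def k(self) -> int:
        """Number of free parameters (0, 2 or 4)."""
        return len(self.free_names)

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in self.free_names])

    @classmethod
    def from_vector(cls, x: np.ndarray, variant: Variant) -> "ModelParams":
        if variant == "simple":
            return cls.simple()
        if variant == "weighted":
            return cls.weighted(*map(float, x))
        return cls.circular(*map(float, x))


def _log_w(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore"):
        return np.log(w), np.log1p(-w)


def F(L: ArrayLike, w: ArrayLike) -> ArrayLike:
    """Message through one weighted link of the binary chain.

    ``F(L, w) = log[(w e^L + 1 - w) / ((1 - w) e^L + w)]``: the log-odds a
    node inherits from a neighbour whose own log-odds are ``L`` when the link
    is trusted with reliability ``w``. Odd in ``L``; identity at ``w = 1``;
    identically zero at ``w = 0.5``; saturates at ``±logit(w)`` for large
    ``|L|``. Computed with ``logaddexp`` so it stays finite for the large
    arguments (``alpha * L``) that arise with strong loops.
    """
    L = np.asarray(L, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(~np.isfinite(L)):
        raise ValueError("F requires finite log-odds; unambiguous trials must be handled by the caller")
    if np.any((w < 0.0) | (w > 1.0)):
        raise ValueError("weight must lie in [0, 1]")
    log_w, log_1mw = _log_w(w)
    num = np.logaddexp(log_w + L, log_1mw)
    den = np.logaddexp(log_1mw + L, log_w)
    out = num - den
    return float(out) if out.ndim == 0 else out


def predict_simple(L_s: ArrayLike, L_p: ArrayLike) -> ArrayLike:
    """Ideal-observer chance logit: ``L_c = L_s + L_p``."""
    out = np.asarray(L_s, dtype=float) + np.asarray(L_p, dtype=float)
    return float(out) if out.ndim == 0 else out


def predict_weighted(L_s: ArrayLike, L_p: ArrayLike, params: ModelParams) -> ArrayLike:
    """Weighted-Bayes chance logit: ``F(L_s, w_s) + F(L_p, w_p)``.

    Exact belief propagation on the three-node chain; reduces to
    :func:`predict_simple` at unit weights.
    """
    out = F(L_s, params.w_s) + F(L_p, params.w_p)
    return float(np.asarray(out)) if np.ndim(out) == 0 else out


def predict_circular(L_s: ArrayLike, L_p: ArrayLike, params: ModelParams) -> ArrayLike:
    """Circular-inference chance logit with reverberating evidence.

    The over-counted contributions ``F(alpha_s * L_s, w_s)`` and
    ``F(alpha_p * L_p, w_p)`` corrupt both the bottom-up and top-down inputs
    equally::

        I   = F(alpha_s * L_s, w_s) + F(alpha_p * L_p, w_p)
        L_c = F(L_s + I, w_s) + F(L_p + I, w_p)

    Reduces exactly to :func:`predict_weighted` at ``alpha_s = alpha_p = 0``.
    With ``alpha_s > 0`` the local slope of ``L_c`` in ``L_s`` at the origin
    can exceed 1 — the signature of evidence counted more than once.
    """
    L_s = np.asarray(L_s, dtype=float)
    L_p = np.asarray(L_p, dtype=float)
    corruption = F(params.alpha_s * L_s, params.w_s) + F(params.alpha_p * L_p, params.w_p)
    out = F(L_s + corruption, params.w_s) + F(L_p + corruption, params.w_p)
    return float(out) if np.ndim(out) == 0 else out


def predict(L_s: ArrayLike, L_p: ArrayLike, params: ModelParams) -> ArrayLike:
    """Dispatch on ``params.variant``; all variants share the circular form's limits."""
    if params.variant == "simple":
        return predict_simple(L_s, L_p)
    if params.variant == "weighted":
        return predict_weighted(L_s, L_p, params)
    return predict_circular(L_s, L_p, params)


@dataclass(frozen=True)
class GenerativeChain:
    """The three-node binary causal chain ``x_p -> x_c -> x_s``.

    ``prior_prob_right`` is the marginal probability that the top variable
    (fisher preference) is 'right'; the conditional tables are symmetric
    channels: ``P(x_c = right | x_p = right) = w_p`` and
    ``P(x_s = right | x_c = right) = w_s``.
    """

    prior_prob_right: float
    w_p: float
    w_s: float

    def __post_init__(self) -> None:
        if not 0.0 < self.prior_prob_right < 1.0:
            raise ValueError("prior_prob_right must lie strictly inside (0, 1)")
        if not (0.0 <= self.w_p <= 1.0 and 0.0 <= self.w_s <= 1.0):
            raise ValueError("chain weights must lie in [0, 1]")


def exact_posterior_oracle(chain: GenerativeChain, evidence_logit: float) -> float:
    """Posterior log-odds of ``x_c`` by exhaustive enumeration.

    Sums the joint probability over all 2x2x2 configurations of
    ``(x_p, x_c, x_s)`` with soft evidence of log-odds ``evidence_logit``
    applied to ``x_s``, then returns ``log P(x_c = right | e) / P(x_c = left | e)``.
    Brute force on purpose: an independent check of the closed-form message
    equations, never a production path. Infinite evidence is handled by its
    limit (the soft-evidence weights become one-hot).
    """
    p_top = chain.prior_prob_right
    # soft-evidence weights on x_s; only their ratio e^L matters
    lam_right = float(expit(evidence_logit))
    lam_left = 1.0 - lam_right
    prob_top = {1: p_top, 0: 1.0 - p_top}
    lam = {1: lam_right, 0: lam_left}

    def channel(child: int, parent: int, w: float) -> float:
        return w if child == parent else 1.0 - w

    mass = {0: 0.0, 1: 0.0}
    for x_p in (0, 1):
        for x_c in (0, 1):
            for x_s in (0, 1):
                mass[x_c] += (
                    prob_top[x_p]
                    * channel(x_c, x_p, chain.w_p)
                    * channel(x_s, x_c, chain.w_s)
                    * lam[x_s]
                )
    if mass[1] == 0.0 or mass[0] == 0.0:
        # deterministic chain (w = 1) with one-hot evidence
        return math.inf if mass[1] > 0.0 else -math.inf
    return math.log(mass[1] / mass[0])
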