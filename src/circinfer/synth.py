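"""Fisher-task design generation and simulated responders.

The study data this package targets are trial-level confidence reports that
are not publicly deposited, so every downstream stage (fitting, model
comparison, behavioural indices) is validated on synthetic participants whose
generating parameters are known. The generator reproduces the task structure:
prior levels 0.1–0.9 (basket-size ratios), likelihood levels 0–1 in steps of
0.1 arranged anti-symmetrically across the two lakes (left proportion is
``1 - P_R``), 8 blocks of 30 trials (240 trials per participant), 50 fish per
lake, and a pseudo-random trial order that is fully reproducible from a seed.

Responders are forward samples of the circular-inference equation: the
predicted chance logit is mapped to the confidence scale by the logistic
function, optional Gaussian noise on the likelihood logit models perceptual
jitter, and truncated Gaussian motor noise on the confidence scale makes the
fitting problem nondegenerate. On unambiguous trials (``P_R`` in {0, 1})
simulated responders answer at the extremity of the scale, as instructed
participants do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ModelParams, TaskTrial, inv_logit, predict

_DEFAULT_PRIOR_LEVELS = tuple(round(0.1 * i, 1) for i in range(1, 10))
_DEFAULT_LIKELIHOOD_LEVELS = tuple(round(0.1 * i, 1) for i in range(0, 11))


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the Fisher-task design.

    Defaults reproduce the task: 8 blocks x 30 trials = 240 trials per
    participant, prior levels {0.1, ..., 0.9}, likelihood levels
    {0, 0.1, ..., 1}, and 50 fish per lake. ``basket_units`` sets the total
    size of the two baskets, so a prior level of 0.8 renders baskets of 8 and
    2 units.
    """

    prior_levels: tuple[float, ...] = _DEFAULT_PRIOR_LEVELS
    likelihood_levels: tuple[float, ...] = _DEFAULT_LIKELIHOOD_LEVELS
    n_blocks: int = 8
    trials_per_block: int = 30
    fish_per_lake: int = 50
    basket_units: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.prior_levels or not self.likelihood_levels:
            raise ValueError("level lists must be nonempty")
        if any(not 0.0 < p < 1.0 for p in self.prior_levels):
            raise ValueError("prior levels must lie strictly inside (0, 1)")
        if any(not 0.0 <= p <= 1.0 for p in self.likelihood_levels):
            raise ValueError("likelihood levels must lie in [0, 1]")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be positive")
        if self.fish_per_lake < 1:
            raise ValueError("fish_per_lake must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class SimulatedParticipant:
    """A simulated responder with known generating parameters.

    ``response_noise_sd`` is truncated Gaussian motor noise on the confidence
    scale (default 0.05). ``likelihood_noise_sd`` is Gaussian noise on the
    likelihood logit (default 0; 0.02 reproduces the variance-driven
    absolute-confidence behaviour of responders with extreme ascending
    loops, for whom any tiny perturbation at zero net evidence lands the
    response at one extreme of the scale).
    """

    true_params: ModelParams
    response_noise_sd: float = 0.05
    likelihood_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.response_noise_sd < 0 or self.likelihood_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")


@dataclass(frozen=True)
class ResponseRecord:
    """A participant's reported confidence (and optional RT) for one trial."""

    confidence: float
    rt: float | None = None


def _balanced_level_sequence(
    levels: tuple[float, ...], config: DesignConfig, rng: np.random.Generator
) -> np.ndarray:
    """Level assignments stratified per block with global counts within 1.

    Each block receives ``floor(trials_per_block / n_levels)`` copies of every
    level; the per-block remainders are dealt from one shuffled global pool
    whose composition keeps whole-design level counts differing by at most 1.
    """
    n_levels = len(levels)
    n_total = config.n_trials
    base_block, rem_block = divmod(config.trials_per_block, n_levels)
    # global target counts: n_total // n_levels (+1 for a random subset)
    base_total, rem_total = divmod(n_total, n_levels)
    counts = np.full(n_levels, base_total)
    counts[rng.choice(n_levels, size=rem_total, replace=False)] += 1
    leftover = counts - base_block * config.n_blocks
    pool = np.repeat(np.arange(n_levels), leftover)
    rng.shuffle(pool)
    assert pool.size == rem_block * config.n_blocks

    out = np.empty(n_total, dtype=int)
    for b in range(config.n_blocks):
        block = np.concatenate(
            [np.repeat(np.arange(n_levels), base_block), pool[b * rem_block : (b + 1) * rem_block]]
        )
        rng.shuffle(block)
        out[b * config.trials_per_block : (b + 1) * config.trials_per_block] = block
    return np.asarray(levels)[out]


def generate_design(config: DesignConfig | None = None) -> list[TaskTrial]:
    """Generate one participant's pseudo-random trial sequence.

    The prior and likelihood factors are each balanced (per-level trial
    counts differ by at most 1 over the design, stratified within blocks) and
    crossed by independent shuffles so both factors stay identifiable. The
    sequence is a pure function of ``config.seed``.
    """
    config = config or DesignConfig()
    rng = np.random.default_rng(config.seed)
    priors = _balanced_level_sequence(config.prior_levels, config, rng)
    likes = _balanced_level_sequence(config.likelihood_levels, config, rng)
    trials = []
    for p_prior, p_like in zip(priors, likes):
        s_right = float(p_prior) * config.basket_units
        trials.append(
            TaskTrial(
                basket_left=config.basket_units - s_right,
                basket_right=s_right,
                p_red_right=float(p_like),
            )
        )
    return trials


def fish_counts(trial: TaskTrial, fish_per_lake: int = 50) -> dict[str, int]:
    """Integer red/black fish counts rendered in each lake.

    Red counts are ``round(p * fish_per_lake)`` with the complement black, so
    each lake always renders exactly ``fish_per_lake`` fish; the left lake's
    red proportion is ``1 - P_R`` by the anti-symmetric design.
    """
    red_right = round(trial.p_red_right * fish_per_lake)
    red_left = round((1.0 - trial.p_red_right) * fish_per_lake)
    return {
        "red_right": red_right,
        "black_right": fish_per_lake - red_right,
        "red_left": red_left,
        "black_left": fish_per_lake - red_left,
    }


def simulate_responses(
    trials: list[TaskTrial], participant: SimulatedParticipant
) -> list[ResponseRecord]:
    """Forward-sample confidence reports for a trial sequence.

    Ambiguous trials: the chance logit predicted by the participant's model
    variant (with optional Gaussian jitter on the likelihood logit) is mapped
    to confidence by the logistic function. Unambiguous trials: the response
    is placed at the scale extremity. Motor noise is then added on the
    confidence scale and the result clamped to [0, 1]. With all noise terms
    at zero, ``logit(c)`` equals the model prediction exactly on ambiguous
    trials.
    """
    if not trials:
        raise ValueError("trials must be nonempty")
    rng = np.random.default_rng(participant.seed)
    params = participant.true_params

    L_p = np.array([t.prior_logit for t in trials])
    ambiguous = np.array([t.is_ambiguous for t in trials])
    L_s = np.array([t.likelihood_logit if t.is_ambiguous else 0.0 for t in trials])
    if participant.likelihood_noise_sd > 0:
        L_s = L_s + rng.normal(0.0, participant.likelihood_noise_sd, size=L_s.shape)

    c = np.where(
        ambiguous,
        inv_logit(predict(L_s, L_p, params)),
        np.array([1.0 if t.p_red_right >= 0.5 else 0.0 for t in trials]),
    )
    if participant.response_noise_sd > 0:
        c = c + rng.normal(0.0, participant.response_noise_sd, size=c.shape)
    c = np.clip(c, 0.0, 1.0)
    return [ResponseRecord(confidence=float(ci)) for ci in c]
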