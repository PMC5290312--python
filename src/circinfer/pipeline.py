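"""End-to-end pipeline stages: simulate, fit, compare, metrics, recover.

All randomness descends from a single master seed: a generator seeded with it
draws one 31-bit child seed per consumer (design, responder, optimizer) in a
fixed order, so each stage is independently reproducible and the whole loop is
deterministic. The ``recover`` stage closes the loop — simulate participants
with known parameters, fit every model variant, compare models at the group
level, and report parameter-recovery statistics.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .comparison import GroupComparison, compare_fits
from .core import ModelParams, TaskTrial, Variant, VARIANTS
from .fitting import DEFAULT_BOUNDS, FitConfig, fit_participant
from .io import participant_records, validate_trial_table, write_trial_table
from .metrics import compute_trial_metrics, jtc_indices
from .synth import DesignConfig, SimulatedParticipant, generate_design, simulate_responses

_SEED_MOD = 2**31


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` child seeds (< 2^31) from one master seed, reproducibly."""
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, _SEED_MOD, size=n)]


def sample_params(
    rng: np.random.Generator,
    variant: Variant = "circular",
    bounds: dict[str, tuple[float, float]] | None = None,
) -> ModelParams:
    """Draw generating parameters uniformly within the fitting box."""
    b = bounds or DEFAULT_BOUNDS
    if variant == "simple":
        return ModelParams.simple()
    draw = {name: float(rng.uniform(*b[name])) for name in b}
    if variant == "weighted":
        return ModelParams.weighted(draw["w_s"], draw["w_p"])
    return ModelParams.circular(draw["w_s"], draw["w_p"], draw["alpha_s"], draw["alpha_p"])


def simulate_dataset(
    n_participants: int,
    master_seed: int,
    variant: Variant = "circular",
    design: DesignConfig | None = None,
    response_noise_sd: float = 0.05,
    likelihood_noise_sd: float = 0.0,
    params_list: Sequence[ModelParams] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (trial table, true-parameter table).

    Each participant gets an independently shuffled design and an independent
    responder seed; generating parameters are drawn uniformly within the
    fitting bounds unless ``params_list`` pins them.
    """
    base = design or DesignConfig()
    seeds = spawn_seeds(master_seed, 3 * n_participants)
    param_rng = np.random.default_rng(spawn_seeds(master_seed + 1, 1)[0])
    rows, truth = [], []
    for i in range(n_participants):
        pid = f"sub{i + 1:03d}"
        design_i = dataclasses.replace(base, seed=seeds[3 * i])
        trials = generate_design(design_i)
        params = params_list[i] if params_list is not None else sample_params(param_rng, variant)
        responder = SimulatedParticipant(
            true_params=params,
            response_noise_sd=response_noise_sd,
            likelihood_noise_sd=likelihood_noise_sd,
            seed=seeds[3 * i + 1],
        )
        responses = simulate_responses(trials, responder)
        for j, (t, r) in enumerate(zip(trials, responses)):
            rows.append(
                {
                    "participant_id": pid,
                    "block": j // base.trials_per_block + 1,
                    "trial": j % base.trials_per_block + 1,
                    "basket_left": t.basket_left,
                    "basket_right": t.basket_right,
                    "p_red_right": t.p_red_right,
                    "confidence": r.confidence,
                }
            )
        truth.append(
            {
                "participant_id": pid,
                "variant": params.variant,
                "w_s": params.w_s,
                "w_p": params.w_p,
                "alpha_s": params.alpha_s,
                "alpha_p": params.alpha_p,
                "response_noise_sd": response_noise_sd,
                "seed": responder.seed,
            }
        )
    return validate_trial_table(pd.DataFrame(rows)), pd.DataFrame(truth)


def fit_dataset(
    df: pd.DataFrame,
    variants: Sequence[Variant] = VARIANTS,
    fit_config: FitConfig | None = None,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Fit every participant with every requested variant.

    Returns one row per participant x variant with fitted parameters, the
    objective value (MSE or KL over ambiguous trials), the residual sum of
    squares used for BIC, and optimizer diagnostics.
    """
    base = fit_config or FitConfig()
    records = participant_records(df)
    seeds = spawn_seeds(master_seed, len(records))
    rows = []
    for seed, (pid, (trials, responses)) in zip(seeds, records.items()):
        for variant in variants:
            cfg = dataclasses.replace(base, seed=seed)
            res = fit_participant(trials, responses, variant, cfg)
            rows.append(
                {
                    "participant_id": pid,
                    "variant": variant,
                    "w_s": res.params.w_s,
                    "w_p": res.params.w_p,
                    "alpha_s": res.params.alpha_s,
                    "alpha_p": res.params.alpha_p,
                    "k": res.params.k,
                    "objective": res.objective,
                    "objective_value": res.objective_value,
                    "sse": float(np.sum(res.residuals**2)),
                    "n_trials_used": res.n_trials_used,
                    "starts_tried": res.starts_tried,
                    "converged": res.converged,
                }
            )
    return pd.DataFrame(rows)


def comparison_from_fits(
    fit_df: pd.DataFrame,
    prior_alpha: float = 1.0,
    seed: int | None = None,
    n_samples: int = 1_000_000,
) -> GroupComparison:
    """Group model comparison (pooled BIC + random effects) from a fit table."""
    variants = list(dict.fromkeys(fit_df["variant"]))
    wide_sse = fit_df.pivot(index="participant_id", columns="variant", values="sse")[variants]
    n_i = (
        fit_df.pivot(index="participant_id", columns="variant", values="n_trials_used")[variants]
        .iloc[:, 0]
        .to_numpy()
    )
    k_map = {v: int(fit_df.loc[fit_df["variant"] == v, "k"].iloc[0]) for v in variants}
    return compare_fits(
        wide_sse.to_numpy(), n_i, k_map, prior_alpha=prior_alpha, seed=seed, n_samples=n_samples
    )


def metrics_table(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial indices and per-participant jumping-to-conclusions summaries."""
    trial_rows, summary_rows = [], []
    for pid, (trials, responses) in participant_records(df).items():
        for j, (t, r) in enumerate(zip(trials, responses)):
            m = compute_trial_metrics(t, r)
            trial_rows.append({"participant_id": pid, "index": j, **dataclasses.asdict(m)})
        summary_rows.append({"participant_id": pid, **jtc_indices(trials, responses)})
    return pd.DataFrame(trial_rows), pd.DataFrame(summary_rows)


def recovery_statistics(truth: pd.DataFrame, fit_df: pd.DataFrame, variant: Variant = "circular") -> dict[str, dict[str, float]]:
    """Pearson correlation and mean bias of recovered vs true parameters."""
    fits = fit_df[fit_df["variant"] == variant].set_index("participant_id")
    tr = truth.set_index("participant_id").loc[fits.index]
    out: dict[str, dict[str, float]] = {}
    for name in ("w_s", "w_p", "alpha_s", "alpha_p"):
        t = tr[name].to_numpy(dtype=float)
        f = fits[name].to_numpy(dtype=float)
        corr = float(np.corrcoef(t, f)[0, 1]) if np.std(t) > 0 and np.std(f) > 0 else float("nan")
        out[name] = {"correlation": corr, "bias": float(np.mean(f - t)), "mean_abs_error": float(np.mean(np.abs(f - t)))}
    return out


def _comparison_dict(comp: GroupComparison) -> dict[str, Any]:
    d = dataclasses.asdict(comp)
    d["model_names"] = list(comp.model_names)
    return d


def run_pipeline(config: dict[str, Any], out_dir: str | Path | None = None) -> dict[str, Any]:
    """Run the requested stages from one config mapping.

    Recognised keys: ``seed`` (master seed), ``stages`` (subset of
    simulate/fit/compare/metrics, or the single stage ``recover`` which
    implies all of them), ``data`` (path to a trial CSV when not simulating),
    ``simulate`` / ``fit`` / ``compare`` sub-mappings with stage options.
    Artifacts are returned in memory and, when ``out_dir`` is given, written
    as CSV/JSON with the seed recorded.
    """
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", ["recover"]))
    if "recover" in stages:
        stages = ["simulate", "fit", "compare", "metrics", "recover"]
    sim_cfg = dict(config.get("simulate", {}))
    fit_cfg = dict(config.get("fit", {}))
    cmp_cfg = dict(config.get("compare", {}))
    artifacts: dict[str, Any] = {"seed": seed, "stages": stages}

    if "simulate" in stages:
        design = DesignConfig(**sim_cfg.pop("design", {}))
        df, truth = simulate_dataset(
            n_participants=int(sim_cfg.pop("n_participants", 25)),
            master_seed=seed,
            design=design,
            **sim_cfg,
        )
        artifacts["trials"], artifacts["true_params"] = df, truth
    elif {"fit", "metrics"} & set(stages):
        from .io import read_trial_table

        if "data" not in config:
            raise ValueError("stages needing data require either the simulate stage or a 'data' path")
        artifacts["trials"] = read_trial_table(config["data"])

    if "fit" in stages:
        variants = tuple(fit_cfg.pop("variants", VARIANTS))
        fc = FitConfig(**fit_cfg)
        artifacts["fits"] = fit_dataset(artifacts["trials"], variants, fc, master_seed=seed)

    if "compare" in stages:
        if "fits" not in artifacts:
            raise ValueError("the compare stage requires the fit stage")
        artifacts["comparison"] = comparison_from_fits(
            artifacts["fits"],
            prior_alpha=float(cmp_cfg.get("prior_alpha", 1.0)),
            seed=seed,
            n_samples=int(cmp_cfg.get("n_samples", 1_000_000)),
        )

    if "metrics" in stages:
        artifacts["trial_metrics"], artifacts["jtc_summary"] = metrics_table(artifacts["trials"])

    if "recover" in stages:
        artifacts["recovery"] = recovery_statistics(artifacts["true_params"], artifacts["fits"])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if "trials" in artifacts:
            write_trial_table(artifacts["trials"], out / "trials.csv", seed=seed)
        for key in ("true_params", "fits", "trial_metrics", "jtc_summary"):
            if key in artifacts:
                artifacts[key].to_csv(out / f"{key}.csv", index=False)
        summary: dict[str, Any] = {"seed": seed, "stages": stages}
        if "comparison" in artifacts:
            summary["comparison"] = _comparison_dict(artifacts["comparison"])
        if "recovery" in artifacts:
            summary["recovery"] = artifacts["recovery"]
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2)
    return artifacts
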