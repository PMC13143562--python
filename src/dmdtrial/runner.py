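"""Scenario orchestration: grids of simulated trials and their summaries.

Runs batches of replicates for one or many :class:`~dmdtrial.simulate.ScenarioConfig`
scenarios and aggregates them into the two standard operating-characteristic
views: the interim/final view (mean and SD of conditional power, rejection
frequency, authorization frequencies at several thresholds, and rejection
frequency among authorized replicates) and the meta-analysis view (mean and
bias of the trial estimate and of the shrinkage estimate, mean
effective-sample-size gain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import DesignSpec, Metric, TimingQuery, sample_size_two_proportions, solve_interim_time
from .simulate import ReplicateRecord, ScenarioConfig, run_replicate, rwd_sample_size

__all__ = [
    "ScenarioSummary",
    "run_replicates",
    "summarize_scenario",
    "run_scenario_grid",
    "default_scenario_grid",
    "null_mode",
    "interim_final_frame",
    "meta_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_C_STARS: tuple[float, ...] = (0.8, 0.85, 0.9)


@dataclass(frozen=True)
class ScenarioSummary:
    """Aggregates of one scenario's replicates.

    ``freq_authorize``/``freq_reject_given_authorize`` are keyed by the
    authorization threshold c*.  Biases are relative to the scenario's true
    trial effect.  Meta-analysis fields are ``nan`` when the scenario was run
    without the meta-analysis step.
    """

    config: ScenarioConfig
    n_total: int
    t: float
    m: int
    n_reps: int
    n_failures: int
    mean_metric: float
    sd_metric: float
    freq_reject: float
    freq_authorize: dict[float, float]
    freq_reject_given_authorize: dict[float, float]
    mean_d_trial: float
    bias_d_trial: float
    mean_theta_hat: float
    bias_theta_hat: float
    mean_gain_percent: float


def run_replicates(config: ScenarioConfig) -> list[ReplicateRecord]:
    """Run ``config.n_reps`` replicates; failures are logged, not raised."""
    records: list[ReplicateRecord] = []
    for i in range(config.n_reps):
        try:
            records.append(run_replicate(config, i))
        except Exception:  # noqa: BLE001 - survey runs must not die mid-grid
            logger.exception(
                "replicate %d of scenario (%s, %s) failed",
                i,
                config.pi_I_trial,
                config.pi_C_trial,
            )
    return records


def summarize_scenario(
    config: ScenarioConfig,
    records: Sequence[ReplicateRecord],
    c_stars: Sequence[float] = DEFAULT_C_STARS,
    condition_on_authorization: bool = False,
) -> ScenarioSummary:
    """Aggregate replicates into a :class:`ScenarioSummary`.

    By default the estimate/bias/gain columns average over *all* replicates;
    with ``condition_on_authorization`` they average only over replicates
    whose interim metric cleared ``config.c_star`` (which biases the trial
    estimate upward — selection on a favorable interim).
    """
    if not records:
        raise ValueError("no successful replicates to summarize")
    metric = np.array(
        [r.interim.cp if Metric(config.metric) is Metric.CP else r.interim.pp for r in records]
    )
    reject = np.array([r.final.reject for r in records], dtype=bool)
    d_trial = np.array([r.final.d_trial for r in records])
    has_meta = records[0].shrinkage is not None
    theta_hat = (
        np.array([r.shrinkage.theta_hat for r in records]) if has_meta else None
    )
    gain_pct = (
        np.array([100.0 * r.shrinkage.gain for r in records]) if has_meta else None
    )

    freq_auth: dict[float, float] = {}
    freq_rej_auth: dict[float, float] = {}
    for c in c_stars:
        auth = metric >= c
        freq_auth[c] = float(auth.mean())
        freq_rej_auth[c] = float(reject[auth].mean()) if auth.any() else float("nan")

    sel = metric >= config.c_star if condition_on_authorization else np.ones(
        len(records), dtype=bool
    )
    delta = config.delta_trial
    n_total = config.resolve_n()
    t = config.resolve_t()
    m = rwd_sample_size(n_total, t)[0] if has_meta else 0
    return ScenarioSummary(
        config=config,
        n_total=n_total,
        t=t,
        m=m,
        n_reps=len(records),
        n_failures=config.n_reps - len(records),
        mean_metric=float(metric.mean()),
        sd_metric=float(metric.std(ddof=1)) if len(records) > 1 else 0.0,
        freq_reject=float(reject.mean()),
        freq_authorize=freq_auth,
        freq_reject_given_authorize=freq_rej_auth,
        mean_d_trial=float(d_trial[sel].mean()),
        bias_d_trial=float(d_trial[sel].mean() - delta),
        mean_theta_hat=float(theta_hat[sel].mean()) if has_meta else float("nan"),
        bias_theta_hat=float(theta_hat[sel].mean() - delta) if has_meta else float("nan"),
        mean_gain_percent=float(gain_pct[sel].mean()) if has_meta else float("nan"),
    )


def run_scenario_grid(
    configs: Iterable[ScenarioConfig],
    n_reps: int | None = None,
    c_stars: Sequence[float] = DEFAULT_C_STARS,
    condition_on_authorization: bool = False,
) -> list[ScenarioSummary]:
    """Run and summarize every scenario in ``configs``.

    ``n_reps`` overrides each config's replicate count (useful for quick
    reduced-replication passes).
    """
    summaries = []
    for cfg in configs:
        if n_reps is not None:
            cfg = replace(cfg, n_reps=n_reps)
        logger.info(
            "scenario piI=%s piC=%s t=%s piI_rwd=%s: %d reps",
            cfg.pi_I_trial,
            cfg.pi_C_trial,
            cfg.t,
            cfg.pi_I_rwd,
            cfg.n_reps,
        )
        records = run_replicates(cfg)
        summaries.append(
            summarize_scenario(cfg, records, c_stars, condition_on_authorization)
        )
    return summaries


def default_scenario_grid(
    metric: Metric = Metric.CP,
    n_reps: int = 5000,
    base_seed: int = 0,
    n_min: int = 60,
    n_max: int = 300,
    run_meta: bool = True,
) -> list[ScenarioConfig]:
    """The standard simulation-study grid.

    Trial device-arm rates in {0.7, 0.8, 0.9}, control rates 0.1/0.2/0.3
    below; designs kept only when ``n_min <= n <= n_max`` (at least 30 per
    arm keeps the normal approximation honest).  For each retained design,
    the interim time is solved for each target expected-metric level in
    {0.8, 0.85, 0.9} on the default t grid, and the RWD device-user rate is
    either far below the trial's (``pi_I - 0.6``) or matched to it; the RWD
    control rate always matches the trial's.  Deterministic, stably ordered.
    """
    configs: list[ScenarioConfig] = []
    for pi_I in (0.7, 0.8, 0.9):
        for gap in (0.3, 0.2, 0.1):
            pi_C = round(pi_I - gap, 10)
            n = sample_size_two_proportions(pi_I, pi_C)
            if not n_min <= n <= n_max:
                continue
            design = DesignSpec(pi_I, pi_C)
            for c_star in (0.8, 0.85, 0.9):
                t = solve_interim_time(
                    design, TimingQuery(c_star=c_star, metric=metric)
                )
                for pi_I_rwd in (round(pi_I - 0.6, 10), pi_I):
                    configs.append(
                        ScenarioConfig(
                            pi_I_trial=pi_I,
                            pi_C_trial=pi_C,
                            pi_I_rwd=pi_I_rwd,
                            pi_C_rwd=pi_C,
                            c_star=c_star,
                            metric=metric,
                            t=t,
                            n_reps=n_reps,
                            base_seed=base_seed,
                            run_meta=run_meta,
                        )
                    )
    return configs


def null_mode(
    configs: Iterable[ScenarioConfig],
    n_reps: int | None = None,
    c_stars: Sequence[float] = DEFAULT_C_STARS,
) -> list[ScenarioSummary]:
    """Re-run scenarios under the null: control rates imposed on both arms.

    Sets ``pi_I_trial = pi_C_trial`` (and the RWD analog), so ``freq_reject``
    is the realized type-I error and ``freq_authorize`` the frequency of
    erroneous temporary authorization.
    """
    nulled = [_null_config(cfg) for cfg in configs]
    return run_scenario_grid(nulled, n_reps=n_reps, c_stars=c_stars)


def _null_config(cfg: ScenarioConfig) -> ScenarioConfig:
    # null responses in every arm, but keep the planned n and t of the
    # alternative design (the design is fixed before the data are seen)
    return replace(
        cfg,
        pi_I_trial=cfg.pi_C_trial,
        pi_I_rwd=cfg.pi_C_rwd,
        t=cfg.resolve_t(),
        n_total=cfg.resolve_n(),
    )


def interim_final_frame(summaries: Sequence[ScenarioSummary]) -> pd.DataFrame:
    """Interim/final operating characteristics, one row per (design, t).

    Scenarios that share a design and interim time (e.g. the two RWD
    settings) are collapsed to the first occurrence, since the trial-side
    columns do not depend on the RWD population.
    """
    rows = []
    seen = set()
    for s in summaries:
        key = (s.config.pi_I_trial, s.config.pi_C_trial, s.t)
        if key in seen:
            continue
        seen.add(key)
        row = {
            "pi_I_trial": s.config.pi_I_trial,
            "pi_C_trial": s.config.pi_C_trial,
            "n": s.n_total,
            "t": s.t,
            "mean_CP": s.mean_metric,
            "sd_CP": s.sd_metric,
            "freq_p_le_alpha": s.freq_reject,
        }
        for c, v in s.freq_authorize.items():
            row[f"freq_CP_ge_{c}"] = v
            row[f"freq_p_le_alpha_given_CP_ge_{c}"] = s.freq_reject_given_authorize[c]
        rows.append(row)
    return pd.DataFrame(rows)


def meta_frame(summaries: Sequence[ScenarioSummary]) -> pd.DataFrame:
    """Meta-analysis summary, one row per (design, t, RWD population)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "pi_I_trial": s.config.pi_I_trial,
                "pi_C_trial": s.config.pi_C_trial,
                "n": s.n_total,
                "t": s.t,
                "pi_I_rwd": s.config.pi_I_rwd,
                "pi_C_rwd": s.config.pi_C_rwd,
                "m": s.m,
                "mean_d_trial": s.mean_d_trial,
                "mean_theta_hat": s.mean_theta_hat,
                "bias_d_trial": s.bias_d_trial,
                "bias_theta_hat": s.bias_theta_hat,
                "gain_percent": s.mean_gain_percent,
            }
        )
    return pd.DataFrame(rows)
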