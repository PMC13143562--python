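"""Synthetic two-arm trials with one interim look, plus parallel RWD cohorts.

The data-generating process: a binary-endpoint superiority trial with true
response rates ``(pi_I_trial, pi_C_trial)``, 1:1 allocation and no dropout.
Individual responses are Bernoulli draws; the interim analysis at information
time ``t`` reads the first ``n_t/2`` subjects of each arm (interim counts are
a prefix of the final counts, emulating continued accrual).  If the interim
metric clears the authorization threshold, a real-world cohort accrues in
parallel with the second half of the trial; its size equals the number of
trial entrants after time ``t``, ``m = n(1 - t)``, split equally between
device users and non-users, with its own true rates
``(pi_I_rwd, pi_C_rwd)``.

Each replicate runs the full pipeline: interim decision, final pooled
one-sided test, RWD summary, and the reference-model shrinkage meta-analysis
of the two (estimate, SE) pairs.  Everything is deterministic given
``(base_seed, replicate_index)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.stats import norm

from .design import Metric, conditional_power, predictive_power, z_statistic
from .shrinkage import (
    HeterogeneityPrior,
    ShrinkageResult,
    StudyEstimate,
    reference_model_posterior,
)

__all__ = [
    "TwoArmCounts",
    "ScenarioConfig",
    "InterimResult",
    "FinalResult",
    "RwdResult",
    "ReplicateRecord",
    "interim_sample_size",
    "rwd_sample_size",
    "simulate_trial",
    "interim_analysis",
    "final_analysis",
    "simulate_rwd",
    "run_replicate",
    "plugin_se",
]


@dataclass(frozen=True)
class TwoArmCounts:
    """Successes and totals for intervention (I) and control (C) arms."""

    x_I: int
    n_I: int
    x_C: int
    n_C: int

    def __post_init__(self) -> None:
        for x, n in ((self.x_I, self.n_I), (self.x_C, self.n_C)):
            if not 0 <= x <= n:
                raise ValueError(f"counts out of range: {x} successes of {n}")

    @property
    def p_I(self) -> float:
        return self.x_I / self.n_I

    @property
    def p_C(self) -> float:
        return self.x_C / self.n_C

    @property
    def diff(self) -> float:
        """Observed risk difference p_I - p_C."""
        return self.p_I - self.p_C

    def has_zero_cell(self) -> bool:
        return (
            self.x_I == 0
            or self.x_C == 0
            or self.x_I == self.n_I
            or self.x_C == self.n_C
        )


def plugin_se(counts: TwoArmCounts, n_I: int | None = None, n_C: int | None = None) -> float:
    """Unpooled plug-in SE of the risk difference, with zero-cell adjustment.

    ``sqrt(pI qI / nI + pC qC / nC)``, with rates estimated from ``counts``.
    If any of the four cells (successes/failures by arm) is zero, 0.5 is
    added to every cell *for the variance only* (point estimates are never
    adjusted), so the SE is strictly positive for any data.

    ``n_I``/``n_C`` override the denominators — used at interim, where the
    variance convention evaluates the plug-in rates at the full-trial per-arm
    size.
    """
    n_I = counts.n_I if n_I is None else n_I
    n_C = counts.n_C if n_C is None else n_C
    if counts.has_zero_cell():
        p_i = (counts.x_I + 0.5) / (counts.n_I + 1.0)
        p_c = (counts.x_C + 0.5) / (counts.n_C + 1.0)
    else:
        p_i, p_c = counts.p_I, counts.p_C
    return math.sqrt(p_i * (1.0 - p_i) / n_I + p_c * (1.0 - p_c) / n_C)


def interim_sample_size(n_total: int, t: float) -> int:
    """Interim total ``n_t``: ``t * n`` rounded to the nearest even integer."""
    if not 0.0 < t < 1.0:
        raise ValueError(f"information time must lie in (0, 1), got {t}")
    n_t = 2 * int(math.floor(t * n_total / 2.0 + 0.5))
    if n_t < 2:
        raise ValueError(f"interim at t={t} leaves no subjects (n={n_total})")
    return n_t


def rwd_sample_size(n_total: int, t: float) -> tuple[int, int, int]:
    """RWD cohort size ``m = n (1 - t)`` (nearest integer) and its arm split.

    Odd ``m`` puts the extra subject in the intervention arm.
    Raises if the cohort would be empty.
    """
    if not 0.0 < t < 1.0:
        raise ValueError(f"information time must lie in (0, 1), got {t}")
    m = int(math.floor(n_total * (1.0 - t) + 0.5))
    if m == 0:
        raise ValueError(
            f"no RWD accrual: n(1-t) rounds to zero for n={n_total}, t={t}"
        )
    m_I = (m + 1) // 2
    m_C = m // 2
    return m, m_I, m_C


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: trial design, interim rule, RWD population."""

    pi_I_trial: float
    pi_C_trial: float
    pi_I_rwd: float
    pi_C_rwd: float
    alpha: float = 0.025
    power: float = 0.9
    c_star: float = 0.8
    metric: Metric = Metric.CP
    t: float | Literal["auto"] = 0.5
    tau_scale: float = 0.5
    n_reps: int = 5000
    base_seed: int = 0
    run_meta: bool = True  # skip the meta-analysis for interim/final-only studies
    n_total: int | None = None  # explicit total size; required for null scenarios

    def __post_init__(self) -> None:
        for name in ("pi_I_trial", "pi_C_trial", "pi_I_rwd", "pi_C_rwd"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")
        if self.n_total is not None and (self.n_total < 2 or self.n_total % 2):
            raise ValueError(f"n_total must be a positive even integer, got {self.n_total}")

    @property
    def delta_trial(self) -> float:
        return self.pi_I_trial - self.pi_C_trial

    def resolve_n(self) -> int:
        """Total trial size: explicit if given, else derived from the design."""
        if self.n_total is not None:
            return self.n_total
        from .design import sample_size_two_proportions

        return sample_size_two_proportions(
            self.pi_I_trial, self.pi_C_trial, self.alpha, self.power
        )

    def resolve_t(self) -> float:
        if self.t == "auto":
            from .design import DesignSpec, TimingQuery, solve_interim_time

            design = DesignSpec(self.pi_I_trial, self.pi_C_trial, self.alpha, self.power)
            return solve_interim_time(
                design, TimingQuery(c_star=self.c_star, metric=self.metric)
            )
        return float(self.t)


@dataclass(frozen=True)
class InterimResult:
    """Interim look: observed state, z-statistic, CP/PP, authorization call."""

    t: float
    n_t: int
    counts: TwoArmCounts
    g_t: float
    k_hat: float
    z_t: float
    cp: float
    pp: float
    authorize: bool


@dataclass(frozen=True)
class FinalResult:
    """Final trial analysis: risk difference, unpooled SE, one-sided p-value."""

    d_trial: float
    sigma_trial: float
    p_value: float
    reject: bool


@dataclass(frozen=True)
class RwdResult:
    """RWD cohort summary feeding the meta-analysis as the secondary study."""

    counts: TwoArmCounts
    d_rwd: float
    sigma_rwd: float


@dataclass(frozen=True)
class ReplicateRecord:
    """One simulated pass through the full three-step framework."""

    config: ScenarioConfig
    replicate_index: int
    interim: InterimResult
    final_counts: TwoArmCounts
    final: FinalResult
    rwd: RwdResult | None
    shrinkage: ShrinkageResult | None


def _rng(base_seed: int, replicate_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([base_seed, replicate_index, stream])


def simulate_trial(
    config: ScenarioConfig, seed: int, replicate_index: int = 0
) -> tuple[TwoArmCounts, TwoArmCounts]:
    """Draw one trial; returns ``(final_counts, interim_counts)``.

    The interim counts are those of the first ``n_t/2`` subjects per arm, so
    they are a prefix of the final data.
    """
    n = config.resolve_n()
    t = config.resolve_t()
    n_t = interim_sample_size(n, t)
    per_arm = n // 2
    per_arm_t = n_t // 2
    rng = _rng(seed, replicate_index, 0)
    arm_I = rng.random(per_arm) < config.pi_I_trial
    arm_C = rng.random(per_arm) < config.pi_C_trial
    final = TwoArmCounts(int(arm_I.sum()), per_arm, int(arm_C.sum()), per_arm)
    interim = TwoArmCounts(
        int(arm_I[:per_arm_t].sum()), per_arm_t, int(arm_C[:per_arm_t].sum()), per_arm_t
    )
    return final, interim


def interim_analysis(
    counts: TwoArmCounts,
    t: float,
    n_total: int,
    alpha: float = 0.025,
    c_star: float = 0.8,
    metric: Metric = Metric.CP,
    k: float | None = None,
) -> InterimResult:
    """Interim decision: compute z_t, CP and PP, and the authorization call.

    The variance convention is plug-in: ``k_hat`` uses the interim response
    rates evaluated at the full-trial per-arm size ``n_total/2`` (the SD the
    final estimator would have if the interim rates were the truth).  Pass
    ``k`` to override with the design-stage (assumed-rates) value instead.
    Conditional power uses the empirical trend ``theta' = g_t``.
    """
    g_t = counts.diff
    per_arm = n_total // 2
    k_hat = k if k is not None else plugin_se(counts, n_I=per_arm, n_C=per_arm)
    z_t = z_statistic(g_t, t, k_hat)
    cp = conditional_power(z_t, t, theta_prime=g_t, k=k_hat, alpha=alpha)
    pp = predictive_power(z_t, t, alpha=alpha)
    value = cp if Metric(metric) is Metric.CP else pp
    return InterimResult(
        t=t,
        n_t=counts.n_I + counts.n_C,
        counts=counts,
        g_t=g_t,
        k_hat=k_hat,
        z_t=z_t,
        cp=cp,
        pp=pp,
        authorize=bool(value >= c_star),
    )


def final_analysis(counts: TwoArmCounts, alpha: float = 0.025) -> FinalResult:
    """Final one-sided test of equal proportions (pooled-variance z-test).

    The test statistic pools the two arms for the null variance,
    ``z = d / sqrt(pbar qbar (1/nI + 1/nC))`` with ``pbar`` the overall
    response rate, and ``p = 1 - Phi(z)``.  The reported ``sigma_trial`` is
    the *unpooled* plug-in SE (zero-cell adjusted), which downstream becomes
    the reference study's standard error in the meta-analysis.  A fully
    degenerate table (pooled variance zero) carries no evidence either way
    and yields p = 0.5.
    """
    d = counts.diff
    p_bar = (counts.x_I + counts.x_C) / (counts.n_I + counts.n_C)
    pooled_var = p_bar * (1.0 - p_bar) * (1.0 / counts.n_I + 1.0 / counts.n_C)
    if pooled_var > 0.0:
        z = d / math.sqrt(pooled_var)
        p_value = float(norm.sf(z))
    else:
        p_value = 0.5
    sigma = plugin_se(counts)
    return FinalResult(
        d_trial=d, sigma_trial=sigma, p_value=p_value, reject=bool(p_value <= alpha)
    )


def simulate_rwd(
    config: ScenarioConfig, m_I: int, m_C: int, seed: int, replicate_index: int = 0
) -> RwdResult:
    """Draw the parallel RWD cohort and summarize it as (d_rwd, sigma_rwd)."""
    if m_I < 1 or m_C < 1:
        raise ValueError(f"RWD arms must be nonempty, got ({m_I}, {m_C})")
    rng = _rng(seed, replicate_index, 1)
    x_I = int((rng.random(m_I) < config.pi_I_rwd).sum())
    x_C = int((rng.random(m_C) < config.pi_C_rwd).sum())
    counts = TwoArmCounts(x_I, m_I, x_C, m_C)
    return RwdResult(counts=counts, d_rwd=counts.diff, sigma_rwd=plugin_se(counts))


def run_replicate(config: ScenarioConfig, replicate_index: int) -> ReplicateRecord:
    """One full replicate: interim -> final -> RWD -> shrinkage meta-analysis.

    Deterministic given ``(config.base_seed, replicate_index)``.  The RWD
    cohort and the meta-analysis are produced unconditionally (whether the
    summary conditions on authorization is an aggregation choice, not a
    simulation one); set ``config.run_meta=False`` to skip them.
    """
    n = config.resolve_n()
    t = config.resolve_t()
    final_counts, interim_counts = simulate_trial(
        config, config.base_seed, replicate_index
    )
    interim = interim_analysis(
        interim_counts, t, n, config.alpha, config.c_star, config.metric
    )
    final = final_analysis(final_counts, config.alpha)
    rwd = None
    shrink = None
    if config.run_meta:
        _, m_I, m_C = rwd_sample_size(n, t)
        rwd = simulate_rwd(config, m_I, m_C, config.base_seed, replicate_index)
        shrink = reference_model_posterior(
            StudyEstimate(final.d_trial, final.sigma_trial, label="trial"),
            StudyEstimate(rwd.d_rwd, rwd.sigma_rwd, label="rwd"),
            HeterogeneityPrior(config.tau_scale),
        )
    return ReplicateRecord(
        config=config,
        replicate_index=replicate_index,
        interim=interim,
        final_counts=final_counts,
        final=final,
        rwd=rwd,
        shrinkage=shrink,
    )
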