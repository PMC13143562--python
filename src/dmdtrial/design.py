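"""Design-stage metrics for a two-arm superiority trial with one interim look.

A two-arm randomized trial (intervention vs. control, 1:1 allocation) tests
``H0: theta = 0`` against ``HA: theta > 0`` one-sided, where ``theta`` is the
difference in response probabilities.  At information time ``t`` (fraction of
the planned sample enrolled) the difference estimator ``G_t`` has variance
``k^2 / t``, with ``k`` the standard deviation of the full-sample estimator,
and the interim statistic is ``Z_t = G_t * sqrt(t) / k``.

The module provides the interim-monitoring quantities built on this z-scale
representation: conditional power (CP) given an assumed post-interim drift,
predictive power (PP, the flat-prior Bayesian average of CP), their
design-stage expectations over the distribution of ``Z_t`` under the
alternative, the probabilities that CP or PP exceed a threshold, and a grid
solver that picks the interim time whose expected metric is closest to a
target.  These are the decision tools for scheduling an interim analysis whose
only purpose is to support an application for temporary regulatory
authorization (no early stopping), so the usual multiplicity concerns do not
apply.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate
from scipy.stats import norm

__all__ = [
    "DesignSpec",
    "Metric",
    "TimingRule",
    "TimingQuery",
    "sample_size_two_proportions",
    "full_information_sd",
    "z_statistic",
    "conditional_power",
    "predictive_power",
    "expected_cp",
    "expected_pp",
    "prob_cp_exceeds",
    "prob_pp_exceeds",
    "solve_interim_time",
]

DEFAULT_T_GRID: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)


class InvalidDesignError(ValueError):
    """Raised when the requested design has a zero or negative effect."""


def sample_size_two_proportions(
    pi_I: float, pi_C: float, alpha: float = 0.025, power: float = 0.9
) -> int:
    """Total sample size for a one-sided two-sample test of proportions.

    Normal-approximation formula with the pooled standard deviation under the
    null and the unpooled one under the alternative; the per-arm size is the
    ceiling of

    ``[z_{1-alpha} sqrt(2 pbar qbar) + z_{1-beta} sqrt(pi_I q_I + pi_C q_C)]^2
    / (pi_I - pi_C)^2``

    with ``pbar = (pi_I + pi_C)/2``.  Returns the even total ``2 * per_arm``.
    """
    _check_prob("alpha", alpha)
    _check_prob("power", power)
    _check_prob("pi_I", pi_I)
    _check_prob("pi_C", pi_C)
    if pi_I <= pi_C:
        raise InvalidDesignError(
            f"superiority design requires pi_I > pi_C, got {pi_I} <= {pi_C}"
        )
    p_bar = 0.5 * (pi_I + pi_C)
    z_a = norm.ppf(1.0 - alpha)
    z_b = norm.ppf(power)
    num = z_a * math.sqrt(2.0 * p_bar * (1.0 - p_bar)) + z_b * math.sqrt(
        pi_I * (1.0 - pi_I) + pi_C * (1.0 - pi_C)
    )
    per_arm = math.ceil((num / (pi_I - pi_C)) ** 2)
    return 2 * per_arm


def full_information_sd(pi_I: float, pi_C: float, n_total: int) -> float:
    """SD ``k`` of the full-sample difference-in-proportions estimator.

    ``k = sqrt([pi_I(1-pi_I) + pi_C(1-pi_C)] / (n_total/2))`` under equal
    allocation.
    """
    if n_total <= 0 or n_total % 2:
        raise ValueError(f"n_total must be a positive even integer, got {n_total}")
    for name, p in (("pi_I", pi_I), ("pi_C", pi_C)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    return math.sqrt((pi_I * (1.0 - pi_I) + pi_C * (1.0 - pi_C)) / (n_total / 2))


def z_statistic(g_t: float, t: float, k: float) -> float:
    """Interim z-statistic ``z_t = g_t * sqrt(t) / k``.

    ``g_t`` is the observed effect estimate at information time ``t`` in
    (0, 1]; ``k`` is the SD of the full-information estimator.
    """
    if not 0.0 < t <= 1.0:
        raise ValueError(f"information time must lie in (0, 1], got {t}")
    if k <= 0.0:
        raise ValueError(f"k must be positive, got {k}")
    return g_t * math.sqrt(t) / k


def conditional_power(
    z_t: float, t: float, theta_prime: float, k: float, alpha: float = 0.025
) -> float:
    """Probability of final-analysis significance given the interim state.

    Conditional on ``Z_t = z_t`` and assuming the post-interim data drift at
    ``theta_prime`` (commonly the interim estimate itself — the "empirical
    trend" — or the design alternative),

    ``CP = Phi( [sqrt(t) z_t + theta' (1-t)/k - z_{1-alpha}] / sqrt(1-t) )``.
    """
    _check_interior_t(t)
    if k <= 0.0:
        raise ValueError(f"k must be positive, got {k}")
    z_a = norm.ppf(1.0 - alpha)
    num = math.sqrt(t) * z_t + theta_prime * (1.0 - t) / k - z_a
    return float(norm.cdf(num / math.sqrt(1.0 - t)))


def predictive_power(z_t: float, t: float, alpha: float = 0.025) -> float:
    """Flat-prior Bayesian predictive probability of final significance.

    Averages the conditional power over the posterior of the effect given the
    interim data under an improper uniform prior:

    ``PP = Phi( [sqrt(t) z_t - t z_{1-alpha}] / sqrt(t (1-t)) )``.

    Equivalently ``PP = Phi(sqrt(t) * Phi^{-1}(CP_empirical))``, which shows
    PP is CP shrunk toward 1/2 — the extra effect-size uncertainty always
    tempers the forecast.
    """
    _check_interior_t(t)
    z_a = norm.ppf(1.0 - alpha)
    num = math.sqrt(t) * z_t - t * z_a
    return float(norm.cdf(num / math.sqrt(t * (1.0 - t))))


def _empirical_cp_of_z(z: np.ndarray, t: float, z_a: float) -> np.ndarray:
    # CP under the empirical trend theta' = g_t, as a function of z_t only
    return norm.cdf((z / math.sqrt(t) - z_a) / math.sqrt(1.0 - t))


def _pp_of_z(z: np.ndarray, t: float, z_a: float) -> np.ndarray:
    return norm.cdf((math.sqrt(t) * z - t * z_a) / math.sqrt(t * (1.0 - t)))


def _expect_over_zt(fn, t: float, theta_A: float, k: float) -> float:
    """Integrate ``fn(z_t)`` against the N(sqrt(t) theta_A / k, 1) density."""
    mu = math.sqrt(t) * theta_A / k
    val, err = integrate.quad(
        lambda z: fn(z) * norm.pdf(z - mu),
        mu - 10.0,
        mu + 10.0,
        epsabs=1e-9,
        limit=200,
    )
    if not math.isfinite(val) or err > 1e-6:
        raise ArithmeticError(
            f"quadrature over the interim statistic failed: value={val}, abserr={err}"
        )
    return float(min(1.0, max(0.0, val)))


def expected_cp(t: float, theta_A: float, k: float, alpha: float = 0.025) -> float:
    """Design-stage expectation of the empirical-trend conditional power.

    Averages CP (with ``theta' = g_t``) over the distribution of the interim
    statistic ``Z_t ~ N(sqrt(t) theta_A / k, 1)`` under the alternative.
    Evaluated by adaptive quadrature over ``z_t`` in mean +/- 10 SD at
    absolute tolerance 1e-9.
    """
    _check_interior_t(t)
    if k <= 0.0:
        raise ValueError(f"k must be positive, got {k}")
    z_a = norm.ppf(1.0 - alpha)
    return _expect_over_zt(lambda z: _empirical_cp_of_z(z, t, z_a), t, theta_A, k)


def expected_pp(t: float, theta_A: float, k: float, alpha: float = 0.025) -> float:
    """Design-stage expectation of the predictive power; see ``expected_cp``."""
    _check_interior_t(t)
    if k <= 0.0:
        raise ValueError(f"k must be positive, got {k}")
    z_a = norm.ppf(1.0 - alpha)
    return _expect_over_zt(lambda z: _pp_of_z(z, t, z_a), t, theta_A, k)


def prob_cp_exceeds(
    t: float, c_star: float, theta_A: float, k: float, alpha: float = 0.025
) -> float:
    """P(empirical-trend CP >= c*) over the interim-statistic distribution.

    The event ``CP >= c*`` is equivalent to
    ``z_t >= sqrt(t) (z_{1-alpha} + sqrt(1-t) Phi^{-1}(c*))``, so the
    probability is an exact normal tail under
    ``Z_t ~ N(sqrt(t) theta_A / k, 1)``.
    """
    _check_interior_t(t)
    _check_prob("c_star", c_star)
    if k <= 0.0:
        raise ValueError(f"k must be positive, got {k}")
    z_a = norm.ppf(1.0 - alpha)
    threshold = math.sqrt(t) * (z_a + math.sqrt(1.0 - t) * norm.ppf(c_star))
    return float(norm.sf(threshold - math.sqrt(t) * theta_A / k))


def prob_pp_exceeds(
    t: float, c_star: float, theta_A: float, k: float, alpha: float = 0.025
) -> float:
    """P(PP >= c*) over the interim-statistic distribution.

    ``PP >= c*`` inverts to
    ``z_t >= sqrt(t) z_{1-alpha} + sqrt(1-t) Phi^{-1}(c*)``.
    """
    _check_interior_t(t)
    _check_prob("c_star", c_star)
    if k <= 0.0:
        raise ValueError(f"k must be positive, got {k}")
    z_a = norm.ppf(1.0 - alpha)
    threshold = math.sqrt(t) * z_a + math.sqrt(1.0 - t) * norm.ppf(c_star)
    return float(norm.sf(threshold - math.sqrt(t) * theta_A / k))


@dataclass(frozen=True)
class DesignSpec:
    """A planned two-arm trial: assumed rates, error rates, derived size.

    Parameters
    ----------
    pi_I, pi_C
        Assumed response probabilities under the alternative for the
        intervention and control arms; ``pi_I > pi_C``.
    alpha
        One-sided type-I error.
    power
        Target power ``1 - beta`` at the assumed rates.

    Derived attributes: ``n_total`` (even total sample size), ``theta_A``
    (effect under the alternative) and ``k`` (full-information SD of the
    difference estimator at the assumed rates).
    """

    pi_I: float
    pi_C: float
    alpha: float = 0.025
    power: float = 0.9

    def __post_init__(self) -> None:
        # triggers the validation, including InvalidDesignError for pi_I <= pi_C
        sample_size_two_proportions(self.pi_I, self.pi_C, self.alpha, self.power)

    @property
    def n_total(self) -> int:
        return sample_size_two_proportions(self.pi_I, self.pi_C, self.alpha, self.power)

    @property
    def theta_A(self) -> float:
        return self.pi_I - self.pi_C

    @property
    def k(self) -> float:
        return full_information_sd(self.pi_I, self.pi_C, self.n_total)


class Metric(str, enum.Enum):
    """Interim decision metric: conditional or predictive power."""

    CP = "CP"
    PP = "PP"


class TimingRule(str, enum.Enum):
    """How the interim time is selected on the grid."""

    EXPECTED_CLOSEST = "expected-closest"
    EXCEEDANCE = "exceedance"


@dataclass(frozen=True)
class TimingQuery:
    """Target for the interim-time solver.

    ``expected-closest`` picks the grid time whose expected metric is closest
    to ``c_star``; ``exceedance`` picks the time at which
    ``P(metric >= c_star)`` is closest to ``gamma``.
    """

    c_star: float = 0.8
    gamma: float = 0.5
    metric: Metric = Metric.CP
    rule: TimingRule = TimingRule.EXPECTED_CLOSEST
    t_grid: tuple[float, ...] = field(default=DEFAULT_T_GRID)

    def __post_init__(self) -> None:
        _check_prob("c_star", self.c_star)
        _check_prob("gamma", self.gamma)
        if len(self.t_grid) == 0:
            raise ValueError("t_grid must be nonempty")
        if any(not 0.0 < t < 1.0 for t in self.t_grid):
            raise ValueError(f"t_grid values must lie in (0, 1), got {self.t_grid}")


def solve_interim_time(design: DesignSpec, query: TimingQuery) -> float:
    """Pick the interim information time from the query's grid.

    Under the ``expected-closest`` rule, returns the grid ``t`` minimizing
    ``|E[metric](t) - c_star|``; under ``exceedance``, the ``t`` minimizing
    ``|P(metric >= c_star)(t) - gamma|``.  Ties break toward the smallest
    ``t`` — the framework exists to authorize early, so the earlier of two
    equally good looks is preferred.
    """
    metric = Metric(query.metric)
    rule = TimingRule(query.rule)
    if rule is TimingRule.EXPECTED_CLOSEST:
        fn = expected_cp if metric is Metric.CP else expected_pp
        objective = [
            abs(fn(t, design.theta_A, design.k, design.alpha) - query.c_star)
            for t in query.t_grid
        ]
    else:
        fn = prob_cp_exceeds if metric is Metric.CP else prob_pp_exceeds
        objective = [
            abs(fn(t, query.c_star, design.theta_A, design.k, design.alpha) - query.gamma)
            for t in query.t_grid
        ]
    order = sorted(range(len(query.t_grid)), key=lambda i: (objective[i], query.t_grid[i]))
    return float(query.t_grid[order[0]])


def timing_table(
    design: DesignSpec,
    c_star: float = 0.8,
    t_grid: Sequence[float] = DEFAULT_T_GRID,
):
    """Per-time summary of all four timing metrics, as a DataFrame.

    Columns: ``t``, ``E_CP``, ``E_PP``, ``P_CP_ge_c`` and ``P_PP_ge_c``.
    """
    import pandas as pd

    rows = []
    for t in t_grid:
        rows.append(
            {
                "t": t,
                "E_CP": expected_cp(t, design.theta_A, design.k, design.alpha),
                "E_PP": expected_pp(t, design.theta_A, design.k, design.alpha),
                "P_CP_ge_c": prob_cp_exceeds(t, c_star, design.theta_A, design.k, design.alpha),
                "P_PP_ge_c": prob_pp_exceeds(t, c_star, design.theta_A, design.k, design.alpha),
            }
        )
    return pd.DataFrame(rows)


def _check_prob(name: str, value: float) -> None:
    if not 0.0 < value < 1.0:
        raise ValueError(f"{name} must lie in (0, 1), got {value}")


def _check_interior_t(t: float) -> None:
    if not 0.0 < t < 1.0:
        raise ValueError(f"information time must lie in (0, 1), got {t}")
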