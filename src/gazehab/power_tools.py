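"""Effect sizes and power for the within-between interaction design.

The design of interest is a 2 (between: group) x 2 (within: test phase)
mixed ANOVA whose interaction term carries the hypothesis. Effect sizes
chain from a reported F statistic:

    eta_p^2 = F * df_effect / (F * df_effect + df_error)
    f       = sqrt(eta_p^2 / (1 - eta_p^2))

Power for the interaction F-test is available both in closed form via the
noncentral F distribution with noncentrality

    lambda = f^2 * N * m / (1 - rho)

(N total participants, m within-subject measurements, rho the
repeated-measures correlation) and by Monte-Carlo simulation from the
Gaussian cell-means model. For m = 2 the interaction test is algebraically
identical to a pooled two-sample t-test on within-subject difference
scores, which is how the simulation evaluates each replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import warnings

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError


def partial_eta_squared(F: float, df_effect: int, df_error: int) -> float:
    """Partial eta-squared from an F statistic and its degrees of freedom."""
    if F < 0:
        raise DataError("F statistic must be non-negative")
    if df_effect < 1 or df_error < 1:
        raise ConfigError("degrees of freedom must be >= 1")
    num = F * df_effect
    return num / (num + df_error)


def cohens_f(eta_p_sq: float) -> float:
    """Cohen's f from partial eta-squared: sqrt(eta / (1 - eta))."""
    if not 0 <= eta_p_sq < 1:
        raise ConfigError("eta_p_sq must be in [0, 1)")
    return math.sqrt(eta_p_sq / (1.0 - eta_p_sq))


@dataclass(frozen=True)
class EffectSize:
    """Effect-size chain from a reported ANOVA F statistic."""

    F: float
    df_effect: int
    df_error: int
    eta_p_sq: float
    f: float

    @classmethod
    def from_f_statistic(cls, F: float, df_effect: int, df_error: int) -> "EffectSize":
        eta = partial_eta_squared(F, df_effect, df_error)
        return cls(F=F, df_effect=df_effect, df_error=df_error, eta_p_sq=eta, f=cohens_f(eta))


@dataclass(frozen=True)
class PowerSpec:
    """Configuration of a power computation for the interaction test.

    rho defaults to 0: the repeated-measures correlation of the design is
    rarely reported alongside the effect size, and zero is the neutral
    choice under which the closed form and the simulation agree with the
    standard noncentrality convention above. It is a free parameter.
    """

    f: float
    n_total: int
    alpha: float = 0.05
    m: int = 2
    rho: float = 0.0
    n_groups: int = 2
    n_sims: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.n_total < 4:
            raise ConfigError("n_total must be >= 4")
        if self.m < 2:
            raise ConfigError("m must be >= 2")
        if not -1 < self.rho < 1:
            raise ConfigError("rho must be in (-1, 1)")
        if self.f < 0:
            raise ConfigError("f must be non-negative")


def analytic_power(spec: PowerSpec) -> float:
    """Closed-form power of the within-between interaction F-test."""
    df1 = (spec.n_groups - 1) * (spec.m - 1)
    df2 = (spec.n_total - spec.n_groups) * (spec.m - 1)
    lam = spec.f**2 * spec.n_total * spec.m / (1.0 - spec.rho)
    crit = stats.f.isf(spec.alpha, df1, df2)
    if lam == 0:  # ncf reduces to the central F; scipy's ncf is inexact here
        return float(stats.f.sf(crit, df1, df2))
    return float(stats.ncf.sf(crit, df1, df2, lam))


@dataclass(frozen=True)
class PowerEstimate:
    power: float
    mc_se: float
    n_sims: int
    analytic: float


def simulate_power(spec: PowerSpec) -> PowerEstimate:
    """Monte-Carlo power of the interaction test in the 2 x m Gaussian model.

    Each replicate draws balanced groups (an odd total puts the extra
    participant in group 1) from the cell-means model with standardized
    interaction effect f and compound-symmetric repeated measures with
    correlation rho, then evaluates the interaction F-test at alpha. For
    m = 2 this is computed exactly as the squared pooled two-sample t on
    difference scores, F(1, N-2). Returns the rejection proportion, its
    binomial standard error and the closed-form value for cross-checking.
    """
    if spec.m != 2 or spec.n_groups != 2:
        raise ConfigError("simulation implements the 2 (between) x 2 (within) design")
    if spec.n_sims < 100:
        warnings.warn("n_sims < 100 gives an unstable power estimate", stacklevel=2)
    rng = np.random.default_rng(spec.seed)
    n1 = spec.n_total - spec.n_total // 2
    n2 = spec.n_total // 2
    delta = spec.f  # cell means (+/- delta) with unit total variance
    sd_within = math.sqrt(1.0 - spec.rho)

    # y_iw = mu_gw + b_i + e_iw with Var(b) = rho, Var(e) = 1 - rho;
    # the subject effect b_i cancels in the difference score.
    e1 = rng.normal(size=(spec.n_sims, n1, 2)) * sd_within
    e2 = rng.normal(size=(spec.n_sims, n2, 2)) * sd_within
    d1 = (-2.0 * delta) + e1[..., 1] - e1[..., 0]  # group 1 cell means (+d, -d)
    d2 = (+2.0 * delta) + e2[..., 1] - e2[..., 0]  # group 2 cell means (-d, +d)

    m1, m2 = d1.mean(axis=1), d2.mean(axis=1)
    v1, v2 = d1.var(axis=1, ddof=1), d2.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (spec.n_total - 2)
    F = (m1 - m2) ** 2 / (sp2 * (1.0 / n1 + 1.0 / n2))
    p = stats.f.sf(F, 1, spec.n_total - 2)
    power = float(np.mean(p < spec.alpha))
    se = math.sqrt(power * (1.0 - power) / spec.n_sims)
    return PowerEstimate(power=power, mc_se=se, n_sims=spec.n_sims, analytic=analytic_power(spec))


def recruitment_target(n_required: int, attrition_rate: float) -> int:
    """Participants to recruit so that n_required survive the attrition rate."""
    if not 0 <= attrition_rate < 1:
        raise ConfigError("attrition_rate must be in [0, 1)")
    if n_required < 1:
        raise ConfigError("n_required must be >= 1")
    return math.ceil(n_required / (1.0 - attrition_rate))
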