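"""Effect-size and power utilities for plate-based screens.

Cohen's d with pooled standard deviation, the normal-approximation power of a
one-sample z test (the convention of R's ``pwr.norm.test``), the inverse
sample-size solver, and long-format power curves for plotting.

The normal (z) approximation treats the standardized effect d as the mean of a
unit-variance normal and asks how many replicates n are needed for the test
statistic ``sqrt(n) * d`` to clear the critical value:

    power(greater)   = Phi(sqrt(n)*d - z_{1-alpha})
    power(less)      = Phi(-sqrt(n)*d - z_{1-alpha})
    power(two_sided) = Phi(sqrt(n)*|d| - z_{1-alpha/2})
                       + Phi(-sqrt(n)*|d| - z_{1-alpha/2})

No t-distribution correction is applied; at screening-scale n the difference is
negligible and the z form is the field's convention for study design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

ALTERNATIVES = ("two_sided", "greater", "less")


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a power computation.

    d : Cohen's d (standardized mean difference, dimensionless)
    n : number of replicates (fields or wells)
    alpha : significance level
    alternative : 'two_sided', 'greater' or 'less'
    """

    d: float
    n: float
    alpha: float = 0.05
    alternative: str = "greater"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n <= 0:
            raise ValueError(f"n must be positive, got {self.n}")
        if self.alternative not in ALTERNATIVES:
            raise ValueError(
                f"alternative must be one of {ALTERNATIVES}, got {self.alternative!r}"
            )


@dataclass(frozen=True)
class EffectSizeResult:
    """Cohen's d between a treated and a control group (treated minus control)."""

    d: float
    n_treated: int
    n_control: int
    pooled_sd: float
    mean_treated: float = field(default=float("nan"))
    mean_control: float = field(default=float("nan"))


def cohens_d(treated, control) -> EffectSizeResult:
    """Cohen's d with pooled standard deviation, treated minus control.

    s_p^2 = ((n_t - 1) s_t^2 + (n_c - 1) s_c^2) / (n_t + n_c - 2), sample
    variances (n-1 denominator).  Raises if either group has fewer than two
    values or if the pooled SD is zero (d undefined).
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("both groups need at least 2 values for a pooled SD")
    nt, nc = t.size, c.size
    sp2 = ((nt - 1) * t.var(ddof=1) + (nc - 1) * c.var(ddof=1)) / (nt + nc - 2)
    sp = math.sqrt(sp2)
    if sp == 0:
        raise ValueError("pooled standard deviation is zero; Cohen's d undefined")
    return EffectSizeResult(
        d=(t.mean() - c.mean()) / sp,
        n_treated=nt,
        n_control=nc,
        pooled_sd=sp,
        mean_treated=t.mean(),
        mean_control=c.mean(),
    )


def power_of_test(spec: PowerSpec) -> float:
    """Normal-approximation power of the one-sample z test for `spec`."""
    d, n, alpha = spec.d, spec.n, spec.alpha
    rn = math.sqrt(n)
    if spec.alternative == "greater":
        return float(norm.cdf(rn * d - norm.ppf(1 - alpha)))
    if spec.alternative == "less":
        return float(norm.cdf(-rn * d - norm.ppf(1 - alpha)))
    zc = norm.ppf(1 - alpha / 2)
    return float(norm.cdf(rn * abs(d) - zc) + norm.cdf(-rn * abs(d) - zc))


def required_n(
    d: float,
    target_power: float,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> tuple[float, int]:
    """Replicates needed to reach `target_power` at effect size `d`.

    Returns ``(continuous_n, nearest_integer)``.  Closed form for the one-sided
    test: n = ((z_{1-alpha} + z_{power}) / d)^2; the two-sided case splits
    alpha and neglects the far-tail term (standard, conservative to < 1e-6 for
    any practical d).  The continuous value is the authoritative output; the
    integer is a nearest-integer convenience report.
    """
    if d == 0:
        raise ValueError("d = 0 requires infinitely many replicates")
    if not 0 < target_power < 1:
        raise ValueError(f"target power must be in (0, 1), got {target_power}")
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    a = alpha / 2 if alternative == "two_sided" else alpha
    n_cont = float(((norm.ppf(1 - a) + norm.ppf(target_power)) / abs(d)) ** 2)
    return n_cont, int(round(n_cont))


def power_curves(
    d_grid,
    n_grid,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Long-format (d, n, power) table over the Cartesian grid, for plotting."""
    d_grid = np.atleast_1d(np.asarray(d_grid, dtype=float))
    n_grid = np.atleast_1d(np.asarray(n_grid, dtype=float))
    if d_grid.size == 0 or n_grid.size == 0:
        raise ValueError("grids must be non-empty")
    rows = [
        (d, n, power_of_test(PowerSpec(d=d, n=n, alpha=alpha, alternative=alternative)))
        for d in d_grid
        for n in n_grid
    ]
    return pd.DataFrame(rows, columns=["d", "n", "power"])


def simulate_power(
    d: float,
    n: int,
    alpha: float = 0.05,
    alternative: str = "greater",
    n_reps: int = 20_000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo rejection rate of the one-sample z test (test oracle, not a
    feature of the analysis pipeline): draws `n_reps` samples of size `n` from
    N(d, 1) and applies the z test at level `alpha`."""
    rng = np.random.default_rng(seed)
    zbar = rng.normal(d, 1.0, size=(n_reps, n)).mean(axis=1) * math.sqrt(n)
    if alternative == "greater":
        return float(np.mean(zbar > norm.ppf(1 - alpha)))
    if alternative == "less":
        return float(np.mean(zbar < -norm.ppf(1 - alpha)))
    zc = norm.ppf(1 - alpha / 2)
    return float(np.mean(np.abs(zbar) > zc))
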