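"""Statistical primitives used across the pipeline.

One-way ANOVA, Tukey's HSD, the single-outlier Grubbs test, two-sample power /
sample-size via the noncentral-t distribution, the exact hypergeometric upper
tail, and least-squares regression through the origin.  Distribution functions
come from :mod:`scipy.stats`; the test statistics themselves are computed here
from textbook sums of squares so they can be cross-checked against independent
oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from ._errors import InsufficientDataError, ValidationError

__all__ = [
    "PowerSpec",
    "GrubbsResult",
    "TukeyResult",
    "grubbs_test",
    "anova_oneway",
    "tukey_hsd",
    "power_at",
    "sample_size",
    "hypergeom_tail",
    "origin_regression",
]


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a minimum-detectable-difference power analysis.

    ``delta`` and ``sd`` are on the same scale as the quantity being compared
    (here, average spectral counts).
    """

    delta: float
    sd: float
    power: float = 0.80
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValidationError("delta must be positive")
        if not self.sd > 0:
            raise ValidationError("sd must be positive")
        if not 0 < self.power < 1:
            raise ValidationError("power must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class GrubbsResult:
    outlier_index: int | None
    g_statistic: float
    critical_value: float


@dataclass(frozen=True)
class TukeyResult:
    """Pairwise Tukey HSD comparisons for one family of groups."""

    pairs: tuple[tuple[int, int], ...]
    mean_diffs: tuple[float, ...]
    p_adjusted: tuple[float, ...]
    alpha: float = 0.05
    reject: tuple[bool, ...] = field(default=())


def _as_1d(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


def grubbs_test(values: Sequence[float], alpha: float = 0.05) -> GrubbsResult:
    """Two-sided single-outlier Grubbs test.

    G = max|x - mean| / sd with the critical value from the closed form based
    on the Student-t quantile at alpha / (2n).  Returns the index of the
    flagged value, or None when G does not exceed the critical value.
    """
    x = _as_1d(values, "values")
    n = x.size
    if n < 3:
        raise InsufficientDataError("Grubbs test requires at least 3 values")
    sd = x.std(ddof=1)
    mean = x.mean()
    t_crit = sps.t.ppf(1 - alpha / (2 * n), n - 2)
    critical = (n - 1) / math.sqrt(n) * math.sqrt(t_crit**2 / (n - 2 + t_crit**2))
    if sd == 0:
        return GrubbsResult(None, 0.0, critical)
    deviations = np.abs(x - mean)
    idx = int(np.argmax(deviations))
    g = float(deviations[idx] / sd)
    return GrubbsResult(idx if g > critical else None, g, critical)


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA from sums of squares.

    Returns (F, p).  A fully degenerate input (no variance anywhere) yields
    F = 0, p = 1 so downstream filters stay total.
    """
    gs = [_as_1d(g, "group") for g in groups]
    if len(gs) < 2:
        raise ValidationError("ANOVA requires at least 2 groups")
    for g in gs:
        if g.size < 2:
            raise ValidationError("each group needs at least 2 observations")
    k = len(gs)
    n_total = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0 and ss_between == 0:
        return 0.0, 1.0
    if ss_within == 0:
        return math.inf, 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    return float(f), float(sps.f.sf(f, df_b, df_w))


def tukey_hsd(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> TukeyResult:
    """Tukey's honestly-significant-difference test (Tukey-Kramer for
    unequal group sizes), with p-values from the studentized-range
    distribution on the within-group degrees of freedom."""
    gs = [_as_1d(g, "group") for g in groups]
    if len(gs) < 2:
        raise ValidationError("Tukey HSD requires at least 2 groups")
    for g in gs:
        if g.size < 2:
            raise ValidationError("each group needs at least 2 observations")
    k = len(gs)
    df_w = sum(g.size for g in gs) - k
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    ms_within = ss_within / df_w
    pairs, diffs, pvals = [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            diff = gs[i].mean() - gs[j].mean()
            se = math.sqrt(ms_within / 2 * (1 / gs[i].size + 1 / gs[j].size))
            if se == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df_w))
            pairs.append((i, j))
            diffs.append(float(diff))
            pvals.append(p)
    reject = tuple(p <= alpha for p in pvals)
    return TukeyResult(tuple(pairs), tuple(diffs), tuple(pvals), alpha, reject)


def power_at(
    n: int, spec: PowerSpec, design: str = "two_sample", n_groups: int = 3
) -> float:
    """Power of the chosen design at ``n`` subjects per group.

    two_sample: two-sided two-sample t-test, noncentrality
    delta / (sd * sqrt(2/n)).  anova: one-way noncentral-F with group means
    (0, delta, 0, ...).
    """
    if n < 2:
        raise ValidationError("n per group must be at least 2")
    d = spec.delta / spec.sd
    if design == "two_sample":
        df = 2 * n - 2
        nc = d * math.sqrt(n / 2)
        t_crit = sps.t.ppf(1 - spec.alpha / 2, df)
        return float(sps.nct.sf(t_crit, df, nc) + sps.nct.cdf(-t_crit, df, nc))
    if design == "anova":
        means = np.zeros(n_groups)
        means[1] = spec.delta
        lam = n * ((means - means.mean()) ** 2).sum() / spec.sd**2
        df1, df2 = n_groups - 1, n_groups * (n - 1)
        f_crit = sps.f.ppf(1 - spec.alpha, df1, df2)
        return float(sps.ncf.sf(f_crit, df1, df2, lam))
    raise ValidationError(f"unknown design {design!r}")


def sample_size(
    spec: PowerSpec, design: str = "two_sample", n_max: int = 10_000
) -> int:
    """Smallest integer per-group n whose power reaches ``spec.power``."""
    for n in range(2, n_max + 1):
        if power_at(n, spec, design=design) >= spec.power:
            return n
    raise ValidationError(f"no n <= {n_max} attains power {spec.power}")


def hypergeom_tail(k: int, m: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeom(N, m, n).

    ``m`` is the subnetwork (category) size, ``n`` the number of draws
    (candidate proteins), ``N`` the universe size.
    """
    if not (0 <= k <= min(m, n) <= N):
        raise ValidationError(
            f"infeasible hypergeometric counts k={k}, m={m}, n={n}, N={N}"
        )
    return float(sps.hypergeom.sf(k - 1, N, m, n))


def origin_regression(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Least-squares fit of y = slope * x through the origin.

    Returns (slope, r_squared) where r_squared is the squared Pearson
    correlation of x and y (NaN when either vector has zero variance).
    """
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if xa.size != ya.size:
        raise ValidationError("x and y must have equal length")
    if xa.size < 2:
        raise InsufficientDataError("need at least 2 points")
    sxx = float(np.dot(xa, xa))
    if sxx == 0:
        raise ValidationError("cannot fit through origin: all x are zero")
    slope = float(np.dot(xa, ya) / sxx)
    if xa.std() == 0 or ya.std() == 0:
        return slope, float("nan")
    r = float(np.corrcoef(xa, ya)[0, 1])
    return slope, r * r
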