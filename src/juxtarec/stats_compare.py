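"""Group-comparison statistics: Welch t, Welch one-way ANOVA and the
Games–Howell post hoc test.

All p-values are two-sided.  Groups with zero variance are handled by a
seeded permutation fallback instead of dividing by zero; such results
are flagged.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["GroupSample", "TestResult", "welch_t", "welch_anova", "games_howell"]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSample:
    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def var(self) -> float:
        return float(np.var(self.values, ddof=1))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    labels: tuple[str, ...]
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0) and not math.isnan(self.p):
            raise StatsError(f"p-value out of range: {self.p}")


def _require_groups(groups: Sequence[GroupSample], min_groups: int = 2) -> None:
    if len(groups) < min_groups:
        raise StatsError(f"need at least {min_groups} groups")
    for g in groups:
        if g.n < 2:
            raise StatsError(f"group {g.label!r} has fewer than 2 values")


def _permutation_p_two_groups(
    a: GroupSample, b: GroupSample, n_perm: int = 10_000, seed: int = 0
) -> float:
    rng = np.random.default_rng(seed)
    pooled = np.array(a.values + b.values)
    observed = abs(a.mean - b.mean)
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        diff = abs(pooled[: a.n].mean() - pooled[a.n :].mean())
        if diff >= observed - 1e-15:
            count += 1
    return (count + 1) / (n_perm + 1)


def _permutation_p_anova(groups: Sequence[GroupSample], n_perm: int = 5_000,
                         seed: int = 0) -> tuple[float, float]:
    """Permutation fallback for heteroscedastic ANOVA with zero-variance
    groups: statistic is the size-weighted between-group sum of squares."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([g.values for g in groups])
    sizes = [g.n for g in groups]
    bounds = np.cumsum([0] + sizes)

    def stat(values: np.ndarray) -> float:
        grand = values.mean()
        return float(sum(n * (values[lo:hi].mean() - grand) ** 2
                         for n, lo, hi in zip(sizes, bounds[:-1], bounds[1:])))

    observed = stat(pooled)
    count = 0
    work = pooled.copy()
    for _ in range(n_perm):
        rng.shuffle(work)
        if stat(work) >= observed - 1e-15:
            count += 1
    return observed, (count + 1) / (n_perm + 1)


def welch_t(a: GroupSample, b: GroupSample) -> TestResult:
    """Two-sided Welch's t-test (unequal variances)."""
    _require_groups([a, b])
    va, vb = a.var / a.n, b.var / b.n
    denom = va + vb
    if denom == 0.0:
        p = 1.0 if a.mean == b.mean else _permutation_p_two_groups(a, b)
        return TestResult(0.0, float(min(a.n, b.n) - 1), p, (a.label, b.label),
                          flags=("zero_variance", "permutation_p"))
    t = (a.mean - b.mean) / math.sqrt(denom)
    df = denom**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), min(p, 1.0), (a.label, b.label))


def welch_anova(groups: Sequence[GroupSample]) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA (F* statistic).

    Weights are n_i/s_i^2; the statistic is referred to an F distribution
    with k-1 numerator df and the Welch-adjusted denominator df.
    """
    _require_groups(groups)
    k = len(groups)
    if any(g.var == 0.0 for g in groups):
        if len({g.mean for g in groups}) == 1 and all(g.var == 0.0 for g in groups):
            return TestResult(0.0, float(k - 1), 1.0, tuple(g.label for g in groups),
                              flags=("zero_variance",))
        statistic, p = _permutation_p_anova(groups)
        return TestResult(statistic, float(k - 1), p, tuple(g.label for g in groups),
                          flags=("zero_variance", "permutation_p"))
    w = np.array([g.n / g.var for g in groups])
    means = np.array([g.mean for g in groups])
    ns = np.array([g.n for g in groups])
    W = w.sum()
    grand = float((w * means).sum() / W)
    numerator = float((w * (means - grand) ** 2).sum()) / (k - 1)
    lam = float((((1.0 - w / W) ** 2) / (ns - 1)).sum())
    denominator = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * lam
    f_stat = numerator / denominator
    df1 = k - 1
    df2 = (k**2 - 1) / (3.0 * lam)
    p = float(stats.f.sf(f_stat, df1, df2))
    return TestResult(float(f_stat), float(df2), min(p, 1.0),
                      tuple(g.label for g in groups))


def games_howell(groups: Sequence[GroupSample]) -> list[TestResult]:
    """Games–Howell post hoc comparisons for all group pairs.

    For each pair, ``q = |mean_i - mean_j| / sqrt((v_i/n_i + v_j/n_j)/2)``
    is referred to the studentized-range distribution with k means and
    the pairwise Welch–Satterthwaite df.  Symmetric in pair order.
    """
    _require_groups(groups)
    k = len(groups)
    results = []
    for a, b in itertools.combinations(groups, 2):
        va, vb = a.var / a.n, b.var / b.n
        denom = va + vb
        if denom == 0.0:
            p = 1.0 if a.mean == b.mean else _permutation_p_two_groups(a, b)
            results.append(TestResult(0.0, float(min(a.n, b.n) - 1), p,
                                      (a.label, b.label),
                                      flags=("zero_variance", "permutation_p")))
            continue
        q = abs(a.mean - b.mean) / math.sqrt(denom / 2.0)
        df = denom**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
        p = float(stats.studentized_range.sf(q, k, df))
        results.append(TestResult(float(q), float(df), min(max(p, 0.0), 1.0),
                                  (a.label, b.label)))
    return results
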