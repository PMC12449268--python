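"""Closed-form recombination-frequency (Rf) estimators and genetic map functions.

Three experimental designs are supported, each with its own count type:

* fluorescent-seed scoring of F2 seed pools (:class:`SeedCounts`),
* two-point backcross progeny classes (:class:`BackcrossCounts`),
* two-point F2 phenotype classes in coupling phase
  (:class:`F2PhenotypeCounts`), estimated by maximum likelihood.

All estimators return an :class:`RfEstimate`.  Internally Rf is a
proportion; the seed estimator reports centimorgans because its closed
form is conventionally printed on that scale (helpers
:func:`cm_to_proportion` / :func:`proportion_to_cm` convert).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "SeedCounts",
    "BackcrossCounts",
    "F2PhenotypeCounts",
    "RfEstimate",
    "rf_from_seed_counts",
    "rf_from_backcross",
    "f2_loglik",
    "rf_from_f2_ml",
    "mean_family_rf",
    "sex_balanced_mean",
    "map_rf",
    "haldane_cm_to_rf",
    "haldane_rf_to_cm",
    "kosambi_cm_to_rf",
    "kosambi_rf_to_cm",
    "cm_to_proportion",
    "proportion_to_cm",
]


class EstimationError(ValueError):
    """Raised when counts are outside an estimator's domain."""


def _check_nonneg_int(name: str, value: int) -> int:
    if value < 0 or value != int(value):
        raise EstimationError(f"{name} must be a non-negative integer, got {value!r}")
    return int(value)


@dataclass(frozen=True)
class SeedCounts:
    """Fluorescent-seed scoring of an F2 seed pool.

    Attributes
    ----------
    g : int
        Number of green-only seeds.
    r : int
        Number of red-only seeds.
    n : int
        Total number of seeds scored.
    """

    g: int
    r: int
    n: int

    def __post_init__(self) -> None:
        _check_nonneg_int("g", self.g)
        _check_nonneg_int("r", self.r)
        _check_nonneg_int("n", self.n)
        if self.n <= 0:
            raise EstimationError("total seed count n must be > 0")
        if self.g + self.r > self.n:
            raise EstimationError("g + r cannot exceed n")

    @property
    def single_colour_fraction(self) -> float:
        return (self.g + self.r) / self.n


@dataclass(frozen=True)
class BackcrossCounts:
    """Two-point backcross progeny classes.

    ``a`` and ``d`` are the non-recombinant classes, ``b`` and ``c`` the
    recombinant ones.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            _check_nonneg_int(name, getattr(self, name))
        if self.n <= 0:
            raise EstimationError("total progeny count must be > 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class F2PhenotypeCounts:
    """Two-point F2 phenotype classes, coupling phase.

    ``a``: double dominant; ``b``: dominant/recessive; ``c``:
    recessive/dominant; ``d``: double recessive.  Both recessive alleles
    are assumed to come from the same parent (coupling), which fixes the
    class probabilities at (2+θ)/4, (1−θ)/4, (1−θ)/4, θ/4.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            _check_nonneg_int(name, getattr(self, name))
        if self.n <= 0:
            raise EstimationError("total progeny count must be > 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RfEstimate:
    """A recombination-fraction estimate with its standard error.

    ``rf`` and ``se`` are proportions for the ``backcross`` and ``f2_ml``
    methods and centimorgans for the ``seed`` method.  ``theta`` (the
    product of the male and female non-recombination probabilities) is
    present only for ``f2_ml``.
    """

    rf: float
    se: float
    n: int
    method: Literal["seed", "backcross", "f2_ml", "mean"]
    theta: float | None = None
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.se < 0:
            raise EstimationError("standard error cannot be negative")
        if (self.theta is not None) != (self.method == "f2_ml"):
            raise EstimationError("theta is present iff method == 'f2_ml'")


def cm_to_proportion(cm: float) -> float:
    """Convert centimorgans-as-percent-recombination to a proportion."""
    return cm / 100.0


def proportion_to_cm(p: float) -> float:
    return p * 100.0


def rf_from_seed_counts(counts: SeedCounts) -> RfEstimate:
    """Rf (cM) from single-colour recombinant seed fractions.

    Implements ``Rf = 100 (1 − sqrt(1 − 2(g+r)/n))``.  The single-colour
    fraction of an F2 seed pool relates to the per-meiosis recombination
    fraction x through f = x − x²/2, which this closed form inverts.

    The standard error (not part of the printed formula; documented
    extension) is the delta-method propagation of the binomial variance
    of f: ``se = 100 · sqrt(f(1−f)/n) / sqrt(1 − 2f)``.  At the domain
    boundary f = 1/2 the derivative diverges and the SE is reported as
    ``inf``.
    """
    f = counts.single_colour_fraction
    if 2.0 * f > 1.0:
        raise EstimationError(
            f"2(g+r)/n = {2 * f:.4f} > 1: seed estimator undefined"
        )
    root = math.sqrt(1.0 - 2.0 * f)
    rf_cm = 100.0 * (1.0 - root)
    if f == 0.0:
        se = 0.0
    elif root == 0.0:
        se = math.inf
    else:
        se = 100.0 * math.sqrt(f * (1.0 - f) / counts.n) / root
    return RfEstimate(rf=rf_cm, se=se, n=counts.n, method="seed")


def rf_from_backcross(counts: BackcrossCounts) -> RfEstimate:
    """Rf from backcross progeny: ``Rf = (b+c)/n``.

    The error is ``sqrt((b+c)(a+d)) / (n sqrt(n))``, which is exactly the
    binomial standard error ``sqrt(p(1−p)/n)`` of the recombinant
    fraction.
    """
    n = counts.n
    rec = counts.b + counts.c
    par = counts.a + counts.d
    rf = rec / n
    se = math.sqrt(rec * par) / (n * math.sqrt(n))
    return RfEstimate(rf=rf, se=se, n=n, method="backcross")


def f2_loglik(theta: float, counts: F2PhenotypeCounts) -> float:
    """Multinomial log-likelihood of θ for coupling-phase F2 classes.

    Class probabilities are (2+θ)/4, (1−θ)/4, (1−θ)/4 and θ/4.  Terms
    with a zero count are dropped (the 0·ln 0 = 0 convention), so the
    function is finite on the whole open-closed interval (0, 1] whenever
    the corresponding counts vanish.
    """
    if not (0.0 < theta <= 1.0):
        raise EstimationError(f"theta must lie in (0, 1], got {theta!r}")

    ll = 0.0
    if counts.a:
        ll += counts.a * math.log((2.0 + theta) / 4.0)
    bc = counts.b + counts.c
    if bc:
        if theta == 1.0:
            return -math.inf
        ll += bc * math.log((1.0 - theta) / 4.0)
    if counts.d:
        ll += counts.d * math.log(theta / 4.0)
    return ll


def rf_from_f2_ml(counts: F2PhenotypeCounts) -> RfEstimate:
    """Maximum-likelihood Rf from coupling-phase F2 phenotype classes.

    θ solves ``nθ² − (a−2b−2c−d)θ − 2d = 0``; the "+" branch is the only
    admissible root (the "−" branch is negative whenever d > 0).  Then
    ``Rf = 1 − sqrt(θ)`` — the complement of the geometric mean of the
    male and female non-recombination probabilities — with error
    ``e = sqrt((1−θ)(2+θ) / (2n(1+2θ)))``.
    """
    n = counts.n
    q = counts.a - 2 * counts.b - 2 * counts.c - counts.d
    if counts.d == 0 and q <= 0:
        raise EstimationError(
            "degenerate F2 counts: d = 0 and a - 2b - 2c - d <= 0 "
            "(log-likelihood has no interior maximum)"
        )
    theta = (q + math.sqrt(q * q + 8.0 * n * counts.d)) / (2.0 * n)
    flags: tuple[str, ...] = ()
    if theta > 1.0:
        warnings.warn(
            f"F2 ML root theta = {theta:.6f} > 1; clamped to 1 "
            "(sampling noise beyond independence)",
            stacklevel=2,
        )
        theta = 1.0
        flags = ("theta_clamped",)
    rf = 1.0 - math.sqrt(theta)
    se = math.sqrt((1.0 - theta) * (2.0 + theta) / (2.0 * n * (1.0 + 2.0 * theta)))
    return RfEstimate(rf=rf, se=se, n=n, method="f2_ml", theta=theta, flags=flags)


def mean_family_rf(
    estimates: Sequence[RfEstimate], min_family_size: int = 50
) -> tuple[RfEstimate, int]:
    """Unweighted mean Rf over families with more than ``min_family_size``
    individuals (strict inequality).

    Returns the pooled estimate and the number of excluded families.  The
    reported SE is the standard error of the family mean (SD of eligible
    family values over sqrt of their number; 0 for a single family).
    """
    if not estimates:
        raise EstimationError("no family estimates supplied")
    eligible = [e for e in estimates if e.n > min_family_size]
    excluded = len(estimates) - len(eligible)
    if not eligible:
        raise EstimationError(
            f"no family exceeds {min_family_size} individuals; cannot average"
        )
    values = np.array([e.rf for e in eligible], dtype=float)
    mean = float(values.mean())
    se = float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) > 1 else 0.0
    total_n = int(sum(e.n for e in eligible))
    return RfEstimate(rf=mean, se=se, n=total_n, method="mean"), excluded


def sex_balanced_mean(
    male: Sequence[float],
    female: Sequence[float],
    seed: int | np.random.Generator,
) -> float:
    """Mean Rf over male and female measurements at balanced sample sizes.

    When one sex has more measurements, a random subset of the larger
    group (without replacement) is drawn to match the smaller group's
    size; the pooled balanced values are then averaged.  Deterministic
    for a fixed seed.
    """
    if len(male) == 0 or len(female) == 0:
        raise EstimationError("both male and female measurement lists must be non-empty")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    m = np.asarray(male, dtype=float)
    f = np.asarray(female, dtype=float)
    k = min(m.size, f.size)
    if m.size > k:
        m = rng.choice(m, size=k, replace=False)
    elif f.size > k:
        f = rng.choice(f, size=k, replace=False)
    return float(np.concatenate([m, f]).mean())


# ---------------------------------------------------------------------------
# Map functions


def haldane_cm_to_rf(cm: float) -> float:
    """Haldane map function: rf = (1 − exp(−2d))/2 with d in Morgans."""
    d = cm / 100.0
    if d < 0:
        raise EstimationError("map distance must be >= 0")
    return (1.0 - math.exp(-2.0 * d)) / 2.0


def haldane_rf_to_cm(rf: float) -> float:
    if not (0.0 <= rf < 0.5):
        raise EstimationError("Haldane inverse requires 0 <= rf < 0.5")
    return -50.0 * math.log1p(-2.0 * rf)


def kosambi_cm_to_rf(cm: float) -> float:
    """Kosambi map function: rf = tanh(2d)/2 with d in Morgans."""
    d = cm / 100.0
    if d < 0:
        raise EstimationError("map distance must be >= 0")
    return math.tanh(2.0 * d) / 2.0


def kosambi_rf_to_cm(rf: float) -> float:
    if not (0.0 <= rf < 0.5):
        raise EstimationError("Kosambi inverse requires 0 <= rf < 0.5")
    return 25.0 * math.log((1.0 + 2.0 * rf) / (1.0 - 2.0 * rf))


_MAP_FUNCS = {
    ("haldane", "cm_to_rf"): haldane_cm_to_rf,
    ("haldane", "rf_to_cm"): haldane_rf_to_cm,
    ("kosambi", "cm_to_rf"): kosambi_cm_to_rf,
    ("kosambi", "rf_to_cm"): kosambi_rf_to_cm,
}


def map_rf(
    value: float,
    model: Literal["haldane", "kosambi"] = "haldane",
    direction: Literal["cm_to_rf", "rf_to_cm"] = "cm_to_rf",
) -> float:
    """Convert between genetic map distance (cM) and recombination fraction."""
    try:
        func = _MAP_FUNCS[(model, direction)]
    except KeyError:
        raise EstimationError(f"unknown map model/direction: {model!r}/{direction!r}")
    return func(value)
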