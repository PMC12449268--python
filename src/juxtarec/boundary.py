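"""Boundary-distance crossover analysis.

Relates each individual's measured interval Rf to the distance between
its heterozygous measurement interval and the nearest homozygous
boundary, and to the length of the adjacent homozygous block: group by
binned distance, correlate group mean Rf with bin midpoint by Spearman
rank, and fit a low-degree polynomial trend to the per-individual data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "IndividualGenotype",
    "IndividualExcluded",
    "boundary_distance",
    "adjacent_hom_length",
    "group_and_correlate",
    "poly_trend",
    "PolyFit",
    "CorrelationResult",
]

Side = Literal["left", "right", "nearest"]


class IndividualExcluded(Exception):
    """Signals that an individual cannot enter the analysis (with a reason)."""


@dataclass(frozen=True)
class IndividualGenotype:
    """One plant: HOM/HET segments, measured interval and its Rf (cM)."""

    sample_id: str
    segments: tuple[tuple[int, int, str], ...]
    interval: tuple[int, int]
    rf: float

    def het_segment(self) -> tuple[int, int]:
        """The HET segment fully containing the measurement interval."""
        lo, hi = self.interval
        for start, end, state in self.segments:
            if state == "HET" and start <= lo and hi <= end:
                return (start, end)
        raise IndividualExcluded(
            f"{self.sample_id}: measurement interval {self.interval} is not "
            "fully inside a heterozygous segment"
        )

    @property
    def chrom_span(self) -> tuple[int, int]:
        return (self.segments[0][0], self.segments[-1][1])


def boundary_distance(ind: IndividualGenotype, side: Side = "nearest") -> int | None:
    """Distance (bp) from the interval edge to the HOM boundary of its
    HET segment, or ``None`` if the HET segment reaches the chromosome
    end on that side."""
    seg_lo, seg_hi = ind.het_segment()
    chrom_lo, chrom_hi = ind.chrom_span
    left = None if seg_lo <= chrom_lo else ind.interval[0] - seg_lo
    right = None if seg_hi >= chrom_hi else seg_hi - ind.interval[1]
    if side == "left":
        return left
    if side == "right":
        return right
    if side == "nearest":
        candidates = [d for d in (left, right) if d is not None]
        return min(candidates) if candidates else None
    raise ValueError(f"unknown side {side!r}")


def adjacent_hom_length(ind: IndividualGenotype, side: Side = "nearest") -> int | None:
    """Length (bp) of the HOM segment immediately beyond the HET boundary.

    For ``side='nearest'`` the side with the smaller boundary distance is
    used.  Returns ``None`` when no boundary (and hence no adjacent HOM
    block) exists on the requested side.
    """
    seg_lo, seg_hi = ind.het_segment()
    if side == "nearest":
        left_d = boundary_distance(ind, "left")
        right_d = boundary_distance(ind, "right")
        if left_d is None and right_d is None:
            return None
        if right_d is None or (left_d is not None and left_d <= right_d):
            side = "left"
        else:
            side = "right"
    segs = list(ind.segments)
    idx = next(i for i, (s, e, _) in enumerate(segs) if (s, e) == (seg_lo, seg_hi))
    j = idx - 1 if side == "left" else idx + 1
    if j < 0 or j >= len(segs):
        return None
    s, e, state = segs[j]
    if state != "HOM":  # adjacent segment should be HOM after normalization
        return None
    return e - s


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n_groups: int
    flags: tuple[str, ...] = ()


def group_and_correlate(
    inds: Sequence[IndividualGenotype],
    key: Literal["distance", "hom_length"] = "distance",
    bin_width: int = 1_000_000,
    side: Side = "nearest",
) -> tuple[pd.DataFrame, CorrelationResult]:
    """Bin individuals by boundary distance (or adjacent HOM length) and
    Spearman-correlate bin midpoints with group mean Rf.

    Individuals whose interval is not fully heterozygous, or whose key is
    undefined (no boundary on the requested side), are excluded and
    logged.  Requires at least 3 non-empty groups.  Ties get average
    ranks; the two-sided p-value uses the t approximation.
    """
    key_fn = boundary_distance if key == "distance" else adjacent_hom_length
    records = []
    for ind in inds:
        try:
            value = key_fn(ind, side)
        except IndividualExcluded as exc:
            logger.info("excluded: %s", exc)
            continue
        if value is None:
            logger.info("excluded: %s has no %s boundary (%s)", ind.sample_id, side, key)
            continue
        records.append((ind.sample_id, value, ind.rf, value // bin_width))
    if not records:
        raise ValueError("no individuals eligible for grouping")
    df = pd.DataFrame(records, columns=["sample_id", key, "rf", "bin"])
    groups = (
        df.groupby("bin")
        .agg(n=("rf", "size"), mean_rf=("rf", "mean"))
        .reset_index()
    )
    groups["bin_start"] = groups["bin"] * bin_width
    groups["bin_end"] = groups["bin_start"] + bin_width
    groups["midpoint"] = groups["bin_start"] + bin_width / 2
    if len(groups) < 3:
        raise ValueError(f"need >= 3 non-empty groups, got {len(groups)}")
    if groups["mean_rf"].nunique() == 1:
        return df, CorrelationResult(
            rho=float("nan"), p=float("nan"), n_groups=len(groups),
            flags=("undefined_correlation",),
        )
    rho, p = stats.spearmanr(groups["midpoint"], groups["mean_rf"])
    result = CorrelationResult(rho=float(rho), p=float(p), n_groups=len(groups))
    df.attrs["groups"] = groups
    return df, result


@dataclass(frozen=True)
class PolyFit:
    coeffs: np.ndarray  # ascending powers
    x: np.ndarray
    fitted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float), self.coeffs)


def poly_trend(
    inds: Sequence[IndividualGenotype],
    degree: int = 3,
    side: Side = "nearest",
) -> PolyFit:
    """Ordinary least-squares polynomial of per-individual Rf on boundary
    distance, with a pointwise 95% confidence band."""
    xs, ys = [], []
    for ind in inds:
        try:
            d = boundary_distance(ind, side)
        except IndividualExcluded:
            continue
        if d is None:
            continue
        xs.append(float(d))
        ys.append(float(ind.rf))
    x = np.asarray(xs)
    y = np.asarray(ys)
    if len(np.unique(x)) <= degree:
        raise ValueError(
            f"need more than {degree} distinct x values, got {len(np.unique(x))}"
        )
    # scale x for conditioning; coefficients reported on the original scale
    x_scale = max(np.abs(x).max(), 1.0)
    design = np.vander(x / x_scale, degree + 1, increasing=True)
    coef_scaled, *_ = np.linalg.lstsq(design, y, rcond=None)
    coeffs = coef_scaled / x_scale ** np.arange(degree + 1)

    fitted = design @ coef_scaled
    resid = y - fitted
    dof = max(len(y) - (degree + 1), 1)
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(design.T @ design)
    band_var = sigma2 * np.einsum("ij,jk,ik->i", design, xtx_inv, design)
    half = stats.t.ppf(0.975, dof) * np.sqrt(np.maximum(band_var, 0.0))
    return PolyFit(coeffs=coeffs, x=x, fitted=fitted, ci_low=fitted - half, ci_high=fitted + half)
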