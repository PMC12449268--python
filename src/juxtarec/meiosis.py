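"""Meiosis simulator with a crossover-redistribution ("juxtaposition") model.

A chromosome pair is described by a piecewise-constant crossover-rate
profile (:class:`RecombinationLandscape`, cM/Mb) and a HOM/HET interval
structure (:class:`ZygosityMap`).  :func:`remodel_landscape` applies a
multiplicative stimulation kernel to heterozygous windows near
homozygous boundaries, funded — when ``conserve`` is on — by
proportional depletion of recombinationally active homozygous windows
near the same boundary, so that total genetic map length is preserved.

Gametes are drawn under a no-interference (Poisson) model, which makes
the Haldane map function an exact oracle for two-point recombinant
fractions.  :func:`simulate_cross` scores gametes for each of the three
experimental designs consumed by :mod:`juxtarec.rf_estimators`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .rf_estimators import (
    BackcrossCounts,
    F2PhenotypeCounts,
    RfEstimate,
    SeedCounts,
    rf_from_backcross,
    rf_from_f2_ml,
    rf_from_seed_counts,
)

__all__ = [
    "RecombinationLandscape",
    "ZygosityMap",
    "JuxtapositionModel",
    "Gamete",
    "CrossDesign",
    "Scenario",
    "remodel_landscape",
    "sample_gamete",
    "simulate_cross",
    "simulate_experiment",
    "map_length",
    "default_scenario",
]

_MAP_TOL = 1e-9


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class RecombinationLandscape:
    """Piecewise-constant crossover-rate profile of one chromosome.

    ``windows`` is an ordered list of ``(start_bp, end_bp, rate_cM_per_Mb)``
    tiling ``[0, chrom_length)`` without gaps or overlaps.
    """

    chrom_length: int
    windows: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        if self.chrom_length <= 0:
            raise SimulationError("chrom_length must be positive")
        if not self.windows:
            raise SimulationError("landscape needs at least one window")
        prev_end = 0
        for start, end, rate in self.windows:
            if start != prev_end or end <= start:
                raise SimulationError("windows must tile [0, chrom_length) in order")
            if rate < 0:
                raise SimulationError("rates must be >= 0")
            prev_end = end
        if prev_end != self.chrom_length:
            raise SimulationError("windows must end at chrom_length")

    @staticmethod
    def from_arrays(
        chrom_length: int, starts: Iterable[int], ends: Iterable[int], rates: Iterable[float]
    ) -> "RecombinationLandscape":
        wins = tuple((int(s), int(e), float(r)) for s, e, r in zip(starts, ends, rates))
        return RecombinationLandscape(chrom_length, wins)

    @staticmethod
    def uniform(chrom_length: int, rate_cm_per_mb: float) -> "RecombinationLandscape":
        return RecombinationLandscape(chrom_length, ((0, chrom_length, rate_cm_per_mb),))

    @property
    def starts(self) -> np.ndarray:
        return np.array([w[0] for w in self.windows], dtype=float)

    @property
    def ends(self) -> np.ndarray:
        return np.array([w[1] for w in self.windows], dtype=float)

    @property
    def rates(self) -> np.ndarray:
        return np.array([w[2] for w in self.windows], dtype=float)

    @property
    def window_map_cm(self) -> np.ndarray:
        """Genetic length of each window, cM."""
        return self.rates * (self.ends - self.starts) / 1e6

    @property
    def total_map_cm(self) -> float:
        return float(self.window_map_cm.sum())

    @property
    def total_map_morgans(self) -> float:
        return self.total_map_cm / 100.0

    def cumulative_cm(self) -> tuple[np.ndarray, np.ndarray]:
        """Breakpoints (bp) and cumulative genetic position (cM) at them."""
        bp = np.concatenate([[0.0], self.ends])
        cm = np.concatenate([[0.0], np.cumsum(self.window_map_cm)])
        return bp, cm

    def genetic_position(self, bp: float | np.ndarray) -> np.ndarray:
        """Cumulative genetic position (cM) at physical position(s)."""
        edges_bp, edges_cm = self.cumulative_cm()
        return np.interp(np.asarray(bp, dtype=float), edges_bp, edges_cm)

    def scaled(self, factor: float) -> "RecombinationLandscape":
        """Uniformly scale all rates (e.g. a per-sex multiplier)."""
        if factor < 0:
            raise SimulationError("scale factor must be >= 0")
        return RecombinationLandscape(
            self.chrom_length, tuple((s, e, r * factor) for s, e, r in self.windows)
        )


def map_length(landscape: RecombinationLandscape, from_bp: float, to_bp: float) -> float:
    """Genetic length (cM) of ``[from_bp, to_bp)`` under ``landscape``."""
    if not (0 <= from_bp <= to_bp <= landscape.chrom_length):
        raise SimulationError("need 0 <= from_bp <= to_bp <= chrom_length")
    pos = landscape.genetic_position(np.array([from_bp, to_bp]))
    return float(pos[1] - pos[0])


ZygosityState = Literal["HOM", "HET"]


@dataclass(frozen=True)
class ZygosityMap:
    """HOM/HET interval structure of a chromosome pair.

    Segments tile the chromosome; construction normalizes them so that
    adjacent segments always differ in state.
    """

    chrom_length: int
    segments: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end, state in self.segments:
            if start != prev_end or end <= start:
                raise SimulationError("zygosity segments must tile the chromosome")
            if state not in ("HOM", "HET"):
                raise SimulationError(f"unknown zygosity state {state!r}")
            prev_end = end
        if prev_end != self.chrom_length:
            raise SimulationError("zygosity segments must end at chrom_length")
        object.__setattr__(self, "segments", self._normalize(self.segments))

    @staticmethod
    def _normalize(segments) -> tuple[tuple[int, int, str], ...]:
        merged: list[list] = []
        for start, end, state in segments:
            if merged and merged[-1][2] == state:
                merged[-1][1] = end
            else:
                merged.append([start, end, state])
        return tuple((s, e, st) for s, e, st in merged)

    @staticmethod
    def from_het_intervals(
        chrom_length: int, het: Sequence[tuple[int, int]]
    ) -> "ZygosityMap":
        """Build a map that is HOM everywhere except the given HET intervals."""
        segs: list[tuple[int, int, str]] = []
        pos = 0
        for start, end in sorted(het):
            if start < pos:
                raise SimulationError("HET intervals must be sorted and disjoint")
            if start > pos:
                segs.append((pos, start, "HOM"))
            segs.append((start, end, "HET"))
            pos = end
        if pos < chrom_length:
            segs.append((pos, chrom_length, "HOM"))
        return ZygosityMap(chrom_length, tuple(segs))

    def state_at(self, bp: float) -> str:
        for start, end, state in self.segments:
            if start <= bp < end:
                return state
        raise SimulationError(f"position {bp} outside chromosome")

    @property
    def states(self) -> set[str]:
        return {s for _, _, s in self.segments}


@dataclass(frozen=True)
class JuxtapositionModel:
    """Parameters of the crossover-redistribution kernel.

    strength
        Maximum multiplicative stimulation of a heterozygous window at a
        HOM/HET boundary (the factor is ``1 + strength`` there).
    decay_cm
        Exponential decay scale of the stimulation, in genetic distance
        on the *base* map; also the reach within which homozygous donor
        windows fund the stimulation.
    activity_threshold
        cM/Mb below which a homozygous window can neither activate a
        boundary nor donate map length.
    conserve
        Whether the total genetic map length is held fixed by depleting
        donors (default: yes).
    """

    strength: float = 2.0
    decay_cm: float = 20.0
    activity_threshold: float = 0.5
    conserve: bool = True

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise SimulationError("strength must be >= 0")
        if self.decay_cm <= 0:
            raise SimulationError("decay_cm must be > 0")
        if self.activity_threshold < 0:
            raise SimulationError("activity_threshold must be >= 0")


def _refine(
    base: RecombinationLandscape, zyg: ZygosityMap, resolution_bp: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split the landscape at zygosity boundaries and to <= resolution_bp.

    Returns (edges_bp, rates, is_het) with len(edges) = len(rates) + 1.
    """
    cuts = {0, base.chrom_length}
    cuts.update(int(e) for _, e, _ in base.windows)
    cuts.update(int(e) for _, e, _ in zyg.segments)
    edges = sorted(cuts)
    fine: list[int] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        n_sub = max(1, math.ceil((hi - lo) / resolution_bp))
        fine.extend(lo + (hi - lo) * k // n_sub for k in range(n_sub))
    fine.append(int(base.chrom_length))
    edges_bp = np.asarray(fine, dtype=float)
    mids = (edges_bp[:-1] + edges_bp[1:]) / 2.0
    idx = np.searchsorted(base.ends, mids, side="right")
    rates = base.rates[idx]
    zyg_ends = np.array([e for _, e, _ in zyg.segments], dtype=float)
    zyg_het = np.array([s == "HET" for _, _, s in zyg.segments])
    is_het = zyg_het[np.searchsorted(zyg_ends, mids, side="right")]
    return edges_bp, rates, is_het


def remodel_landscape(
    base: RecombinationLandscape,
    zyg: ZygosityMap,
    model: JuxtapositionModel,
    resolution_bp: int = 100_000,
) -> RecombinationLandscape:
    """Redistribute crossover rate toward heterozygous windows near
    recombinationally active homozygous boundaries.

    Each heterozygous window is multiplied by ``1 + S exp(-g/delta)``
    where ``g`` is the genetic distance (on the base map) from the window
    midpoint to the nearest *active* HOM/HET boundary — one whose
    homozygous side carries rate >= ``activity_threshold`` within
    ``delta``.  With ``conserve`` on, the added map length attributed to
    each boundary is removed proportionally from active homozygous donor
    windows within ``delta`` of that boundary; if donors cannot fund the
    demand the stimulation from that boundary is scaled down (with a
    warning) so rates never go negative and total map length is
    conserved.  Fully homozygous or fully heterozygous chromosomes are
    returned unchanged.
    """
    if zyg.chrom_length != base.chrom_length:
        raise SimulationError("zygosity map and landscape cover different chromosomes")
    if model.strength == 0.0 or len(zyg.states) < 2:
        return base

    edges_bp, rates, is_het = _refine(base, zyg, resolution_bp)
    lens_mb = np.diff(edges_bp) / 1e6
    map_cm = rates * lens_mb
    cum_cm = np.concatenate([[0.0], np.cumsum(map_cm)])
    mid_cm = (cum_cm[:-1] + cum_cm[1:]) / 2.0

    # Boundary genetic positions, with the HOM side recorded.
    boundaries: list[tuple[float, int]] = []  # (genetic pos, hom side: -1 left/+1 right)
    for i in range(1, len(rates)):
        if is_het[i] != is_het[i - 1]:
            hom_side = -1 if is_het[i] else +1
            boundaries.append((cum_cm[i], hom_side))

    delta = model.decay_cm
    thr = model.activity_threshold
    active = rates >= thr

    def _is_active_boundary(g_b: float, hom_side: int) -> bool:
        if hom_side < 0:
            mask = (~is_het) & (mid_cm < g_b) & (g_b - mid_cm <= delta)
        else:
            mask = (~is_het) & (mid_cm >= g_b) & (mid_cm - g_b <= delta)
        return bool(np.any(mask & active))

    active_bounds = [(g, side) for g, side in boundaries if _is_active_boundary(g, side)]
    if not active_bounds:
        return base

    bound_g = np.array([g for g, _ in active_bounds])
    # Nearest active boundary per window (genetic distance from midpoint).
    dists = np.abs(mid_cm[:, None] - bound_g[None, :])
    nearest = np.argmin(dists, axis=1)
    g_near = dists[np.arange(len(rates)), nearest]

    stim = np.where(is_het, model.strength * np.exp(-g_near / delta), 0.0)
    gain = map_cm * stim  # extra cM requested per window

    new_map = map_cm.copy()
    if not model.conserve:
        new_map += gain
    else:
        remaining = np.where((~is_het) & active, map_cm, 0.0).copy()
        for b_idx, (g_b, _side) in enumerate(active_bounds):
            sel = is_het & (nearest == b_idx)
            demand = float(gain[sel].sum())
            if demand <= 0.0:
                continue
            donors = (~is_het) & active & (np.abs(mid_cm - g_b) <= delta)
            capacity = float(remaining[donors].sum())
            scale = 1.0
            if capacity < demand:
                scale = capacity / demand if demand > 0 else 0.0
                warnings.warn(
                    "insufficient donor map length near boundary at "
                    f"{g_b:.3f} cM: stimulation scaled by {scale:.3f}",
                    stacklevel=2,
                )
            take = demand * scale
            if capacity > 0:
                frac = take / capacity
                new_map[donors] -= remaining[donors] * frac
                remaining[donors] *= 1.0 - frac
            new_map[sel] += gain[sel] * scale

    new_rates = np.where(lens_mb > 0, new_map / lens_mb, 0.0)
    new_rates = np.maximum(new_rates, 0.0)
    out = RecombinationLandscape.from_arrays(
        base.chrom_length, edges_bp[:-1], edges_bp[1:], new_rates
    )
    if model.conserve:
        drift = abs(out.total_map_cm - base.total_map_cm)
        if drift > max(_MAP_TOL, 1e-9 * base.total_map_cm):  # pragma: no cover
            raise SimulationError(f"map length not conserved (drift {drift:.3e} cM)")
    return out


@dataclass(frozen=True)
class Gamete:
    """One meiotic product: crossover breakpoints plus starting phase."""

    breakpoints: tuple[float, ...]
    start_phase: int

    def __post_init__(self) -> None:
        if self.start_phase not in (0, 1):
            raise SimulationError("start_phase must be 0 or 1")
        if any(b >= a for a, b in zip(self.breakpoints[1:], self.breakpoints)):
            raise SimulationError("breakpoints must be strictly increasing")

    def phase_at(self, bp: float) -> int:
        crossed = sum(1 for x in self.breakpoints if x <= bp)
        return (self.start_phase + crossed) % 2


def _sample_breakpoint_sets(
    landscape: RecombinationLandscape,
    n: int,
    rng: np.random.Generator,
    obligate_co: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized draw of crossover positions for ``n`` gametes.

    Returns (positions, counts): flat bp positions grouped by gamete
    (unsorted within gametes) and the per-gamete crossover counts.
    Counts are Poisson with mean = total map length in Morgans;
    positions are i.i.d. with density proportional to the local rate.
    """
    mean = landscape.total_map_morgans
    counts = rng.poisson(mean, size=n)
    if obligate_co:
        if mean <= 0:
            raise SimulationError("obligate crossover impossible on a zero-length map")
        zero = counts == 0
        while np.any(zero):  # truncated Poisson by redraw
            counts[zero] = rng.poisson(mean, size=int(zero.sum()))
            zero = counts == 0
    total = int(counts.sum())
    edges_bp, edges_cm = landscape.cumulative_cm()
    u = rng.random(total) * landscape.total_map_cm
    positions = np.interp(u, edges_cm, edges_bp)
    return positions, counts


def sample_gamete(
    landscape: RecombinationLandscape,
    rng: np.random.Generator,
    obligate_co: bool = False,
) -> Gamete:
    """Draw one gamete under the no-interference model."""
    positions, _ = _sample_breakpoint_sets(landscape, 1, rng, obligate_co)
    phase = int(rng.integers(2))
    return Gamete(tuple(np.unique(positions)), phase)


@dataclass(frozen=True)
class CrossDesign:
    """Which cross produced the scored progeny and where the markers are."""

    kind: Literal["backcross", "f2", "seed_fluorescence"]
    marker_left: int
    marker_right: int
    sex: Literal["male", "female", "NA"] = "NA"

    def __post_init__(self) -> None:
        if self.kind not in ("backcross", "f2", "seed_fluorescence"):
            raise SimulationError(f"unknown cross design {self.kind!r}")
        if self.marker_left >= self.marker_right:
            raise SimulationError("markers must be distinct and ordered")


def _phase_and_parity(
    positions: np.ndarray,
    counts: np.ndarray,
    start_phase: np.ndarray,
    m1: float,
    m2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per gamete: phase at the left marker and crossover parity in [m1, m2)."""
    n = counts.size
    gid = np.repeat(np.arange(n), counts)
    before = np.bincount(gid[positions <= m1], minlength=n)
    inside = np.bincount(gid[(positions > m1) & (positions <= m2)], minlength=n)
    phase_m1 = (start_phase + before) % 2
    recomb = inside % 2 == 1
    return phase_m1, recomb


def simulate_cross(
    design: CrossDesign,
    landscape: RecombinationLandscape,
    n_progeny: int,
    seed: int | np.random.Generator,
    landscape_other_parent: RecombinationLandscape | None = None,
) -> BackcrossCounts | F2PhenotypeCounts | SeedCounts:
    """Simulate scored progeny counts for one plant.

    ``backcross`` scores a single measured meiosis per progeny; ``f2``
    and ``seed_fluorescence`` combine two independent meioses (the second
    drawn from ``landscape_other_parent`` when given, e.g. to model a
    per-sex rate difference).
    """
    if n_progeny <= 0:
        raise SimulationError("n_progeny must be > 0")
    m1, m2 = float(design.marker_left), float(design.marker_right)
    if not (0 <= m1 < m2 <= landscape.chrom_length):
        raise SimulationError("markers must lie within the chromosome")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    other = landscape_other_parent or landscape

    pos1, cnt1 = _sample_breakpoint_sets(landscape, n_progeny, rng)
    ph1 = rng.integers(2, size=n_progeny)
    phase1, rec1 = _phase_and_parity(pos1, cnt1, ph1, m1, m2)

    if design.kind == "backcross":
        b = int(np.sum(rec1 & (phase1 == 0)))
        c = int(np.sum(rec1 & (phase1 == 1)))
        a = int(np.sum(~rec1 & (phase1 == 0)))
        d = int(np.sum(~rec1 & (phase1 == 1)))
        return BackcrossCounts(a=a, b=b, c=c, d=d)

    pos2, cnt2 = _sample_breakpoint_sets(other, n_progeny, rng)
    ph2 = rng.integers(2, size=n_progeny)
    phase2, rec2 = _phase_and_parity(pos2, cnt2, ph2, m1, m2)
    # phase 0 carries the dominant (reporter-bearing) haplotype
    g1_left, g1_right = phase1 == 0, (phase1 == 0) ^ rec1
    g2_left, g2_right = phase2 == 0, (phase2 == 0) ^ rec2

    if design.kind == "f2":
        dom_left = g1_left | g2_left
        dom_right = g1_right | g2_right
        a = int(np.sum(dom_left & dom_right))
        b = int(np.sum(dom_left & ~dom_right))
        c = int(np.sum(~dom_left & dom_right))
        d = int(np.sum(~dom_left & ~dom_right))
        return F2PhenotypeCounts(a=a, b=b, c=c, d=d)

    # seed_fluorescence: left marker = green reporter, right = red reporter
    green = g1_left | g2_left
    red = g1_right | g2_right
    g = int(np.sum(green & ~red))
    r = int(np.sum(red & ~green))
    return SeedCounts(g=g, r=r, n=n_progeny)


_ESTIMATORS = {
    "backcross": rf_from_backcross,
    "f2": rf_from_f2_ml,
    "seed_fluorescence": rf_from_seed_counts,
}


@dataclass(frozen=True)
class Scenario:
    """A complete simulated experiment over several chromosome configurations."""

    base: RecombinationLandscape
    configurations: dict[str, ZygosityMap]
    model: JuxtapositionModel
    design: CrossDesign
    plants_per_config: int
    progeny_per_plant: int
    seed: int
    resolution_bp: int = 100_000


def simulate_experiment(scenario: Scenario) -> pd.DataFrame:
    """Run every configuration of a scenario and estimate per-plant Rf.

    Returns a tidy table with one row per simulated plant:
    configuration, plant id, estimator method, rf, se, theta, n.
    The remodelled interval map length of each configuration is included
    for diagnostics.
    """
    estimator = _ESTIMATORS[scenario.design.kind]
    ss = np.random.SeedSequence(scenario.seed)
    rows = []
    for (name, zyg), child in zip(
        scenario.configurations.items(), ss.spawn(len(scenario.configurations))
    ):
        landscape = remodel_landscape(
            scenario.base, zyg, scenario.model, scenario.resolution_bp
        )
        interval_cm = map_length(
            landscape, scenario.design.marker_left, scenario.design.marker_right
        )
        rng = np.random.default_rng(child)
        for plant in range(scenario.plants_per_config):
            counts = simulate_cross(
                scenario.design, landscape, scenario.progeny_per_plant, rng
            )
            est = estimator(counts)
            rows.append(
                {
                    "configuration": name,
                    "plant": plant,
                    "method": est.method,
                    "rf": est.rf,
                    "se": est.se,
                    "theta": est.theta,
                    "n": est.n,
                    "interval_cm": interval_cm,
                }
            )
    return pd.DataFrame(rows)


def default_scenario(
    seed: int = 0,
    strength: float = 2.0,
    decay_cm: float = 20.0,
    plants_per_config: int = 12,
    progeny_per_plant: int = 400,
) -> Scenario:
    """The five canonical chromosome configurations on a 100 Mb chromosome.

    A uniform 1.5 cM/Mb base landscape with a 10 Mb measured interval at
    [45, 55] Mb.  Configurations: Inbred (all HOM), Hybrid (all HET),
    Juxtaposed (HET interval only), Reverse juxtaposed (HOM interval
    only) and Interrupted juxtaposed (HET with a central HOM block inside
    the measured interval).
    """
    length = 100_000_000
    lo, hi = 45_000_000, 55_000_000
    base = RecombinationLandscape.uniform(length, 1.5)
    configs = {
        "inbred": ZygosityMap(length, ((0, length, "HOM"),)),
        "hybrid": ZygosityMap(length, ((0, length, "HET"),)),
        "juxtaposed": ZygosityMap.from_het_intervals(length, [(lo, hi)]),
        "reverse_juxtaposed": ZygosityMap(
            length, ((0, lo, "HET"), (lo, hi, "HOM"), (hi, length, "HET"))
        ),
        "interrupted_juxtaposed": ZygosityMap.from_het_intervals(
            length, [(lo, 48_000_000), (52_000_000, hi)]
        ),
    }
    return Scenario(
        base=base,
        configurations=configs,
        model=JuxtapositionModel(strength=strength, decay_cm=decay_cm),
        design=CrossDesign("backcross", lo, hi),
        plants_per_config=plants_per_config,
        progeny_per_plant=progeny_per_plant,
        seed=seed,
    )
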