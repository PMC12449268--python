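"""Heterozygosity-block segmentation from SNP positions.

SNP positions (e.g. from a VCF of an F1 or NIL cross mapped against one
parent) are binned into fixed-width windows; windows whose SNP density
exceeds a threshold seed heterozygous blocks, nearby seeds are merged
and short blocks dropped.  The remainder of the chromosome is called
homozygous.  Coordinates are 0-based half-open throughout; VCF's 1-based
positions are converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SnpDensityTrack",
    "ZygosityCall",
    "snp_density",
    "call_blocks",
    "positions_from_vcf",
    "write_density_tsv",
    "write_segments_bed",
]


class BlockCallError(ValueError):
    pass


@dataclass(frozen=True)
class SnpDensityTrack:
    """Per-window SNP counts over a tiling of one chromosome.

    All windows are ``window_size`` bp except possibly the last, which is
    truncated at ``chrom_length``.
    """

    chrom_length: int
    window_size: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        expected = -(-self.chrom_length // self.window_size)
        if len(self.counts) != expected:
            raise BlockCallError(
                f"expected {expected} windows for length {self.chrom_length} "
                f"at window {self.window_size}, got {len(self.counts)}"
            )
        if np.any(np.asarray(self.counts) < 0):
            raise BlockCallError("window counts must be >= 0")

    @property
    def window_starts(self) -> np.ndarray:
        return np.arange(len(self.counts), dtype=np.int64) * self.window_size

    @property
    def window_ends(self) -> np.ndarray:
        ends = self.window_starts + self.window_size
        ends[-1] = min(ends[-1], self.chrom_length)
        return ends

    @property
    def density_per_kb(self) -> np.ndarray:
        lengths = (self.window_ends - self.window_starts) / 1000.0
        return np.asarray(self.counts, dtype=float) / lengths


@dataclass(frozen=True)
class ZygosityCall:
    """Segmentation of a chromosome into HOM/HET blocks plus the
    parameters that produced it."""

    chrom_length: int
    segments: tuple[tuple[int, int, str], ...]
    het_min_density: float
    merge_gap: int
    min_block: int

    def __post_init__(self) -> None:
        prev = 0
        for start, end, state in self.segments:
            if start != prev or end <= start:
                raise BlockCallError("segments must sort, tile and not overlap")
            prev = end
        if prev != self.chrom_length:
            raise BlockCallError("segments must cover the whole chromosome")

    @property
    def het_intervals(self) -> list[tuple[int, int]]:
        return [(s, e) for s, e, st in self.segments if st == "HET"]


def snp_density(
    positions: Sequence[int], chrom_length: int, window: int = 10_000
) -> SnpDensityTrack:
    """Count SNPs per half-open window of ``window`` bp.

    The last window may be shorter.  Unsorted input is sorted with a
    warning; positions outside ``[0, chrom_length)`` are an error.
    """
    if window <= 0:
        raise BlockCallError("window must be > 0")
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size and np.any(np.diff(pos) < 0):
        warnings.warn("SNP positions were not sorted; sorting", stacklevel=2)
        pos = np.sort(pos)
    if pos.size and (pos[0] < 0 or pos[-1] >= chrom_length):
        raise BlockCallError("SNP positions must lie in [0, chrom_length)")
    n_windows = -(-chrom_length // window)
    counts = np.bincount(pos // window, minlength=n_windows)
    return SnpDensityTrack(chrom_length, window, counts)


def call_blocks(
    track: SnpDensityTrack,
    het_min_density: float = 0.1,
    merge_gap: int = 1_000_000,
    min_block: int = 500_000,
) -> ZygosityCall:
    """Segment a density track into HET and HOM blocks.

    Windows with density >= ``het_min_density`` SNPs/kb seed HET runs;
    runs separated by a gap < ``merge_gap`` bp are merged; merged runs
    shorter than ``min_block`` bp are dropped.  Everything else is HOM.
    Deterministic.
    """
    if het_min_density <= 0 or merge_gap <= 0 or min_block <= 0:
        raise BlockCallError("thresholds must be positive")
    dense = track.density_per_kb >= het_min_density
    starts, ends = track.window_starts, track.window_ends

    runs: list[list[int]] = []
    for i, flag in enumerate(dense):
        if not flag:
            continue
        if runs and starts[i] - runs[-1][1] < merge_gap:
            runs[-1][1] = int(ends[i])
        else:
            runs.append([int(starts[i]), int(ends[i])])
    kept = [(s, e) for s, e in runs if e - s >= min_block]

    segments: list[tuple[int, int, str]] = []
    pos = 0
    for s, e in kept:
        if s > pos:
            segments.append((pos, s, "HOM"))
        segments.append((s, e, "HET"))
        pos = e
    if pos < track.chrom_length:
        segments.append((pos, track.chrom_length, "HOM"))
    if not segments:
        segments.append((0, track.chrom_length, "HOM"))
    return ZygosityCall(
        track.chrom_length, tuple(segments), het_min_density, merge_gap, min_block
    )


def positions_from_vcf(path: str | Path, chrom: str) -> np.ndarray:
    """0-based positions of biallelic SNPs on ``chrom`` from a VCF.

    Indels, multiallelic records and symbolic alleles are skipped.  No
    genotype-quality filtering is applied.
    """
    from cyvcf2 import VCF

    positions: list[int] = []
    vcf = VCF(str(path))
    try:
        for variant in vcf:
            if variant.CHROM != chrom:
                continue
            if len(variant.ALT) != 1:
                continue
            ref, alt = variant.REF, variant.ALT[0]
            if len(ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                continue
            positions.append(variant.start)  # cyvcf2 start is 0-based
    finally:
        vcf.close()
    return np.asarray(sorted(positions), dtype=np.int64)


def write_density_tsv(track: SnpDensityTrack, chrom: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcount\n")
        for s, e, c in zip(track.window_starts, track.window_ends, track.counts):
            fh.write(f"{chrom}\t{s}\t{e}\t{c}\n")


def write_segments_bed(call: ZygosityCall, chrom: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, e, state in call.segments:
            fh.write(f"{chrom}\t{s}\t{e}\t{state}\n")
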