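"""Per-exon mean coverage from a run-length depth track.

Coverage of an exon is the average number of reads covering each base
within that exon; positions absent from the track count as depth 0.  The
track is run-length encoded as sorted, non-overlapping 1-based inclusive
(start, end, depth) runs per chromosome; bedGraph input (half-open,
0-based) is converted at the boundary.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from .records import ExonRecord

Run = tuple[int, int, int]  # 1-based inclusive start, end, depth


class DepthTrack:
    """Run-length encoded per-base depth, per chromosome."""

    def __init__(self, runs: Mapping[str, Sequence[Run]]):
        self._runs: dict[str, list[Run]] = {}
        self._starts: dict[str, list[int]] = {}
        for chrom, rs in runs.items():
            rs = sorted((int(s), int(e), int(d)) for s, e, d in rs)
            prev_end = 0
            for s, e, d in rs:
                if s < 1 or e < s:
                    raise ValueError(f"invalid run {chrom}:{s}-{e}")
                if d < 0:
                    raise ValueError("depth must be >= 0")
                if s <= prev_end:
                    raise ValueError(f"overlapping runs on {chrom} at {s}")
                prev_end = e
            self._runs[chrom] = rs
            self._starts[chrom] = [s for s, _, _ in rs]

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "DepthTrack":
        runs: dict[str, list[Run]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
                chrom, start0, end0, depth = fields[0], int(fields[1]), int(fields[2]), fields[3]
                runs.setdefault(chrom, []).append((start0 + 1, end0, int(float(depth))))
        return cls(runs)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._runs):
                for s, e, d in self._runs[chrom]:
                    fh.write(f"{chrom}\t{s - 1}\t{e}\t{d}\n")

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(sorted(self._runs))

    def runs(self, chrom: str) -> list[Run]:
        return list(self._runs.get(chrom, []))

    def depth_at(self, chrom: str, pos: int) -> int:
        rs = self._runs.get(chrom)
        if not rs:
            return 0
        i = bisect.bisect_right(self._starts[chrom], pos) - 1
        if i >= 0:
            s, e, d = rs[i]
            if s <= pos <= e:
                return d
        return 0

    def interval_sum(self, chrom: str, start: int, end: int) -> int:
        """Sum of per-base depth over the 1-based inclusive interval."""
        rs = self._runs.get(chrom)
        if not rs or end < start:
            return 0
        total = 0
        i = max(0, bisect.bisect_right(self._starts[chrom], start) - 1)
        for s, e, d in rs[i:]:
            if s > end:
                break
            lo, hi = max(s, start), min(e, end)
            if lo <= hi:
                total += d * (hi - lo + 1)
        return total

    def __add__(self, other: "DepthTrack") -> "DepthTrack":
        """Base-wise sum of two tracks (e.g. lane subsets of one run)."""
        merged: dict[str, list[Run]] = {}
        for chrom in set(self._runs) | set(other._runs):
            bounds: set[int] = set()
            for track in (self, other):
                for s, e, _ in track._runs.get(chrom, []):
                    bounds.add(s)
                    bounds.add(e + 1)
            edges = sorted(bounds)
            runs: list[Run] = []
            for lo, hi in zip(edges, edges[1:]):
                d = self.depth_at(chrom, lo) + other.depth_at(chrom, lo)
                if d:
                    if runs and runs[-1][1] == lo - 1 and runs[-1][2] == d:
                        runs[-1] = (runs[-1][0], hi - 1, d)
                    else:
                        runs.append((lo, hi - 1, d))
            if runs:
                merged[chrom] = runs
        return DepthTrack(merged)

    def scaled(self, k: int) -> "DepthTrack":
        return DepthTrack(
            {c: [(s, e, d * k) for s, e, d in rs] for c, rs in self._runs.items()}
        )


@dataclass(frozen=True)
class ExonCoverage:
    exon: ExonRecord
    mean_coverage: float

    def __post_init__(self) -> None:
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be >= 0")


@dataclass(frozen=True)
class CoverageSummary:
    """Coverage adequacy across exons.

    ``fraction_ge_threshold`` is the share of exons whose mean coverage
    meets the threshold; ``median_of_covered`` is the median mean-coverage
    among those exons only (NaN when none qualify).
    """

    fraction_ge_threshold: float
    median_of_covered: float
    threshold: float
    n_exons: int
    n_covered: int


def exon_mean_coverage(track: DepthTrack, exon: ExonRecord) -> ExonCoverage:
    """Mean per-base depth over the exon, zeros included."""
    total = track.interval_sum(exon.chrom, exon.start, exon.end)
    return ExonCoverage(exon=exon, mean_coverage=total / exon.length)


def _lower_median(values: Sequence[float]) -> float:
    ordered = sorted(values)
    return float(ordered[(len(ordered) - 1) // 2])


def coverage_summary(
    covs: Sequence[ExonCoverage],
    threshold: float = 5.0,
    comparator: Literal["ge", "gt"] = "ge",
    median_convention: Literal["lower", "mean"] = "lower",
) -> CoverageSummary:
    """Fraction of exons meeting the coverage threshold, and their median.

    The threshold comparator defaults to >= ("at least 5x"); the median of
    the covered subset uses the lower-median convention for even counts
    unless ``median_convention='mean'``.
    """
    if not covs:
        raise ValueError("coverage_summary requires a non-empty list of exon coverages")
    if comparator == "ge":
        covered = [c.mean_coverage for c in covs if c.mean_coverage >= threshold]
    elif comparator == "gt":
        covered = [c.mean_coverage for c in covs if c.mean_coverage > threshold]
    else:
        raise ValueError(f"unknown comparator {comparator!r}")
    if not covered:
        median = float("nan")
    elif median_convention == "lower":
        median = _lower_median(covered)
    elif median_convention == "mean":
        ordered = sorted(covered)
        n = len(ordered)
        median = float(ordered[n // 2]) if n % 2 else (ordered[n // 2 - 1] + ordered[n // 2]) / 2.0
    else:
        raise ValueError(f"unknown median_convention {median_convention!r}")
    return CoverageSummary(
        fraction_ge_threshold=len(covered) / len(covs),
        median_of_covered=median,
        threshold=threshold,
        n_exons=len(covs),
        n_covered=len(covered),
    )
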