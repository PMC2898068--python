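"""Shared data model for the gDNA/cDNA SNV concordance pipeline.

All coordinates are 1-based and inclusive (pileup/VCF convention); BED and
bedGraph inputs are converted at the I/O boundary.  Genotypes are unordered
allele pairs stored as a sorted 2-tuple of single bases; phase is never
represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

BASES = frozenset("ACGT")

#: IUPAC ambiguity codes for the ten unordered base pairs.
IUPAC_TO_PAIR: dict[str, tuple[str, str]] = {
    "A": ("A", "A"),
    "C": ("C", "C"),
    "G": ("G", "G"),
    "T": ("T", "T"),
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}

PAIR_TO_IUPAC: dict[tuple[str, str], str] = {v: k for k, v in IUPAC_TO_PAIR.items()}

Genotype = tuple[str, str]


def make_genotype(a: str, b: str) -> Genotype:
    """Canonical unordered allele pair (sorted 2-tuple of bases)."""
    a, b = a.upper(), b.upper()
    if a not in BASES or b not in BASES:
        raise ValueError(f"genotype alleles must be A/C/G/T, got {a!r}/{b!r}")
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True, slots=True)
class VariantCall:
    """One SNV call — the atomic record of both call sets.

    ``alt_end_fraction`` is the fraction of reads supporting the
    non-reference allele whose supporting base is the first or last base of
    its read (a splice-boundary misalignment signature in cDNA).
    ``transcript_ids``/``gene_ids`` are filled in by exon restriction.
    """

    chrom: str
    pos: int
    ref_allele: str
    genotype: Genotype
    snp_quality: float
    read_depth: int
    alt_support: int
    alt_end_fraction: float = 0.0
    source: str = "cDNA"
    transcript_ids: tuple[str, ...] = ()
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele not in BASES:
            raise ValueError(f"ref_allele must be A/C/G/T, got {self.ref_allele!r}")
        gt = make_genotype(*self.genotype)
        object.__setattr__(self, "genotype", gt)
        if not any(a != self.ref_allele for a in gt):
            raise ValueError(
                f"{self.chrom}:{self.pos} genotype {gt} carries no non-reference allele"
            )
        if self.snp_quality < 0:
            raise ValueError("snp_quality must be >= 0")
        if not 0 <= self.alt_support <= self.read_depth:
            raise ValueError(
                f"alt_support must satisfy 0 <= {self.alt_support} <= depth {self.read_depth}"
            )
        if not 0.0 <= self.alt_end_fraction <= 1.0:
            raise ValueError("alt_end_fraction must lie in [0, 1]")
        if self.source not in ("gDNA", "cDNA"):
            raise ValueError(f"source must be 'gDNA' or 'cDNA', got {self.source!r}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]

    @property
    def alt_alleles(self) -> tuple[str, ...]:
        return tuple(a for a in set(self.genotype) if a != self.ref_allele)

    def annotated(self, transcript_ids: Iterable[str], gene_ids: Iterable[str]) -> "VariantCall":
        return replace(
            self,
            transcript_ids=tuple(sorted(set(transcript_ids))),
            gene_ids=tuple(sorted(set(gene_ids))),
        )


@dataclass(frozen=True, slots=True)
class ExonRecord:
    """An annotated exon interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    transcript_id: str
    gene_id: str
    is_core: bool = False
    is_canonical: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid exon interval {self.chrom}:{self.start}-{self.end} (1-based inclusive)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True, slots=True)
class ExpressionRecord:
    """Transcript expression as percent of the tissue's most-expressed transcript."""

    transcript_id: str
    expression_pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.expression_pct <= 100.0:
            raise ValueError(
                f"expression_pct must lie in [0, 100], got {self.expression_pct}"
            )


@dataclass(frozen=True, slots=True)
class GeneAnnotation:
    gene_id: str
    has_paralog: bool


class PositionSet:
    """A set of (chrom, pos) keys, 1-based — e.g. a dbSNP-like known-site list."""

    __slots__ = ("_keys",)

    def __init__(self, keys: Iterable[tuple[str, int]] = ()):
        self._keys: frozenset[tuple[str, int]] = frozenset(
            (str(c), int(p)) for c, p in keys
        )

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._keys

    def __len__(self) -> int:
        return len(self._keys)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(sorted(self._keys))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PositionSet) and self._keys == other._keys

    def __repr__(self) -> str:
        return f"PositionSet(n={len(self)})"
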