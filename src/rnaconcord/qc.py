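"""Quality-control screens applied to each call set before concordance analysis.

The screens mirror the post-caller filters used for short-read SNV tables:
a minimum Phred-scaled variant quality (30 for cDNA, 20 for gDNA), at least
three reads supporting the non-reference allele, a per-site maximum depth
(10 million gDNA / 1 million cDNA, i.e. effectively off), and — for cDNA
only — removal of calls where more than 20% of the alt-supporting reads
contribute their first or last base (a splice-boundary misalignment
signature).

Threshold senses follow the literal reading of each rule: quality >= min
passes, alt_support >= min passes, end fraction > max fails.  Each
comparator is configurable so a strict-inequality variant is one flag away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .records import ExonRecord, VariantCall

logger = logging.getLogger(__name__)

#: Rule names in their declared application order; a removed call is
#: attributed to the first rule it fails.
RULE_ORDER = ("snp_quality", "alt_support", "max_site_depth", "alt_end_fraction")


@dataclass
class FilterParams:
    """Thresholds for :func:`filter_calls`.

    Defaults follow the cDNA screen; use :meth:`for_gdna` / :meth:`for_cdna`
    for the per-source presets.
    """

    min_snp_quality: float = 30.0
    min_alt_support: int = 3
    max_alt_end_fraction: float = 0.20
    max_site_depth: int = 1_000_000
    apply_end_filter: bool = True
    # comparator knobs: inclusive=True means the boundary value passes
    quality_inclusive: bool = True
    alt_support_inclusive: bool = True
    end_fraction_inclusive: bool = True  # end fraction == max passes; only > max fails
    depth_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.min_snp_quality < 0 or self.min_alt_support < 0 or self.max_site_depth < 0:
            raise ValueError("all thresholds must be >= 0")
        if not 0.0 <= self.max_alt_end_fraction <= 1.0:
            raise ValueError("max_alt_end_fraction must lie in [0, 1]")

    @classmethod
    def for_cdna(cls, **overrides) -> "FilterParams":
        return cls(**{"min_snp_quality": 30.0, "max_site_depth": 1_000_000,
                      "apply_end_filter": True, **overrides})

    @classmethod
    def for_gdna(cls, **overrides) -> "FilterParams":
        return cls(**{"min_snp_quality": 20.0, "max_site_depth": 10_000_000,
                      "apply_end_filter": False, **overrides})

    # --- per-rule predicates (True = passes the rule) -------------------
    def pass_quality(self, c: VariantCall) -> bool:
        return (c.snp_quality >= self.min_snp_quality if self.quality_inclusive
                else c.snp_quality > self.min_snp_quality)

    def pass_alt_support(self, c: VariantCall) -> bool:
        return (c.alt_support >= self.min_alt_support if self.alt_support_inclusive
                else c.alt_support > self.min_alt_support)

    def pass_depth(self, c: VariantCall) -> bool:
        return (c.read_depth <= self.max_site_depth if self.depth_inclusive
                else c.read_depth < self.max_site_depth)

    def pass_end_fraction(self, c: VariantCall) -> bool:
        if not self.apply_end_filter:
            return True
        return (c.alt_end_fraction <= self.max_alt_end_fraction if self.end_fraction_inclusive
                else c.alt_end_fraction < self.max_alt_end_fraction)

    def passes(self, c: VariantCall) -> bool:
        return (self.pass_quality(c) and self.pass_alt_support(c)
                and self.pass_depth(c) and self.pass_end_fraction(c))

    def first_failing_rule(self, c: VariantCall) -> str | None:
        for rule, pred in zip(
            RULE_ORDER,
            (self.pass_quality, self.pass_alt_support, self.pass_depth, self.pass_end_fraction),
        ):
            if not pred(c):
                return rule
        return None


@dataclass
class FilterReport:
    input_count: int
    pass_count: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.input_count == self.pass_count + sum(self.removed_by_rule.values())

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "pass_count": self.pass_count,
            "removed_by_rule": dict(self.removed_by_rule),
        }


def filter_calls(
    calls: Sequence[VariantCall], params: FilterParams
) -> tuple[list[VariantCall], FilterReport]:
    """Apply the QC screen; returns the surviving calls and a removal report.

    All calls must come from one source (the thresholds are per-source).
    """
    sources = {c.source for c in calls}
    if len(sources) > 1:
        raise ValueError(f"mixed call sources {sorted(sources)}: filter one set at a time")
    kept: list[VariantCall] = []
    removed = {rule: 0 for rule in RULE_ORDER}
    for c in calls:
        rule = params.first_failing_rule(c)
        if rule is None:
            kept.append(c)
        else:
            removed[rule] += 1
    report = FilterReport(
        input_count=len(calls),
        pass_count=len(kept),
        removed_by_rule={r: n for r, n in removed.items() if n},
    )
    return kept, report


def build_exon_index(exons: Iterable[ExonRecord]) -> dict[str, IntervalTree]:
    """Per-chromosome interval index over 1-based inclusive exon intervals."""
    index: dict[str, IntervalTree] = {}
    for e in exons:
        index.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end + 1, e)
    return index


def restrict_to_exons(
    calls: Sequence[VariantCall], exons: Sequence[ExonRecord]
) -> list[VariantCall]:
    """Keep only calls falling inside an exon (endpoints inclusive).

    Kept calls are annotated with the transcript and gene ids of every
    covering exon.
    """
    if not exons:
        logger.warning("restrict_to_exons: empty exon list, all calls removed")
        return []
    index = build_exon_index(exons)
    kept: list[VariantCall] = []
    for c in calls:
        tree = index.get(c.chrom)
        if tree is None:
            continue
        hits = tree[c.pos]
        if hits:
            kept.append(
                c.annotated(
                    (iv.data.transcript_id for iv in hits),
                    (iv.data.gene_id for iv in hits),
                )
            )
    return kept
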