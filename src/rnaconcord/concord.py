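"""Classify cDNA calls against gDNA calls and compute concordance metrics.

The gDNA call set is treated as truth.  Following the benchmarking
convention of the RNA-Seq variant-calling literature:

* sensitivity = TP / (TP + FN) — the fraction of genome-identified exonic
  SNVs recovered from the transcriptome (a recall);
* specificity = TP / (TP + FP) — the fraction of transcriptome SNV calls
  confirmed in the genome (a precision, despite the name).

Two matching modes exist: ``position`` (same chrom/pos) and ``genotype``
(same chrom/pos and identical unordered allele pair).  In genotype mode a
position-matched pair with discordant genotypes contributes one FP *and*
one FN by default — the genomic variant was missed and a wrong variant was
asserted — which preserves the conservation laws tp+fn=|gDNA| and
tp+fp=|cDNA|.  The convention is configurable (``mismatch_policy``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .records import VariantCall

Mode = Literal["position", "genotype"]

_NAN = float("nan")


@dataclass(frozen=True)
class ConcordanceCounts:
    """TP/FP/FN confusion triple for one comparison."""

    tp: int
    fp: int
    fn: int
    mode: str = "position"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n_gdna(self) -> int:
        return self.tp + self.fn

    @property
    def n_cdna(self) -> int:
        return self.tp + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_gdna if self.n_gdna else _NAN

    @property
    def specificity(self) -> float:
        return self.tp / self.n_cdna if self.n_cdna else _NAN


@dataclass
class ClassifiedCalls:
    """Partition of the union of both call sets by (chrom, pos)."""

    tp_pairs: list[tuple[VariantCall, VariantCall]]  # (gDNA, cDNA)
    fp_calls: list[VariantCall]  # cDNA-only
    fn_calls: list[VariantCall]  # gDNA-only
    mode: str = "position"

    @property
    def counts(self) -> ConcordanceCounts:
        return ConcordanceCounts(
            tp=len(self.tp_pairs), fp=len(self.fp_calls), fn=len(self.fn_calls), mode=self.mode
        )


@dataclass(frozen=True)
class ZygosityBreakdown:
    """Zygosity agreement among position-matched pairs.

    Categories are exclusive and exhaust the TP pairs: pairs sharing no
    allele are ``full_allele_mismatch``; otherwise het/hom discordance in
    either direction; otherwise ``zygosity_match``.
    """

    zygosity_match: int
    het_gdna_hom_cdna: int
    hom_gdna_het_cdna: int
    full_allele_mismatch: int

    @property
    def total(self) -> int:
        return (self.zygosity_match + self.het_gdna_hom_cdna
                + self.hom_gdna_het_cdna + self.full_allele_mismatch)


def _check_unique(calls: Sequence[VariantCall], label: str) -> dict[tuple[str, int], VariantCall]:
    by_key: dict[tuple[str, int], VariantCall] = {}
    for c in calls:
        if c.key in by_key:
            raise ValueError(
                f"duplicate position {c.chrom}:{c.pos} in {label} call set "
                "(dedup belongs upstream: rnaconcord.io.dedup_calls)"
            )
        by_key[c.key] = c
    return by_key


def classify_calls(
    gdna: Sequence[VariantCall],
    cdna: Sequence[VariantCall],
    mode: Mode = "position",
    mismatch_policy: Literal["fp+fn", "fp_only", "drop"] = "fp+fn",
) -> ClassifiedCalls:
    """Match the cDNA call set against the gDNA call set.

    Both sets must already be QC-filtered, exon-restricted and unique per
    (chrom, pos).  A shared position with disagreeing reference alleles is
    an error (the inputs must share one reference build).
    """
    if mode not in ("position", "genotype"):
        raise ValueError(f"unknown mode {mode!r}")
    g_by_key = _check_unique(gdna, "gDNA")
    c_by_key = _check_unique(cdna, "cDNA")

    tp_pairs: list[tuple[VariantCall, VariantCall]] = []
    fp_calls: list[VariantCall] = []
    fn_calls: list[VariantCall] = []

    for key in sorted(c_by_key):
        c = c_by_key[key]
        g = g_by_key.get(key)
        if g is None:
            fp_calls.append(c)
            continue
        if g.ref_allele != c.ref_allele:
            raise ValueError(
                f"reference allele disagreement at {c.chrom}:{c.pos} "
                f"({g.ref_allele} vs {c.ref_allele}): inputs must share a reference build"
            )
        if mode == "position" or g.genotype == c.genotype:
            tp_pairs.append((g, c))
        else:  # position overlap, genotype mismatch
            if mismatch_policy == "fp+fn":
                fp_calls.append(c)
                fn_calls.append(g)
            elif mismatch_policy == "fp_only":
                fp_calls.append(c)
            elif mismatch_policy != "drop":
                raise ValueError(f"unknown mismatch_policy {mismatch_policy!r}")
    for key in sorted(g_by_key):
        if key not in c_by_key:
            fn_calls.append(g_by_key[key])
    fn_calls.sort(key=lambda c: c.key)
    return ClassifiedCalls(tp_pairs=tp_pairs, fp_calls=fp_calls, fn_calls=fn_calls, mode=mode)


def concordance_metrics(counts: ConcordanceCounts) -> tuple[float, float]:
    """(sensitivity, specificity); NaN where the denominator is zero."""
    return counts.sensitivity, counts.specificity


def zygosity_breakdown(classified: ClassifiedCalls) -> ZygosityBreakdown:
    """Zygosity-discordance accounting over position-matched pairs."""
    if classified.mode != "position":
        raise ValueError("zygosity breakdown requires a position-mode classification")
    match = het_hom = hom_het = mismatch = 0
    for g, c in classified.tp_pairs:
        if not set(g.genotype) & set(c.genotype):
            mismatch += 1
        elif g.is_het and not c.is_het:
            het_hom += 1
        elif not g.is_het and c.is_het:
            hom_het += 1
        else:
            match += 1
    return ZygosityBreakdown(
        zygosity_match=match,
        het_gdna_hom_cdna=het_hom,
        hom_gdna_het_cdna=hom_het,
        full_allele_mismatch=mismatch,
    )
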