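"""Stratified concordance metrics.

Recomputes sensitivity/specificity within strata defined by transcript
expression (log-spaced percent-of-max bins), cDNA read-depth windows,
paralog status of the covering genes, known-site (dbSNP-like) membership,
and cumulative sequencing amount (lane curves).

Annotation conventions: a call covered by several transcripts takes the
maximum expression among them (the variant is detectable if any covering
transcript is expressed); one paralogous covering gene suffices to place a
call in the with-paralog stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .concord import ClassifiedCalls, ConcordanceCounts, classify_calls
from .records import ExpressionRecord, GeneAnnotation, PositionSet, VariantCall


@dataclass(frozen=True)
class ExpressionBins:
    """Log-spaced bin edges on the percent-of-max expression scale.

    The "expressed" threshold (default 4% of the most highly expressed
    transcript) must coincide with one of the edges so the expressed /
    not-expressed split is representable exactly.
    """

    edges: tuple[float, ...]
    expressed_threshold: float = 4.0

    def __post_init__(self) -> None:
        if len(self.edges) < 2:
            raise ValueError("need at least two bin edges")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("bin edges must be strictly increasing")
        if not any(math.isclose(e, self.expressed_threshold, rel_tol=1e-9) for e in self.edges):
            raise ValueError(
                f"expressed threshold {self.expressed_threshold} is not a bin edge"
            )

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def assign(self, value: float) -> int:
        """Bin index for an expression value; -1 = below the first edge.

        Bins are [e_i, e_{i+1}) with the last bin closed on both ends.
        """
        if value < self.edges[0]:
            return -1
        for i in range(self.n_bins):
            if self.edges[i] <= value < self.edges[i + 1]:
                return i
        return self.n_bins - 1  # value == last edge (or numerically above)

    def label(self, i: int) -> str:
        if i < 0:
            return f"<{self.edges[0]:g}%"
        return f"[{self.edges[i]:g}%, {self.edges[i + 1]:g}%)"


def make_log_bins(min_pct: float, max_pct: float, bins_per_decade: int,
                  expressed_threshold: float = 4.0) -> ExpressionBins:
    """Edges at ``min_pct * 10^(k / bins_per_decade)``, capped at ``max_pct``."""
    if not 0 < min_pct < max_pct <= 100:
        raise ValueError("need 0 < min_pct < max_pct <= 100")
    if bins_per_decade < 1:
        raise ValueError("bins_per_decade must be >= 1")
    edges = [min_pct]
    k = 1
    while True:
        e = min_pct * 10 ** (k / bins_per_decade)
        if e >= max_pct * (1 - 1e-12):
            edges.append(max_pct)
            break
        edges.append(e)
        k += 1
    return ExpressionBins(edges=tuple(edges), expressed_threshold=expressed_threshold)


def default_bins() -> ExpressionBins:
    """Two bins per decade spanning 0.04%-100%; 4% is an exact edge."""
    return make_log_bins(0.04, 100.0, 2)


@dataclass(frozen=True)
class StratumResult:
    """Concordance metrics within one stratum."""

    label: str
    counts: ConcordanceCounts
    extras: Mapping[str, float] = field(default_factory=dict)

    @property
    def sensitivity(self) -> float:
        return self.counts.sensitivity

    @property
    def specificity(self) -> float:
        return self.counts.specificity


def _expression_of(call: VariantCall, expr: Mapping[str, float]) -> float:
    """Max expression over the call's covering transcripts (0 if unmeasured)."""
    if not call.transcript_ids:
        raise ValueError(
            f"call {call.chrom}:{call.pos} carries no transcript annotation; "
            "run restrict_to_exons first"
        )
    return max((expr.get(t, 0.0) for t in call.transcript_ids), default=0.0)


def expression_map(records: Sequence[ExpressionRecord]) -> dict[str, float]:
    return {r.transcript_id: r.expression_pct for r in records}


def stratify_by_expression(
    classified: ClassifiedCalls,
    expr: Sequence[ExpressionRecord] | Mapping[str, float],
    bins: ExpressionBins | None = None,
) -> list[StratumResult]:
    """Per-expression-bin concordance metrics.

    Each call is assigned one expression value (max over covering
    transcripts) and one bin; a TP pair is binned by its gDNA member (both
    members share the exons, hence the value).  Returns one StratumResult
    per bin, low to high, with an extra underflow stratum first when calls
    fall below the lowest edge.
    """
    if bins is None:
        bins = default_bins()
    emap = expr if isinstance(expr, Mapping) else expression_map(expr)
    tp = [0] * (bins.n_bins + 1)
    fp = [0] * (bins.n_bins + 1)
    fn = [0] * (bins.n_bins + 1)
    for g, _ in classified.tp_pairs:
        tp[bins.assign(_expression_of(g, emap)) + 1] += 1
    for c in classified.fp_calls:
        fp[bins.assign(_expression_of(c, emap)) + 1] += 1
    for g in classified.fn_calls:
        fn[bins.assign(_expression_of(g, emap)) + 1] += 1
    out: list[StratumResult] = []
    for slot in range(bins.n_bins + 1):
        i = slot - 1
        if i < 0 and tp[0] + fp[0] + fn[0] == 0:
            continue
        counts = ConcordanceCounts(tp=tp[slot], fp=fp[slot], fn=fn[slot], mode=classified.mode)
        mid = (bins.edges[i] * bins.edges[i + 1]) ** 0.5 if i >= 0 else float("nan")
        out.append(StratumResult(label=bins.label(i), counts=counts,
                                 extras={"bin_geometric_mid_pct": mid}))
    return out


def filter_by_depth_window(
    classified: ClassifiedCalls, d_min: int, d_max: int | None = None
) -> StratumResult:
    """Concordance after restricting cDNA calls to a read-depth window.

    The window [d_min, d_max] (inclusive both ends; d_max=None means
    unbounded) applies to the cDNA side only.  FN is recomputed against the
    *full* gDNA set, so sensitivity drops when the window excludes true
    calls; gDNA depth is a different quantity and is never windowed.
    """
    if d_min < 1:
        raise ValueError("d_min must be >= 1")
    if d_max is not None and d_max < d_min:
        raise ValueError("d_max must be >= d_min")

    def in_window(c: VariantCall) -> bool:
        return c.read_depth >= d_min and (d_max is None or c.read_depth <= d_max)

    tp = sum(1 for _, c in classified.tp_pairs if in_window(c))
    fp = sum(1 for c in classified.fp_calls if in_window(c))
    n_gdna = len(classified.tp_pairs) + len(classified.fn_calls)
    fn = n_gdna - tp
    label = f"depth [{d_min}, {'inf' if d_max is None else d_max}]"
    return StratumResult(
        label=label,
        counts=ConcordanceCounts(tp=tp, fp=fp, fn=fn, mode=classified.mode),
    )


def partition_by_paralog(
    classified: ClassifiedCalls, genes: Sequence[GeneAnnotation] | Mapping[str, bool]
) -> tuple[StratumResult, StratumResult]:
    """Split calls by paralog status of their covering genes.

    A call lands in the with-paralog stratum iff *any* covering gene is
    flagged paralogous; the two strata are disjoint and exhaustive.  A
    covering gene missing from the annotation table is an error.
    """
    gmap = genes if isinstance(genes, Mapping) else {g.gene_id: g.has_paralog for g in genes}
    missing: set[str] = set()

    def has_paralog(call: VariantCall) -> bool:
        if not call.gene_ids:
            raise ValueError(
                f"call {call.chrom}:{call.pos} carries no gene annotation; "
                "run restrict_to_exons first"
            )
        hit = False
        for gid in call.gene_ids:
            if gid not in gmap:
                missing.add(gid)
            elif gmap[gid]:
                hit = True
        return hit

    with_counts = {"tp": 0, "fp": 0, "fn": 0}
    without_counts = {"tp": 0, "fp": 0, "fn": 0}
    for cls_name, calls in (
        ("tp", [g for g, _ in classified.tp_pairs]),
        ("fp", classified.fp_calls),
        ("fn", classified.fn_calls),
    ):
        for call in calls:
            (with_counts if has_paralog(call) else without_counts)[cls_name] += 1
    if missing:
        raise ValueError(
            "genes absent from annotation table: " + ", ".join(sorted(missing))
        )
    return (
        StratumResult("with-paralog", ConcordanceCounts(mode=classified.mode, **with_counts)),
        StratumResult("without-paralog", ConcordanceCounts(mode=classified.mode, **without_counts)),
    )


def known_site_rates(
    classified: ClassifiedCalls, sites: PositionSet
) -> dict[str, float]:
    """Fraction of each class whose (chrom, pos) is in the known-site list.

    Classes: TP (cDNA member), FP, FN, and gdna_all (TP u FN).  An empty
    class yields NaN.
    """

    def rate(calls: Sequence[VariantCall]) -> float:
        if not calls:
            return float("nan")
        return sum(1 for c in calls if c.key in sites) / len(calls)

    tp_calls = [c for _, c in classified.tp_pairs]
    gdna_all = [g for g, _ in classified.tp_pairs] + list(classified.fn_calls)
    return {
        "tp": rate(tp_calls),
        "fp": rate(classified.fp_calls),
        "fn": rate(classified.fn_calls),
        "gdna_all": rate(gdna_all),
    }


def lane_accumulation_curve(
    lane_callsets: Sequence[Sequence[VariantCall]],
    gdna: Sequence[VariantCall],
    mode: str = "position",
) -> list[StratumResult]:
    """Concordance per cumulative-lane snapshot (1..L lanes of cDNA data).

    Snapshots must represent cumulative data; TP monotonicity across
    snapshots is checked and any violation is reported in the stratum
    extras (``tp_monotonic`` flag), never silently fixed.
    """
    if not lane_callsets:
        raise ValueError("lane_accumulation_curve requires at least one snapshot")
    results: list[StratumResult] = []
    prev_tp: int | None = None
    for i, snapshot in enumerate(lane_callsets, start=1):
        counts = classify_calls(gdna, snapshot, mode=mode).counts
        monotonic = prev_tp is None or counts.tp >= prev_tp
        results.append(
            StratumResult(
                label=f"lanes={i}",
                counts=counts,
                extras={"tp_monotonic": float(monotonic)},
            )
        )
        prev_tp = counts.tp
    return results
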