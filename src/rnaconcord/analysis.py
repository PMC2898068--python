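"""Model/results front end for the concordance benchmark.

:class:`ConcordanceAnalysis` is built from a gDNA and a cDNA call set plus
optional annotation tables; ``fit()`` runs QC filtering, exon restriction,
deduplication and classification, and returns a
:class:`ConcordanceResults` carrying the confusion counts, sensitivity and
specificity with Wilson confidence intervals, the zygosity breakdown and
the stratified views.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import norm

from . import io as rcio
from .concord import (
    ClassifiedCalls,
    ConcordanceCounts,
    classify_calls,
    zygosity_breakdown,
)
from .qc import FilterParams, FilterReport, filter_calls, restrict_to_exons
from .records import (
    ExonRecord,
    ExpressionRecord,
    GeneAnnotation,
    PositionSet,
    VariantCall,
)
from .stratify import (
    ExpressionBins,
    StratumResult,
    filter_by_depth_window,
    known_site_rates,
    lane_accumulation_curve,
    partition_by_paralog,
    stratify_by_expression,
)

_AUTO = object()


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    if n == 0:
        return (float("nan"), float("nan"))
    z = norm.ppf(1 - alpha / 2)
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


class ConcordanceAnalysis:
    """Concordance of a transcriptome SNV call set against a genome call set.

    Parameters
    ----------
    gdna_calls, cdna_calls
        Raw call sets (post-caller, pre-QC).
    exons
        Exon annotation; when given, both sets are restricted to exons and
        kept calls are annotated with covering transcripts/genes.
    expression, genes, known_sites
        Optional tables enabling the stratified views on the results.
    gdna_filter, cdna_filter
        QC thresholds; default to the per-source presets
        (quality >= 20/30, alt support >= 3, end-of-read rule for cDNA).
        Pass ``None`` to skip QC for a set.
    """

    def __init__(
        self,
        gdna_calls: Sequence[VariantCall],
        cdna_calls: Sequence[VariantCall],
        *,
        exons: Sequence[ExonRecord] | None = None,
        expression: Sequence[ExpressionRecord] | Mapping[str, float] | None = None,
        genes: Sequence[GeneAnnotation] | Mapping[str, bool] | None = None,
        known_sites: PositionSet | None = None,
        gdna_filter: FilterParams | None = _AUTO,  # type: ignore[assignment]
        cdna_filter: FilterParams | None = _AUTO,  # type: ignore[assignment]
        dedup: bool = True,
    ):
        self.gdna_calls = list(gdna_calls)
        self.cdna_calls = list(cdna_calls)
        self.exons = list(exons) if exons is not None else None
        self.expression = expression
        self.genes = genes
        self.known_sites = known_sites
        self.gdna_filter = FilterParams.for_gdna() if gdna_filter is _AUTO else gdna_filter
        self.cdna_filter = FilterParams.for_cdna() if cdna_filter is _AUTO else cdna_filter
        self.dedup = dedup

    @classmethod
    def from_files(
        cls,
        gdna_path: str,
        cdna_path: str,
        *,
        dialect: str = "pileup-tsv",
        exons_path: str | None = None,
        expression_path: str | None = None,
        genes_path: str | None = None,
        known_sites_path: str | None = None,
        **kwargs,
    ) -> "ConcordanceAnalysis":
        return cls(
            rcio.read_variant_table(gdna_path, dialect, "gDNA"),
            rcio.read_variant_table(cdna_path, dialect, "cDNA"),
            exons=rcio.read_exon_annotation(exons_path) if exons_path else None,
            expression=rcio.read_expression_table(expression_path) if expression_path else None,
            genes=rcio.read_gene_annotations(genes_path) if genes_path else None,
            known_sites=rcio.read_position_set(known_sites_path) if known_sites_path else None,
            **kwargs,
        )

    def prepare(self, calls: Sequence[VariantCall], params: FilterParams | None
                ) -> tuple[list[VariantCall], FilterReport | None]:
        """QC-filter, exon-restrict and deduplicate one call set."""
        report = None
        out = list(calls)
        if params is not None:
            out, report = filter_calls(out, params)
        if self.exons is not None:
            out = restrict_to_exons(out, self.exons)
        if self.dedup:
            out = rcio.dedup_calls(out)
        return out, report

    def fit(self, mode: str = "position", mismatch_policy: str = "fp+fn") -> "ConcordanceResults":
        gdna, gdna_report = self.prepare(self.gdna_calls, self.gdna_filter)
        cdna, cdna_report = self.prepare(self.cdna_calls, self.cdna_filter)
        classified = classify_calls(gdna, cdna, mode=mode, mismatch_policy=mismatch_policy)
        return ConcordanceResults(
            model=self,
            classified=classified,
            gdna_report=gdna_report,
            cdna_report=cdna_report,
        )


@dataclass
class ConcordanceResults:
    """Fitted concordance: counts, metrics, uncertainties and strata."""

    model: ConcordanceAnalysis
    classified: ClassifiedCalls
    gdna_report: FilterReport | None = None
    cdna_report: FilterReport | None = None

    @property
    def counts(self) -> ConcordanceCounts:
        return self.classified.counts

    @property
    def sensitivity(self) -> float:
        return self.counts.sensitivity

    @property
    def specificity(self) -> float:
        return self.counts.specificity

    def conf_int(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        c = self.counts
        return {
            "sensitivity": wilson_interval(c.tp, c.n_gdna, alpha),
            "specificity": wilson_interval(c.tp, c.n_cdna, alpha),
        }

    # --- stratified views ----------------------------------------------
    def zygosity(self):
        return zygosity_breakdown(self.classified)

    def by_expression(self, bins: ExpressionBins | None = None) -> list[StratumResult]:
        if self.model.expression is None:
            raise ValueError("model was built without an expression table")
        return stratify_by_expression(self.classified, self.model.expression, bins)

    def by_depth_window(self, d_min: int, d_max: int | None = None) -> StratumResult:
        return filter_by_depth_window(self.classified, d_min, d_max)

    def by_paralog(self) -> tuple[StratumResult, StratumResult]:
        if self.model.genes is None:
            raise ValueError("model was built without a gene (paralog) table")
        return partition_by_paralog(self.classified, self.model.genes)

    def known_site_rates(self) -> dict[str, float]:
        if self.model.known_sites is None:
            raise ValueError("model was built without a known-site list")
        return known_site_rates(self.classified, self.model.known_sites)

    def lane_curve(self, lane_callsets: Sequence[Sequence[VariantCall]]) -> list[StratumResult]:
        """Classify cumulative-lane cDNA snapshots through the same pipeline."""
        gdna, _ = self.model.prepare(self.model.gdna_calls, self.model.gdna_filter)
        prepared = [self.model.prepare(s, self.model.cdna_filter)[0] for s in lane_callsets]
        return lane_accumulation_curve(prepared, gdna, mode=self.classified.mode)

    # --- reporting ------------------------------------------------------
    def summary(self, alpha: float = 0.05) -> str:
        c = self.counts
        ci = self.conf_int(alpha)
        lines = [
            "      RNA-Seq vs genome SNV concordance",
            "=" * 48,
            f"match mode          {self.classified.mode}",
            f"gDNA calls          {c.n_gdna}",
            f"cDNA calls          {c.n_cdna}",
            f"TP / FP / FN        {c.tp} / {c.fp} / {c.fn}",
            "-" * 48,
            f"sensitivity  {c.sensitivity:7.4f}   "
            f"[{ci['sensitivity'][0]:.4f}, {ci['sensitivity'][1]:.4f}]",
            f"specificity  {c.specificity:7.4f}   "
            f"[{ci['specificity'][0]:.4f}, {ci['specificity'][1]:.4f}]",
        ]
        if self.classified.mode == "position" and self.classified.tp_pairs:
            z = self.zygosity()
            lines += [
                "-" * 48,
                f"zygosity match      {z.zygosity_match}",
                f"het gDNA, hom cDNA  {z.het_gdna_hom_cdna}",
                f"hom gDNA, het cDNA  {z.hom_gdna_het_cdna}",
                f"full allele mismatch {z.full_allele_mismatch}",
            ]
        lines.append("=" * 48)
        return "\n".join(lines)

    def plot_expression(self, bins: ExpressionBins | None = None, ax=None):
        """Sensitivity/specificity vs expression bin (requires matplotlib)."""
        import matplotlib.pyplot as plt

        strata = self.by_expression(bins)
        strata = [s for s in strata if not math.isnan(s.extras.get("bin_geometric_mid_pct", float("nan")))]
        x = [s.extras["bin_geometric_mid_pct"] for s in strata]
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(x, [s.sensitivity for s in strata], "o-", label="sensitivity")
        ax.plot(x, [s.specificity for s in strata], "s-", label="specificity")
        ax.set_xscale("log")
        ax.set_xlabel("expression (% of most expressed transcript)")
        ax.set_ylabel("metric")
        ax.set_ylim(0, 1.05)
        ax.legend()
        return ax
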