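"""Ground-truthed synthetic inputs for the concordance pipeline.

The generator emulates the statistical structure the analysis assumes,
without ever materialising reads:

* one synthetic chromosome with genes tiled at fixed gaps, one transcript
  per gene, Poisson exon counts and lengths;
* heavy-tailed (log-normal) transcript expression rescaled so the most
  highly expressed transcript is 100%;
* gDNA site depth ~ Poisson(mean 24x); cDNA exon depth ~ Poisson with mean
  proportional to expression x lanes, calibrated so the median depth of
  expressed exons (>= 4% of max) hits a configured value (126x at 8 lanes);
* binomial allele sampling for heterozygotes (p=1/2), with an optional
  allelic-imbalance process under which a heterozygous site expresses a
  single allele;
* three planted false-positive processes in cDNA: paralog misalignment
  (alt reads driven by the *partner* gene's depth), end-of-read splice
  artifacts (high alt_end_fraction), and per-base sequencing noise
  (depth-proportional, hence concentrated at high read depths);
* known-site (dbSNP-like) membership planted per class: true variants with
  one probability, artifact sites with another.

Cumulative per-lane snapshots share one realised read stream (lane l is a
subset of lane l+1), so TP monotonicity across lanes is a true property of
the draw, not an artifact of resampling.  Identical config + seed gives
byte-identical fixture bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as rcio
from .coverage import DepthTrack
from .records import (
    ExonRecord,
    ExpressionRecord,
    GeneAnnotation,
    PositionSet,
    VariantCall,
    make_genotype,
)

_BASES = np.array(["A", "C", "G", "T"])
CHROM = "chrS"


@dataclass
class SimulationConfig:
    """Generative parameters; defaults encode the emulated study conditions.

    Depth anchors: 24x mean gDNA coverage, 8 lanes of ~35M reads each, and
    a 126x median cDNA depth among expressed exons at the full 8 lanes.
    73% of genes carry a paralog; 4% of the most expressed transcript is
    the "expressed" threshold.  ``n_genes`` sets the problem size and is a
    scale knob, not a study condition.
    """

    n_genes: int = 400
    mean_exons_per_gene: float = 6.0
    mean_exon_length: float = 160.0
    min_exon_length: int = 40
    intron_gap: int = 200
    gene_gap: int = 2000
    het_rate: float = 7e-4          # truth variants per exon base
    hom_fraction: float = 0.33      # fraction of truth variants homozygous non-ref
    expression_sigma: float = 1.4   # log-normal sigma of transcript expression
    silent_fraction: float = 0.3    # genes not expressed in the tissue at all
    paralog_fraction: float = 0.73
    core_fraction: float = 0.8
    lanes: int = 8
    reads_per_lane: int = 35_000_000
    gdna_mean_depth: float = 24.0
    median_expressed_depth: float = 126.0
    expressed_threshold_pct: float = 4.0
    per_base_error: float = 0.002
    allelic_imbalance: float = 0.10  # P(a het site expresses a single allele)
    paralog_hotspot_rate: float = 5e-3   # misalignment-prone sites per paralog exon base
    paralog_fp_rate: float = 0.05        # misaligned alt reads per unit of partner depth
    paralog_fp_cap: float = 8.0          # expected misaligned reads saturate here (full lanes)
    end_hotspot_rate: float = 1e-3       # splice-edge artifact sites per exon base
    end_fp_rate: float = 0.02            # artifact alt reads per unit of host depth
    end_artifact_rate: float = 2.0 / 75.0  # baseline P(an alt-supporting base is a read end)
    artifact_end_fraction: float = 0.9     # same probability at edge-artifact sites
    noise_site_rate: float = 1.5e-3      # error-prone candidate sites per exon base
    known_site_prob_true: float = 0.94
    known_site_prob_artifact: float = 0.23
    min_alt_reads_caller: int = 3
    quality_jitter: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("het_rate", "hom_fraction", "paralog_fraction", "core_fraction",
                     "silent_fraction",
                     "per_base_error", "allelic_imbalance", "paralog_hotspot_rate",
                     "end_hotspot_rate", "end_artifact_rate", "artifact_end_fraction",
                     "noise_site_rate", "known_site_prob_true", "known_site_prob_artifact"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_genes < 1 or self.lanes < 1 or self.min_alt_reads_caller < 1:
            raise ValueError("counts must be positive")
        if self.gdna_mean_depth < 0 or self.median_expressed_depth <= 0:
            raise ValueError("depth anchors must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass(frozen=True)
class TruthVariant:
    chrom: str
    pos: int
    ref: str
    genotype: tuple[str, str]
    transcript_id: str
    gene_id: str
    exon_index: int
    in_known_sites: bool

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]


@dataclass(frozen=True)
class ArtifactSite:
    """A planted false-positive candidate site (class metadata retained)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str  # 'paralog' | 'end' | 'noise'
    transcript_id: str
    gene_id: str
    exon_index: int
    in_known_sites: bool
    partner_gene_index: int = -1  # paralog sites: index of the misaligning gene


@dataclass
class TruthSet:
    """Latent ground truth plus every annotation table the pipeline reads."""

    exons: list[ExonRecord]
    expression: list[ExpressionRecord]
    genes: list[GeneAnnotation]
    known_sites: PositionSet
    variants: list[TruthVariant]
    artifact_sites: list[ArtifactSite]
    config: SimulationConfig
    depth_coefficient: float  # per-lane cDNA depth per expression percent

    @property
    def expression_by_gene(self) -> dict[str, float]:
        tid_to_pct = {e.transcript_id: e.expression_pct for e in self.expression}
        return {t.replace("TRANS", "GENE"): p for t, p in tid_to_pct.items()}


def _gene_ids(i: int) -> tuple[str, str]:
    return f"TRANS{i:05d}", f"GENE{i:05d}"


def simulate_truth(config: SimulationConfig, rng: np.random.Generator | None = None) -> TruthSet:
    """Generate gene geometry, expression, paralogy and planted sites."""
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n = config.n_genes
    exon_counts = 1 + rng.poisson(max(config.mean_exons_per_gene - 1.0, 0.0), size=n)
    raw_expr = rng.lognormal(mean=0.0, sigma=config.expression_sigma, size=n)
    silent = rng.random(n) < config.silent_fraction
    raw_expr[silent] = 0.0
    if raw_expr.max() <= 0:
        raise ValueError("all genes silent: lower silent_fraction")
    expr_pct = raw_expr / raw_expr.max() * 100.0
    has_paralog = rng.random(n) < config.paralog_fraction
    paralog_gene_indices = np.flatnonzero(has_paralog)

    exons: list[ExonRecord] = []
    expression: list[ExpressionRecord] = []
    genes: list[GeneAnnotation] = []
    variants: list[TruthVariant] = []
    artifacts: list[ArtifactSite] = []
    known: list[tuple[str, int]] = []

    cursor = 1
    for gi in range(n):
        tid, gid = _gene_ids(gi)
        expression.append(ExpressionRecord(tid, float(expr_pct[gi])))
        genes.append(GeneAnnotation(gid, bool(has_paralog[gi])))
        for _ in range(int(exon_counts[gi])):
            length = max(config.min_exon_length, int(rng.poisson(config.mean_exon_length)))
            start, end = cursor, cursor + length - 1
            is_core = bool(rng.random() < config.core_fraction)
            exon_idx = len(exons)
            exons.append(ExonRecord(CHROM, start, end, tid, gid, is_core, True))

            n_var = int(rng.binomial(length, config.het_rate))
            n_par = (int(rng.binomial(length, config.paralog_hotspot_rate))
                     if has_paralog[gi] and len(paralog_gene_indices) > 1 else 0)
            n_end = int(rng.binomial(length, config.end_hotspot_rate))
            n_noise = int(rng.binomial(length, config.noise_site_rate))
            total = n_var + n_par + n_end + n_noise
            if total > length:
                raise ValueError(
                    f"site density exhausts exon {CHROM}:{start}-{end} "
                    f"({total} sites for {length} bases): lower the planted rates"
                )
            offsets = rng.choice(length, size=total, replace=False)
            positions = start + np.sort(offsets)
            rng.shuffle(positions)
            idx = 0

            for _ in range(n_var):
                pos = int(positions[idx]); idx += 1
                ref, alt = rng.choice(4, size=2, replace=False)
                ref_b, alt_b = str(_BASES[ref]), str(_BASES[alt])
                hom = rng.random() < config.hom_fraction
                gt = make_genotype(alt_b, alt_b) if hom else make_genotype(ref_b, alt_b)
                in_known = bool(rng.random() < config.known_site_prob_true)
                variants.append(TruthVariant(CHROM, pos, ref_b, gt, tid, gid, exon_idx, in_known))
                if in_known:
                    known.append((CHROM, pos))

            for kind, count in (("paralog", n_par), ("end", n_end), ("noise", n_noise)):
                for _ in range(count):
                    pos = int(positions[idx]); idx += 1
                    ref, alt = rng.choice(4, size=2, replace=False)
                    in_known = bool(rng.random() < config.known_site_prob_artifact)
                    partner = -1
                    if kind == "paralog":
                        choices = paralog_gene_indices[paralog_gene_indices != gi]
                        partner = int(rng.choice(choices))
                    artifacts.append(
                        ArtifactSite(CHROM, pos, str(_BASES[ref]), str(_BASES[alt]), kind,
                                     tid, gid, exon_idx, in_known, partner)
                    )
                    if in_known:
                        known.append((CHROM, pos))
            cursor = end + 1 + config.intron_gap
        cursor += config.gene_gap

    # calibrate per-lane depth per expression percent so the median depth of
    # expressed exons reaches the configured anchor at the full lane count
    expressed = [expr_pct[gi] for gi, nex in enumerate(exon_counts)
                 for _ in range(int(nex)) if expr_pct[gi] >= config.expressed_threshold_pct]
    if expressed:
        med = float(np.median(expressed))
        depth_coefficient = config.median_expressed_depth / (med * config.lanes)
    else:
        depth_coefficient = config.median_expressed_depth / (100.0 * config.lanes)

    return TruthSet(
        exons=exons,
        expression=expression,
        genes=genes,
        known_sites=PositionSet(known),
        variants=variants,
        artifact_sites=artifacts,
        config=config,
        depth_coefficient=depth_coefficient,
    )


def _quality(alt: int, depth: int, jitter_u: float, jitter_scale: float) -> float:
    """Monotone quality proxy: grows with alt support and depth, bounded noise."""
    q = 10.0 * alt + 0.05 * depth + 4.0 * jitter_u * jitter_scale
    return float(min(255.0, max(0.0, q)))


def _called_genotype(ref: str, alt: str, depth: int, alt_count: int) -> tuple[str, str]:
    """Hom-alt when the alt fraction is >= 0.9, het otherwise."""
    if depth > 0 and alt_count / depth >= 0.9:
        return make_genotype(alt, alt)
    return make_genotype(ref, alt)


def simulate_gdna_callset(
    truth: TruthSet, config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[VariantCall]:
    """Whole-genome call set: Poisson depth, binomial allele sampling.

    A truth variant is emitted iff its alt support reaches the raw caller
    gate (>= 3 reads) — at 24x this leaves the emission probability of a
    heterozygote at the closed-form Binomial(depth, 1/2) upper tail.
    Sporadic false positives arise only at planted noise sites through the
    per-base error process (a ~cubic tail in the error rate).
    """
    config = config or truth.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    calls: list[VariantCall] = []

    def emit(pos: int, ref: str, alt_allele: str, p_alt: float) -> None:
        depth = int(rng.poisson(config.gdna_mean_depth))
        u = float(rng.uniform(-1.0, 1.0))
        if depth == 0:
            return
        alt = int(rng.binomial(depth, p_alt))
        ends = int(rng.binomial(alt, config.end_artifact_rate)) if alt else 0
        if alt < config.min_alt_reads_caller:
            return
        calls.append(
            VariantCall(
                chrom=CHROM, pos=pos, ref_allele=ref,
                genotype=_called_genotype(ref, alt_allele, depth, alt),
                snp_quality=_quality(alt, depth, u, config.quality_jitter),
                read_depth=depth, alt_support=alt,
                alt_end_fraction=ends / alt if alt else 0.0,
                source="gDNA",
            )
        )

    for v in truth.variants:
        alt_allele = next(a for a in v.genotype if a != v.ref)
        p_alt = (1.0 - config.per_base_error) if not v.is_het else 0.5
        emit(v.pos, v.ref, alt_allele, p_alt)
    for site in truth.artifact_sites:
        if site.kind == "noise":
            emit(site.pos, site.ref, site.alt, config.per_base_error)
    calls.sort(key=lambda c: c.pos)
    return calls


@dataclass
class CdnaSimulation:
    """Realised cDNA call sets: full set plus nested cumulative lane snapshots."""

    calls: list[VariantCall]
    depth_track: DepthTrack
    lane_snapshots: list[list[VariantCall]]


def simulate_cdna_callset(
    truth: TruthSet, config: SimulationConfig | None = None,
    lanes: int | None = None, rng: np.random.Generator | None = None,
) -> CdnaSimulation:
    """Transcriptome call set with expression-proportional depth.

    Every site realises one per-lane read stream; snapshot l carries the
    calls supported by the first l lanes, so alt support (and hence the raw
    TP set) is non-decreasing across snapshots.  Calls are emitted at the
    raw caller gate (alt >= 3) *before* pipeline QC.
    """
    config = config or truth.config
    if lanes is None:
        lanes = config.lanes
    if not 1 <= lanes <= config.lanes:
        raise ValueError(f"lanes must lie in [1, {config.lanes}]")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)

    expr = {e.transcript_id: e.expression_pct for e in truth.expression}
    gene_expr = [e.expression_pct for e in truth.expression]  # index = gene index
    k = truth.depth_coefficient

    # per-exon per-lane depths (shared by every site in the exon)
    exon_lane_depth: list[np.ndarray] = []
    runs: list[tuple[int, int, int]] = []
    for e in truth.exons:
        lam = k * expr[e.transcript_id]
        d = rng.poisson(lam, size=lanes)
        exon_lane_depth.append(d)
        full = int(d.sum())
        if full:
            runs.append((e.start, e.end, full))
    track = DepthTrack({CHROM: runs})

    snapshots: list[list[VariantCall]] = [[] for _ in range(lanes)]

    def realize(pos: int, ref: str, alt_allele: str,
                alt_per_lane: np.ndarray, extra_depth: np.ndarray,
                host_depth: np.ndarray, p_end: float) -> None:
        ends_per_lane = rng.binomial(alt_per_lane, p_end)
        u = float(rng.uniform(-1.0, 1.0))
        alt_c = np.cumsum(alt_per_lane)
        depth_c = np.cumsum(host_depth) + np.cumsum(extra_depth)
        ends_c = np.cumsum(ends_per_lane)
        for snap in range(lanes):
            a, d, e = int(alt_c[snap]), int(depth_c[snap]), int(ends_c[snap])
            if a < config.min_alt_reads_caller:
                continue
            snapshots[snap].append(
                VariantCall(
                    chrom=CHROM, pos=pos, ref_allele=ref,
                    genotype=_called_genotype(ref, alt_allele, d, a),
                    snp_quality=_quality(a, d, u, config.quality_jitter),
                    read_depth=d, alt_support=a,
                    alt_end_fraction=e / a,
                    source="cDNA",
                )
            )

    zero = np.zeros(lanes, dtype=np.int64)
    for v in truth.variants:
        d = exon_lane_depth[v.exon_index]
        alt_allele = next(a for a in v.genotype if a != v.ref)
        if v.is_het:
            if rng.random() < config.allelic_imbalance:
                expressed_alt = rng.random() < 0.5
                p_alt = (1.0 - config.per_base_error) if expressed_alt else config.per_base_error
            else:
                p_alt = 0.5
        else:
            p_alt = 1.0 - config.per_base_error
        alt = rng.binomial(d, p_alt)
        realize(v.pos, v.ref, alt_allele, alt, zero, d, config.end_artifact_rate)

    for site in truth.artifact_sites:
        d = exon_lane_depth[site.exon_index]
        if site.kind == "paralog":
            # misaligned reads originate from the partner gene's transcript
            # pool; the pile saturates because only reads straddling the
            # homologous junction can misalign
            partner_lam = min(
                config.paralog_fp_rate * k * gene_expr[site.partner_gene_index],
                config.paralog_fp_cap / config.lanes,
            )
            x = rng.poisson(partner_lam, size=lanes)
            realize(site.pos, site.ref, site.alt, x, x, d, config.end_artifact_rate)
        elif site.kind == "end":
            x = rng.poisson(config.end_fp_rate * d)
            realize(site.pos, site.ref, site.alt, x, x, d, config.artifact_end_fraction)
        else:  # noise
            x = rng.binomial(d, config.per_base_error)
            realize(site.pos, site.ref, site.alt, x, zero, d, config.end_artifact_rate)

    for snap in snapshots:
        snap.sort(key=lambda c: c.pos)
    return CdnaSimulation(
        calls=snapshots[lanes - 1],
        depth_track=track,
        lane_snapshots=snapshots,
    )


@dataclass
class StudyData:
    """An in-memory fixture bundle: truth plus both realised call sets."""

    truth: TruthSet
    gdna_calls: list[VariantCall]
    cdna: CdnaSimulation


def simulate_study(config: SimulationConfig) -> StudyData:
    """Truth + gDNA + cDNA realisations from independent seed streams."""
    truth = simulate_truth(config)
    gdna = simulate_gdna_callset(truth)
    cdna = simulate_cdna_callset(truth)
    return StudyData(truth=truth, gdna_calls=gdna, cdna=cdna)


def _truth_json(truth: TruthSet) -> dict:
    return {
        "config": truth.config.to_dict(),
        "depth_coefficient": truth.depth_coefficient,
        "counts": {
            "genes": len(truth.genes),
            "exons": len(truth.exons),
            "truth_variants": len(truth.variants),
            "artifact_sites": len(truth.artifact_sites),
            "known_sites": len(truth.known_sites),
        },
        "variants": [
            {"chrom": v.chrom, "pos": v.pos, "ref": v.ref,
             "genotype": list(v.genotype), "transcript_id": v.transcript_id,
             "gene_id": v.gene_id, "is_het": v.is_het, "in_known_sites": v.in_known_sites}
            for v in truth.variants
        ],
        "artifact_sites": [
            {"chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt,
             "kind": s.kind, "transcript_id": s.transcript_id, "gene_id": s.gene_id,
             "in_known_sites": s.in_known_sites, "partner_gene_index": s.partner_gene_index}
            for s in truth.artifact_sites
        ],
    }


def generate_fixture_bundle(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write every pipeline input in its external format; returns the manifest.

    Files: exons.bed, expression.tsv, genes.tsv, known_sites.tsv,
    gdna.pileup.tsv, cdna.pileup.tsv, cdna.lane{l}.pileup.tsv,
    depth.bedgraph, truth.json, manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config)
    truth = study.truth

    rcio.write_exon_annotation(truth.exons, outdir / "exons.bed")
    with open(outdir / "expression.tsv", "w") as fh:
        fh.write("transcript_id\texpression_pct\n")
        for e in truth.expression:
            fh.write(f"{e.transcript_id}\t{e.expression_pct!r}\n")
    with open(outdir / "genes.tsv", "w") as fh:
        fh.write("gene_id\thas_paralog\n")
        for g in truth.genes:
            fh.write(f"{g.gene_id}\t{int(g.has_paralog)}\n")
    rcio.write_position_set(truth.known_sites, outdir / "known_sites.tsv")
    rcio.write_variant_table(study.gdna_calls, outdir / "gdna.pileup.tsv")
    rcio.write_variant_table(study.cdna.calls, outdir / "cdna.pileup.tsv")
    for i, snap in enumerate(study.cdna.lane_snapshots, start=1):
        rcio.write_variant_table(snap, outdir / f"cdna.lane{i}.pileup.tsv")
    study.cdna.depth_track.to_bedgraph(outdir / "depth.bedgraph")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(_truth_json(truth), fh, indent=1, sort_keys=True)
        fh.write("\n")

    files = sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "files": {
            name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
            for name in files
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
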