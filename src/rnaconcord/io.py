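"""Readers and writers for all external tables.

Two variant-call dialects are supported: standard VCF (via pysam) and a
pileup-style TSV mirroring a consensus caller's per-site output.  The
pileup-TSV dialect is tab-separated with a header line and columns::

    chrom  pos  ref  genotype_iupac  snp_quality  read_depth  alt_support  alt_end_fraction

Exons arrive as BED (half-open, 0-based) and are converted to the internal
1-based inclusive convention at this boundary; the BED name field encodes
``transcript_id|gene_id`` and optional extra columns 5/6 carry 0/1
core/canonical flags.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

from .records import (
    BASES,
    ExonRecord,
    ExpressionRecord,
    GeneAnnotation,
    IUPAC_TO_PAIR,
    PAIR_TO_IUPAC,
    PositionSet,
    VariantCall,
    make_genotype,
)

logger = logging.getLogger(__name__)

PILEUP_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "genotype_iupac",
    "snp_quality",
    "read_depth",
    "alt_support",
    "alt_end_fraction",
)


def convert_quality_score(encoded: int, offset_from: int = 64, offset_to: int = 33) -> int:
    """Re-base an encoded Phred character code (e.g. Illumina+64 -> Sanger+33).

    The underlying Phred value ``encoded - offset_from`` is preserved.
    """
    if encoded < offset_from:
        raise ValueError(
            f"encoded quality {encoded} below offset {offset_from}: corrupt encoding"
        )
    return encoded - offset_from + offset_to


def _parse_pileup_line(fields: Sequence[str], source: str) -> VariantCall | None:
    """One pileup-TSV row -> VariantCall, or None for an indel row."""
    chrom, pos, ref, gt_code = fields[0], int(fields[1]), fields[2].upper(), fields[3].upper()
    if ref == "*" or gt_code == "*" or "+" in gt_code or "-" in gt_code:
        return None  # indel row
    if gt_code not in IUPAC_TO_PAIR:
        raise ValueError(f"unknown IUPAC genotype code {gt_code!r}")
    return VariantCall(
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        genotype=IUPAC_TO_PAIR[gt_code],
        snp_quality=float(fields[4]),
        read_depth=int(fields[5]),
        alt_support=int(fields[6]),
        alt_end_fraction=float(fields[7]),
        source=source,
    )


def _read_pileup_tsv(path: Path, source: str) -> list[VariantCall]:
    calls: list[VariantCall] = []
    skipped_indels = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PILEUP_COLUMNS:
            raise ValueError(
                f"{path}: pileup-tsv header mismatch, expected {list(PILEUP_COLUMNS)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(PILEUP_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(PILEUP_COLUMNS)} columns, got {len(fields)}"
                )
            try:
                call = _parse_pileup_line(fields, source)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            if call is None:
                skipped_indels += 1
            else:
                calls.append(call)
    if skipped_indels:
        logger.info("%s: skipped %d indel rows", path, skipped_indels)
    return calls


def _read_vcf(path: Path, source: str) -> list[VariantCall]:
    import pysam

    calls: list[VariantCall] = []
    skipped_indels = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alleles = [rec.ref] + list(rec.alts or ())
            if any(a is None or len(a) != 1 or a.upper() not in BASES for a in alleles):
                skipped_indels += 1
                continue
            if not rec.samples:
                raise ValueError(f"{path}: VCF has no sample column at {rec.chrom}:{rec.pos}")
            sample = rec.samples[0]
            gt_idx = sample.get("GT")
            if gt_idx is None or any(i is None for i in gt_idx) or len(gt_idx) != 2:
                logger.warning("%s: missing/partial GT at %s:%d, row skipped", path, rec.chrom, rec.pos)
                continue
            called = [alleles[i].upper() for i in gt_idx]
            if len(set(called)) > 2:
                logger.warning(
                    "%s: >2 distinct alleles called at %s:%d, row rejected", path, rec.chrom, rec.pos
                )
                continue
            depth = rec.info.get("DP", sample.get("DP"))
            if depth is None:
                raise ValueError(f"{path}: DP missing at {rec.chrom}:{rec.pos}")
            ad = sample.get("AD")
            if ad is None:
                raise ValueError(f"{path}: AD missing at {rec.chrom}:{rec.pos}")
            alt_support = int(sum(ad[1:]))
            endfrac = rec.info.get("ENDFRAC")
            if endfrac is None:
                logger.warning(
                    "%s: ENDFRAC absent at %s:%d, assuming 0", path, rec.chrom, rec.pos
                )
                endfrac = 0.0
            calls.append(
                VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref.upper(),
                    genotype=make_genotype(called[0], called[-1]),
                    snp_quality=float(rec.qual if rec.qual is not None else 0.0),
                    read_depth=int(depth),
                    alt_support=alt_support,
                    alt_end_fraction=float(endfrac),
                    source=source,
                )
            )
    if skipped_indels:
        logger.info("%s: skipped %d indel/non-SNV rows", path, skipped_indels)
    return calls


def read_variant_table(path: str | Path, dialect: str, source: str) -> list[VariantCall]:
    """Read a variant call table in the given dialect ('vcf' or 'pileup-tsv')."""
    path = Path(path)
    if source not in ("gDNA", "cDNA"):
        raise ValueError(f"source must be 'gDNA' or 'cDNA', got {source!r}")
    if dialect == "pileup-tsv":
        return _read_pileup_tsv(path, source)
    if dialect == "vcf":
        return _read_vcf(path, source)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_variant_table(calls: Iterable[VariantCall], path: str | Path) -> None:
    """Write calls in the pileup-TSV dialect (lossless for the core fields)."""
    with open(path, "w") as fh:
        fh.write("\t".join(PILEUP_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    (
                        c.chrom,
                        str(c.pos),
                        c.ref_allele,
                        PAIR_TO_IUPAC[c.genotype],
                        repr(float(c.snp_quality)),
                        str(c.read_depth),
                        str(c.alt_support),
                        repr(float(c.alt_end_fraction)),
                    )
                )
                + "\n"
            )


def dedup_calls(calls: Iterable[VariantCall]) -> list[VariantCall]:
    """Collapse duplicate (chrom, pos) records within one call set.

    Keeps the highest-quality record; exact quality ties break
    deterministically on (chrom, pos, genotype) lexicographic order.
    """
    best: dict[tuple[str, int], VariantCall] = {}
    for c in calls:
        cur = best.get(c.key)
        if (
            cur is None
            or c.snp_quality > cur.snp_quality
            or (c.snp_quality == cur.snp_quality and c.genotype < cur.genotype)
        ):
            best[c.key] = c
    return [best[k] for k in sorted(best)]


def read_exon_annotation(path: str | Path) -> list[ExonRecord]:
    """Read exons from BED; convert half-open 0-based to 1-based inclusive."""
    path = Path(path)
    records: list[ExonRecord] = []
    seen: set[tuple[str, int, int, str]] = set()
    duplicates = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs >= 4 columns")
            chrom, bed_start, bed_end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            start, end = bed_start + 1, bed_end
            if end < start:
                raise ValueError(
                    f"{path}:{lineno}: empty/negative interval after BED conversion"
                )
            try:
                transcript_id, gene_id = name.split("|", 1)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: BED name must be 'transcript_id|gene_id', got {name!r}"
                ) from exc
            is_core = len(fields) > 4 and fields[4] not in ("0", ".", "")
            is_canonical = len(fields) > 5 and fields[5] not in ("0", ".", "")
            key = (chrom, start, end, transcript_id)
            if key in seen:
                duplicates += 1
                continue
            seen.add(key)
            records.append(
                ExonRecord(chrom, start, end, transcript_id, gene_id, is_core, is_canonical)
            )
    if duplicates:
        logger.info("%s: dropped %d duplicate exon lines", path, duplicates)
    if not records:
        logger.warning("%s: no exon records read", path)
    return records


def write_exon_annotation(exons: Iterable[ExonRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in exons:
            fh.write(
                f"{e.chrom}\t{e.start - 1}\t{e.end}\t{e.transcript_id}|{e.gene_id}"
                f"\t{int(e.is_core)}\t{int(e.is_canonical)}\n"
            )


def _read_tsv_rows(path: Path, required: Sequence[str]) -> list[dict[str, str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for col in required:
            if col not in header:
                raise ValueError(f"{path}: missing required column {col!r}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValueError(f"{path}:{lineno}: column count mismatch")
            rows.append(dict(zip(header, fields)))
    return rows


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Per-transcript expression on the percent-of-max scale (0-100)."""
    path = Path(path)
    rows = _read_tsv_rows(path, ("transcript_id", "expression_pct"))
    seen: set[str] = set()
    out: list[ExpressionRecord] = []
    for row in rows:
        tid = row["transcript_id"]
        if tid in seen:
            raise ValueError(f"{path}: duplicate transcript_id {tid!r}")
        seen.add(tid)
        pct = float(row["expression_pct"])
        if math.isnan(pct) or not 0.0 <= pct <= 100.0:
            raise ValueError(f"{path}: expression_pct {pct} outside [0, 100] for {tid}")
        out.append(ExpressionRecord(tid, pct))
    return out


def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    path = Path(path)
    rows = _read_tsv_rows(path, ("gene_id", "has_paralog"))
    seen: set[str] = set()
    out: list[GeneAnnotation] = []
    truthy, falsy = {"1", "true", "yes"}, {"0", "false", "no"}
    for row in rows:
        gid = row["gene_id"]
        if gid in seen:
            raise ValueError(f"{path}: duplicate gene_id {gid!r}")
        seen.add(gid)
        flag = row["has_paralog"].strip().lower()
        if flag in truthy:
            out.append(GeneAnnotation(gid, True))
        elif flag in falsy:
            out.append(GeneAnnotation(gid, False))
        else:
            raise ValueError(f"{path}: unparseable has_paralog value {row['has_paralog']!r}")
    return out


def read_position_set(path: str | Path) -> PositionSet:
    """Known-site (dbSNP-like) positions; duplicates collapse silently."""
    path = Path(path)
    rows = _read_tsv_rows(path, ("chrom", "pos"))
    return PositionSet((row["chrom"], int(row["pos"])) for row in rows)


def write_position_set(sites: PositionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\n")
        for chrom, pos in sites:
            fh.write(f"{chrom}\t{pos}\n")
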