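"""Readers and writers for the standard formats the pipeline consumes.

VCF v4.2 (via pysam) for variant calls, BED 3+2 (chrom, start, end, gene,
coding_flag) for the panel definition, and TSV (chrom, start, end, depth)
run-length tables for depth profiles.  All readers transparently accept
gzip-compressed input.
"""

from __future__ import annotations

import gzip
import os
from typing import Iterable, Sequence

import numpy as np
import pysam

from .core import DepthProfile, GenomicInterval, VariantRecord

__all__ = [
    "read_variants",
    "write_variants",
    "read_panel_bed",
    "write_panel_bed",
    "read_depth_tsv",
    "write_depth_tsv",
]

# VAF is quantized to this many decimals on write and read so that the
# VCF Float (32-bit) round-trip is exact.
_VAF_DECIMALS = 6

_INFO_LINES = [
    ('CONS', 'A', 'String', 'Annotated consequence category'),
    ('CODING', 'A', 'Integer', 'Allele lies in a coding region (1/0)'),
    ('DBSNP', 'A', 'Integer', 'Allele present in dbSNP (likely germline, 1/0)'),
    ('PATHO', 'A', 'Float', 'Predicted pathogenicity score in [0,1]'),
    ('REC', 'A', 'Integer', 'Recurrence count in large cancer databases'),
    ('WL', 'A', 'Integer', 'Internally validated tumor-derived mutation (1/0)'),
]


def _open_text(path: str | os.PathLike):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_variants(vcf_path: str | os.PathLike) -> list[VariantRecord]:
    """Read a VCF into :class:`VariantRecord` objects, one per ALT allele.

    Multi-allelic sites are decomposed, with per-allele depths taken from the
    AD ordering.  An explicit per-allele VAF FORMAT tag is trusted when
    present; otherwise VAF is recomputed as alt_depth / total_depth.

    Raises ``ValueError`` for malformed rows or records lacking depth fields.
    """
    out: list[VariantRecord] = []
    with pysam.VariantFile(os.fspath(vcf_path)) as vf:
        if len(vf.header.samples) < 1:
            # site-only VCF: must still be iterable (empty body is fine)
            for rec in vf:
                raise ValueError(
                    f"VCF record {rec.chrom}:{rec.pos} has no sample with depth fields"
                )
            return out
        sample = vf.header.samples[0]
        for rec in vf:
            try:
                out.extend(_decompose(rec, sample))
            except (KeyError, TypeError) as exc:
                raise ValueError(
                    f"VCF record {rec.chrom}:{rec.pos} missing depth fields: {exc}"
                ) from exc
    return out


def _info_per_allele(rec, tag: str, i: int, default):
    try:
        val = rec.info.get(tag)
    except (KeyError, ValueError):  # tag absent from the header
        return default
    if val is None:
        return default
    if isinstance(val, tuple):
        return val[i] if i < len(val) and val[i] is not None else default
    return val


def _decompose(rec, sample: str) -> list[VariantRecord]:
    fmt = rec.samples[sample]
    ad = fmt.get("AD")
    if ad is None:
        raise KeyError("AD")
    dp = fmt.get("DP")
    if dp is None:
        dp = int(sum(x for x in ad if x is not None))
    vaf_tag = fmt.get("VAF")
    filter_pass = (len(rec.filter) == 0) or ("PASS" in rec.filter)
    records = []
    for i, alt in enumerate(rec.alts or ()):
        alt_depth = int(ad[i + 1]) if ad[i + 1] is not None else 0
        if vaf_tag is not None:
            v = vaf_tag[i] if isinstance(vaf_tag, tuple) else vaf_tag
            vaf = round(float(v), _VAF_DECIMALS)
        else:
            vaf = round(alt_depth / dp, _VAF_DECIMALS) if dp > 0 else 0.0
        records.append(
            VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=alt,
                vaf=vaf,
                alt_depth=alt_depth,
                total_depth=int(dp),
                filter_pass=filter_pass,
                in_dbsnp=bool(_info_per_allele(rec, "DBSNP", i, 0)),
                consequence=str(_info_per_allele(rec, "CONS", i, "missense")),
                is_coding=bool(_info_per_allele(rec, "CODING", i, 1)),
            )
        )
    return records


def write_variants(
    vcf_path: str | os.PathLike,
    variants: Sequence[VariantRecord],
    annotations: dict[tuple, dict] | None = None,
    sample: str = "TUMOR",
) -> None:
    """Write variants to a single-sample VCF.

    ``annotations`` optionally maps variant keys (chrom, pos, ref, alt) to
    dicts with ``pathogenicity``, ``recurrence`` and ``whitelist`` entries,
    emitted as PATHO/REC/WL INFO fields for downstream MRD ranking.
    """
    header = pysam.VariantHeader()
    header.filters.add("artifact", None, None, "Failed caller post-filtering")
    for tag, num, typ, desc in _INFO_LINES:
        header.info.add(tag, num, typ, desc)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt...)")
    header.formats.add("DP", "1", "Integer", "Total read depth")
    header.formats.add("VAF", "A", "Float", "Variant allele fraction")
    for chrom in dict.fromkeys(v.chrom for v in variants):
        header.contigs.add(chrom)
    header.add_sample(sample)
    annotations = annotations or {}
    with pysam.VariantFile(os.fspath(vcf_path), "w", header=header) as vf:
        for v in sorted(variants, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            rec = vf.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                alleles=(v.ref, v.alt),
                filter="PASS" if v.filter_pass else "artifact",
            )
            rec.info["CONS"] = (v.consequence,)
            rec.info["CODING"] = (int(v.is_coding),)
            rec.info["DBSNP"] = (int(v.in_dbsnp),)
            ann = annotations.get(v.key)
            if ann:
                if "pathogenicity" in ann:
                    rec.info["PATHO"] = (float(ann["pathogenicity"]),)
                if "recurrence" in ann:
                    rec.info["REC"] = (int(ann["recurrence"]),)
                if "whitelist" in ann:
                    rec.info["WL"] = (int(ann["whitelist"]),)
            rec.samples[sample]["AD"] = (v.total_depth - v.alt_depth, v.alt_depth)
            rec.samples[sample]["DP"] = v.total_depth
            rec.samples[sample]["VAF"] = round(v.vaf, _VAF_DECIMALS)
            vf.write(rec)


def read_annotations(vcf_path: str | os.PathLike) -> dict[tuple, dict]:
    """Extract MRD-ranking annotations (PATHO/REC/WL) keyed by variant."""
    out: dict[tuple, dict] = {}
    with pysam.VariantFile(os.fspath(vcf_path)) as vf:
        for rec in vf:
            for i, alt in enumerate(rec.alts or ()):
                key = (rec.chrom, rec.pos, rec.ref, alt)
                ann = {}
                patho = _info_per_allele(rec, "PATHO", i, None)
                recur = _info_per_allele(rec, "REC", i, None)
                wl = _info_per_allele(rec, "WL", i, None)
                if patho is not None:
                    ann["pathogenicity"] = round(float(patho), _VAF_DECIMALS)
                if recur is not None:
                    ann["recurrence"] = int(recur)
                if wl is not None:
                    ann["whitelist"] = bool(wl)
                if ann:
                    out[key] = ann
    return out


def read_panel_bed(bed_path: str | os.PathLike) -> list[GenomicInterval]:
    """Read a 3+2-column BED panel (chrom, start, end, gene, coding_flag)."""
    panel: list[GenomicInterval] = []
    with _open_text(bed_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{bed_path}: line {ln}: expected >=3 BED columns")
            gene = parts[3] if len(parts) > 3 else ""
            coding = bool(int(parts[4])) if len(parts) > 4 else False
            panel.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), gene, coding)
            )
    return panel


def write_panel_bed(bed_path: str | os.PathLike, panel: Iterable[GenomicInterval]) -> None:
    with open(bed_path, "w") as fh:
        for iv in panel:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.gene}\t{int(iv.is_coding)}\n")


def read_depth_tsv(tsv_path: str | os.PathLike) -> DepthProfile:
    """Read a run-length depth table (chrom, start, end, depth) into a
    :class:`DepthProfile`.  Consecutive rows on a chromosome must not overlap.
    """
    intervals: list[GenomicInterval] = []
    depths: list[np.ndarray] = []
    with _open_text(tsv_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{tsv_path}: line {ln}: expected 4 columns")
            chrom, start, end, depth = parts[0], int(parts[1]), int(parts[2]), int(parts[3])
            intervals.append(GenomicInterval(chrom, start, end))
            depths.append(np.full(end - start, depth, dtype=np.int64))
    flat = np.concatenate(depths) if depths else np.empty(0, dtype=np.int64)
    return DepthProfile(intervals, flat)


def write_depth_tsv(tsv_path: str | os.PathLike, profile: DepthProfile) -> None:
    """Write a depth profile as a run-length (chrom, start, end, depth) TSV."""
    with open(tsv_path, "w") as fh:
        off = 0
        for iv in profile.intervals:
            d = profile.depth[off : off + iv.length]
            off += iv.length
            # run-length encode within the interval
            change = np.flatnonzero(np.diff(d)) + 1
            bounds = np.concatenate(([0], change, [iv.length]))
            for a, b in zip(bounds[:-1], bounds[1:]):
                fh.write(f"{iv.chrom}\t{iv.start + a}\t{iv.start + b}\t{int(d[a])}\n")
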