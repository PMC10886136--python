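"""Gene fusion calling from split-read breakpoint evidence.

Each soft-clipped read whose clipped remainder re-aligns to a second panel
gene contributes one piece of breakpoint evidence.  Evidence is clustered
when both partner loci agree within a positional tolerance; a fusion is
reported when a cluster is supported by at least 2 distinct
breakpoint-spanning reads.  Detection is DNA-level (intron-targeted); only
inter-gene events are considered.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pysam

from .core import GenomicInterval

__all__ = [
    "Locus",
    "BreakpointEvidence",
    "FusionCall",
    "cluster_breakpoints",
    "detect_fusions",
    "evidence_from_sam",
    "read_evidence_tsv",
    "write_evidence_tsv",
]

MIN_SPANNING_READS = 2
DEFAULT_TOLERANCE = 5
DEFAULT_MIN_CLIP = 20


@dataclass(frozen=True)
class Locus:
    chrom: str
    pos: int
    strand: str  # "+" | "-"


@dataclass(frozen=True)
class BreakpointEvidence:
    """One split read supporting a putative junction: the aligned segment
    ends at ``locus_a`` and its soft-clipped remainder re-aligns at
    ``locus_b``."""

    read_id: str
    locus_a: Locus
    locus_b: Locus
    clip_length: int
    gene_a: str = ""
    gene_b: str = ""


@dataclass(frozen=True)
class FusionCall:
    gene_pair: tuple[str, str]  # alphabetically ordered
    breakpoint_a: Locus
    breakpoint_b: Locus
    spanning_reads: int
    reported: bool


def _oriented(e: BreakpointEvidence) -> BreakpointEvidence:
    """Normalize evidence so locus_a sorts before locus_b; both read
    orientations of the same junction then collapse together."""
    if (e.locus_a.chrom, e.locus_a.pos) <= (e.locus_b.chrom, e.locus_b.pos):
        return e
    return BreakpointEvidence(
        e.read_id, e.locus_b, e.locus_a, e.clip_length, e.gene_b, e.gene_a
    )


def _modal_locus(loci: Sequence[Locus]) -> Locus:
    pos = Counter(l.pos for l in loci)
    best = min(p for p, c in pos.items() if c == max(pos.values()))
    strand = Counter(l.strand for l in loci).most_common(1)[0][0]
    return Locus(loci[0].chrom, best, strand)


def cluster_breakpoints(
    evidence: Iterable[BreakpointEvidence],
    tolerance: int = DEFAULT_TOLERANCE,
    min_reads: int = MIN_SPANNING_READS,
) -> list[FusionCall]:
    """Cluster breakpoint evidence into fusion calls.

    Two pieces of evidence join the same cluster when they share both
    partner chromosomes and their positions agree within ``tolerance`` bp at
    both loci (single linkage: agreement is transitive across the cluster).
    ``spanning_reads`` counts distinct read ids; the consensus breakpoint is
    the modal position.  A call is ``reported`` iff it reaches
    ``min_reads`` spanning reads.
    """
    ev = [_oriented(e) for e in evidence]
    calls: list[FusionCall] = []
    # partition by chromosome pair first; link within partitions
    groups: dict[tuple[str, str], list[BreakpointEvidence]] = {}
    for e in ev:
        groups.setdefault((e.locus_a.chrom, e.locus_b.chrom), []).append(e)
    for key in sorted(groups):
        members = groups[key]
        parent = list(range(len(members)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if (
                    abs(a.locus_a.pos - b.locus_a.pos) <= tolerance
                    and abs(a.locus_b.pos - b.locus_b.pos) <= tolerance
                ):
                    parent[find(i)] = find(j)
        clusters: dict[int, list[BreakpointEvidence]] = {}
        for i in range(len(members)):
            clusters.setdefault(find(i), []).append(members[i])
        for root in sorted(clusters, key=lambda r: min(m.locus_a.pos for m in clusters[r])):
            cluster = clusters[root]
            n_reads = len({m.read_id for m in cluster})
            gene_a = Counter(m.gene_a for m in cluster).most_common(1)[0][0]
            gene_b = Counter(m.gene_b for m in cluster).most_common(1)[0][0]
            pair = tuple(sorted((gene_a, gene_b)))
            calls.append(
                FusionCall(
                    gene_pair=pair,  # type: ignore[arg-type]
                    breakpoint_a=_modal_locus([m.locus_a for m in cluster]),
                    breakpoint_b=_modal_locus([m.locus_b for m in cluster]),
                    spanning_reads=n_reads,
                    reported=n_reads >= min_reads,
                )
            )
    return calls


def _gene_at(panel_index: dict[str, list[GenomicInterval]], locus: Locus) -> str:
    for iv in panel_index.get(locus.chrom, ()):
        if iv.start <= locus.pos < iv.end:
            return iv.gene
    return ""


def detect_fusions(
    evidence: Iterable[BreakpointEvidence],
    panel: Sequence[GenomicInterval],
    min_clip: int = DEFAULT_MIN_CLIP,
    tolerance: int = DEFAULT_TOLERANCE,
    min_reads: int = MIN_SPANNING_READS,
) -> list[FusionCall]:
    """Assign panel genes to evidence loci, drop intra-gene and off-panel
    events and short clips, then cluster and report.

    Evidence whose clip is shorter than ``min_clip``, whose loci fall outside
    panel genes, or whose two loci map to the same gene is excluded.
    """
    index: dict[str, list[GenomicInterval]] = {}
    for iv in panel:
        index.setdefault(iv.chrom, []).append(iv)
    kept: list[BreakpointEvidence] = []
    for e in evidence:
        if e.clip_length < min_clip:
            continue
        ga = e.gene_a or _gene_at(index, e.locus_a)
        gb = e.gene_b or _gene_at(index, e.locus_b)
        if not ga or not gb or ga == gb:
            continue
        kept.append(
            BreakpointEvidence(e.read_id, e.locus_a, e.locus_b, e.clip_length, ga, gb)
        )
    return cluster_breakpoints(kept, tolerance=tolerance, min_reads=min_reads)


def evidence_from_sam(sam_path, min_clip: int = DEFAULT_MIN_CLIP) -> tuple[list[BreakpointEvidence], int]:
    """Extract breakpoint evidence from a SAM/BAM with SA supplementary tags.

    The primary alignment's terminal soft clip marks locus_a; the SA tag's
    first entry gives locus_b where the clipped remainder re-aligns.  Returns
    (evidence, n_skipped) where ``n_skipped`` counts clipped reads without an
    SA annotation.
    """
    out: list[BreakpointEvidence] = []
    skipped = 0
    with pysam.AlignmentFile(sam_path, check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.is_supplementary or read.is_secondary:
                continue
            cig = read.cigartuples or []
            if not cig:
                continue
            clip_len, at_start = 0, False
            if cig[0][0] == 4 and cig[0][1] >= min_clip:
                clip_len, at_start = cig[0][1], True
            elif cig[-1][0] == 4 and cig[-1][1] >= min_clip:
                clip_len = cig[-1][1]
            if clip_len == 0:
                continue
            if not read.has_tag("SA"):
                skipped += 1
                continue
            sa = read.get_tag("SA").split(";")[0].split(",")
            pos_a = read.reference_start if at_start else read.reference_end
            out.append(
                BreakpointEvidence(
                    read_id=read.query_name,
                    locus_a=Locus(read.reference_name, int(pos_a), "-" if read.is_reverse else "+"),
                    locus_b=Locus(sa[0], int(sa[1]) - 1, sa[2]),
                    clip_length=clip_len,
                )
            )
    return out, skipped


def read_evidence_tsv(path) -> list[BreakpointEvidence]:
    """Read evidence TSV: read_id, chromA, posA, strandA, chromB, posB,
    strandB, clip_len."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            if len(p) != 8:
                raise ValueError(f"{path}: line {ln}: expected 8 columns")
            out.append(
                BreakpointEvidence(
                    p[0],
                    Locus(p[1], int(p[2]), p[3]),
                    Locus(p[4], int(p[5]), p[6]),
                    int(p[7]),
                )
            )
    return out


def write_evidence_tsv(path, evidence: Iterable[BreakpointEvidence]) -> None:
    with open(path, "w") as fh:
        for e in evidence:
            fh.write(
                f"{e.read_id}\t{e.locus_a.chrom}\t{e.locus_a.pos}\t{e.locus_a.strand}\t"
                f"{e.locus_b.chrom}\t{e.locus_b.pos}\t{e.locus_b.strand}\t{e.clip_length}\n"
            )
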