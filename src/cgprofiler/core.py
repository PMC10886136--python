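"""Core domain types and sample-level QC for tumor-normal panel profiling.

Coordinate conventions: BED-style intervals are 0-based half-open
(``start`` inclusive, ``end`` exclusive); VCF variant positions are 1-based.
All internal interval arithmetic is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "VariantRecord",
    "SampleQC",
    "DepthProfile",
    "qc_gate",
    "effective_panel_size",
    "filter_clustered",
    "CONSEQUENCES",
]

#: Recognised consequence categories for annotated variants.
CONSEQUENCES = frozenset(
    {
        "synonymous",
        "missense",
        "nonsense",
        "frameshift",
        "inframe_indel",
        "splice",
        "noncoding",
    }
)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, optionally tagged with a gene symbol.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive.
    """

    chrom: str
    start: int
    end: int
    gene: str = ""
    is_coding: bool = False

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class VariantRecord:
    """One somatic or germline small-variant call (single ALT allele).

    ``pos`` is the 1-based VCF position.  ``vaf`` is the alt allele fraction
    in [0, 1].  ``in_dbsnp`` marks likely-germline sites seen in population
    databases; ``consequence`` is the pre-annotated coding effect.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    alt_depth: int
    total_depth: int
    filter_pass: bool = True
    in_dbsnp: bool = False
    consequence: str = "missense"
    is_coding: bool = True
    variant_class: str = field(default="")

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")
        if self.alt_depth < 0 or self.total_depth < 0:
            raise ValueError("read depths must be non-negative")
        if self.alt_depth > self.total_depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} exceeds total_depth {self.total_depth}"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must lie in [0, 1], got {self.vaf}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.total_depth > 0:
            # VAF must agree with the depths up to count-rounding slack.
            if abs(self.vaf - self.alt_depth / self.total_depth) > 2.0 / self.total_depth:
                raise ValueError(
                    f"vaf {self.vaf} inconsistent with depths "
                    f"{self.alt_depth}/{self.total_depth}"
                )
        if not self.variant_class:
            cls = "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"
            object.__setattr__(self, "variant_class", cls)
        elif self.variant_class not in ("SNV", "INDEL"):
            raise ValueError(f"variant_class must be SNV or INDEL, got {self.variant_class!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Exact-allele identity used for truth-set matching."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SampleQC:
    """Sequencing-level sample QC: mean on-target depth and breadth at 100X."""

    mean_depth: float
    pct_cov_100x: float
    passed: bool


def qc_gate(mean_depth: float, pct_cov_100x: float) -> SampleQC:
    """Apply the sample QC gate: mean depth >= 150X and >= 75% of panel
    bases covered at 100X.  Both comparisons are inclusive.

    Raises ``ValueError`` for a negative depth or a percentage outside
    [0, 100].
    """
    if mean_depth < 0:
        raise ValueError(f"mean_depth must be >= 0, got {mean_depth}")
    if not 0.0 <= pct_cov_100x <= 100.0:
        raise ValueError(f"pct_cov_100x must lie in [0, 100], got {pct_cov_100x}")
    passed = (mean_depth >= 150.0) and (pct_cov_100x >= 75.0)
    return SampleQC(mean_depth=float(mean_depth), pct_cov_100x=float(pct_cov_100x), passed=passed)


class DepthProfile:
    """Per-base read depth over a set of genomic intervals.

    Stores one flat integer depth array aligned to the concatenation of the
    intervals, with a per-chromosome index for region queries.
    """

    def __init__(self, intervals: Sequence[GenomicInterval], depth: np.ndarray):
        depth = np.asarray(depth)
        if depth.ndim != 1:
            raise ValueError("depth must be a 1-D array")
        total = sum(iv.length for iv in intervals)
        if depth.size != total:
            raise ValueError(
                f"depth array length {depth.size} does not match total interval "
                f"length {total}"
            )
        if depth.size and depth.min() < 0:
            raise ValueError("depth values must be non-negative")
        self.intervals = list(intervals)
        self.depth = depth.astype(np.int64, copy=False)
        # index: chrom -> (starts, ends, offsets) sorted by start
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        offsets: dict[str, list[tuple[int, int, int]]] = {}
        off = 0
        for iv in self.intervals:
            offsets.setdefault(iv.chrom, []).append((iv.start, iv.end, off))
            off += iv.length
        for chrom, rows in offsets.items():
            rows.sort()
            starts = np.array([r[0] for r in rows])
            ends = np.array([r[1] for r in rows])
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping depth intervals on {chrom}")
            offs = np.array([r[2] for r in rows])
            self._index[chrom] = (starts, ends, offs)

    @property
    def n_bases(self) -> int:
        return int(self.depth.size)

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if self.depth.size else 0.0

    @property
    def pct_cov_100x(self) -> float:
        if not self.depth.size:
            return 0.0
        return float(100.0 * (self.depth >= 100).mean())

    def qc(self) -> SampleQC:
        """Sample QC computed from this profile."""
        return qc_gate(self.mean_depth, self.pct_cov_100x)

    def region_depth(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base depths over [start, end); raises ``KeyError`` if any base
        of the region is not covered by the profile."""
        if chrom not in self._index:
            raise KeyError(f"chromosome {chrom!r} not in depth profile")
        starts, ends, offs = self._index[chrom]
        out = np.empty(end - start, dtype=np.int64)
        pos = start
        while pos < end:
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            if i < 0 or pos >= ends[i]:
                raise KeyError(f"position {chrom}:{pos} not covered by depth profile")
            take = min(end, int(ends[i])) - pos
            src = offs[i] + (pos - starts[i])
            out[pos - start : pos - start + take] = self.depth[src : src + take]
            pos += take
        return out

    def depth_at(self, chrom: str, pos0: int) -> int:
        """Depth at a single 0-based position."""
        return int(self.region_depth(chrom, pos0, pos0 + 1)[0])

    def thinned(self, target_mean_depth: float, rng: np.random.Generator) -> "DepthProfile":
        """Binomially downsample every base toward a target mean depth."""
        if self.mean_depth <= 0:
            raise ValueError("cannot thin an empty/zero-depth profile")
        p = min(1.0, target_mean_depth / self.mean_depth)
        return DepthProfile(self.intervals, rng.binomial(self.depth, p))


def effective_panel_size(
    depth_profile: DepthProfile,
    panel: Iterable[GenomicInterval],
    min_depth: int = 15,
) -> int:
    """Number of coding panel bases with depth >= ``min_depth``.

    This is the TMB denominator: the panel size is counted only over coding
    bases that reached the minimal total depth.  Non-coding panel intervals
    never contribute.  Raises ``ValueError`` naming the intervals the depth
    profile does not cover.
    """
    count = 0
    uncovered: list[str] = []
    for iv in panel:
        if not iv.is_coding:
            continue
        try:
            d = depth_profile.region_depth(iv.chrom, iv.start, iv.end)
        except KeyError:
            uncovered.append(f"{iv.chrom}:{iv.start}-{iv.end}")
            continue
        count += int((d >= min_depth).sum())
    if uncovered:
        raise ValueError(
            "depth profile does not cover panel intervals: " + ", ".join(uncovered)
        )
    return count


def filter_clustered(
    variants: Sequence[VariantRecord],
    max_in_window: int = 2,
    window: int = 10,
) -> list[VariantRecord]:
    """Remove clustered events: discard every variant belonging to a
    ``window``-bp stretch holding more than ``max_in_window`` variants on the
    same chromosome.  Such clusters are characteristic FFPE/processing
    artifacts rather than independent somatic events.
    """
    order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos))
    drop: set[int] = set()
    for a in range(len(order)):
        ia = order[a]
        run = [ia]
        for b in range(a + 1, len(order)):
            ib = order[b]
            if variants[ib].chrom != variants[ia].chrom:
                break
            if variants[ib].pos - variants[ia].pos > window:
                break
            run.append(ib)
        if len(run) > max_in_window:
            drop.update(run)
    return [v for i, v in enumerate(variants) if i not in drop]
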