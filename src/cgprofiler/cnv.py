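"""Gene amplification calling from binned on-target coverage.

Coverage is summarised in 100-bp bins over panel regions, library-size
normalized, and divided by a panel-of-normals baseline (per-bin median of
normalized coverage across a normal cohort).  A gene is called amplified
when the mean copy ratio over its bins (the segment mean, linear scale) is
at least 2.0 — at full purity that corresponds to four or more copies,
which makes the +3-copy reference standards callable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval

__all__ = [
    "NormalBaseline",
    "CopyRatioTrack",
    "build_baseline",
    "call_amplification",
    "read_bin_coverage_tsv",
    "write_bin_coverage_tsv",
]

AMPLIFICATION_THRESHOLD = 2.0
LOSS_THRESHOLD = 0.5  # reported as "loss" only; not analytically validated


@dataclass
class NormalBaseline:
    """Panel-of-normals coverage baseline on a fixed 100-bp bin grid."""

    bins: list[GenomicInterval]
    level: np.ndarray  # per-bin median of library-size-normalized coverage
    dispersion: np.ndarray  # per-bin median absolute deviation
    mask: np.ndarray  # True where the bin is usable (median > 0)
    n_normals: int

    def __post_init__(self) -> None:
        n = len(self.bins)
        if not (len(self.level) == len(self.dispersion) == len(self.mask) == n):
            raise ValueError("baseline arrays must match the bin grid")


@dataclass
class CopyRatioTrack:
    """Per-bin copy ratios and per-gene segment means for one sample."""

    bins: list[GenomicInterval]
    ratio: np.ndarray  # per-bin copy ratio; NaN where masked
    genes: pd.DataFrame  # columns: gene, n_bins, segment_mean, amplified, loss, callable


def _normalize(coverage: np.ndarray) -> np.ndarray:
    """Scale a coverage vector to unit mean (library-size normalization)."""
    total = coverage.sum()
    if total <= 0:
        raise ValueError("coverage sums to zero; cannot normalize")
    return coverage * (coverage.size / total)


def build_baseline(
    normal_coverages: Sequence[np.ndarray],
    bins: Sequence[GenomicInterval],
    gc_correct: Callable[[np.ndarray], np.ndarray] | None = None,
) -> NormalBaseline:
    """Build the panel-of-normals baseline from >= 2 normal-sample
    coverage vectors on an identical bin grid.

    Each sample is library-size normalized before taking the per-bin median;
    bins whose median is zero are masked.  ``gc_correct`` is an optional
    per-sample correction hook (off by default).
    """
    if len(normal_coverages) < 2:
        raise ValueError("need at least 2 normal samples to build a baseline")
    n_bins = len(bins)
    mat = []
    for i, cov in enumerate(normal_coverages):
        cov = np.asarray(cov, dtype=float)
        if cov.shape != (n_bins,):
            raise ValueError(f"normal sample {i}: coverage grid mismatch ({cov.shape} vs {n_bins} bins)")
        cov = _normalize(cov)
        if gc_correct is not None:
            cov = gc_correct(cov)
        mat.append(cov)
    mat = np.vstack(mat)
    level = np.median(mat, axis=0)
    dispersion = np.median(np.abs(mat - level), axis=0)
    mask = level > 0
    return NormalBaseline(list(bins), level, dispersion, mask, n_normals=len(normal_coverages))


def call_amplification(
    sample_coverage: np.ndarray,
    baseline: NormalBaseline,
    threshold: float = AMPLIFICATION_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
) -> CopyRatioTrack:
    """Call per-gene amplification from one sample's binned coverage.

    The sample is library-size normalized, divided by the baseline level
    bin-wise, and recentred by the median ratio so the diploid state sits at
    1.0 even when amplified bins inflate the library size; each gene's
    segment mean is the plain mean of its unmasked bin ratios.  Amplified
    iff segment mean >= ``threshold`` (inclusive).  Genes whose bins are all
    masked are reported uncallable, never negative.
    """
    cov = np.asarray(sample_coverage, dtype=float)
    if cov.shape != (len(baseline.bins),):
        raise ValueError(
            f"sample coverage grid mismatch ({cov.shape} vs {len(baseline.bins)} bins)"
        )
    norm = _normalize(cov)
    ratio = np.full(cov.shape, np.nan)
    m = baseline.mask
    ratio[m] = norm[m] / baseline.level[m]
    # Median-of-ratios recentring: total-count scaling is biased by the
    # amplified bins themselves, so anchor the diploid state at ratio 1 via
    # the (robust) median ratio across all usable bins.
    med = np.median(ratio[m])
    if med > 0:
        ratio[m] /= med
    genes = {}
    for i, b in enumerate(baseline.bins):
        if b.gene:
            genes.setdefault(b.gene, []).append(i)
    rows = []
    for gene in sorted(genes):
        idx = np.array(genes[gene])
        usable = idx[m[idx]]
        if usable.size == 0:
            rows.append(
                dict(gene=gene, n_bins=0, segment_mean=np.nan,
                     amplified=False, loss=False, callable=False)
            )
            continue
        seg = float(ratio[usable].mean())
        rows.append(
            dict(
                gene=gene,
                n_bins=int(usable.size),
                segment_mean=seg,
                amplified=bool(seg >= threshold),
                loss=bool(seg <= loss_threshold),
                callable=True,
            )
        )
    return CopyRatioTrack(baseline.bins, ratio, pd.DataFrame(rows))


def read_bin_coverage_tsv(path) -> tuple[list[GenomicInterval], np.ndarray]:
    """Read a binned coverage TSV (chrom, start, end, gene, depth)."""
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "gene", "depth"], comment="#")
    bins = [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end), str(r.gene))
        for r in df.itertuples()
    ]
    return bins, df["depth"].to_numpy(dtype=float)


def write_bin_coverage_tsv(path, bins: Sequence[GenomicInterval], coverage: np.ndarray) -> None:
    with open(path, "w") as fh:
        for b, c in zip(bins, coverage):
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.gene}\t{c:.6g}\n")
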