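"""Analytical-validation statistics: confusion counts against reference
truth sets, limit of detection, categorical concordance, and linear fits."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "LodEstimate",
    "LinearFit",
    "normalize_allele",
    "confusion",
    "estimate_lod",
    "concordance",
    "fit_linear",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None


@dataclass(frozen=True)
class LodEstimate:
    vaf_levels: tuple[float, ...]
    detection_fraction: dict
    lod: float | None  # None when no level qualifies


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float


def normalize_allele(key: tuple[str, int, str, str]) -> tuple[str, int, str, str]:
    """Parsimony-normalize a (chrom, pos, ref, alt) key: trim the shared
    allele suffix, then the shared prefix (keeping at least one base each),
    advancing pos over trimmed prefix bases.  Makes differently written but
    identical indels comparable without a reference genome."""
    chrom, pos, ref, alt = key
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)


def confusion(
    truth_positives: Iterable[tuple],
    truth_negatives: Iterable[tuple],
    called: Iterable[tuple],
) -> ConfusionCounts:
    """Exact-allele confusion counts over a declared truth universe.

    Keys are (chrom, pos, ref, alt) tuples, parsimony-normalized before
    matching.  ``truth_negatives`` are the reference material's verified
    wild-type positions; calls outside the declared universe are ignored.
    Counts always partition the universe: tp+fn = |positives| and
    tn+fp = |negatives|.  Duplicate truth entries raise ``ValueError``.
    """
    pos_list = [normalize_allele(k) for k in truth_positives]
    neg_list = [normalize_allele(k) for k in truth_negatives]
    pos, neg = set(pos_list), set(neg_list)
    if len(pos) != len(pos_list) or len(neg) != len(neg_list):
        raise ValueError("duplicate truth entries")
    if pos & neg:
        raise ValueError("truth positives and negatives overlap")
    calls = {normalize_allele(k) for k in called}
    tp = len(pos & calls)
    fn = len(pos - calls)
    fp = len(neg & calls)
    tn = len(neg - calls)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def estimate_lod(
    replicate_detections: Mapping[float, Sequence[bool]],
    min_fraction: float = 0.95,
) -> LodEstimate:
    """Limit of detection from per-level replicate detections.

    The LOD is the minimum VAF level whose replicate detection fraction is
    at least ``min_fraction`` (inclusive).  Each level needs >= 3
    replicates.  When no level qualifies the LOD is None.
    """
    levels = tuple(sorted(replicate_detections))
    fractions = {}
    for lv in levels:
        det = list(replicate_detections[lv])
        if len(det) < 3:
            raise ValueError(f"level {lv}: need >= 3 replicates, got {len(det)}")
        fractions[lv] = sum(bool(d) for d in det) / len(det)
    qualifying = [lv for lv in levels if fractions[lv] >= min_fraction]
    return LodEstimate(
        vaf_levels=levels,
        detection_fraction=fractions,
        lod=min(qualifying) if qualifying else None,
    )


def concordance(calls_a: Mapping, calls_b: Mapping) -> float:
    """Fraction of paired samples with identical categorical calls.

    Raises ``ValueError`` when the two call sets cover different samples.
    """
    if set(calls_a) != set(calls_b):
        raise ValueError("unpaired samples between the two call sets")
    if not calls_a:
        raise ValueError("no paired samples")
    agree = sum(1 for k in calls_a if calls_a[k] == calls_b[k])
    return agree / len(calls_a)


def fit_linear(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least squares line fit with R^2 = 1 - SSres/SStot.

    Raises ``ValueError`` for zero variance in x or fewer than 2 points.
    A constant y gives R^2 = 0 by convention (SStot = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    pred = res.intercept + res.slope * x
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept), r_squared=r2)
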