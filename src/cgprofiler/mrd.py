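"""Personalized ctDNA / minimal-residual-disease tracking.

Tumor variants are ranked by a composite score combining tissue VAF,
predicted pathogenicity, mutation type, recurrence in large cancer
databases and internal whitelist membership; the top two to five per
patient seed a bespoke amplicon panel.  Plasma amplicons sequenced to
~100,000X are evaluable at >= 10,000X coverage, and a timepoint is ctDNA
positive when any evaluable amplicon shows VAF strictly above 0.05%.
Longitudinal positivity yields clearance and molecular-relapse events.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import VariantRecord

__all__ = [
    "ScoreWeights",
    "RankedVariant",
    "TrackingSet",
    "AmpliconMeasurement",
    "PlasmaTimepoint",
    "TrajectoryEvent",
    "TrajectoryReport",
    "score_variant",
    "rank_variants",
    "select_tracking_variants",
    "call_plasma",
    "track_longitudinal",
]

MIN_AMPLICON_COVERAGE = 10_000
POSITIVITY_VAF_PCT = 0.05  # strict: positive when VAF is ABOVE this percent

TRUNCATING = {"nonsense", "frameshift"}


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the composite ranking score (must sum to 1)."""

    vaf: float = 0.30
    pathogenicity: float = 0.25
    mutation_type: float = 0.15
    db_frequency: float = 0.20
    whitelist: float = 0.10

    def __post_init__(self) -> None:
        total = self.vaf + self.pathogenicity + self.mutation_type + self.db_frequency + self.whitelist
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"score weights must sum to 1, got {total}")


@dataclass(frozen=True)
class RankedVariant:
    variant: VariantRecord
    components: dict
    score: float
    rank: int = 0


@dataclass(frozen=True)
class TrackingSet:
    variants: tuple[RankedVariant, ...]
    insufficient: bool  # fewer candidates than the minimum tracking-set size


@dataclass(frozen=True)
class AmpliconMeasurement:
    """One plasma amplicon: deep-sequenced coverage and alt reads at a
    tracked mutation site.  ``vaf`` is in percent."""

    variant_id: str
    coverage: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.coverage < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_reads > self.coverage:
            raise ValueError("alt_reads cannot exceed coverage")

    @property
    def vaf(self) -> float:
        return 100.0 * self.alt_reads / self.coverage if self.coverage else 0.0

    @property
    def evaluable(self) -> bool:
        return self.coverage >= MIN_AMPLICON_COVERAGE


@dataclass
class PlasmaTimepoint:
    sample_id: str
    collection_label: str
    measurements: list[AmpliconMeasurement]
    ctdna_positive: bool | None = None  # None when uncallable
    status: str = "uncalled"  # positive | negative | uncallable
    input_ok: bool = True  # cfDNA >= 0.15 ng/uL or >= 3 ng total (pre-analytic flag)
    date: object = None

    @property
    def max_vaf(self) -> float:
        vals = [m.vaf for m in self.measurements if m.evaluable]
        return max(vals) if vals else float("nan")


@dataclass(frozen=True)
class TrajectoryEvent:
    kind: str  # "clearance" | "molecular_relapse"
    index: int  # timepoint index at which the new state is observed


@dataclass(frozen=True)
class TrajectoryReport:
    labels: tuple[str, ...]
    statuses: tuple[str, ...]
    max_vafs: tuple[float, ...]
    events: tuple[TrajectoryEvent, ...]
    persistent_mrd: bool  # positive at every callable timepoint


def _type_term(v: VariantRecord, recurrence: int | None, hotspot_min_recurrence: int) -> float:
    if v.consequence in TRUNCATING:
        return 1.0
    if v.consequence == "missense":
        if recurrence is not None and recurrence >= hotspot_min_recurrence:
            return 0.8
        return 0.6
    return 0.3


def score_variant(
    v: VariantRecord,
    annotations: Mapping[str, object] | None,
    weights: ScoreWeights = ScoreWeights(),
    hotspot_min_recurrence: int = 20,
    db_recurrence_cap: int = 1000,
) -> RankedVariant:
    """Composite MRD-tracking score for one tumor variant.

    Components, each in [0, 1]:
      vaf_term            min(tissue VAF / 0.5, 1)
      pathogenicity_term  annotation-provided score in [0, 1]
      type_term           1.0 truncating/frameshift, 0.8 missense hotspot,
                          0.6 other missense, 0.3 other
      dbfreq_term         log-scaled database recurrence, capped at 1
      whitelist_term      1 for internally validated tumor-derived mutations

    A missing annotation zeroes its term with a warning; scoring never fails.
    """
    ann = annotations or {}
    patho = ann.get("pathogenicity")
    recurrence = ann.get("recurrence")
    whitelist = ann.get("whitelist")
    for name, val in (("pathogenicity", patho), ("recurrence", recurrence), ("whitelist", whitelist)):
        if val is None:
            warnings.warn(
                f"variant {v.chrom}:{v.pos} missing {name} annotation; term set to 0",
                stacklevel=2,
            )
    vaf_term = min(v.vaf / 0.5, 1.0)
    patho_term = float(patho) if patho is not None else 0.0
    if not 0.0 <= patho_term <= 1.0:
        raise ValueError("pathogenicity score must lie in [0, 1]")
    type_term = _type_term(v, recurrence if recurrence is not None else None, hotspot_min_recurrence)
    if recurrence is not None and recurrence > 0:
        dbfreq_term = min(math.log10(1 + recurrence) / math.log10(1 + db_recurrence_cap), 1.0)
    else:
        dbfreq_term = 0.0
    wl_term = 1.0 if whitelist else 0.0
    components = {
        "vaf_term": vaf_term,
        "pathogenicity_term": patho_term,
        "type_term": type_term,
        "dbfreq_term": dbfreq_term,
        "whitelist_term": wl_term,
    }
    score = (
        weights.vaf * vaf_term
        + weights.pathogenicity * patho_term
        + weights.mutation_type * type_term
        + weights.db_frequency * dbfreq_term
        + weights.whitelist * wl_term
    )
    return RankedVariant(variant=v, components=components, score=score)


def rank_variants(
    variants: Sequence[VariantRecord],
    annotations: Mapping[tuple, Mapping] | None = None,
    weights: ScoreWeights = ScoreWeights(),
    **score_kwargs,
) -> list[RankedVariant]:
    """Score and rank candidate tracking variants.

    Sorted by score descending; ties broken by tissue VAF descending, then
    (chrom, pos) ascending.  Ranks are 1-based.
    """
    annotations = annotations or {}
    scored = [score_variant(v, annotations.get(v.key), weights, **score_kwargs) for v in variants]
    scored.sort(key=lambda r: (-r.score, -r.variant.vaf, r.variant.chrom, r.variant.pos))
    return [
        RankedVariant(r.variant, r.components, r.score, rank=i + 1)
        for i, r in enumerate(scored)
    ]


def select_tracking_variants(
    ranked: Sequence[RankedVariant],
    k_min: int = 2,
    k_max: int = 5,
) -> TrackingSet:
    """Select the top-ranked variants (at most ``k_max``) for plasma tracking.

    When fewer than ``k_min`` candidates exist, all are returned with the
    ``insufficient`` flag set.  An empty candidate list is an error.
    """
    if not ranked:
        raise ValueError("no candidate variants to select from")
    chosen = tuple(ranked[: min(k_max, len(ranked))])
    return TrackingSet(variants=chosen, insufficient=len(ranked) < k_min)


def call_plasma(
    measurements: Sequence[AmpliconMeasurement],
    vaf_threshold_pct: float = POSITIVITY_VAF_PCT,
    min_coverage: int = MIN_AMPLICON_COVERAGE,
    sample_id: str = "",
    collection_label: str = "",
    input_ok: bool = True,
    date=None,
) -> PlasmaTimepoint:
    """ctDNA positivity call for one plasma sample.

    Amplicons below ``min_coverage`` are unsuccessful and excluded; the
    sample is positive iff any remaining amplicon's VAF (percent) is
    strictly above ``vaf_threshold_pct``.  With no evaluable amplicon the
    status is ``uncallable`` — never negative.
    """
    if not measurements:
        raise ValueError("at least one amplicon measurement required")
    evaluable = [m for m in measurements if m.coverage >= min_coverage]
    tp = PlasmaTimepoint(
        sample_id=sample_id,
        collection_label=collection_label,
        measurements=list(measurements),
        input_ok=input_ok,
        date=date,
    )
    if not evaluable:
        tp.ctdna_positive = None
        tp.status = "uncallable"
        return tp
    positive = any(m.vaf > vaf_threshold_pct for m in evaluable)
    tp.ctdna_positive = positive
    tp.status = "positive" if positive else "negative"
    return tp


def track_longitudinal(timepoints: Sequence[PlasmaTimepoint]) -> TrajectoryReport:
    """Derive MRD events from an ordered series of called timepoints.

    A positive -> negative transition is a clearance; negative -> positive
    is a molecular relapse.  Uncallable timepoints carry no state change.
    ``persistent_mrd`` is set when every callable timepoint is positive
    (and at least two are).  Raises ``ValueError`` for unordered dates.
    """
    if not timepoints:
        raise ValueError("no timepoints provided")
    dates = [tp.date for tp in timepoints if tp.date is not None]
    if len(dates) > 1 and any(b < a for a, b in zip(dates, dates[1:])):
        raise ValueError("timepoints must be ordered by collection date")
    events: list[TrajectoryEvent] = []
    prev: bool | None = None
    n_callable = 0
    n_positive = 0
    for i, tp in enumerate(timepoints):
        if tp.ctdna_positive is None:
            continue
        n_callable += 1
        n_positive += int(tp.ctdna_positive)
        if prev is not None:
            if prev and not tp.ctdna_positive:
                events.append(TrajectoryEvent("clearance", i))
            elif not prev and tp.ctdna_positive:
                events.append(TrajectoryEvent("molecular_relapse", i))
        prev = tp.ctdna_positive
    return TrajectoryReport(
        labels=tuple(tp.collection_label for tp in timepoints),
        statuses=tuple(tp.status for tp in timepoints),
        max_vafs=tuple(tp.max_vaf for tp in timepoints),
        events=tuple(events),
        persistent_mrd=(n_callable >= 2 and n_positive == n_callable),
    )
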