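"""Tumor mutational burden: eligibility filtering, scoring, classification,
and the in-silico tumor-fraction dilution experiment.

TMB is the count of eligible somatic variants divided by the effective
panel size in megabases.  A variant is eligible when it passed caller
filters, is not a likely-germline dbSNP site, lies in a coding region, is
non-synonymous, and meets VAF >= 5%, alt depth >= 5 and total depth >= 15
(all inclusive).  Samples at or above 10 mutations/Mb are TMB-High.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import DepthProfile, GenomicInterval, VariantRecord, effective_panel_size

__all__ = [
    "TmbResult",
    "MixSpec",
    "is_tmb_eligible",
    "compute_tmb",
    "mix_and_subsample",
    "mix_site_counts",
    "tmb_stability_experiment",
]

TMB_HIGH_THRESHOLD = 10.0


@dataclass(frozen=True)
class TmbResult:
    eligible_count: int
    panel_mb: float
    score: float
    status: str  # "TMB-H" | "TMB-L"


@dataclass(frozen=True)
class MixSpec:
    """A tumor:normal in-silico mixing recipe.

    ``tumor_parts``:``normal_parts`` is the volumetric mixing ratio; the
    expected tumor fraction of the mixture is
    tumor_parts / (tumor_parts + normal_parts).
    """

    tumor_parts: int
    normal_parts: int
    target_mean_depth: float
    seed: int

    def __post_init__(self) -> None:
        if self.tumor_parts <= 0 or self.normal_parts < 0:
            raise ValueError("tumor_parts must be positive, normal_parts non-negative")
        if self.tumor_parts + self.normal_parts <= 0:
            raise ValueError("total parts must be positive")

    @property
    def tumor_fraction(self) -> float:
        return self.tumor_parts / (self.tumor_parts + self.normal_parts)


def is_tmb_eligible(
    v: VariantRecord,
    min_vaf: float = 0.05,
    min_alt: int = 5,
    min_depth: int = 15,
) -> bool:
    """Somatic-variant TMB eligibility predicate (all comparisons inclusive)."""
    return (
        v.filter_pass
        and not v.in_dbsnp
        and v.is_coding
        and v.consequence != "synonymous"
        and v.vaf >= min_vaf
        and v.alt_depth >= min_alt
        and v.total_depth >= min_depth
    )


def compute_tmb(
    variants: Iterable[VariantRecord],
    depth_profile: DepthProfile,
    panel: Sequence[GenomicInterval],
    threshold: float = TMB_HIGH_THRESHOLD,
    min_vaf: float = 0.05,
    min_alt: int = 5,
    min_depth: int = 15,
) -> TmbResult:
    """Compute the TMB score and TMB-H/TMB-L status.

    The denominator is the effective panel size: coding panel bases with
    total depth >= ``min_depth``.  Raises ``ValueError`` when that size is
    zero — TMB is then uncomputable, not zero.
    """
    size = effective_panel_size(depth_profile, panel, min_depth=min_depth)
    if size == 0:
        raise ValueError("effective panel size is 0: TMB is uncomputable")
    eligible = sum(
        1 for v in variants if is_tmb_eligible(v, min_vaf=min_vaf, min_alt=min_alt, min_depth=min_depth)
    )
    panel_mb = size / 1e6
    score = eligible / panel_mb
    status = "TMB-H" if score >= threshold else "TMB-L"
    return TmbResult(eligible_count=eligible, panel_mb=panel_mb, score=score, status=status)


def mix_and_subsample(tumor_reads: Sequence, normal_reads: Sequence, spec: MixSpec) -> list:
    """Mix two read collections at the spec's ratio and downsample.

    The number of sampled reads equals ``round(spec.target_mean_depth)``
    (reads stand in for depth units at a locus).  Tumor-origin membership is
    binomial with p = tumor fraction; reads are then drawn without
    replacement from each pool.  Reproducible under the spec seed.

    Raises ``ValueError`` when the requested depth exceeds available
    material in either pool.
    """
    if len(tumor_reads) == 0 or len(normal_reads) == 0:
        raise ValueError("both read collections must be non-empty")
    rng = np.random.default_rng(spec.seed)
    n_total = int(round(spec.target_mean_depth))
    n_tumor = int(rng.binomial(n_total, spec.tumor_fraction))
    n_normal = n_total - n_tumor
    if n_tumor > len(tumor_reads) or n_normal > len(normal_reads):
        raise ValueError(
            f"target depth {n_total} exceeds available material "
            f"(need {n_tumor} tumor / {n_normal} normal, "
            f"have {len(tumor_reads)} / {len(normal_reads)})"
        )
    idx_t = rng.choice(len(tumor_reads), size=n_tumor, replace=False)
    idx_n = rng.choice(len(normal_reads), size=n_normal, replace=False)
    mixed = [tumor_reads[i] for i in idx_t] + [normal_reads[i] for i in idx_n]
    rng.shuffle(mixed)
    return mixed


def mix_site_counts(
    tumor_alt: int,
    tumor_depth: int,
    normal_alt: int,
    normal_depth: int,
    spec: MixSpec,
    rng: np.random.Generator | None = None,
) -> tuple[int, int]:
    """Per-site allele-count form of in-silico mixing.

    Returns (alt, depth) at the mixed, downsampled site: tumor-origin read
    count is binomial(depth, fraction); alt reads are drawn without
    replacement (hypergeometric) from each pool's alt/ref composition.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    depth = int(round(spec.target_mean_depth))
    n_tumor = int(rng.binomial(depth, spec.tumor_fraction))
    n_normal = depth - n_tumor
    if n_tumor > tumor_depth or n_normal > normal_depth:
        raise ValueError("target depth exceeds available material at site")
    alt = int(rng.hypergeometric(tumor_alt, tumor_depth - tumor_alt, n_tumor)) if n_tumor else 0
    if n_normal and normal_alt:
        alt += int(rng.hypergeometric(normal_alt, normal_depth - normal_alt, n_normal))
    return alt, depth


def tmb_stability_experiment(
    tumor_fixture,
    normal_fixture,
    fractions: Sequence[float],
    depths: Sequence[float],
    reps: int = 20,
    seed: int = 0,
    threshold: float = TMB_HIGH_THRESHOLD,
) -> pd.DataFrame:
    """Recompute TMB over a grid of simulated tumor fractions and depths.

    ``tumor_fixture`` is a :class:`cgprofiler.synth.SomaticFixture` whose
    truth manifest records the planted TMB; ``normal_fixture`` contributes
    only alt-free background (its depth profile is unused beyond depth
    bookkeeping, since the matched normal carries no somatic alt reads).

    For each (fraction, depth, rep): the tumor depth profile is binomially
    thinned to the target mean depth, each planted variant's observed VAF is
    diluted to ``fraction * true VAF`` via a binomial alt-read draw at its
    local depth, and TMB is recomputed with the standard eligibility filter
    applied to the observed values.  Rows failing the sample QC gate are
    flagged ``qc_pass = False``.
    """
    rng = np.random.default_rng(seed)
    variants = tumor_fixture.variants
    rows = []
    for fraction in fractions:
        for depth in depths:
            for rep in range(reps):
                profile = tumor_fixture.depth_profile.thinned(depth, rng)
                observed = []
                for v in variants:
                    d = profile.depth_at(v.chrom, v.pos - 1)
                    if d == 0:
                        continue
                    alt = int(rng.binomial(d, min(1.0, v.vaf * fraction)))
                    if alt == 0:
                        continue
                    observed.append(
                        VariantRecord(
                            chrom=v.chrom,
                            pos=v.pos,
                            ref=v.ref,
                            alt=v.alt,
                            vaf=round(alt / d, 6),
                            alt_depth=alt,
                            total_depth=d,
                            filter_pass=v.filter_pass,
                            in_dbsnp=v.in_dbsnp,
                            consequence=v.consequence,
                            is_coding=v.is_coding,
                        )
                    )
                qc = profile.qc()
                result = compute_tmb(observed, profile, tumor_fixture.panel, threshold=threshold)
                rows.append(
                    {
                        "fraction": fraction,
                        "target_depth": depth,
                        "rep": rep,
                        "mean_depth": qc.mean_depth,
                        "pct_cov_100x": qc.pct_cov_100x,
                        "qc_pass": qc.passed,
                        "tmb": result.score,
                        "status": result.status,
                    }
                )
    return pd.DataFrame(rows)
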