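"""Microsatellite instability calling.

NGS mode compares tumor vs matched-normal repeat-length distributions per
microsatellite locus; a sample is MSI-High when at least 20% of the
detected (adequately covered) loci are unstable.  The PCR mode classifies
from the five NCI mononucleotide markers: at least 2 altered markers
implies MSI-High.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MsiLocusProfile",
    "MsiResult",
    "PcrMsiResult",
    "PCR_MARKERS",
    "call_locus_instability",
    "classify_msi",
    "classify_msi_pcr",
    "read_locus_tsv",
    "write_locus_tsv",
]

PCR_MARKERS = ("BAT-25", "BAT-26", "MONO-27", "NR-21", "NR-24")


@dataclass
class MsiLocusProfile:
    """Repeat-length read-count distributions for one microsatellite locus
    in the tumor and its matched normal."""

    locus_id: str
    chrom: str
    pos: int
    repeat_unit: str
    normal_counts: dict[int, int]
    tumor_counts: dict[int, int]
    unstable: bool | None = field(default=None)

    def __post_init__(self) -> None:
        for counts in (self.normal_counts, self.tumor_counts):
            if any(c < 0 for c in counts.values()):
                raise ValueError(f"negative read count at locus {self.locus_id}")

    def evaluable(self, min_reads: int = 20) -> bool:
        return (
            sum(self.normal_counts.values()) >= min_reads
            and sum(self.tumor_counts.values()) >= min_reads
        )


@dataclass(frozen=True)
class MsiResult:
    n_loci_detected: int
    n_unstable: int
    proportion: float  # percent
    status: str  # "MSI-H" | "MSS" | "UNCALLABLE"


@dataclass(frozen=True)
class PcrMsiResult:
    markers: tuple[str, ...]
    altered: tuple[bool, ...]
    status: str  # "MSI-H" | "MSS"


def _modal_length(counts: Mapping[int, int]) -> int:
    # smallest length wins ties, for determinism
    return min((length for length, c in counts.items() if c == max(counts.values())))


def _merged_table(normal: Mapping[int, int], tumor: Mapping[int, int]) -> np.ndarray:
    """2 x L contingency table over the union of repeat lengths, with
    adjacent length bins greedily merged until every expected count is >= 5
    (or a single bin remains)."""
    lengths = sorted(set(normal) | set(tumor))
    table = np.array(
        [[normal.get(l, 0) for l in lengths], [tumor.get(l, 0) for l in lengths]],
        dtype=float,
    )
    table = table[:, table.sum(axis=0) > 0]
    while table.shape[1] > 1:
        col_tot = table.sum(axis=0)
        row_tot = table.sum(axis=1)
        expected = np.outer(row_tot, col_tot) / table.sum()
        if (expected >= 5).all():
            break
        j = int(expected.min(axis=0).argmin())
        k = j + 1 if j + 1 < table.shape[1] else j - 1
        table[:, k] += table[:, j]
        table = np.delete(table, j, axis=1)
    return table


def call_locus_instability(
    profile: MsiLocusProfile,
    alpha: float = 0.05,
    min_reads: int = 20,
) -> bool:
    """Per-locus instability call: a chi-squared test on the pooled
    repeat-length histograms (bins with expected count < 5 merged) must
    reject at ``alpha`` AND the tumor modal repeat length must differ from
    the normal one.

    Raises ``ValueError`` for an under-covered (non-evaluable) locus; such
    loci are excluded from the detected-locus denominator by the caller.
    """
    if not profile.evaluable(min_reads):
        raise ValueError(f"locus {profile.locus_id} under-covered (<{min_reads} reads)")
    if _modal_length(profile.tumor_counts) == _modal_length(profile.normal_counts):
        return False
    table = _merged_table(profile.normal_counts, profile.tumor_counts)
    if table.shape[1] < 2:
        return False
    _, p, _, _ = stats.chi2_contingency(table)
    return bool(p < alpha)


def classify_msi(
    profiles: Iterable[MsiLocusProfile],
    threshold_pct: float = 20.0,
    alpha: float = 0.05,
    min_reads: int = 20,
) -> MsiResult:
    """Sample-level MSI status from per-locus profiles.

    The denominator counts detected loci only — those with at least
    ``min_reads`` reads in both tumor and normal.  MSI-H when the unstable
    proportion is at least ``threshold_pct`` percent (inclusive).  With zero
    evaluable loci the status is UNCALLABLE, never MSS.
    """
    detected = 0
    unstable = 0
    for p in profiles:
        if not p.evaluable(min_reads):
            p.unstable = None
            continue
        detected += 1
        p.unstable = call_locus_instability(p, alpha=alpha, min_reads=min_reads)
        unstable += int(p.unstable)
    if detected == 0:
        return MsiResult(0, 0, float("nan"), "UNCALLABLE")
    proportion = 100.0 * unstable / detected
    status = "MSI-H" if proportion >= threshold_pct else "MSS"
    return MsiResult(detected, unstable, proportion, status)


def classify_msi_pcr(altered_flags: Mapping[str, bool] | Sequence[bool]) -> PcrMsiResult:
    """Classify MSI from the five PCR mononucleotide markers.

    MSI-H when at least 2 of the 5 markers are altered.  Accepts either a
    marker-name -> altered mapping (must cover exactly the five standard
    markers) or a sequence of five flags in standard marker order.
    """
    if isinstance(altered_flags, Mapping):
        if set(altered_flags) != set(PCR_MARKERS):
            raise ValueError(f"expected exactly the markers {PCR_MARKERS}")
        flags = tuple(bool(altered_flags[m]) for m in PCR_MARKERS)
    else:
        if len(altered_flags) != len(PCR_MARKERS):
            raise ValueError(f"expected {len(PCR_MARKERS)} marker flags")
        flags = tuple(bool(f) for f in altered_flags)
    status = "MSI-H" if sum(flags) >= 2 else "MSS"
    return PcrMsiResult(markers=PCR_MARKERS, altered=flags, status=status)


def read_locus_tsv(tumor_path, normal_path) -> list[MsiLocusProfile]:
    """Read tumor and normal locus tables
    (locus_id, chrom, pos, repeat_unit, sample, length, count) into profiles."""
    cols = ["locus_id", "chrom", "pos", "repeat_unit", "sample", "length", "count"]
    frames = [pd.read_csv(p, sep="\t", names=cols, comment="#") for p in (tumor_path, normal_path)]
    profiles: dict[str, MsiLocusProfile] = {}
    for which, df in zip(("tumor", "normal"), frames):
        for (locus_id, chrom, pos, unit), grp in df.groupby(
            ["locus_id", "chrom", "pos", "repeat_unit"], sort=True
        ):
            prof = profiles.setdefault(
                str(locus_id),
                MsiLocusProfile(str(locus_id), str(chrom), int(pos), str(unit), {}, {}),
            )
            counts = dict(zip(grp["length"].astype(int), grp["count"].astype(int)))
            if which == "tumor":
                prof.tumor_counts = counts
            else:
                prof.normal_counts = counts
    return [profiles[k] for k in sorted(profiles)]


def write_locus_tsv(path, profiles: Iterable[MsiLocusProfile], which: str) -> None:
    """Write one sample's (tumor or normal) locus count table."""
    with open(path, "w") as fh:
        for p in profiles:
            counts = p.tumor_counts if which == "tumor" else p.normal_counts
            for length in sorted(counts):
                fh.write(
                    f"{p.locus_id}\t{p.chrom}\t{p.pos}\t{p.repeat_unit}\t{which}\t"
                    f"{length}\t{counts[length]}\n"
                )
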