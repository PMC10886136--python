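"""Synthetic fixture generation with known truth for every pipeline stage.

The generators emulate the commercial reference standards used to validate
tumor-normal panel assays: a somatic truth set of 211 SNVs + 17 indels at
VAF >= 5% over a ~1.7 Mb coding panel sequenced to 500X, copy-number
standards carrying 3 additional copies (copy ratio 2.5) of six oncogenes,
a six-junction fusion standard, tumor/normal microsatellite length tables
over ~800 loci, and ultra-deep (~100,000X) plasma amplicon pileups.  Every
planted truth is recorded in a manifest emitted alongside the data, and a
fixed seed yields byte-identical outputs.

Depth is drawn negative-binomially around the target mean (mild
overdispersion emulating FFPE coverage variability) rather than Poisson.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .core import DepthProfile, GenomicInterval, VariantRecord, effective_panel_size
from .fusion import BreakpointEvidence, Locus
from .mrd import AmpliconMeasurement
from .msi import MsiLocusProfile

__all__ = [
    "SomaticSpec",
    "MsiSpec",
    "CnvSpec",
    "FusionSpec",
    "PlasmaSpec",
    "FixtureSpec",
    "SomaticFixture",
    "generate_somatic_fixture",
    "generate_msi_fixture",
    "generate_cnv_fixture",
    "generate_fusion_fixture",
    "generate_plasma_fixture",
    "generate_cnv_fusion_plasma_fixtures",
    "make_panel",
    "simulate_detection_replicate",
    "simulate_vaf_detection",
    "write_somatic_fixture",
]

AMPLIFIED_STANDARD_GENES = ("ERBB2", "FGFR3", "MYC", "EGFR", "MET", "MYCN")
FUSION_STANDARD_PAIRS = (
    ("TPM3", "NTRK1"),
    ("QKI", "NTRK2"),
    ("ETV6", "NTRK3"),
    ("EML4", "ALK"),
    ("CCDC6", "RET"),
    ("SLC34A2", "ROS1"),
)

_NONSYN = ("missense", "nonsense", "frameshift", "inframe_indel", "splice")
_BASES = "ACGT"


@dataclass(frozen=True)
class SomaticSpec:
    """Somatic truth-set recipe (defaults emulate a 228-variant standard)."""

    n_snv: int = 211
    n_indel: int = 17
    n_ineligible: int = 40
    vaf_min: float = 0.05
    vaf_max: float = 0.50
    mean_depth: float = 500.0
    nb_dispersion: float = 50.0  # negative-binomial size; larger = closer to Poisson
    n_genes: int = 20
    coding_bases: int = 200_000
    noncoding_bases_per_gene: int = 500


@dataclass(frozen=True)
class MsiSpec:
    n_loci: int = 800
    unstable_fraction: float = 0.0
    reads_per_locus: int = 100
    modal_shift: int = -3  # repeat units; magnitude >= 2 for unstable loci


@dataclass(frozen=True)
class CnvSpec:
    amplified_genes: tuple[str, ...] = AMPLIFIED_STANDARD_GENES
    extra_copies: int = 3  # ratio (2 + extra) / 2 = 2.5
    n_background_genes: int = 14
    bins_per_gene: int = 50
    bin_width: int = 100
    n_normals: int = 90
    mean_bin_depth: float = 150.0


@dataclass(frozen=True)
class FusionSpec:
    pairs: tuple[tuple[str, str], ...] = FUSION_STANDARD_PAIRS
    reads_per_junction: int = 5
    clip_length: int = 40
    position_jitter: int = 2


@dataclass(frozen=True)
class PlasmaSpec:
    n_amplicons: int = 5
    mean_coverage: float = 100_000.0
    ctdna_vaf_pct: float = 0.1  # planted ctDNA VAF per amplicon, percent
    error_rate: float = 1e-4  # per-read background error


@dataclass(frozen=True)
class FixtureSpec:
    """Full simulation recipe; the defaults are the assay's study conditions."""

    seed: int = 0
    somatic: SomaticSpec = field(default_factory=SomaticSpec)
    msi: MsiSpec = field(default_factory=MsiSpec)
    cnv: CnvSpec = field(default_factory=CnvSpec)
    fusion: FusionSpec = field(default_factory=FusionSpec)
    plasma: PlasmaSpec = field(default_factory=PlasmaSpec)


@dataclass
class SomaticFixture:
    variants: list[VariantRecord]
    depth_profile: DepthProfile
    panel: list[GenomicInterval]
    annotations: dict
    truth: dict


def make_panel(
    n_genes: int = 20,
    coding_bases: int = 200_000,
    noncoding_bases_per_gene: int = 500,
    chrom_prefix: str = "chr",
) -> list[GenomicInterval]:
    """A synthetic capture panel: ``n_genes`` genes spread over chromosomes,
    each with one coding exon block plus a small non-coding (intronic)
    block.  Total coding length is exactly ``coding_bases``."""
    per_gene = coding_bases // n_genes
    remainder = coding_bases - per_gene * n_genes
    panel: list[GenomicInterval] = []
    for g in range(n_genes):
        chrom = f"{chrom_prefix}{(g % 10) + 1}"
        start = 1_000_000 + (g // 10) * 5_000_000
        size = per_gene + (remainder if g == n_genes - 1 else 0)
        gene = f"GENE{g + 1:03d}"
        panel.append(GenomicInterval(chrom, start, start + size, gene, True))
        if noncoding_bases_per_gene > 0:
            panel.append(
                GenomicInterval(
                    chrom, start + size + 100, start + size + 100 + noncoding_bases_per_gene, gene, False
                )
            )
    return panel


def _nb_depth(rng: np.random.Generator, mean: float, size_param: float, n: int) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n).astype(np.int64)


def _draw_alt(rng: np.random.Generator, depth: int, vaf: float,
              min_vaf: float, min_alt: int) -> int:
    """Binomial alt-read draw conditioned on meeting the eligibility floor
    so that planted-eligible counts are exact by construction."""
    for _ in range(1000):
        alt = int(rng.binomial(depth, vaf))
        if alt >= min_alt and depth > 0 and alt / depth >= min_vaf:
            return alt
    raise ValueError(f"cannot plant eligible variant at vaf={vaf}, depth={depth}")


def generate_somatic_fixture(spec: SomaticSpec = SomaticSpec(), seed: int = 0) -> SomaticFixture:
    """Generate a tumor VCF-equivalent variant list, depth profile, panel
    and truth manifest.

    All ``n_snv + n_indel`` planted variants are TMB-eligible by
    construction (coding, non-synonymous, PASS, non-dbSNP, VAF/depths at or
    above the eligibility floor); ``n_ineligible`` decoys each violate
    exactly one criterion.  Depths are negative-binomial around
    ``mean_depth``.
    """
    rng = np.random.default_rng(seed)
    panel = make_panel(spec.n_genes, spec.coding_bases, spec.noncoding_bases_per_gene)
    depth = _nb_depth(rng, spec.mean_depth, spec.nb_dispersion,
                      sum(iv.length for iv in panel))
    profile = DepthProfile(panel, depth)

    coding = [iv for iv in panel if iv.is_coding]
    coding_len = sum(iv.length for iv in coding)
    n_total = spec.n_snv + spec.n_indel + spec.n_ineligible
    offsets = rng.choice(coding_len, size=n_total, replace=False)
    bounds = np.cumsum([iv.length for iv in coding])

    def locate(off: int) -> tuple[str, int]:
        i = int(np.searchsorted(bounds, off, side="right"))
        prev = 0 if i == 0 else int(bounds[i - 1])
        return coding[i].chrom, coding[i].start + (off - prev) + 1  # 1-based

    variants: list[VariantRecord] = []
    annotations: dict[tuple, dict] = {}
    eligible_keys: list[list] = []

    def alleles(is_indel: bool) -> tuple[str, str]:
        ref = _BASES[rng.integers(4)]
        if not is_indel:
            alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            return ref, alt
        ins = "".join(_BASES[rng.integers(4)] for _ in range(int(rng.integers(1, 4))))
        if rng.random() < 0.5:
            return ref, ref + ins  # insertion
        return ref + ins, ref  # deletion

    # planted-eligible variants
    for i in range(spec.n_snv + spec.n_indel):
        is_indel = i >= spec.n_snv
        chrom, pos = locate(int(offsets[i]))
        d = max(profile.depth_at(chrom, pos - 1), 15)
        vaf = float(rng.uniform(spec.vaf_min, spec.vaf_max))
        alt_reads = _draw_alt(rng, d, vaf, spec.vaf_min, 5)
        ref, alt = alleles(is_indel)
        cons = ("frameshift" if rng.random() < 0.6 else "inframe_indel") if is_indel else (
            str(rng.choice(["missense", "nonsense", "splice"], p=[0.7, 0.2, 0.1]))
        )
        v = VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            vaf=round(alt_reads / d, 6), alt_depth=alt_reads, total_depth=d,
            filter_pass=True, in_dbsnp=False, consequence=cons, is_coding=True,
        )
        variants.append(v)
        eligible_keys.append(list(v.key))
        annotations[v.key] = {
            "pathogenicity": round(float(rng.beta(5, 2)), 6),
            "recurrence": int(rng.geometric(0.02)) - 1,
            "whitelist": bool(rng.random() < 0.5),
        }

    # decoys, each failing exactly one eligibility criterion
    modes = ["synonymous", "dbsnp", "noncoding", "low_vaf", "filter_fail"]
    for j in range(spec.n_ineligible):
        chrom, pos = locate(int(offsets[spec.n_snv + spec.n_indel + j]))
        d = max(profile.depth_at(chrom, pos - 1), 15)
        mode = modes[j % len(modes)]
        vaf = 0.02 if mode == "low_vaf" else float(rng.uniform(spec.vaf_min, spec.vaf_max))
        if mode == "low_vaf":
            alt_reads = max(5, int(rng.binomial(d, vaf)))
            while alt_reads / d >= 0.05:
                alt_reads -= 1
        else:
            alt_reads = _draw_alt(rng, d, vaf, spec.vaf_min, 5)
        ref, alt = alleles(False)
        variants.append(
            VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                vaf=round(alt_reads / d, 6), alt_depth=alt_reads, total_depth=d,
                filter_pass=mode != "filter_fail",
                in_dbsnp=mode == "dbsnp",
                consequence="synonymous" if mode == "synonymous" else "missense",
                is_coding=mode != "noncoding",
            )
        )

    effective = effective_panel_size(profile, panel, min_depth=15)
    truth = {
        "n_snv": spec.n_snv,
        "n_indel": spec.n_indel,
        "n_ineligible": spec.n_ineligible,
        "n_eligible": spec.n_snv + spec.n_indel,
        "eligible_keys": eligible_keys,
        "effective_bases": effective,
        "truth_tmb": (spec.n_snv + spec.n_indel) / (effective / 1e6),
        "mean_depth": profile.mean_depth,
    }
    return SomaticFixture(variants, profile, panel, annotations, truth)


def generate_msi_fixture(spec: MsiSpec = MsiSpec(), seed: int = 0) -> tuple[list[MsiLocusProfile], dict]:
    """Tumor/normal microsatellite locus profiles with planted instability.

    Unstable loci have the tumor modal repeat length shifted by
    ``modal_shift`` (at least 2 units); stable loci re-draw reads from the
    normal's multinomial distribution.  Returns (profiles, truth manifest).
    """
    if abs(spec.modal_shift) < 2:
        raise ValueError("modal_shift magnitude must be >= 2 repeat units")
    rng = np.random.default_rng(seed)
    n_unstable = int(round(spec.n_loci * spec.unstable_fraction))
    unstable_idx = set(rng.choice(spec.n_loci, size=n_unstable, replace=False).tolist())
    profiles: list[MsiLocusProfile] = []
    probs = np.array([0.15, 0.70, 0.15])
    for i in range(spec.n_loci):
        modal = int(rng.integers(12, 30))
        normal = rng.multinomial(spec.reads_per_locus, probs)
        t_modal = modal + spec.modal_shift if i in unstable_idx else modal
        tumor = rng.multinomial(spec.reads_per_locus, probs)
        profiles.append(
            MsiLocusProfile(
                locus_id=f"MS{i + 1:04d}",
                chrom=f"chr{(i % 22) + 1}",
                pos=100_000 + i * 1_000,
                repeat_unit="A",
                normal_counts={modal + k - 1: int(c) for k, c in enumerate(normal) if c},
                tumor_counts={t_modal + k - 1: int(c) for k, c in enumerate(tumor) if c},
            )
        )
    truth = {
        "n_loci": spec.n_loci,
        "n_unstable": n_unstable,
        "unstable_loci": sorted(f"MS{i + 1:04d}" for i in unstable_idx),
        "unstable_fraction": spec.unstable_fraction,
    }
    return profiles, truth


def generate_cnv_fixture(
    spec: CnvSpec = CnvSpec(), seed: int = 0
) -> tuple[list[GenomicInterval], list[np.ndarray], np.ndarray, dict]:
    """CNV bins, a normal coverage cohort, and one tumor sample.

    Per-bin capture bias is shared across samples (lognormal); counts are
    Poisson around the biased mean.  Amplified genes are scaled by
    (2 + extra_copies) / 2.  Returns (bins, normal coverage list, tumor
    coverage, truth manifest).
    """
    rng = np.random.default_rng(seed)
    genes = list(spec.amplified_genes) + [
        f"BKG{i + 1:02d}" for i in range(spec.n_background_genes)
    ]
    bins: list[GenomicInterval] = []
    for g, gene in enumerate(genes):
        chrom = f"chr{(g % 22) + 1}"
        start = 10_000_000 + g * 1_000_000
        for b in range(spec.bins_per_gene):
            s = start + b * spec.bin_width
            bins.append(GenomicInterval(chrom, s, s + spec.bin_width, gene))
    n_bins = len(bins)
    bias = rng.lognormal(0.0, 0.15, size=n_bins)
    normals = []
    for _ in range(spec.n_normals):
        libsize = rng.uniform(0.7, 1.3)
        normals.append(rng.poisson(spec.mean_bin_depth * bias * libsize).astype(float))
    scale = np.ones(n_bins)
    ratio = (2 + spec.extra_copies) / 2
    for i, b in enumerate(bins):
        if b.gene in spec.amplified_genes:
            scale[i] = ratio
    tumor = rng.poisson(spec.mean_bin_depth * bias * scale).astype(float)
    truth = {
        "amplified_genes": list(spec.amplified_genes),
        "true_ratio": ratio,
        "background_genes": [g for g in genes if g not in spec.amplified_genes],
    }
    return bins, normals, tumor, truth


def generate_fusion_fixture(
    spec: FusionSpec = FusionSpec(), seed: int = 0
) -> tuple[list[BreakpointEvidence], list[GenomicInterval], dict]:
    """Breakpoint evidence for the planted fusion junctions plus the panel
    intervals covering the partner genes' targeted introns."""
    rng = np.random.default_rng(seed)
    panel: list[GenomicInterval] = []
    evidence: list[BreakpointEvidence] = []
    truth_pairs = []
    for k, (ga, gb) in enumerate(spec.pairs):
        chrom_a, chrom_b = f"chr{2 * k + 1}", f"chr{2 * k + 2}"
        bp_a, bp_b = 50_000_000 + k * 1_000, 80_000_000 + k * 1_000
        panel.append(GenomicInterval(chrom_a, bp_a - 5_000, bp_a + 5_000, ga))
        panel.append(GenomicInterval(chrom_b, bp_b - 5_000, bp_b + 5_000, gb))
        truth_pairs.append(tuple(sorted((ga, gb))))
        for r in range(spec.reads_per_junction):
            ja = int(rng.integers(-spec.position_jitter, spec.position_jitter + 1))
            jb = int(rng.integers(-spec.position_jitter, spec.position_jitter + 1))
            evidence.append(
                BreakpointEvidence(
                    read_id=f"{ga}_{gb}_r{r}",
                    locus_a=Locus(chrom_a, bp_a + ja, "+"),
                    locus_b=Locus(chrom_b, bp_b + jb, "+"),
                    clip_length=spec.clip_length,
                )
            )
    order = rng.permutation(len(evidence))
    evidence = [evidence[i] for i in order]
    truth = {"pairs": sorted(truth_pairs), "reads_per_junction": spec.reads_per_junction}
    return evidence, panel, truth


def generate_plasma_fixture(
    spec: PlasmaSpec = PlasmaSpec(), seed: int = 0
) -> tuple[list[AmpliconMeasurement], dict]:
    """Plasma amplicon pileups: coverage Poisson around the target ultra
    depth, alt reads binomial at planted ctDNA VAF plus background error."""
    rng = np.random.default_rng(seed)
    p_alt = spec.ctdna_vaf_pct / 100.0 + spec.error_rate
    measurements = []
    for i in range(spec.n_amplicons):
        cov = int(rng.poisson(spec.mean_coverage))
        alt = int(rng.binomial(cov, min(p_alt, 1.0)))
        measurements.append(AmpliconMeasurement(f"AMP{i + 1:02d}", cov, alt))
    truth = {
        "ctdna_vaf_pct": spec.ctdna_vaf_pct,
        "error_rate": spec.error_rate,
        "expected_alt_per_amplicon": spec.mean_coverage * p_alt,
    }
    return measurements, truth


def generate_cnv_fusion_plasma_fixtures(spec: FixtureSpec = FixtureSpec()):
    """Convenience wrapper generating the CNV, fusion and plasma fixtures
    from one composite spec with derived per-stage seeds."""
    cnv = generate_cnv_fixture(spec.cnv, seed=spec.seed + 1)
    fus = generate_fusion_fixture(spec.fusion, seed=spec.seed + 2)
    plasma = generate_plasma_fixture(spec.plasma, seed=spec.seed + 3)
    return cnv, fus, plasma


def simulate_detection_replicate(
    fixture: SomaticFixture,
    seed: int,
    min_alt: int = 8,
    error_rate: float = 1e-4,
    n_negative: int = 300,
) -> tuple[list[tuple], list[tuple], list[tuple]]:
    """Emulate one sequencing replicate of the fixture's truth set.

    Alt reads are redrawn binomially for every planted variant at its local
    depth and true VAF; a variant is called when at least ``min_alt`` alt
    reads appear.  ``n_negative`` verified wild-type coding positions are
    emulated with per-read background error ``error_rate`` and subjected to
    the same calling rule.

    Returns (called_keys, negative_keys, false_positive_keys).
    """
    rng = np.random.default_rng(seed)
    called = []
    for v in fixture.variants:
        d = fixture.depth_profile.depth_at(v.chrom, v.pos - 1)
        if rng.binomial(d, v.vaf) >= min_alt:
            called.append(v.key)
    occupied = {(v.chrom, v.pos) for v in fixture.variants}
    coding = [iv for iv in fixture.panel if iv.is_coding]
    bounds = np.cumsum([iv.length for iv in coding])
    negatives: list[tuple] = []
    false_pos: list[tuple] = []
    while len(negatives) < n_negative:
        off = int(rng.integers(bounds[-1]))
        i = int(np.searchsorted(bounds, off, side="right"))
        prev = 0 if i == 0 else int(bounds[i - 1])
        chrom, pos = coding[i].chrom, coding[i].start + (off - prev) + 1
        if (chrom, pos) in occupied:
            continue
        occupied.add((chrom, pos))
        key = (chrom, pos, "A", "G")
        negatives.append(key)
        d = fixture.depth_profile.depth_at(chrom, pos - 1)
        if rng.binomial(d, error_rate) >= min_alt:
            false_pos.append(key)
    return called, negatives, false_pos


def simulate_vaf_detection(
    levels: tuple[float, ...] = (0.01, 0.02, 0.05, 0.10),
    reps: int = 100,
    depth: int = 500,
    min_alt: int = 8,
    seed: int = 0,
) -> dict[float, list[bool]]:
    """Per-VAF-level technical-replicate detections for LOD estimation.

    Each replicate draws alt reads binomially at the given depth; detection
    requires at least ``min_alt`` alt reads.
    """
    rng = np.random.default_rng(seed)
    return {
        lv: [bool(rng.binomial(depth, lv) >= min_alt) for _ in range(reps)]
        for lv in levels
    }


def write_somatic_fixture(fixture: SomaticFixture, out_dir: str | os.PathLike) -> dict:
    """Write the somatic fixture (VCF, panel BED, depth TSV, truth JSON)."""
    from . import vcfio

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "tumor.vcf"),
        "panel": os.path.join(out_dir, "panel.bed"),
        "depth": os.path.join(out_dir, "depth.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    vcfio.write_variants(paths["vcf"], fixture.variants, annotations=fixture.annotations)
    vcfio.write_panel_bed(paths["panel"], fixture.panel)
    vcfio.write_depth_tsv(paths["depth"], fixture.depth_profile)
    with open(paths["truth"], "w") as fh:
        json.dump(fixture.truth, fh, indent=1, sort_keys=True)
    return paths
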