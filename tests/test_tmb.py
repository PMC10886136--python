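"""TMB eligibility, scoring, classification and in-silico mixing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgprofiler import synth
from cgprofiler.core import DepthProfile, GenomicInterval, VariantRecord
from cgprofiler.tmb import (
    MixSpec,
    compute_tmb,
    is_tmb_eligible,
    mix_and_subsample,
    mix_site_counts,
    tmb_stability_experiment,
)


def make_variant(**kw):
    base = dict(
        chrom="chr1", pos=100, ref="A", alt="T", vaf=0.10, alt_depth=10,
        total_depth=100, filter_pass=True, in_dbsnp=False,
        consequence="missense", is_coding=True,
    )
    base.update(kw)
    return VariantRecord(**base)


class TestEligibility:
    def test_boundary_values_are_inclusive(self):
        v = make_variant(vaf=0.05, alt_depth=5, total_depth=100)
        assert is_tmb_eligible(v)
        v15 = make_variant(vaf=5 / 15, alt_depth=5, total_depth=15)
        assert is_tmb_eligible(v15)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(consequence="synonymous"),
            dict(in_dbsnp=True),
            dict(is_coding=False),
            dict(filter_pass=False),
            dict(vaf=0.049, alt_depth=5, total_depth=102),
            dict(alt_depth=4, vaf=0.05, total_depth=80),
            dict(total_depth=14, alt_depth=5, vaf=5 / 14),
        ],
    )
    def test_each_criterion_excludes(self, kw):
        assert not is_tmb_eligible(make_variant(**kw))


class TestComputeTmb:
    def test_seventeen_per_1p7mb_sits_exactly_on_tmb_high_boundary(self):
        panel = [GenomicInterval("chr1", 0, 1_700_000, "G", True)]
        profile = DepthProfile(panel, np.full(1_700_000, 500))
        variants = [make_variant(pos=p) for p in range(1000, 1000 + 17 * 50, 50)]
        res = compute_tmb(variants, profile, panel)
        assert res.score == pytest.approx(10.0)
        assert res.status == "TMB-H"

    def test_no_eligible_variants_scores_zero_low(self, flat_profile):
        panel, profile = flat_profile
        res = compute_tmb([], profile, panel)
        assert res.score == 0.0 and res.status == "TMB-L"

    def test_zero_panel_is_uncomputable_not_zero(self):
        panel = [GenomicInterval("chr1", 0, 100, "G", True)]
        profile = DepthProfile(panel, np.zeros(100))
        with pytest.raises(ValueError, match="uncomputable"):
            compute_tmb([], profile, panel)

    def test_matches_independent_filter_recount_on_fixture(self, small_somatic_fixture):
        fx = small_somatic_fixture
        res = compute_tmb(fx.variants, fx.depth_profile, fx.panel)
        # independent oracle: re-apply the published criteria one by one
        oracle = sum(
            1
            for v in fx.variants
            if v.filter_pass
            and not v.in_dbsnp
            and v.is_coding
            and v.consequence != "synonymous"
            and v.vaf >= 0.05
            and v.alt_depth >= 5
            and v.total_depth >= 15
        )
        assert res.eligible_count == oracle == fx.truth["n_eligible"]
        assert res.score == pytest.approx(fx.truth["truth_tmb"])

    def test_invariant_under_permutation_and_ineligible_padding(self, small_somatic_fixture):
        fx = small_somatic_fixture
        base = compute_tmb(fx.variants, fx.depth_profile, fx.panel)
        shuffled = list(reversed(fx.variants))
        padding = [
            make_variant(chrom=fx.panel[0].chrom, pos=fx.panel[0].start + 1 + i,
                         consequence="synonymous")
            for i in range(5)
        ]
        again = compute_tmb(shuffled + padding, fx.depth_profile, fx.panel)
        assert (again.eligible_count, again.score) == (base.eligible_count, base.score)


class TestMixing:
    def test_ratio_arithmetic_exact(self):
        assert MixSpec(3, 1, 100, 0).tumor_fraction == 0.75
        assert MixSpec(1, 1, 100, 0).tumor_fraction == 0.5
        assert MixSpec(3, 7, 100, 0).tumor_fraction == pytest.approx(0.3)

    def test_rejects_invalid_parts(self):
        with pytest.raises(ValueError):
            MixSpec(0, 1, 100, 0)

    def test_read_mixing_reproducible_and_without_replacement(self):
        tumor = [f"t{i}" for i in range(500)]
        normal = [f"n{i}" for i in range(500)]
        spec = MixSpec(1, 1, 300, seed=5)
        a = mix_and_subsample(tumor, normal, spec)
        b = mix_and_subsample(tumor, normal, spec)
        assert a == b
        assert len(a) == 300 and len(set(a)) == 300

    def test_depth_exceeding_material_is_error(self):
        with pytest.raises(ValueError, match="material"):
            mix_and_subsample(["t"] * 5, ["n"] * 5, MixSpec(1, 1, 100, seed=0))

    def test_planted_vaf_scales_with_tumor_fraction(self):
        """Diluted VAF equals fraction x original VAF within 3 binomial SDs
        of the mean over >= 100 replicates (closed-form oracle)."""
        vaf0, depth, reps = 0.40, 1000, 200
        rng = np.random.default_rng(99)
        for parts, frac in [((3, 1), 0.75), ((1, 1), 0.5), ((3, 7), 0.3)]:
            spec = MixSpec(*parts, target_mean_depth=depth, seed=0)
            alts = [
                mix_site_counts(int(vaf0 * 5000), 5000, 0, 5000, spec, rng)[0]
                for _ in range(reps)
            ]
            p = frac * vaf0
            se3 = 3 * np.sqrt(p * (1 - p) / (depth * reps))
            assert np.mean(alts) / depth == pytest.approx(p, abs=se3)


class TestStabilityExperiment:
    def test_full_fraction_full_depth_recovers_truth(self):
        spec = synth.SomaticSpec(n_snv=30, n_indel=0, n_ineligible=0,
                                 vaf_min=0.25, vaf_max=0.45,
                                 n_genes=4, coding_bases=60_000)
        fx = synth.generate_somatic_fixture(spec, seed=3)
        table = tmb_stability_experiment(fx, None, fractions=[1.0],
                                         depths=[500], reps=3, seed=1)
        assert table["tmb"].mean() == pytest.approx(fx.truth["truth_tmb"], rel=0.10)

    def test_low_fraction_low_vaf_collapses(self):
        """Variants at truth VAF 0.10 diluted to 10% tumor fraction fall
        below the 5% eligibility cutoff, collapsing TMB toward zero."""
        spec = synth.SomaticSpec(n_snv=30, n_indel=0, n_ineligible=0,
                                 vaf_min=0.10, vaf_max=0.10 + 1e-9,
                                 n_genes=4, coding_bases=60_000)
        fx = synth.generate_somatic_fixture(spec, seed=4)
        table = tmb_stability_experiment(fx, None, fractions=[0.10],
                                         depths=[150], reps=5, seed=2)
        assert table["tmb"].mean() < 0.2 * fx.truth["truth_tmb"]

    def test_qc_flag_tracks_depth(self):
        spec = synth.SomaticSpec(n_snv=5, n_indel=0, n_ineligible=0,
                                 n_genes=2, coding_bases=20_000)
        fx = synth.generate_somatic_fixture(spec, seed=5)
        table = tmb_stability_experiment(fx, None, fractions=[1.0],
                                         depths=[500, 100], reps=2, seed=3)
        assert table.loc[table.target_depth == 500, "qc_pass"].all()
        assert not table.loc[table.target_depth == 100, "qc_pass"].any()


@settings(max_examples=50, deadline=None)
@given(st.integers(1, 5), st.integers(0, 5))
def test_tumor_fraction_formula(tumor_parts, normal_parts):
    spec = MixSpec(tumor_parts, normal_parts, 100, 0)
    assert spec.tumor_fraction == tumor_parts / (tumor_parts + normal_parts)
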