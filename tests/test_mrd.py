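"""Variant ranking, tracking-set selection, plasma calling, trajectories."""

import numpy as np
import pytest
from scipy import stats

from cgprofiler import synth
from cgprofiler.core import VariantRecord
from cgprofiler.mrd import (
    AmpliconMeasurement,
    ScoreWeights,
    call_plasma,
    rank_variants,
    score_variant,
    select_tracking_variants,
    track_longitudinal,
)


def make_variant(vaf=0.10, consequence="missense", pos=100):
    depth = 1000
    return VariantRecord(
        "chr1", pos, "A", "T", vaf, int(round(vaf * depth)), depth,
        consequence=consequence,
    )


FULL_ANN = {"pathogenicity": 1.0, "recurrence": 10**6, "whitelist": True}
NULL_ANN = {"pathogenicity": 0.0, "recurrence": 0, "whitelist": False}


class TestScoreVariant:
    def test_upper_and_lower_bounds(self):
        top = score_variant(make_variant(vaf=0.5, consequence="frameshift"), FULL_ANN)
        assert top.score == pytest.approx(1.0)
        bottom = score_variant(make_variant(vaf=0.0, consequence="noncoding"), NULL_ANN)
        assert bottom.components["type_term"] == 0.3
        assert bottom.score == pytest.approx(0.15 * 0.3)

    def test_hand_computed_weighted_sum(self):
        """Components (1, 0.8, 0.6, 0.5, 1) with the default weights
        (0.30, 0.25, 0.15, 0.20, 0.10) give 0.30+0.20+0.09+0.10+0.10 = 0.79."""
        # vaf 0.5 -> term 1; patho 0.8; plain missense -> 0.6;
        # recurrence r with log10(1+r)/log10(1001) = 0.5 -> r = 1001**0.5 - 1
        r = int(round(1001 ** 0.5)) - 1
        v = make_variant(vaf=0.5, consequence="missense")
        ann = {"pathogenicity": 0.8, "recurrence": r, "whitelist": True}
        ranked = score_variant(v, ann, hotspot_min_recurrence=10**6)
        assert ranked.components["dbfreq_term"] == pytest.approx(0.5, abs=0.01)
        assert ranked.score == pytest.approx(0.79, abs=0.005)

    def test_missing_annotation_warns_and_zeroes_term(self):
        with pytest.warns(UserWarning, match="pathogenicity"):
            r = score_variant(make_variant(), {"recurrence": 0, "whitelist": False})
        assert r.components["pathogenicity_term"] == 0.0

    def test_truncating_and_hotspot_type_terms(self):
        assert score_variant(make_variant(consequence="nonsense"), FULL_ANN).components["type_term"] == 1.0
        hot = score_variant(make_variant(), {"pathogenicity": 0, "recurrence": 100, "whitelist": False})
        assert hot.components["type_term"] == 0.8
        cold = score_variant(make_variant(), {"pathogenicity": 0, "recurrence": 1, "whitelist": False})
        assert cold.components["type_term"] == 0.6

    def test_monotone_in_each_component(self):
        base = score_variant(make_variant(vaf=0.1), dict(NULL_ANN)).score
        assert score_variant(make_variant(vaf=0.2), dict(NULL_ANN)).score > base
        assert score_variant(make_variant(vaf=0.1), {**NULL_ANN, "pathogenicity": 0.5}).score > base
        assert score_variant(make_variant(vaf=0.1), {**NULL_ANN, "whitelist": True}).score > base

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ScoreWeights(vaf=0.5, pathogenicity=0.5, mutation_type=0.5,
                         db_frequency=0.0, whitelist=0.0)


class TestRankAndSelect:
    def _ranked(self, n):
        variants = [make_variant(vaf=0.05 + 0.005 * i, pos=100 + i) for i in range(n)]
        ann = {v.key: dict(NULL_ANN) for v in variants}
        return rank_variants(variants, ann)

    def test_ranks_are_a_permutation_sorted_by_score(self):
        ranked = self._ranked(10)
        assert [r.rank for r in ranked] == list(range(1, 11))
        scores = [r.score for r in ranked]
        assert scores == sorted(scores, reverse=True)

    @pytest.mark.parametrize("n,expected,insufficient", [(50, 5, False), (3, 3, False), (1, 1, True)])
    def test_top_two_to_five_selection(self, n, expected, insufficient):
        sel = select_tracking_variants(self._ranked(n))
        assert len(sel.variants) == expected
        assert sel.insufficient is insufficient

    def test_empty_candidate_list_is_error(self):
        with pytest.raises(ValueError):
            select_tracking_variants([])


class TestCallPlasma:
    def test_vaf_just_above_threshold_is_positive(self):
        tp = call_plasma([AmpliconMeasurement("v1", 100_000, 60)])
        assert tp.status == "positive"
        assert tp.max_vaf == pytest.approx(0.06)

    def test_exactly_at_threshold_is_negative(self):
        """The positivity rule is strictly 'above 0.05%'."""
        tp = call_plasma([AmpliconMeasurement("v1", 100_000, 50)])
        assert tp.status == "negative"

    def test_only_amplicon_below_coverage_floor_is_uncallable(self):
        tp = call_plasma([AmpliconMeasurement("v1", 9_999, 60)])
        assert tp.status == "uncallable" and tp.ctdna_positive is None

    def test_coverage_floor_is_inclusive(self):
        tp = call_plasma([AmpliconMeasurement("v1", 10_000, 6)])
        assert tp.status == "positive"  # 0.06% > 0.05%

    def test_positivity_monotone_in_alt_reads(self):
        statuses = [
            call_plasma([AmpliconMeasurement("v1", 100_000, alt)]).status
            for alt in (0, 25, 50, 51, 200)
        ]
        flips = [s == "positive" for s in statuses]
        assert flips == sorted(flips)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            AmpliconMeasurement("v1", 100_000, -1)

    def test_detection_probability_matches_binomial_oracle(self):
        """Planted ctDNA at VAF 0.1% across 5 amplicons at 100,000X is
        detected essentially always; with VAF 0 and per-read error 1e-4 the
        false-positive rate matches the binomial tail above 0.05%."""
        detected = 0
        reps = 200
        for rep in range(reps):
            ms, _ = synth.generate_plasma_fixture(
                synth.PlasmaSpec(ctdna_vaf_pct=0.1), seed=rep
            )
            detected += call_plasma(ms).status == "positive"
        assert detected / reps >= 0.99

        false_pos = 0
        for rep in range(reps):
            ms, _ = synth.generate_plasma_fixture(
                synth.PlasmaSpec(ctdna_vaf_pct=0.0, error_rate=1e-4), seed=10_000 + rep
            )
            false_pos += call_plasma(ms).status == "positive"
        # per-amplicon tail P(Bin(1e5, 1e-4) > 50) is ~0; 5 amplicons/sample
        per_amp = stats.binom.sf(50, 100_000, 1e-4)
        bound = 1 - (1 - per_amp) ** 5
        assert false_pos / reps <= bound + 3 * np.sqrt(bound * (1 - bound) / reps) + 0.01


class TestTrajectory:
    @staticmethod
    def _tp(vaf_pct, label, date):
        cov = 100_000
        alt = int(round(vaf_pct / 100 * cov))
        return call_plasma(
            [AmpliconMeasurement("v1", cov, alt)],
            collection_label=label, date=date,
        )

    def test_clearance_then_molecular_relapse(self):
        tps = [
            self._tp(0.5, "pre-op", 1),
            self._tp(0.0, "post-op", 2),
            self._tp(0.3, "post-CRT", 3),
        ]
        report = track_longitudinal(tps)
        assert [(e.kind, e.index) for e in report.events] == [
            ("clearance", 1),
            ("molecular_relapse", 2),
        ]
        assert not report.persistent_mrd

    def test_all_negative_has_no_events(self):
        report = track_longitudinal([self._tp(0.0, "a", 1), self._tp(0.0, "b", 2)])
        assert report.events == ()

    def test_declining_but_positive_is_persistent_mrd(self):
        tps = [self._tp(2.0, "pre-op", 1), self._tp(0.2, "post-op", 2), self._tp(0.08, "post-CRT", 3)]
        report = track_longitudinal(tps)
        assert report.persistent_mrd and report.events == ()
        assert list(report.max_vafs) == sorted(report.max_vafs, reverse=True)

    def test_unordered_dates_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            track_longitudinal([self._tp(0.1, "a", 5), self._tp(0.1, "b", 1)])
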