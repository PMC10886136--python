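"""Breakpoint clustering, the >=2 spanning-read rule and fusion detection."""

import numpy as np
import pytest

from cgprofiler import synth
from cgprofiler.fusion import (
    BreakpointEvidence,
    Locus,
    cluster_breakpoints,
    detect_fusions,
    read_evidence_tsv,
    write_evidence_tsv,
)


def ev(read_id, pos_a, pos_b, chrom_a="chr1", chrom_b="chr2", clip=30, ga="", gb=""):
    return BreakpointEvidence(
        read_id, Locus(chrom_a, pos_a, "+"), Locus(chrom_b, pos_b, "+"), clip, ga, gb
    )


def brute_force_clusters(evidence, tolerance=5):
    """Independent oracle: connected components of the pairwise
    both-loci-within-tolerance graph (BFS)."""
    n = len(evidence)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = evidence[i], evidence[j]
            if (
                a.locus_a.chrom == b.locus_a.chrom
                and a.locus_b.chrom == b.locus_b.chrom
                and abs(a.locus_a.pos - b.locus_a.pos) <= tolerance
                and abs(a.locus_b.pos - b.locus_b.pos) <= tolerance
            ):
                adj[i].append(j)
                adj[j].append(i)
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u])
        seen |= comp
        comps.append(frozenset(evidence[i].read_id for i in comp))
    return sorted(comps, key=sorted)


class TestClusterBreakpoints:
    def test_two_identical_reads_reported(self):
        calls = cluster_breakpoints([ev("r1", 100, 200), ev("r2", 100, 200)])
        (c,) = calls
        assert c.spanning_reads == 2 and c.reported

    def test_single_read_not_reported(self):
        (c,) = cluster_breakpoints([ev("r1", 100, 200)])
        assert c.spanning_reads == 1 and not c.reported

    def test_chain_within_tolerance_forms_one_cluster(self):
        calls = cluster_breakpoints(
            [ev("r1", 100, 200), ev("r2", 102, 200), ev("r3", 104, 200)], tolerance=5
        )
        assert len(calls) == 1 and calls[0].spanning_reads == 3

    def test_consensus_is_modal_position(self):
        calls = cluster_breakpoints(
            [ev("r1", 100, 200), ev("r2", 100, 200), ev("r3", 103, 201)]
        )
        assert calls[0].breakpoint_a.pos == 100
        assert calls[0].breakpoint_b.pos == 200

    def test_empty_input_gives_empty_list(self):
        assert cluster_breakpoints([]) == []

    def test_both_read_orientations_collapse(self):
        forward = ev("r1", 100, 200, ga="A", gb="B")
        backward = BreakpointEvidence(
            "r2", Locus("chr2", 200, "+"), Locus("chr1", 100, "+"), 30, "B", "A"
        )
        (c,) = cluster_breakpoints([forward, backward])
        assert c.spanning_reads == 2 and c.gene_pair == ("A", "B")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_component_oracle(self, seed):
        rng = np.random.default_rng(seed)
        evidence = [
            ev(
                f"r{i}",
                int(rng.integers(0, 60)),
                int(rng.integers(0, 60)),
                chrom_a=f"chr{rng.integers(1, 3)}",
                chrom_b="chr9",
            )
            for i in range(25)
        ]
        calls = cluster_breakpoints(evidence, tolerance=5)
        expected = brute_force_clusters(evidence, tolerance=5)
        assert sorted(len(c) for c in expected) == sorted(c.spanning_reads for c in calls)


class TestDetectFusions:
    def test_planted_junction_reported_with_gene_names(self):
        evidence, panel, truth = synth.generate_fusion_fixture(seed=3)
        calls = detect_fusions(evidence, panel)
        reported = sorted(c.gene_pair for c in calls if c.reported)
        assert reported == [tuple(p) for p in truth["pairs"]]

    def test_intra_gene_clips_excluded(self):
        _, panel, _ = synth.generate_fusion_fixture(seed=3)
        g = panel[0]
        same_gene = [
            ev("r1", g.start + 10, g.start + 400, chrom_a=g.chrom, chrom_b=g.chrom),
            ev("r2", g.start + 10, g.start + 400, chrom_a=g.chrom, chrom_b=g.chrom),
        ]
        assert detect_fusions(same_gene, panel) == []

    def test_short_clips_and_off_panel_loci_excluded(self):
        _, panel, _ = synth.generate_fusion_fixture(seed=3)
        a, b = panel[0], panel[1]
        short = ev("r1", a.start + 1, b.start + 1, chrom_a=a.chrom, chrom_b=b.chrom, clip=5)
        off_panel = ev("r2", a.start + 1, 1, chrom_a=a.chrom, chrom_b="chrZ")
        assert detect_fusions([short, off_panel], panel) == []

    def test_shuffled_evidence_order_gives_identical_calls(self):
        evidence, panel, _ = synth.generate_fusion_fixture(seed=4)
        rng = np.random.default_rng(0)
        shuffled = [evidence[i] for i in rng.permutation(len(evidence))]
        a = detect_fusions(evidence, panel)
        b = detect_fusions(shuffled, panel)
        assert sorted((c.gene_pair, c.spanning_reads) for c in a) == sorted(
            (c.gene_pair, c.spanning_reads) for c in b
        )

    def test_no_planted_junctions_yields_zero_calls(self):
        _, panel, _ = synth.generate_fusion_fixture(seed=5)
        assert detect_fusions([], panel) == []

    def test_reported_monotone_in_spanning_reads(self):
        for n in range(1, 6):
            evidence = [ev(f"r{i}", 100, 200, ga="A", gb="B") for i in range(n)]
            (c,) = cluster_breakpoints(evidence)
            assert c.reported == (n >= 2)


class TestEvidenceTsv:
    def test_round_trip(self, tmp_path):
        evidence, _, _ = synth.generate_fusion_fixture(seed=6)
        p = tmp_path / "evidence.tsv"
        write_evidence_tsv(p, evidence)
        back = read_evidence_tsv(p)
        strip = lambda e: (e.read_id, e.locus_a, e.locus_b, e.clip_length)
        assert [strip(e) for e in back] == [strip(e) for e in evidence]
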