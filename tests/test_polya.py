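"""Cleavage-site tallying, priming screen, and clustering."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from csikit.polya import (
    PolyAPeak,
    cluster_sites,
    extract_peak_window,
    filter_peaks,
    reverse_complement,
    score_internal_priming,
    tally_read_starts,
)


def make_read(chrom_len, start, length, reverse, name="r"):
    header = pysam.AlignmentHeader.from_dict(
        {"SQ": [{"SN": "chr1", "LN": chrom_len}]}
    )
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.reference_id = 0
    rec.reference_start = start
    rec.cigarstring = f"{length}M"
    rec.query_sequence = "A" * length
    rec.flag = 16 if reverse else 0
    rec.mapping_quality = 60
    return rec


class TestTally:
    def test_plus_strand_read_starts(self):
        reads = [make_read(1000, 100, 30, False) for _ in range(3)]
        reads.append(make_read(1000, 105, 30, False))
        tally = tally_read_starts(reads)
        assert tally[("chr1", "+")] == {100: 3, 105: 1}

    def test_minus_strand_keys_rightmost_base(self):
        reads = [make_read(1000, 90, 30, True)]  # aligned [90, 120)
        tally = tally_read_starts(reads)
        assert tally[("chr1", "-")] == {119: 1}

    def test_empty_input(self):
        assert tally_read_starts([]) == {}

    def test_unmapped_skipped(self):
        rec = make_read(1000, 0, 30, False)
        rec.flag |= 4
        assert tally_read_starts([rec]) == {}

    def test_opposite_mode_flips_strand_and_end(self):
        reads = [make_read(1000, 90, 30, False)]  # forward [90, 120)
        tally = tally_read_starts(reads, strand_mode="opposite")
        assert tally[("chr1", "-")] == {119: 1}


class TestWindows:
    def test_plus_window_coordinates(self, genome, sim_ref):
        peak = PolyAPeak("chrSim", 50, "+", 1)
        seq, idx = extract_peak_window(peak, genome)
        assert len(seq) == 71 and idx == 40
        assert seq == sim_ref.sequence[10:81].upper()

    def test_left_truncated_no_padding(self, genome):
        seq, idx = extract_peak_window(PolyAPeak("chrSim", 5, "+", 1), genome)
        assert len(seq) == 36 and idx == 5  # [0, 36): 5 upstream + site + 30

    def test_minus_window_is_reverse_complement(self, genome, sim_ref):
        seq, idx = extract_peak_window(PolyAPeak("chrSim", 500, "-", 1), genome)
        fwd = sim_ref.sequence[470:541].upper()
        assert seq == reverse_complement(fwd)
        assert seq[idx] == reverse_complement(sim_ref.sequence[500].upper())

    def test_unknown_contig_named_in_error(self, genome):
        with pytest.raises(KeyError, match="chrNope"):
            extract_peak_window(PolyAPeak("chrNope", 5, "+", 1), genome)


class TestPrimingScreen:
    def window(self, downstream, upstream="G" * 40, site="C"):
        return upstream + site + downstream, len(upstream)

    def test_pure_a_downstream_rejected(self):
        seq, idx = self.window("A" * 30)
        assert score_internal_priming(seq, idx) < 0

    def test_moderate_a_without_run_accepted(self):
        seq, idx = self.window("AAGCU" * 6)  # 40% A, max run 2
        assert score_internal_priming(seq, idx) > 0

    def test_fraction_exactly_at_threshold_rejected(self):
        # enumerate the boundary: 0.65 * 20 = 13 A in 20 nt, run-free
        down = "AAG" * 6 + "AC"
        assert down.count("A") / len(down) == 0.65
        seq, idx = self.window(down)
        assert not score_internal_priming(seq, idx) > 0
        # one A fewer: strictly below threshold, accepted
        seq2, idx2 = self.window("G" + down[1:])
        assert score_internal_priming(seq2, idx2) > 0

    def test_a_run_alone_rejects(self):
        # 6-run present but fraction low
        seq, idx = self.window("AAAAAA" + "GCGCUGCGUCGGCUACGCGUGCGC"[:24])
        assert score_internal_priming(seq, idx) < 0
        seq5, idx5 = self.window("AAAAA" + "GCGCUGCGUCGGCUACGCGUGCGCG"[:25])
        assert score_internal_priming(seq5, idx5) > 0  # run of 5 passes

    def test_short_downstream_rejected(self):
        seq = "G" * 40 + "C" + "GCGC"  # 4 nt downstream
        assert score_internal_priming(seq, 40) < 0


class TestFilterPeaks:
    @pytest.mark.parametrize(
        "count,score,min_reads,kept",
        [(1, 1.0, 2, False), (2, 1.0, 2, True), (5, -0.5, 1, False)],
    )
    def test_threshold_and_sign(self, count, score, min_reads, kept):
        peak = PolyAPeak("chr1", 10, "+", count, score)
        assert (peak in filter_peaks([peak], min_reads)) is kept


def brute_force_single_linkage(positions, gap):
    """Union-find over all pairs within the gap; independent oracle."""
    parent = {p: p for p in positions}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a in positions:
        for b in positions:
            if abs(a - b) <= gap:
                parent[find(a)] = find(b)
    groups = {}
    for p in positions:
        groups.setdefault(find(p), set()).add(p)
    return sorted(frozenset(g) for g in groups.values())


class TestClustering:
    def peaks(self, positions, counts=None):
        counts = counts or [1] * len(positions)
        return [
            PolyAPeak("chr1", p, "+", c, 1.0)
            for p, c in zip(positions, counts)
        ]

    def test_matches_brute_force_oracle(self):
        positions = [100, 120, 160]
        clusters = cluster_sites(self.peaks(positions), cluster_gap=30)
        got = sorted(
            (frozenset(p.position for p in c.member_peaks) for c in clusters),
            key=min,
        )
        assert got == sorted(brute_force_single_linkage(positions, 30), key=min)
        assert got == [frozenset({100, 120}), frozenset({160})]

    def test_singleton(self):
        (c,) = cluster_sites(self.peaks([42]))
        assert c.representative == 42 and c.total_reads == 1

    def test_order_invariance(self):
        positions = [500, 100, 130, 160, 480, 300]
        a = cluster_sites(self.peaks(positions))
        b = cluster_sites(self.peaks(sorted(positions, reverse=True)))
        assert [
            {p.position for p in c.member_peaks} for c in a
        ] == [{p.position for p in c.member_peaks} for c in b]

    def test_representative_max_count_ties_most_3prime(self):
        (c,) = cluster_sites(self.peaks([100, 110, 120], [2, 5, 5]))
        assert c.representative == 120
        minus = [
            PolyAPeak("chr1", p, "-", n, 1.0)
            for p, n in [(100, 5), (110, 5), (120, 2)]
        ]
        (cm,) = cluster_sites(minus)
        assert cm.representative == 100  # most 3' on the minus strand

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.integers(min_value=0, max_value=2000),
            min_size=1,
            max_size=40,
            unique=True,
        ),
        st.integers(min_value=1, max_value=60),
    )
    def test_property_partition_matches_oracle(self, positions, gap):
        clusters = cluster_sites(self.peaks(positions), cluster_gap=gap)
        got = sorted(
            (frozenset(p.position for p in c.member_peaks) for c in clusters),
            key=min,
        )
        assert got == sorted(brute_force_single_linkage(positions, gap), key=min)
        # every site in exactly one cluster
        assert sorted(p for g in got for p in g) == sorted(positions)
        # inter-cluster distance exceeds the gap
        spans = sorted((min(g), max(g)) for g in got)
        for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
            assert lo2 - hi1 > gap

    def test_idempotent_on_cluster_output(self):
        clusters = cluster_sites(self.peaks([100, 120, 160]))
        again = cluster_sites(
            [p for c in clusters for p in c.member_peaks]
        )
        assert len(again) == len(clusters)


def test_fixture_decoys_rejected_true_sites_kept(sim_ref, genome):
    """Planted A-run decoys fail the screen; every true site passes."""
    from csikit.polya import score_peaks

    peaks = []
    for g in sim_ref.truth.genes:
        for p in g.cleavage_sites:
            peaks.append(PolyAPeak("chrSim", p, g.strand, 10))
        for p in g.decoy_sites:
            peaks.append(PolyAPeak("chrSim", p, g.strand, 10))
    score_peaks(peaks, genome)
    decoys = {
        (g.strand, p) for g in sim_ref.truth.genes for p in g.decoy_sites
    }
    for peak in peaks:
        expected_reject = (peak.strand, peak.position) in decoys
        assert (peak.priming_score <= 0) is expected_reject, (
            peak.position,
            peak.strand,
        )
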