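"""PolyA cleavage-site calling from 3'-end sequencing alignments.

The 3'-end protocols (polyA-Seq and relatives) prime on the polyA tail,
so after trimming, a read's 5' end marks the cleavage position. This
module tallies read starts, extracts genomic windows around each
candidate peak, screens internal-priming artifacts (oligo-dT priming on
genomic adenine runs rather than true tails), and clusters accepted
sites that fall within a small genomic gap of each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pysam
from pyfaidx import Fasta

logger = logging.getLogger("csikit")

#: upstream / downstream extents of the sequence window around a peak,
#: matching the convention of trained cleavage-site classifiers.
WINDOW_UPSTREAM = 40
WINDOW_DOWNSTREAM = 30

#: internal-priming screen defaults: reject if the adenine fraction of
#: the downstream 30 nt reaches A_FRAC_MAX, or an A-run of A_RUN_MAX or
#: more is present there.
A_FRAC_MAX = 0.65
A_RUN_MAX = 6

DEFAULT_CLUSTER_GAP = 30
DEFAULT_MIN_READS = 1

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PolyAPeak:
    """A candidate cleavage site: one genomic position with read support."""

    chrom: str
    position: int
    strand: str
    read_count: int
    priming_score: float = 0.0


@dataclass
class PolyACluster:
    """Accepted cleavage sites chained within ``cluster_gap`` of each other.

    ``representative`` is the member with the highest read count (ties
    broken toward the most 3' member); ``distal_position`` is the
    strand-aware most 3' member coordinate, used as the interval
    boundary so the reported UTR extent is maximal.
    """

    member_peaks: list[PolyAPeak] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.member_peaks[0].chrom

    @property
    def strand(self) -> str:
        return self.member_peaks[0].strand

    @property
    def total_reads(self) -> int:
        return sum(p.read_count for p in self.member_peaks)

    @property
    def representative(self) -> int:
        peaks = self.member_peaks
        best = peaks[0]
        for p in peaks[1:]:
            if p.read_count > best.read_count:
                best = p
            elif p.read_count == best.read_count:
                if (self.strand == "+" and p.position > best.position) or (
                    self.strand == "-" and p.position < best.position
                ):
                    best = p
        return best.position

    @property
    def distal_position(self) -> int:
        positions = [p.position for p in self.member_peaks]
        return max(positions) if self.strand == "+" else min(positions)


def _open_alignments(
    alignments: str | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
) -> Iterator[pysam.AlignedSegment]:
    if isinstance(alignments, str):
        with pysam.AlignmentFile(alignments) as fh:
            yield from fh
    elif isinstance(alignments, pysam.AlignmentFile):
        yield from alignments
    else:
        yield from alignments


def tally_read_starts(
    alignments: str | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    strand_mode: str = "same",
) -> dict[tuple[str, str], dict[int, int]]:
    """Tally alignment 5'-end positions per (chrom, strand).

    The key position is the read's 5' end in transcript orientation:
    ``reference_start`` for a forward alignment, the rightmost aligned
    base (``reference_end - 1``) for a reverse alignment.

    Parameters
    ----------
    alignments
        SAM/BAM path, open AlignmentFile, or an iterable of records.
    strand_mode
        ``"same"``: the transcript strand is the alignment strand
        (default; read starts mark the cleavage site directly).
        ``"opposite"``: libraries whose reads align antisense to the
        transcript; the attributed strand is flipped and the key becomes
        the alignment's 3' end.

    Returns
    -------
    dict
        ``{(chrom, strand): {position: count}}``. Unmapped records are
        skipped; the skip count is logged.
    """
    if strand_mode not in ("same", "opposite"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    counts: dict[tuple[str, str], dict[int, int]] = {}
    skipped = 0
    for rec in _open_alignments(alignments):
        if rec.is_unmapped:
            skipped += 1
            continue
        aln_strand = "-" if rec.is_reverse else "+"
        five_prime = rec.reference_end - 1 if rec.is_reverse else rec.reference_start
        three_prime = rec.reference_start if rec.is_reverse else rec.reference_end - 1
        if strand_mode == "same":
            strand, pos = aln_strand, five_prime
        else:
            strand = "-" if aln_strand == "+" else "+"
            pos = three_prime
        per = counts.setdefault((rec.reference_name, strand), {})
        per[pos] = per.get(pos, 0) + 1
    if skipped:
        logger.info("tally_read_starts: skipped %d unmapped records", skipped)
    return counts


def peaks_from_tally(
    tally: Mapping[tuple[str, str], Mapping[int, int]]
) -> list[PolyAPeak]:
    """Flatten a read-start tally into sorted PolyAPeak records."""
    peaks = [
        PolyAPeak(chrom, pos, strand, count)
        for (chrom, strand), per in tally.items()
        for pos, count in per.items()
    ]
    peaks.sort(key=lambda p: (p.chrom, p.strand, p.position))
    return peaks


def extract_peak_window(
    peak: PolyAPeak,
    genome: Fasta,
    upstream: int = WINDOW_UPSTREAM,
    downstream: int = WINDOW_DOWNSTREAM,
) -> tuple[str, int]:
    """Strand-oriented sequence window around a cleavage site.

    Covers ``upstream`` nt before through ``downstream`` nt after the
    site in transcript orientation (<= upstream+downstream+1 nt total;
    truncated without padding at contig edges). Minus-strand windows are
    reverse-complemented.

    Returns
    -------
    (sequence, site_index)
        ``sequence[site_index]`` is the cleavage-site base.
    """
    if peak.chrom not in genome:
        raise KeyError(f"contig {peak.chrom!r} not in genome FASTA")
    contig = genome[peak.chrom]
    contig_len = len(contig)
    if not 0 <= peak.position < contig_len:
        raise ValueError(
            f"peak position {peak.position} outside contig "
            f"{peak.chrom} (length {contig_len})"
        )
    if peak.strand == "+":
        lo = max(peak.position - upstream, 0)
        hi = min(peak.position + downstream + 1, contig_len)
        seq = str(contig[lo:hi]).upper()
        site_index = peak.position - lo
    else:
        lo = max(peak.position - downstream, 0)
        hi = min(peak.position + upstream + 1, contig_len)
        seq = reverse_complement(str(contig[lo:hi]).upper())
        site_index = hi - 1 - peak.position
    return seq, site_index


def extract_peak_windows(
    peaks: Iterable[PolyAPeak],
    genome: Fasta | str,
    upstream: int = WINDOW_UPSTREAM,
    downstream: int = WINDOW_DOWNSTREAM,
) -> list[tuple[PolyAPeak, str, int]]:
    """Vector form of :func:`extract_peak_window`."""
    if isinstance(genome, str):
        genome = Fasta(genome)
    return [
        (p, *extract_peak_window(p, genome, upstream, downstream)) for p in peaks
    ]


def _longest_run(seq: str, base: str) -> int:
    best = run = 0
    for ch in seq:
        run = run + 1 if ch == base else 0
        best = max(best, run)
    return best


def score_internal_priming(
    window: str,
    site_index: int,
    a_frac_max: float = A_FRAC_MAX,
    a_run_max: int = A_RUN_MAX,
    downstream: int = WINDOW_DOWNSTREAM,
) -> float:
    """Score a cleavage-site window for internal-priming artifacts.

    A true polyA event has its adenines supplied by the non-templated
    tail; a genomic adenine run immediately downstream of the candidate
    site instead suggests the oligo-dT primer annealed inside the
    transcript body. The score is positive iff the downstream
    ``downstream`` nt have an A fraction strictly below ``a_frac_max``
    AND no run of ``a_run_max`` or more consecutive A. Only the sign is
    contractual; the magnitude (margin below the fraction threshold) is
    informational.

    Windows with fewer than 10 nt downstream of the site are rejected
    (score < 0) with a warning.
    """
    down = window[site_index + 1 : site_index + 1 + downstream].upper()
    if len(down) < 10:
        logger.warning(
            "cleavage-site window has only %d nt downstream; rejected",
            len(down),
        )
        return -1.0
    a_frac = down.count("A") / len(down)
    if _longest_run(down, "A") >= a_run_max:
        return -max(a_frac, 1e-9)
    # strict inequality: a site exactly at the threshold is rejected
    return a_frac_max - a_frac  # <= 0 when a_frac >= a_frac_max


def score_peaks(
    peaks: Iterable[PolyAPeak],
    genome: Fasta | str,
    a_frac_max: float = A_FRAC_MAX,
    a_run_max: int = A_RUN_MAX,
    score_table: Mapping[tuple[str, int, str], float] | None = None,
) -> list[PolyAPeak]:
    """Attach priming scores to peaks, in place, and return them.

    ``score_table`` injects externally computed per-site scores (keyed
    ``(chrom, position, strand)``), e.g. from a trained classifier; the
    heuristic is used for sites absent from the table.
    """
    scored = []
    for peak, window, site_index in extract_peak_windows(peaks, genome):
        if score_table is not None and (
            key := (peak.chrom, peak.position, peak.strand)
        ) in score_table:
            peak.priming_score = float(score_table[key])
        else:
            peak.priming_score = score_internal_priming(
                window, site_index, a_frac_max, a_run_max
            )
        scored.append(peak)
    return scored


def filter_peaks(
    peaks: Iterable[PolyAPeak], min_reads: int = DEFAULT_MIN_READS
) -> list[PolyAPeak]:
    """Keep peaks with read support >= min_reads and a positive score."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return [
        p for p in peaks if p.read_count >= min_reads and p.priming_score > 0
    ]


def cluster_sites(
    sites: Iterable[PolyAPeak], cluster_gap: int = DEFAULT_CLUSTER_GAP
) -> list[PolyACluster]:
    """Single-linkage clustering of accepted sites per (chrom, strand).

    Adjacent sites at most ``cluster_gap`` bp apart are chained into one
    cluster; chaining may extend a cluster's total span beyond the gap.
    Input order is irrelevant. Every site belongs to exactly one
    cluster, and distinct clusters on the same chrom/strand are more
    than ``cluster_gap`` apart.
    """
    by_group: dict[tuple[str, str], list[PolyAPeak]] = {}
    for s in sites:
        by_group.setdefault((s.chrom, s.strand), []).append(s)
    clusters: list[PolyACluster] = []
    for key in sorted(by_group):
        members = sorted(by_group[key], key=lambda p: p.position)
        current = [members[0]]
        for peak in members[1:]:
            if peak.position - current[-1].position <= cluster_gap:
                current.append(peak)
            else:
                clusters.append(PolyACluster(current))
                current = [peak]
        clusters.append(PolyACluster(current))
    return clusters


def read_site_table(path: str) -> list[PolyAPeak]:
    """Read a 6-column BED-like site table.

    Columns: chrom, start, end, name, count, strand. The site position
    is the BED start; ``end`` must equal ``start + 1``.
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 6 columns, got {len(fields)}"
                )
            chrom, start, end, _name, count, strand = fields[:6]
            if int(end) != int(start) + 1:
                raise ValueError(
                    f"{path}:{lineno}: site rows must be 1 bp wide"
                )
            peaks.append(PolyAPeak(chrom, int(start), strand, int(count)))
    peaks.sort(key=lambda p: (p.chrom, p.strand, p.position))
    return peaks


def read_score_table(path: str) -> dict[tuple[str, int, str], float]:
    """Read a TSV of externally computed priming scores.

    Columns: chrom, position (0-based), strand, score.
    """
    table: dict[tuple[str, int, str], float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, pos, strand, score = line.split("\t")[:4]
            table[(chrom, int(pos), strand)] = float(score)
    return table


def call_clusters(
    alignments: str | Iterable[pysam.AlignedSegment],
    genome: Fasta | str,
    strand_mode: str = "same",
    min_reads: int = DEFAULT_MIN_READS,
    cluster_gap: int = DEFAULT_CLUSTER_GAP,
    a_frac_max: float = A_FRAC_MAX,
    a_run_max: int = A_RUN_MAX,
    score_table: Mapping[tuple[str, int, str], float] | None = None,
) -> list[PolyACluster]:
    """Full site-calling pipeline: tally, score, filter, cluster."""
    peaks = peaks_from_tally(tally_read_starts(alignments, strand_mode))
    scored = score_peaks(peaks, genome, a_frac_max, a_run_max, score_table)
    return cluster_sites(filter_peaks(scored, min_reads), cluster_gap)
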