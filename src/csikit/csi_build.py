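"""Cleavage-site interval (CSI) construction and BED I/O.

A CSI is the genomic segment between two consecutive functional
polyadenylation sites of one gene — or between the gene's distal stop
codon and its first site. N accepted clusters in a gene's terminal
region yield N adjacent intervals tiling the stretch from the stop
codon out to the distal cluster. Intervals are emitted in a modified
8-column BED dialect:

    chrom  begin  end  identifier  1  strand  gene_id  symbol

with identifier ``<gene_id>:<stop>_<begin>-<end>`` (genomic half-open
coordinates; the score column is the constant 1).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

from .annotation import GeneModel, GenomicInterval, TerminalRegion
from .polya import PolyACluster

logger = logging.getLogger("csikit")


@dataclass(frozen=True)
class CSI:
    """One cleavage-site interval of a gene.

    ``index`` is the 1-based rank counted from the stop codon outward:
    index 1 always abuts the stop codon, on either strand.
    """

    gene_id: str
    symbol: str
    index: int
    interval: GenomicInterval
    stop_codon: int

    @property
    def identifier(self) -> str:
        return (
            f"{self.gene_id}:{self.stop_codon}"
            f"_{self.interval.begin}-{self.interval.end}"
        )


_ID_RE = re.compile(r"^(?P<gene>.+):(?P<stop>\d+)_(?P<begin>\d+)-(?P<end>\d+)$")


def parse_identifier(identifier: str) -> tuple[str, int, int, int]:
    """Split a CSI identifier into (gene_id, stop, begin, end)."""
    m = _ID_RE.match(identifier)
    if m is None:
        raise ValueError(f"malformed CSI identifier {identifier!r}")
    return (
        m.group("gene"),
        int(m.group("stop")),
        int(m.group("begin")),
        int(m.group("end")),
    )


@dataclass
class ClusterAssignment:
    """Clusters assigned to one gene, ordered proximal to distal."""

    gene_id: str
    clusters: list[PolyACluster]
    ambiguous: bool = False


def assign_clusters(
    clusters: Iterable[PolyACluster],
    regions: Iterable[TerminalRegion],
    genes: Mapping[str, GeneModel],
) -> dict[str, ClusterAssignment]:
    """Assign each polyA cluster to the gene whose terminal region holds it.

    A cluster whose representative coordinate lies in exactly one
    terminal region (matching chrom and strand) goes to that gene;
    clusters in no region are discarded; a cluster inside two or more
    regions is assigned to the gene with the nearest stop codon and the
    assignment flagged ambiguous (equidistant ties go to every tied
    gene, flagged). Output lists are ordered by increasing distance
    from the stop codon.
    """
    region_list = list(regions)
    out: dict[str, ClusterAssignment] = {}
    n_discarded = 0
    for cluster in clusters:
        hits = [
            r
            for r in region_list
            if r.region.chrom == cluster.chrom
            and r.region.strand == cluster.strand
            and r.region.begin <= cluster.representative < r.region.end
        ]
        if not hits:
            n_discarded += 1
            continue
        ambiguous = len(hits) > 1
        if ambiguous:
            dist = {
                r.gene_id: abs(
                    cluster.representative - genes[r.gene_id].distal_stop
                )
                for r in hits
            }
            best = min(dist.values())
            hits = [r for r in hits if dist[r.gene_id] == best]
        for r in hits:
            a = out.setdefault(r.gene_id, ClusterAssignment(r.gene_id, []))
            a.clusters.append(cluster)
            a.ambiguous = a.ambiguous or ambiguous
    if n_discarded:
        logger.info(
            "assign_clusters: %d clusters outside all terminal regions "
            "discarded",
            n_discarded,
        )
    for gid, a in out.items():
        stop = genes[gid].distal_stop
        a.clusters.sort(key=lambda c: abs(c.distal_position - stop))
    return out


def build_csis(
    gene_id: str,
    symbol: str,
    chrom: str,
    strand: str,
    distal_stop: int,
    boundaries: Iterable[int],
) -> list[CSI]:
    """Tile the stretch from the distal stop codon to the distal site.

    ``boundaries`` are the strand-aware most-3' coordinates of the
    gene's assigned clusters, ordered or not; N boundaries yield N
    adjacent intervals, interval k spanning boundary_{k-1} ->
    boundary_k with boundary_0 = distal_stop. Minus-strand intervals
    are emitted with begin < end, index 1 abutting the stop codon.
    """
    bounds = sorted(set(boundaries), reverse=(strand == "-"))
    if not bounds:
        logger.warning("gene %s: no clusters; unresolved, no CSIs", gene_id)
        return []
    csis: list[CSI] = []
    prev = distal_stop
    for k, b in enumerate(bounds, start=1):
        if strand == "+":
            if b <= prev:
                raise ValueError(
                    f"gene {gene_id}: boundary {b} not 3' of {prev}"
                )
            iv = GenomicInterval(chrom, prev, b, strand)
        else:
            if b >= prev:
                raise ValueError(
                    f"gene {gene_id}: boundary {b} not 3' of {prev}"
                )
            iv = GenomicInterval(chrom, b, prev, strand)
        csis.append(CSI(gene_id, symbol, k, iv, distal_stop))
        prev = b
    return csis


def build_all_csis(
    genes: Mapping[str, GeneModel],
    assignments: Mapping[str, ClusterAssignment],
) -> list[CSI]:
    """Build CSIs for every gene with at least one assigned cluster."""
    csis: list[CSI] = []
    for gid in sorted(assignments):
        g = genes[gid]
        boundaries = [c.distal_position for c in assignments[gid].clusters]
        # the stop codon itself can host a cluster boundary; drop it
        boundaries = [b for b in boundaries if b != g.distal_stop]
        if not boundaries:
            logger.warning("gene %s: no usable boundaries; no CSIs", gid)
            continue
        csis.extend(
            build_csis(
                gid, g.symbol, g.chrom, g.strand, g.distal_stop, boundaries
            )
        )
    csis.sort(key=lambda c: (c.interval.chrom, c.interval.begin, c.interval.end))
    return csis


class CsiBedError(ValueError):
    """Malformed CSI BED content; message names the line number."""


def write_csi_bed(csis: Iterable[CSI], path_or_handle: str | IO[str]) -> None:
    """Write CSIs as tab-separated 8-column BED, no header."""
    rows = sorted(
        csis, key=lambda c: (c.interval.chrom, c.interval.begin, c.interval.end)
    )
    own = isinstance(path_or_handle, str)
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        for c in rows:
            fh.write(
                "\t".join(
                    (
                        c.interval.chrom,
                        str(c.interval.begin),
                        str(c.interval.end),
                        c.identifier,
                        "1",
                        c.interval.strand,
                        c.gene_id,
                        c.symbol,
                    )
                )
                + "\n"
            )
    finally:
        if own:
            fh.close()


def read_csi_bed(path_or_handle: str | IO[str] | Iterable[str]) -> list[CSI]:
    """Read an 8-column CSI BED file back into CSI records.

    Round-trips with :func:`write_csi_bed`. The per-gene 1-based index
    is reconstructed from genomic order and strand.
    """
    if isinstance(path_or_handle, str):
        with open(path_or_handle) as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_handle)
    raw: list[tuple[str, int, int, str, str, str, str]] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        if len(fields) != 8:
            raise CsiBedError(
                f"line {lineno}: expected 8 tab-separated columns, "
                f"got {len(fields)}"
            )
        chrom, begin, end, identifier, _score, strand, gene_id, symbol = fields
        begin_i, end_i = int(begin), int(end)
        if begin_i >= end_i:
            raise CsiBedError(
                f"line {lineno}: begin {begin_i} must be < end {end_i}"
            )
        raw.append((chrom, begin_i, end_i, identifier, strand, gene_id, symbol))

    by_gene: dict[str, list[tuple]] = {}
    for row in raw:
        by_gene.setdefault(row[5], []).append(row)
    csis: list[CSI] = []
    for gene_rows in by_gene.values():
        strand = gene_rows[0][4]
        gene_rows.sort(key=lambda r: r[1], reverse=(strand == "-"))
        for k, (chrom, begin, end, identifier, strand, gene_id, symbol) in (
            enumerate(gene_rows, start=1)
        ):
            _gid, stop, id_begin, id_end = parse_identifier(identifier)
            if (id_begin, id_end) != (begin, end):
                raise CsiBedError(
                    f"identifier {identifier!r} disagrees with coordinates "
                    f"[{begin}, {end})"
                )
            csis.append(
                CSI(gene_id, symbol, k, GenomicInterval(chrom, begin, end, strand), stop)
            )
    csis.sort(key=lambda c: (c.interval.chrom, c.interval.begin, c.interval.end))
    return csis


def write_bed6(csis: Iterable[CSI], path: str) -> None:
    """Standard 6-column BED export for genome browsers."""
    with open(path, "w") as fh:
        for c in sorted(
            csis,
            key=lambda c: (c.interval.chrom, c.interval.begin, c.interval.end),
        ):
            fh.write(
                f"{c.interval.chrom}\t{c.interval.begin}\t{c.interval.end}"
                f"\t{c.identifier}\t1\t{c.interval.strand}\n"
            )
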