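"""Gene-model parsing and terminal-region derivation.

Parses Ensembl-dialect GTF into per-gene models (exons, stop codons,
strand), determines the distal (most 3') stop codon of each coding gene,
and derives the *terminal region*: the stretch of genome from the distal
stop codon to the nearest coding-exon boundary of a different gene, in
which polyA clusters may later be assigned.

All coordinates are 0-based half-open (BED convention); GTF 1-based
inclusive coordinates are converted on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator

logger = logging.getLogger("csikit")

DEFAULT_MAX_EXTENT = 40_000
"""Default cap (bp) on terminal-region length downstream of the stop codon.

Genome-wide polyA-site surveys place <5% of clustered sites beyond 40 kb
of the distal stop codon, so extension past that is rarely evidence-backed.
"""


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [begin, end) on a strand."""

    chrom: str
    begin: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.begin < 0:
            raise ValueError(f"begin must be >= 0, got {self.begin}")
        if self.begin >= self.end:
            raise ValueError(
                f"begin must be < end, got [{self.begin}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.begin

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.begin < other.end
            and other.begin < self.end
        )


@dataclass
class GeneModel:
    """A protein-coding gene: exons, stop codons and the distal stop.

    ``distal_stop`` is the strand-aware most-3' boundary over all stop
    codons: the maximal ``end`` on '+', the minimal ``begin`` on '-'.
    It is the coordinate at which the first cleavage-site interval of the
    gene is anchored.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    stop_codons: list[GenomicInterval] = field(default_factory=list)

    @property
    def distal_stop(self) -> int:
        if not self.stop_codons:
            raise ValueError(f"gene {self.gene_id} has no stop codons")
        if self.strand == "+":
            return max(s.end for s in self.stop_codons)
        return min(s.begin for s in self.stop_codons)

    @property
    def span(self) -> GenomicInterval:
        begin = min(e.begin for e in self.exons + self.stop_codons)
        end = max(e.end for e in self.exons + self.stop_codons)
        return GenomicInterval(self.chrom, begin, end, self.strand)


@dataclass(frozen=True)
class TerminalRegion:
    """Candidate zone for polyA-cluster assignment for one gene.

    Runs from the gene's distal stop codon to the nearest coding-exon
    boundary of a different gene in the 3' direction (any strand), or to
    ``distal_stop +/- max_extent`` if no such boundary is nearer.
    ``capped`` is set when the max_extent truncation was the binding
    constraint.
    """

    gene_id: str
    region: GenomicInterval
    capped: bool = False


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    """Parse an Ensembl GTF attribute column, tolerant of key order."""
    return dict(_ATTR_RE.findall(attr_field))


def _merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Union of overlapping/adjacent-overlapping intervals, sorted."""
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.begin, i.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.begin < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = replace(last, end=iv.end)
        else:
            merged.append(iv)
    return merged


def _iter_lines(gtf_stream: str | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(gtf_stream, str):
        with open(gtf_stream) as fh:
            yield from fh
    else:
        yield from gtf_stream


def parse_gtf(gtf_stream: str | IO[str] | Iterable[str]) -> list[GeneModel]:
    """Parse a GTF into gene models with distal stop codons.

    Parameters
    ----------
    gtf_stream
        Path, open text handle, or iterable of GTF lines (Ensembl
        attribute dialect: ``gene_id "X"; gene_name "Y";``).

    Returns
    -------
    list of GeneModel
        One model per gene carrying at least one ``stop_codon`` feature.
        Genes with exons but no stop codon (non-coding) are excluded with
        a logged warning. Overlapping stop-codon records of a gene are
        merged. Gene records under different ids are merged into one
        model when their intervals overlap and their symbols match
        (Ensembl + RefSeq union annotations).

    Raises
    ------
    GtfParseError
        If a non-comment line does not have 9 tab-separated fields or
        carries non-numeric coordinates; the message names the line
        number.
    """
    genes: dict[str, GeneModel] = {}
    for lineno, line in enumerate(_iter_lines(gtf_stream), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(
                f"line {lineno}: expected 9 tab-separated fields, "
                f"got {len(fields)}"
            )
        chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
        if feature not in ("exon", "stop_codon"):
            continue
        try:
            begin0, end0 = int(start) - 1, int(end)
        except ValueError:
            raise GtfParseError(
                f"line {lineno}: non-integer coordinates {start!r}..{end!r}"
            ) from None
        if strand not in ("+", "-"):
            raise GtfParseError(f"line {lineno}: invalid strand {strand!r}")
        attributes = _parse_attributes(attrs)
        gene_id = attributes.get("gene_id")
        if gene_id is None:
            raise GtfParseError(f"line {lineno}: missing gene_id attribute")
        symbol = attributes.get("gene_name", gene_id)
        model = genes.get(gene_id)
        if model is None:
            model = GeneModel(gene_id, symbol, chrom, strand)
            genes[gene_id] = model
        iv = GenomicInterval(chrom, begin0, end0, strand)
        if feature == "exon":
            model.exons.append(iv)
        else:
            model.stop_codons.append(iv)

    models = _merge_same_symbol(list(genes.values()))

    out: list[GeneModel] = []
    for model in models:
        if not model.stop_codons:
            logger.warning(
                "gene %s has exons but no stop_codon feature; excluded",
                model.gene_id,
            )
            continue
        if not model.exons:
            logger.warning(
                "gene %s has stop codons but no exons; excluded", model.gene_id
            )
            continue
        model.exons = _merge_intervals(model.exons)
        model.stop_codons = _merge_intervals(model.stop_codons)
        out.append(model)
    out.sort(key=lambda g: (g.chrom, g.span.begin))
    return out


def _merge_same_symbol(models: list[GeneModel]) -> list[GeneModel]:
    # Union of gene records listed under distinct ids (e.g. Ensembl +
    # RefSeq): merge when symbols match and stop/exon spans overlap on
    # the same chrom/strand. First-seen gene_id wins.
    by_key: dict[tuple[str, str, str], list[GeneModel]] = {}
    singles: list[GeneModel] = []
    for m in models:
        if not (m.exons or m.stop_codons):
            continue
        by_key.setdefault((m.chrom, m.strand, m.symbol), []).append(m)
    merged: list[GeneModel] = []
    for group in by_key.values():
        group.sort(key=lambda g: g.span.begin)
        current = group[0]
        for nxt in group[1:]:
            if nxt.gene_id != current.gene_id and not current.span.overlaps(
                nxt.span
            ):
                merged.append(current)
                current = nxt
                continue
            current.exons.extend(nxt.exons)
            current.stop_codons.extend(nxt.stop_codons)
        merged.append(current)
    return merged + singles


def terminal_regions(
    genes: list[GeneModel],
    max_extent: int = DEFAULT_MAX_EXTENT,
    chrom_lengths: dict[str, int] | None = None,
) -> list[TerminalRegion]:
    """Derive per-gene terminal regions downstream of the distal stop.

    The region runs 3' from each gene's distal stop codon up to the
    nearest coding-exon boundary of *any other* gene (regardless of
    strand), truncated at ``max_extent`` bp, and at the chromosome end
    when ``chrom_lengths`` is given. Genes whose stop codon is already
    overlapped by another gene's coding exon get no region (warned).
    """
    if max_extent <= 0:
        raise ValueError("max_extent must be > 0")
    chrom_lengths = chrom_lengths or {}
    # all coding exons (exons + stop codons) grouped per chrom, tagged
    # with owner so a gene never limits itself
    exons_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        for iv in g.exons + g.stop_codons:
            exons_by_chrom.setdefault(g.chrom, []).append(
                (iv.begin, iv.end, g.gene_id)
            )

    regions: list[TerminalRegion] = []
    for g in genes:
        stop = g.distal_stop
        others = [
            (b, e)
            for (b, e, gid) in exons_by_chrom.get(g.chrom, [])
            if gid != g.gene_id
        ]
        if g.strand == "+":
            begin = stop
            end = stop + max_extent
            capped = True
            # nearest other-gene exon reaching past the stop
            blocking = [b for (b, e) in others if e > stop]
            if blocking:
                nearest = min(blocking)
                if nearest <= begin:
                    logger.warning(
                        "gene %s: another gene's coding exon overlaps the "
                        "distal stop codon; no terminal region",
                        g.gene_id,
                    )
                    continue
                if nearest < end:
                    end, capped = nearest, False
            clen = chrom_lengths.get(g.chrom)
            if clen is not None and end > clen:
                end, capped = clen, False
        else:
            end = stop
            begin = max(stop - max_extent, 0)
            capped = stop - max_extent >= 0
            # nearest other-gene exon reaching before the stop
            blocking = [e for (b, e) in others if b < stop]
            if blocking:
                nearest = max(blocking)
                if nearest >= end:
                    logger.warning(
                        "gene %s: another gene's coding exon overlaps the "
                        "distal stop codon; no terminal region",
                        g.gene_id,
                    )
                    continue
                if nearest > begin:
                    begin, capped = nearest, False
        if begin >= end:
            logger.warning("gene %s: empty terminal region", g.gene_id)
            continue
        regions.append(
            TerminalRegion(
                g.gene_id,
                GenomicInterval(g.chrom, begin, end, g.strand),
                capped=capped,
            )
        )
    return regions
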