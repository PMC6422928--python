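"""Seeded synthetic test universe: genome, annotation, reads, truth.

Generates a deterministic single-contig genome carrying protein-coding
genes with known stop codons, planted cleavage sites (each preceded by
a polyA-signal hexamer 10-30 nt upstream, as the cleavage machinery
expects), and decoy genomic adenine runs that mimic internal-priming
artifacts. From that truth it simulates polyA-Seq alignments (read
starts at the planted sites, small jitter, plus decoy reads on the
A-runs) and RNA-Seq alignments whose per-isoform 3' ends follow known
per-condition usage vectors, so every pipeline stage can be tested
end-to-end with no external data.

All randomness flows from explicit seeds; no global RNG state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pysam

from .polya import reverse_complement

CONTIG = "chrSim"
POLYA_SIGNAL = "AATAAA"  # DNA-alphabet polyA signal hexamer
DECOY_RUN_LENGTH = 15
READ_LENGTH_POLYA = 30
READ_LENGTH_RNA = 50


@dataclass(frozen=True)
class SimGene:
    """Layout of one simulated gene (all coordinates 0-based)."""

    gene_id: str
    symbol: str
    strand: str
    exon: tuple[int, int]
    stop_codon: tuple[int, int]
    distal_stop: int
    cleavage_sites: tuple[int, ...]  # proximal -> distal
    decoy_sites: tuple[int, ...]


@dataclass
class SimTruth:
    """Everything the tests need to judge pipeline output."""

    seed: int
    genome_length: int
    genes: list[SimGene]
    psi_true: dict[str, list[np.ndarray]]  # condition -> per-gene usage
    library_depth: int

    def gene(self, gene_id: str) -> SimGene:
        return next(g for g in self.genes if g.gene_id == gene_id)


@dataclass
class SimConfig:
    """The stated world of the simulation.

    Defaults give a compact universe that still exercises every rule:
    a handful of genes on both strands, three cleavage sites per gene
    spaced well beyond the clustering gap, one internal-priming decoy
    per gene between the stop codon and the first site, and uniform
    usage in both conditions unless vectors are supplied.
    """

    n_genes: int = 6
    sites_per_gene: int = 3
    cds_length: int = 300
    site_spacing: int = 250
    tail: int = 200  # slack past the distal site, before the next gene
    spacer: int = 400  # intergenic gap ensuring terminal regions close
    margin: int = 500
    decoys_per_gene: int = 1
    conditions: tuple[str, str] = ("A", "B")
    psi_vectors: dict[str, list[Sequence[float]]] | None = None
    library_depth: int = 500  # expected RNA-Seq reads per gene per sample

    def psi_for(self, condition: str) -> list[np.ndarray]:
        if self.psi_vectors is not None and condition in self.psi_vectors:
            out = [np.asarray(v, dtype=float) for v in self.psi_vectors[condition]]
        else:
            out = [
                np.full(self.sites_per_gene, 1.0 / self.sites_per_gene)
                for _ in range(self.n_genes)
            ]
        for v in out:
            if not np.isclose(v.sum(), 1.0):
                raise ValueError("psi vectors must sum to 1")
        return out


@dataclass
class ReferenceSim:
    """A simulated reference: genome sequence, GTF lines, and truth."""

    sequence: str
    gtf_lines: list[str]
    truth: SimTruth

    def write_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            fh.write(f">{CONTIG}\n")
            for i in range(0, len(self.sequence), width):
                fh.write(self.sequence[i : i + width] + "\n")

    def write_gtf(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.writelines(line + "\n" for line in self.gtf_lines)

    def header(self) -> pysam.AlignmentHeader:
        return pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [{"SN": CONTIG, "LN": len(self.sequence)}],
            }
        )


def _random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    """Random DNA with homopolymer runs capped at 4 nt.

    The cap keeps the background free of accidental internal-priming
    signals so every rejection in the fixtures traces to a planted
    decoy.
    """
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seq = bases[rng.integers(0, 4, size=length)].copy()
    run = 1
    for i in range(1, length):
        if seq[i] == seq[i - 1]:
            run += 1
            if run > 4:
                choices = [b for b in bases if b != seq[i]]
                seq[i] = choices[rng.integers(3)]
                run = 1
        else:
            run = 1
    return seq


def simulate_reference(
    config: SimConfig | None = None, seed: int = 0
) -> ReferenceSim:
    """Build the deterministic genome + GTF + truth for a config.

    Genes alternate strands along one contig. For each planted
    cleavage site a polyA-signal hexamer is embedded 10-30 nt upstream
    in transcript orientation; decoy A-runs (transcript-strand
    adenines) start 1 nt downstream of each decoy site position.
    """
    config = config or SimConfig()
    if config.n_genes < 1:
        raise ValueError("config must list >= 1 gene")
    if config.site_spacing <= 2 * DECOY_RUN_LENGTH + 60:
        raise ValueError("site_spacing too small for decoy placement")
    rng = np.random.default_rng(seed)
    utr_len = config.sites_per_gene * config.site_spacing + config.tail
    slot = config.cds_length + utr_len + config.spacer
    genome_length = 2 * config.margin + config.n_genes * slot
    seq = _random_sequence(genome_length, rng)

    genes: list[SimGene] = []
    for gi in range(config.n_genes):
        o = config.margin + gi * slot
        strand = "+" if gi % 2 == 0 else "-"
        gene_id = f"SIMG{gi:04d}"
        if strand == "+":
            exon = (o, o + config.cds_length)
            stop_codon = (exon[1] - 3, exon[1])
            distal = exon[1]
            sites = tuple(
                distal + (k + 1) * config.site_spacing
                for k in range(config.sites_per_gene)
            )
            decoys = tuple(
                distal + config.site_spacing // 2 + d * 60
                for d in range(config.decoys_per_gene)
            )
        else:
            exon = (o + slot - config.spacer - config.cds_length,
                    o + slot - config.spacer)
            stop_codon = (exon[0], exon[0] + 3)
            distal = exon[0]
            sites = tuple(
                distal - (k + 1) * config.site_spacing
                for k in range(config.sites_per_gene)
            )
            decoys = tuple(
                distal - config.site_spacing // 2 - d * 60
                for d in range(config.decoys_per_gene)
            )
        # plant the polyA signal 10-30 nt upstream of each site
        for p in sites:
            offset = int(rng.integers(10, 31))
            if strand == "+":
                start = p - offset - len(POLYA_SIGNAL)
                seq[start : start + len(POLYA_SIGNAL)] = np.frombuffer(
                    POLYA_SIGNAL.encode(), dtype="S1"
                )
            else:
                start = p + offset + 1
                rc = reverse_complement(POLYA_SIGNAL)
                seq[start : start + len(rc)] = np.frombuffer(
                    rc.encode(), dtype="S1"
                )
        # plant decoy adenine runs just downstream of each decoy site
        for p in decoys:
            if strand == "+":
                seq[p + 1 : p + 1 + DECOY_RUN_LENGTH] = b"A"
            else:
                seq[p - DECOY_RUN_LENGTH : p] = b"T"
        genes.append(
            SimGene(
                gene_id,
                f"Sim{gi}",
                strand,
                exon,
                stop_codon,
                distal,
                sites,
                decoys,
            )
        )

    gtf_lines = []
    for g in genes:
        attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
        for feature, (b, e) in (("exon", g.exon), ("stop_codon", g.stop_codon)):
            gtf_lines.append(
                "\t".join(
                    (
                        CONTIG,
                        "sim",
                        feature,
                        str(b + 1),
                        str(e),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    )
                )
            )

    truth = SimTruth(
        seed=seed,
        genome_length=genome_length,
        genes=genes,
        psi_true={c: config.psi_for(c) for c in config.conditions},
        library_depth=config.library_depth,
    )
    return ReferenceSim("".join(s.decode() for s in seq), gtf_lines, truth)


def _make_read(
    header: pysam.AlignmentHeader,
    name: str,
    start: int,
    length: int,
    reverse: bool,
    genome: str,
) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.reference_id = 0
    rec.reference_start = start
    rec.mapping_quality = 60
    rec.cigarstring = f"{length}M"
    rec.flag = 16 if reverse else 0
    sub = genome[start : start + length]
    rec.query_sequence = reverse_complement(sub) if reverse else sub
    rec.set_tag("NH", 1)
    return rec


def simulate_polya_reads(
    reference: ReferenceSim,
    depth: int = 50,
    jitter: int = 2,
    seed: int = 0,
    decoy_depth: int | None = None,
) -> list[pysam.AlignedSegment]:
    """PolyA-Seq-like alignments: starts at planted sites, plus decoys.

    Each planted site receives ``depth`` reads whose transcript-
    orientation 5' ends fall within +/-``jitter`` (<= 5) nt of the
    site; each decoy A-run position receives ``decoy_depth`` reads
    (default: same depth). Reads are on the gene strand, coordinate
    sorted.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1 per site")
    if jitter > 5:
        raise ValueError("jitter must be <= 5 nt")
    decoy_depth = depth if decoy_depth is None else decoy_depth
    rng = np.random.default_rng(seed)
    header = reference.header()
    genome = reference.sequence
    reads: list[pysam.AlignedSegment] = []
    serial = 0
    for g in reference.truth.genes:
        for kind, positions, n in (
            ("site", g.cleavage_sites, depth),
            ("decoy", g.decoy_sites, decoy_depth),
        ):
            for p in positions:
                for _ in range(n):
                    j = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
                    pos = p + j
                    if g.strand == "+":
                        start = pos
                    else:
                        start = pos - (READ_LENGTH_POLYA - 1)
                    reads.append(
                        _make_read(
                            header,
                            f"pa_{g.gene_id}_{kind}_{serial}",
                            start,
                            READ_LENGTH_POLYA,
                            g.strand == "-",
                            genome,
                        )
                    )
                    serial += 1
    reads.sort(key=lambda r: r.reference_start)
    return reads


def simulate_rnaseq(
    reference: ReferenceSim,
    design: dict[str, str],
    depth: int | None = None,
    seed: int = 0,
    read_length: int = READ_LENGTH_RNA,
) -> dict[str, list[pysam.AlignedSegment]]:
    """Per-sample RNA-Seq alignments over the simulated 3'UTRs.

    ``design`` maps sample id -> condition label. Per gene and sample,
    the read total is Poisson(``depth``); each read's 3' isoform is
    drawn from the condition's true usage vector and the read is placed
    uniformly within that isoform's UTR span (stop codon to the
    isoform's cleavage site), so proximal intervals accumulate coverage
    from every longer isoform — the survival-function model.
    """
    truth = reference.truth
    depth = truth.library_depth if depth is None else depth
    rng = np.random.default_rng(seed)
    header = reference.header()
    genome = reference.sequence
    out: dict[str, list[pysam.AlignedSegment]] = {}
    for sample, condition in design.items():
        if condition not in truth.psi_true:
            raise ValueError(f"condition {condition!r} not in truth")
        reads: list[pysam.AlignedSegment] = []
        serial = 0
        for gi, g in enumerate(truth.genes):
            psi = truth.psi_true[condition][gi]
            if len(psi) != len(g.cleavage_sites):
                raise ValueError(
                    f"psi vector length {len(psi)} != site count for "
                    f"{g.gene_id}"
                )
            n = rng.poisson(depth)
            isoforms = rng.choice(len(psi), size=n, p=psi)
            for k in isoforms:
                site = g.cleavage_sites[k]
                if g.strand == "+":
                    span = (g.distal_stop, site)
                else:
                    span = (site, g.distal_stop)
                span_len = span[1] - span[0]
                length = min(read_length, span_len)
                start = span[0] + int(rng.integers(0, span_len - length + 1))
                reads.append(
                    _make_read(
                        header,
                        f"rna_{sample}_{g.gene_id}_{serial}",
                        start,
                        length,
                        g.strand == "-",
                        genome,
                    )
                )
                serial += 1
        reads.sort(key=lambda r: r.reference_start)
        out[sample] = reads
    return out


def write_sam(
    reads: Sequence[pysam.AlignedSegment],
    header: pysam.AlignmentHeader,
    path: str,
) -> None:
    """Write alignments as plain-text SAM."""
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for r in reads:
            fh.write(r)


def write_design(design: dict[str, str], sam_paths: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for sample, condition in design.items():
            fh.write(f"{sample}\t{condition}\t{sam_paths.get(sample, '')}\n")


def expected_counts(
    gene: SimGene, psi: np.ndarray, read_length: int = READ_LENGTH_RNA
) -> np.ndarray:
    """Analytic per-CSI expected count fractions under uniform placement.

    For isoform j (span stop -> site_j) reads of length L start
    uniformly over ``span_len - L + 1`` positions; the probability that
    a read overlaps CSI_k = [b_{k-1}, b_k) is the fraction of start
    positions with ``start < b_k`` and ``start + L > b_{k-1}`` (genomic
    coordinates mirrored on the minus strand). Returns, per CSI, the
    expected number of overlapping reads per simulated read (can exceed
    1 summed over CSIs: boundary-spanning reads count twice).
    """
    sites = gene.cleavage_sites
    bounds = [0] + [abs(s - gene.distal_stop) for s in sites]  # UTR-local
    expect = np.zeros(len(sites))
    for j, pj in enumerate(psi):
        span_len = bounds[j + 1]
        length = min(read_length, span_len)
        n_starts = span_len - length + 1
        for k in range(len(sites)):
            lo, hi = bounds[k], bounds[k + 1]
            # starts in [max(0, lo - L + 1), min(n_starts - 1, hi - 1)]
            s_lo = max(0, lo - length + 1)
            s_hi = min(n_starts - 1, hi - 1)
            if s_hi >= s_lo:
                expect[k] += pj * (s_hi - s_lo + 1) / n_starts
    return expect
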