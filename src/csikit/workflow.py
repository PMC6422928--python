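"""End-to-end composition of the annotation and site-calling stages."""

from __future__ import annotations

from typing import Iterable, Mapping

import pysam
from pyfaidx import Fasta

from . import annotation, csi_build, polya


def build_csi_annotation(
    gtf_stream,
    genome: Fasta | str,
    polya_alignments: str | Iterable[pysam.AlignedSegment],
    max_extent: int = annotation.DEFAULT_MAX_EXTENT,
    chrom_lengths: dict[str, int] | None = None,
    strand_mode: str = "same",
    min_reads: int = polya.DEFAULT_MIN_READS,
    cluster_gap: int = polya.DEFAULT_CLUSTER_GAP,
    a_frac_max: float = polya.A_FRAC_MAX,
    a_run_max: int = polya.A_RUN_MAX,
    score_table: Mapping[tuple[str, int, str], float] | None = None,
) -> list[csi_build.CSI]:
    """GTF + genome + polyA-Seq alignments -> CSI annotation.

    Runs the full construction: parse gene models, derive terminal
    regions, call/screen/cluster cleavage sites, assign clusters to
    genes, and tile the cleavage-site intervals.
    """
    genes = annotation.parse_gtf(gtf_stream)
    gene_map = {g.gene_id: g for g in genes}
    regions = annotation.terminal_regions(genes, max_extent, chrom_lengths)
    clusters = polya.call_clusters(
        polya_alignments,
        genome,
        strand_mode=strand_mode,
        min_reads=min_reads,
        cluster_gap=cluster_gap,
        a_frac_max=a_frac_max,
        a_run_max=a_run_max,
        score_table=score_table,
    )
    assignments = csi_build.assign_clusters(clusters, regions, gene_map)
    return csi_build.build_all_csis(gene_map, assignments)
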