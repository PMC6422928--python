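"""Read counting over CSIs, CPM normalization, and expression filters.

Counts uniquely mapped RNA-Seq reads per cleavage-site interval per
sample, scales to counts-per-million (CPM), applies the half-up integer
rounding used by the usage statistics (``floor(CPM + 0.5)``), and
enforces the contiguous-expression filter: a CSI is only testable if
every CSI between it and the stop codon has pooled read evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .csi_build import CSI

logger = logging.getLogger("csikit")

DEFAULT_MAPQ_MIN = 30


@dataclass
class ComparisonDesign:
    """Two-condition design: sample ids mapped to condition labels."""

    condition_1: str
    condition_2: str
    sample_conditions: dict[str, str]
    bam_paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = set(self.sample_conditions.values())
        for cond in (self.condition_1, self.condition_2):
            if cond not in labels:
                raise ValueError(f"no samples labelled {cond!r}")

    def samples(self, condition: str) -> list[str]:
        return [
            s for s, c in self.sample_conditions.items() if c == condition
        ]

    @property
    def m(self) -> int:
        """Replicates in condition 1."""
        return len(self.samples(self.condition_1))

    @property
    def n(self) -> int:
        """Replicates in condition 2."""
        return len(self.samples(self.condition_2))


def read_design(path: str | IO[str]) -> ComparisonDesign:
    """Read a sample->condition design TSV.

    Columns: sample_id, condition, and optionally bam_path. Condition 1
    is the first condition encountered, condition 2 the second; more
    than two conditions is an error.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype=str
    )
    if df.shape[1] < 2:
        raise ValueError("design table needs >= 2 columns (sample, condition)")
    samples = dict(zip(df[0], df[1]))
    conditions = list(dict.fromkeys(df[1]))
    if len(conditions) != 2:
        raise ValueError(
            f"design table must define exactly 2 conditions, got {conditions}"
        )
    bams = dict(zip(df[0], df[2])) if df.shape[1] >= 3 else {}
    return ComparisonDesign(conditions[0], conditions[1], samples, bams)


def filter_unique(
    alignments: Iterable[pysam.AlignedSegment],
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> Iterable[pysam.AlignedSegment]:
    """Yield uniquely mapping records.

    A record passes when its alignment-multiplicity tag (``NH``) equals
    1; records without the tag fall back to mapping quality >=
    ``mapq_min``. Unmapped records never pass.
    """
    for rec in alignments:
        if rec.is_unmapped:
            continue
        if rec.has_tag("NH"):
            if rec.get_tag("NH") == 1:
                yield rec
        elif rec.mapping_quality >= mapq_min:
            yield rec


class _IntervalIndex:
    """Per-chromosome sorted interval lookup (begin-sorted + max length)."""

    def __init__(self, csis: Sequence[CSI]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int]] = {}
        per: dict[str, list[tuple[int, int, int]]] = {}
        for i, c in enumerate(csis):
            per.setdefault(c.interval.chrom, []).append(
                (c.interval.begin, c.interval.end, i)
            )
        for chrom, rows in per.items():
            rows.sort()
            begins = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            idx = np.array([r[2] for r in rows], dtype=np.int64)
            maxlen = int((ends - begins).max())
            self._by_chrom[chrom] = (begins, ends, idx, maxlen)

    def overlapping(self, chrom: str, qbegin: int, qend: int) -> list[int]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        begins, ends, idx, maxlen = entry
        hi = int(np.searchsorted(begins, qend, side="left"))
        lo = int(np.searchsorted(begins, qbegin - maxlen, side="left"))
        return [
            int(idx[i])
            for i in range(lo, hi)
            if ends[i] > qbegin and begins[i] < qend
        ]


def count_reads(
    alignments: str | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    csis: Sequence[CSI],
    unique_only: bool = True,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    primary_interval_only: bool = False,
) -> np.ndarray:
    """Count reads per CSI for one sample.

    A read increments every CSI that any of its aligned blocks overlaps
    by at least 1 bp (at most once per CSI per read); a read spanning
    the boundary of two adjacent CSIs therefore counts in both — the
    per-interval coverage semantics. With ``primary_interval_only`` a
    read instead counts once, in the overlapped CSI with the largest
    overlapped base count (ties to the leftmost).

    Spliced reads are judged on aligned blocks, not their full
    reference span. Reads on chromosomes absent from the CSI set are
    ignored and tallied in the log.

    Returns
    -------
    numpy int array aligned with ``csis``.
    """
    if isinstance(alignments, str):
        handle = pysam.AlignmentFile(alignments)
        records: Iterable[pysam.AlignedSegment] = handle
    else:
        handle = None
        records = alignments
    index = _IntervalIndex(csis) if csis else None
    counts = np.zeros(len(csis), dtype=np.int64)
    missing_chrom = 0
    try:
        if unique_only:
            records = filter_unique(records, mapq_min)
        for rec in records:
            if index is None:
                break
            chrom = rec.reference_name
            if chrom not in index._by_chrom:
                missing_chrom += 1
                continue
            hit: dict[int, int] = {}
            for bstart, bend in rec.get_blocks():
                for i in index.overlapping(chrom, bstart, bend):
                    ov = min(bend, csis[i].interval.end) - max(
                        bstart, csis[i].interval.begin
                    )
                    hit[i] = hit.get(i, 0) + ov
            if not hit:
                continue
            if primary_interval_only:
                best = max(hit.items(), key=lambda kv: (kv[1], -kv[0]))[0]
                counts[best] += 1
            else:
                for i in hit:
                    counts[i] += 1
    finally:
        if handle is not None:
            handle.close()
    if missing_chrom:
        logger.info(
            "count_reads: %d reads on chromosomes absent from the CSI set",
            missing_chrom,
        )
    return counts


def cpm_normalize(
    raw: pd.DataFrame, library_sizes: pd.Series | None = None
) -> pd.DataFrame:
    """Scale raw counts to counts per million.

    ``cpm[i, s] = raw[i, s] * 1e6 / library_sizes[s]``. By default the
    library size is the per-sample total over the counted CSIs, so each
    CPM column sums to exactly 1e6; pass whole-library mapped-read
    totals to normalize against the full library instead.
    """
    if library_sizes is None:
        library_sizes = raw.sum(axis=0)
    for sample, size in library_sizes.items():
        if size <= 0:
            raise ValueError(f"sample {sample!r} has zero library size")
    return raw * 1e6 / library_sizes


def round_cpm(cpm: pd.DataFrame) -> pd.DataFrame:
    """Half-up integer rounding, ``floor(CPM + 0.5)``, elementwise."""
    return np.floor(cpm + 0.5).astype(np.int64)


def contiguity_filter(gene_counts: Sequence[int]) -> list[int]:
    """Indices (1-based) of the maximal contiguously expressed prefix.

    ``gene_counts`` are one gene's CSI counts pooled across all samples
    of the comparison, ordered by CSI index from the stop codon
    outward. Only the prefix of CSIs with pooled count > 0 is retained:
    expression evidence must be contiguous from the CDS end, so the
    first zero-count CSI and everything beyond it is excluded.
    """
    retained: list[int] = []
    for k, c in enumerate(gene_counts, start=1):
        if c <= 0:
            break
        retained.append(k)
    return retained


@dataclass
class CountMatrix:
    """CSI x sample counts with CPM and rounded-CPM views.

    ``rounded`` holds the ``floor(CPM + 0.5)`` integers that the usage
    statistics consume; ``condition_sums(design, cond)`` gives the
    per-CSI sums of those integers over a condition's replicates.
    """

    csis: list[CSI]
    raw: pd.DataFrame  # index: csi identifier, columns: sample ids
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.raw.values < 0).any():
            raise ValueError("negative raw counts")
        expected = [c.identifier for c in self.csis]
        if list(self.raw.index) != expected:
            raise ValueError("raw matrix index must match CSI identifiers")

    @property
    def samples(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def cpm(self) -> pd.DataFrame:
        return cpm_normalize(self.raw, self.library_sizes)

    @property
    def rounded(self) -> pd.DataFrame:
        return round_cpm(self.cpm)

    def condition_sums(
        self, design: ComparisonDesign, condition: str
    ) -> pd.Series:
        reps = design.samples(condition)
        return self.rounded[reps].sum(axis=1)

    def gene_order(self) -> dict[str, list[int]]:
        """Row positions per gene, ordered by CSI index."""
        per: dict[str, list[tuple[int, int]]] = {}
        for pos, c in enumerate(self.csis):
            per.setdefault(c.gene_id, []).append((c.index, pos))
        return {
            g: [pos for _i, pos in sorted(rows)] for g, rows in per.items()
        }


def make_count_matrix(
    csis: Sequence[CSI],
    sample_alignments: dict[str, str | Iterable[pysam.AlignedSegment]],
    library_sizes: dict[str, int] | None = None,
    **count_kwargs,
) -> CountMatrix:
    """Count every sample over the CSI set and assemble a CountMatrix."""
    csis = list(csis)
    data = {
        sample: count_reads(aln, csis, **count_kwargs)
        for sample, aln in sample_alignments.items()
    }
    raw = pd.DataFrame(data, index=[c.identifier for c in csis])
    sizes = (
        pd.Series(library_sizes)[raw.columns]
        if library_sizes is not None
        else raw.sum(axis=0)
    )
    return CountMatrix(csis, raw, sizes)


def write_matrix(matrix: pd.DataFrame, path: str) -> None:
    """Write a raw-count or normalized expression matrix as TSV."""
    matrix.to_csv(path, sep="\t", index_label="csi_id")
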