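"""RNA-binding-protein motif enrichment around CSI boundaries.

Cleavage sites sit in a dense regulatory neighborhood: the polyA signal
(canonically AAUAAA) lies 10-30 nt upstream of the cleavage position,
and RNA-binding-protein motifs concentrate near it. This module
extracts fixed-width windows around the boundaries of significantly
changed CSIs, builds composition-preserving shuffled backgrounds, scans
IUPAC consensus motifs, and reports per-motif enrichment
(foreground-vs-background Fisher test, BH across motifs) plus a
positional centrality statistic locating where within the window the
hits concentrate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta
from scipy import stats

from .csi_build import CSI
from .diffexp import bh_adjust
from .polya import reverse_complement

logger = logging.getLogger("csikit")

DEFAULT_WINDOW_WIDTH = 100
DEFAULT_SUBWINDOW = 21  # matches the reported -30..-10 concentration span

IUPAC_RNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}


@dataclass(frozen=True)
class MotifRecord:
    """A consensus binding motif: id, protein symbol, IUPAC string."""

    motif_id: str
    protein: str
    consensus: str

    def __post_init__(self) -> None:
        cons = self.consensus.upper().replace("T", "U")
        if not cons:
            raise ValueError(f"motif {self.motif_id}: empty consensus")
        for ch in cons:
            if ch not in IUPAC_RNA:
                raise ValueError(
                    f"motif {self.motif_id}: invalid IUPAC symbol {ch!r}"
                )
        object.__setattr__(self, "consensus", cons)


@dataclass
class BoundaryWindow:
    """Strand-oriented RNA-alphabet window around one CSI boundary.

    ``boundary_index`` is the window position of the boundary base;
    offsets reported downstream are ``hit_start - boundary_index``
    (negative = upstream of the boundary in transcript orientation).
    """

    csi_id: str
    sequence: str
    boundary_index: int
    truncated: bool = False


@dataclass
class MotifEnrichment:
    """Per-motif enrichment result."""

    motif_id: str
    protein: str
    fg_hits: int
    fg_total: int
    bg_hits: int
    bg_total: int
    p: float
    q: float = float("nan")
    position_histogram: dict[int, int] = field(default_factory=dict)
    central_window: tuple[int, int] | None = None
    central_p: float = float("nan")


def read_motif_table(path: str | IO[str]) -> list[MotifRecord]:
    """Read a motif TSV: motif_id, protein symbol, IUPAC consensus."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError("motif table needs 3 columns (id, protein, consensus)")
    return [MotifRecord(r[0], r[1], r[2]) for r in df.itertuples(index=False)]


def extract_boundary_windows(
    csis: Iterable[CSI],
    genome: Fasta | str,
    width: int = DEFAULT_WINDOW_WIDTH,
    anchor: str = "3prime",
) -> list[BoundaryWindow]:
    """Windows of ``width`` nt centered on CSI boundaries.

    ``anchor`` selects the 3' boundary (default), the 5' boundary, or
    ``"both"``. Windows are strand-oriented, transcribed to the RNA
    alphabet (T -> U), and truncated (flagged) at contig edges.
    """
    if isinstance(genome, str):
        genome = Fasta(genome)
    if anchor not in ("3prime", "5prime", "both"):
        raise ValueError(f"unknown anchor {anchor!r}")
    half = width // 2
    windows: list[BoundaryWindow] = []
    for c in csis:
        iv = c.interval
        contig = genome[iv.chrom]
        clen = len(contig)
        anchors = []
        if anchor in ("3prime", "both"):
            anchors.append(iv.end if iv.strand == "+" else iv.begin)
        if anchor in ("5prime", "both"):
            anchors.append(iv.begin if iv.strand == "+" else iv.end)
        for b in anchors:
            lo, hi = max(b - half, 0), min(b + half, clen)
            truncated = (lo, hi) != (b - half, b + half)
            seq = str(contig[lo:hi]).upper()
            if iv.strand == "+":
                boundary_index = b - lo
            else:
                seq = reverse_complement(seq)
                boundary_index = hi - b
            windows.append(
                BoundaryWindow(
                    c.identifier,
                    seq.replace("T", "U"),
                    boundary_index,
                    truncated,
                )
            )
            if truncated:
                logger.warning(
                    "window for %s truncated at contig edge", c.identifier
                )
    return windows


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle preserving the exact dinucleotide multiset."""
    if len(seq) <= 2:
        return seq
    # edge multiset of the doublet graph
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)
    # pick a random "last edge" per non-terminal vertex forming a tree
    # into `last` (rejection sampling; windows are short, retries cheap)
    for _ in range(10_000):
        last_edge = {
            v: edges[v][rng.integers(len(edges[v]))]
            for v in vertices
            if v != last
        }
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - practically unreachable
        raise RuntimeError("dinucleotide shuffle failed to find a valid tree")
    # shuffle remaining edges, append the reserved last edge
    ordered: dict[str, list[str]] = {}
    for v, targets in edges.items():
        pool = list(targets)
        if v != last:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if v != last:
            pool.append(last_edge[v])
        ordered[v] = pool
    # Eulerian walk from the first letter
    out = [seq[0]]
    ptr = {v: 0 for v in ordered}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = ordered[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def shuffle_background(
    sequences: Sequence[str], k: int = 2, seed: int = 0
) -> list[str]:
    """Per-sequence k-let-preserving shuffles for the null background.

    ``k=1`` permutes letters (exact mononucleotide conservation);
    ``k=2`` preserves the dinucleotide multiset exactly (Eulerian-walk
    shuffle). Deterministic for a fixed seed.
    """
    if k not in (1, 2):
        raise ValueError("only k=1 (letter) and k=2 (dinucleotide) supported")
    rng = np.random.default_rng(seed)
    out = []
    for seq in sequences:
        if k == 1:
            letters = list(seq)
            rng.shuffle(letters)
            out.append("".join(letters))
        else:
            out.append(_dinucleotide_shuffle(seq, rng))
    return out


def scan_motif(sequence: str, consensus: str) -> list[int]:
    """All start offsets where the IUPAC consensus matches the sequence.

    The sequence is normalized to the RNA alphabet; positions containing
    characters outside ACGU (e.g. N in the genome) never match anything
    but N-class consensus symbols.
    """
    seq = sequence.upper().replace("T", "U")
    classes = []
    for ch in consensus.upper().replace("T", "U"):
        if ch not in IUPAC_RNA:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in consensus")
        classes.append(IUPAC_RNA[ch])
    m = len(classes)
    hits = []
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in classes[j] for j in range(m)):
            hits.append(i)
    return hits


def enrichment_test(
    fg_hits: int, fg_total: int, bg_hits: int, bg_total: int
) -> float:
    """One-sided Fisher exact p for foreground enrichment.

    Counts are sequences-with-at-least-one-hit (not total hits), which
    keeps per-sequence hit clumping from inflating significance.
    """
    if fg_total == 0:
        raise ValueError("fg_total = 0: untestable")
    if not (0 <= fg_hits <= fg_total and 0 <= bg_hits <= bg_total):
        raise ValueError("hit counts exceed totals")
    table = [[fg_hits, fg_total - fg_hits], [bg_hits, bg_total - bg_hits]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def positional_enrichment(
    hit_offsets: Sequence[int],
    window_width: int,
    subwindow: int = DEFAULT_SUBWINDOW,
    motif_length: int = 1,
) -> tuple[tuple[int, int], float, float]:
    """Locate the offset range where hits concentrate (centrality).

    Slides a ``subwindow``-offset-wide range over the scannable offsets
    (``-width/2 .. width/2 - motif_length``) and binomial-tests the hit
    count inside each range against the uniform expectation
    ``subwindow / n_scannable``. Returns the best range ``(lo, hi)``
    (inclusive offsets relative to the boundary), its Bonferroni-
    adjusted p over the number of ranges tried, and the raw p.
    """
    offsets = np.asarray(hit_offsets, dtype=int)
    if offsets.size == 0:
        raise ValueError("positional_enrichment requires >= 1 hit")
    half = window_width // 2
    lo_off, hi_off = -half, half - motif_length  # inclusive scannable range
    n_scannable = hi_off - lo_off + 1
    sub = min(subwindow, n_scannable)
    p0 = sub / n_scannable
    n = offsets.size
    starts = range(lo_off, hi_off - sub + 2)
    n_windows = len(starts)
    best_start, best_p = lo_off, 1.0
    for s in starts:
        x = int(((offsets >= s) & (offsets < s + sub)).sum())
        p = stats.binomtest(x, n, p0, alternative="greater").pvalue
        if p < best_p:
            best_p, best_start = p, s
    adjusted = min(best_p * n_windows, 1.0)
    return (best_start, best_start + sub - 1), adjusted, float(best_p)


def enrich_motifs(
    foreground: Sequence[BoundaryWindow],
    motifs: Sequence[MotifRecord],
    k: int = 2,
    seed: int = 0,
    background: Sequence[str] | None = None,
    window_width: int = DEFAULT_WINDOW_WIDTH,
    subwindow: int = DEFAULT_SUBWINDOW,
) -> list[MotifEnrichment]:
    """Full enrichment pass over a motif table.

    The background defaults to per-sequence k-let shuffles of the
    foreground windows. Sequence-level hits feed the Fisher enrichment
    test (BH across motifs); pooled foreground hit offsets relative to
    the boundary feed the centrality statistic.
    """
    fg_seqs = [w.sequence for w in foreground]
    bg_seqs = (
        list(background)
        if background is not None
        else shuffle_background(fg_seqs, k=k, seed=seed)
    )
    results: list[MotifEnrichment] = []
    for motif in motifs:
        fg_hit_seqs = 0
        all_offsets: list[int] = []
        for w in foreground:
            hits = scan_motif(w.sequence, motif.consensus)
            if hits:
                fg_hit_seqs += 1
                all_offsets.extend(h - w.boundary_index for h in hits)
        bg_hit_seqs = sum(
            1 for s in bg_seqs if scan_motif(s, motif.consensus)
        )
        p = (
            enrichment_test(fg_hit_seqs, len(fg_seqs), bg_hit_seqs, len(bg_seqs))
            if fg_seqs
            else float("nan")
        )
        res = MotifEnrichment(
            motif.motif_id,
            motif.protein,
            fg_hit_seqs,
            len(fg_seqs),
            bg_hit_seqs,
            len(bg_seqs),
            p,
        )
        if all_offsets:
            hist: dict[int, int] = {}
            for o in all_offsets:
                hist[o] = hist.get(o, 0) + 1
            res.position_histogram = hist
            res.central_window, res.central_p, _ = positional_enrichment(
                all_offsets,
                window_width,
                subwindow,
                motif_length=len(motif.consensus),
            )
        results.append(res)
    ps = [r.p for r in results if not np.isnan(r.p)]
    if ps:
        qs = iter(bh_adjust(ps))
        for r in results:
            if not np.isnan(r.p):
                r.q = float(next(qs))
    return results


def results_frame(results: Iterable[MotifEnrichment]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "motif_id": r.motif_id,
                "protein": r.protein,
                "fg_hits": r.fg_hits,
                "fg_total": r.fg_total,
                "bg_hits": r.bg_hits,
                "bg_total": r.bg_total,
                "p": r.p,
                "q": r.q,
                "central_lo": r.central_window[0] if r.central_window else None,
                "central_hi": r.central_window[1] if r.central_window else None,
                "central_p": r.central_p,
            }
        )
    return pd.DataFrame(rows)


def write_fasta(sequences: Sequence[str], path: str, prefix: str = "seq") -> None:
    """Export windows as FASTA for external motif suites."""
    with open(path, "w") as fh:
        for i, seq in enumerate(sequences):
            fh.write(f">{prefix}_{i}\n{seq}\n")
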