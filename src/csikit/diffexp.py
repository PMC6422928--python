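"""Per-CSI differential usage statistics.

Two statistics are computed per cleavage-site interval between two
conditions A and B:

* PAIRWISE — an equal-variance two-sample t-test on the per-replicate
  rounded-CPM vectors of a single CSI. Sensitive to overall gene
  expression change as well as usage change.
* WITHIN — a usage test that removes gene-level expression: each CSI's
  usage fraction psi_i = A_i / sum_j A_j (summing rounded CPM over the
  condition's replicates and the gene's retained CSIs) is compared
  between conditions with a two-sided Fisher exact test on the table
  [[A_i, sum A - A_i], [B_i, sum B - B_i]]; delta-psi = psi_A - psi_B.

p-values are Benjamini-Hochberg corrected per method across all tested
CSIs of the comparison. Genes or CSIs that cannot be tested carry a
machine-readable reason code instead of being silently dropped.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .csi_build import CSI
from .quantify import ComparisonDesign, CountMatrix, contiguity_filter

logger = logging.getLogger("csikit")

# reason codes for untested CSIs
REASON_OK = ""
REASON_NOT_CONTIGUOUS = "not_contiguous"
REASON_ZERO_TOTAL = "zero_gene_total"
REASON_SINGLE_CSI = "single_csi"
REASON_TOO_FEW_REPS = "insufficient_replicates"

RESULT_COLUMNS = [
    "csi_id",
    "gene_id",
    "symbol",
    "method",
    "psi_A",
    "psi_B",
    "delta_psi",
    "p_value",
    "q_value",
    "reason",
]


def pairwise_test(
    v1: Sequence[float], v2: Sequence[float], equal_var: bool = True
) -> float:
    """Two-sided two-sample t-test p-value for one CSI.

    ``v1``/``v2`` are the per-replicate (rounded) CPM values of the CSI
    in conditions 1 and 2. Student's pooled-variance flavor by default;
    Welch via ``equal_var=False``. Requires >= 2 replicates per side.
    When both vectors are constant the statistic is undefined: p = 1 if
    they are constant and equal, 0 if constant and different.
    """
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("pairwise_test requires >= 2 replicates per side")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def psi(condition_sums: Sequence[float]) -> np.ndarray:
    """Usage fractions of one gene's CSIs within one condition.

    psi_i = A_i / sum_j A_j over the gene's retained CSIs; sums to 1.
    A zero gene total is an error (the caller excludes such genes with
    a reason code).
    """
    a = np.asarray(condition_sums, dtype=float)
    if (a < 0).any():
        raise ValueError("negative condition sums")
    total = a.sum()
    if total <= 0:
        raise ValueError("zero gene total; gene must be excluded")
    return a / total


def delta_psi(psi_a: Sequence[float], psi_b: Sequence[float]) -> np.ndarray:
    """Between-condition usage difference, psi_A - psi_B, in [-1, 1]."""
    pa = np.asarray(psi_a, dtype=float)
    pb = np.asarray(psi_b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("psi vectors must be aligned")
    return pa - pb


def within_test(
    a_i: int, sum_a: int, b_i: int, sum_b: int, alternative: str = "two-sided"
) -> float:
    """Fisher exact p for differential usage of one CSI.

    Contingency table: reads in the CSI vs reads in the rest of the
    gene, per condition — ``[[a_i, sum_a - a_i], [b_i, sum_b - b_i]]``.
    """
    if not (0 <= a_i <= sum_a and 0 <= b_i <= sum_b):
        raise ValueError("require 0 <= a_i <= sum_a and 0 <= b_i <= sum_b")
    if sum_a == 0 or sum_b == 0:
        raise ValueError("zero condition total; CSI untestable")
    table = [[a_i, sum_a - a_i], [b_i, sum_b - b_i]]
    return float(stats.fisher_exact(table, alternative=alternative)[1])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _retained_rows(matrix: CountMatrix) -> tuple[dict[str, list[int]], dict[int, str]]:
    """Apply the contiguity filter; map gene -> retained row positions."""
    pooled = matrix.raw.sum(axis=1).to_numpy()
    retained: dict[str, list[int]] = {}
    excluded: dict[int, str] = {}
    for gene, rows in matrix.gene_order().items():
        keep = contiguity_filter([pooled[r] for r in rows])
        retained[gene] = rows[: len(keep)]
        for r in rows[len(keep):]:
            excluded[r] = REASON_NOT_CONTIGUOUS
    return retained, excluded


def _result_row(csi: CSI, method: str, **kw) -> dict:
    row = {
        "csi_id": csi.identifier,
        "gene_id": csi.gene_id,
        "symbol": csi.symbol,
        "method": method,
        "psi_A": np.nan,
        "psi_B": np.nan,
        "delta_psi": np.nan,
        "p_value": np.nan,
        "q_value": np.nan,
        "reason": REASON_OK,
    }
    row.update(kw)
    return row


def run_within(
    matrix: CountMatrix,
    design: ComparisonDesign,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """WITHIN usage testing for every gene of a comparison.

    Single-CSI genes (psi identically 1) and genes with a zero rounded
    total in either condition are excluded with reason codes. q-values
    are BH-adjusted across all tested CSIs.
    """
    retained, excluded = _retained_rows(matrix)
    sums_a = matrix.condition_sums(design, design.condition_1).to_numpy()
    sums_b = matrix.condition_sums(design, design.condition_2).to_numpy()
    rows: list[dict] = []
    for pos, reason in excluded.items():
        rows.append(_result_row(matrix.csis[pos], "WITHIN", reason=reason))
    for gene, positions in retained.items():
        csis = [matrix.csis[p] for p in positions]
        if len(positions) == 0:
            continue
        if len(positions) == 1:
            rows.append(
                _result_row(csis[0], "WITHIN", reason=REASON_SINGLE_CSI)
            )
            continue
        a = sums_a[positions].astype(int)
        b = sums_b[positions].astype(int)
        if a.sum() == 0 or b.sum() == 0:
            for c in csis:
                rows.append(
                    _result_row(c, "WITHIN", reason=REASON_ZERO_TOTAL)
                )
            continue
        psi_a, psi_b = psi(a), psi(b)
        dps = delta_psi(psi_a, psi_b)
        for k, c in enumerate(csis):
            p = within_test(
                int(a[k]), int(a.sum()), int(b[k]), int(b.sum()), alternative
            )
            rows.append(
                _result_row(
                    c,
                    "WITHIN",
                    psi_A=psi_a[k],
                    psi_B=psi_b[k],
                    delta_psi=dps[k],
                    p_value=p,
                )
            )
    return _finalize(rows)


def run_pairwise(
    matrix: CountMatrix,
    design: ComparisonDesign,
    equal_var: bool = True,
    use_rounded: bool = True,
) -> pd.DataFrame:
    """PAIRWISE t-testing of every retained CSI of a comparison.

    Uses the rounded per-replicate CPM vectors by default (``use_rounded
    =False`` switches to raw CPM). Requires >= 2 replicates per
    condition; otherwise every CSI carries the insufficient-replicates
    reason code. psi columns are filled for context where the gene
    totals permit.
    """
    retained, excluded = _retained_rows(matrix)
    values = matrix.rounded if use_rounded else matrix.cpm
    reps_1 = design.samples(design.condition_1)
    reps_2 = design.samples(design.condition_2)
    sums_a = matrix.condition_sums(design, design.condition_1).to_numpy()
    sums_b = matrix.condition_sums(design, design.condition_2).to_numpy()
    rows: list[dict] = []
    for pos, reason in excluded.items():
        rows.append(_result_row(matrix.csis[pos], "PAIRWISE", reason=reason))
    too_few = len(reps_1) < 2 or len(reps_2) < 2
    for gene, positions in retained.items():
        csis = [matrix.csis[p] for p in positions]
        a_tot, b_tot = sums_a[positions].sum(), sums_b[positions].sum()
        psi_a = (
            psi(sums_a[positions]) if a_tot > 0 else [np.nan] * len(positions)
        )
        psi_b = (
            psi(sums_b[positions]) if b_tot > 0 else [np.nan] * len(positions)
        )
        for k, (pos, c) in enumerate(zip(positions, csis)):
            if too_few:
                rows.append(
                    _result_row(c, "PAIRWISE", reason=REASON_TOO_FEW_REPS)
                )
                continue
            v1 = values.iloc[pos][reps_1].to_numpy(dtype=float)
            v2 = values.iloc[pos][reps_2].to_numpy(dtype=float)
            p = pairwise_test(v1, v2, equal_var=equal_var)
            dp = (
                psi_a[k] - psi_b[k]
                if a_tot > 0 and b_tot > 0
                else np.nan
            )
            rows.append(
                _result_row(
                    c,
                    "PAIRWISE",
                    psi_A=psi_a[k],
                    psi_B=psi_b[k],
                    delta_psi=dp,
                    p_value=p,
                )
            )
    return _finalize(rows)


def _finalize(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    tested = df["p_value"].notna()
    if tested.any():
        df.loc[tested, "q_value"] = bh_adjust(df.loc[tested, "p_value"])
    return df.sort_values(["gene_id", "csi_id"]).reset_index(drop=True)


def run_tests(
    matrix: CountMatrix,
    design: ComparisonDesign,
    method: str = "both",
    **kwargs,
) -> pd.DataFrame:
    """Run WITHIN, PAIRWISE, or both; concatenated result frame."""
    frames = []
    if method in ("within", "both"):
        frames.append(run_within(matrix, design))
    if method in ("pairwise", "both"):
        frames.append(run_pairwise(matrix, design, **kwargs))
    if not frames:
        raise ValueError(f"unknown method {method!r}")
    return pd.concat(frames, ignore_index=True)


def write_results(results: pd.DataFrame, path: str) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")


def export_dexseq(
    raw: pd.DataFrame,
    csis: Sequence[CSI],
    out_dir: str,
    prefix: str = "csi",
) -> tuple[list[str], str]:
    """Export counts + flattened annotation for exon-usage GLM tools.

    CSIs behave like cassette exons of the 3'UTR, so their counts can
    be fed to a negative-binomial exon-usage model. Writes one
    two-column count file per sample with features keyed
    ``gene_id:csi_index`` and a flattened GFF with one aggregate-gene
    line per gene and one exonic-part line per CSI. The GLM itself is
    not run here.

    Returns (count file paths, gff path).
    """
    os.makedirs(out_dir, exist_ok=True)
    keys = [f"{c.gene_id}:{c.index:03d}" for c in csis]
    count_paths = []
    for sample in raw.columns:
        path = os.path.join(out_dir, f"{prefix}_{sample}.counts.txt")
        with open(path, "w") as fh:
            for key, value in zip(keys, raw[sample].astype(int)):
                fh.write(f"{key}\t{value}\n")
        count_paths.append(path)

    gff_path = os.path.join(out_dir, f"{prefix}_flattened.gff")
    by_gene: dict[str, list[CSI]] = {}
    for c in csis:
        by_gene.setdefault(c.gene_id, []).append(c)
    with open(gff_path, "w") as fh:
        for gene in sorted(by_gene):
            parts = sorted(by_gene[gene], key=lambda c: c.index)
            begin = min(c.interval.begin for c in parts)
            end = max(c.interval.end for c in parts)
            chrom = parts[0].interval.chrom
            strand = parts[0].interval.strand
            fh.write(
                f"{chrom}\tcsikit\taggregate_gene\t{begin + 1}\t{end}\t.\t"
                f'{strand}\t.\tgene_id "{gene}"\n'
            )
            for c in parts:
                fh.write(
                    f"{chrom}\tcsikit\texonic_part\t{c.interval.begin + 1}\t"
                    f"{c.interval.end}\t.\t{strand}\t.\t"
                    f'gene_id "{gene}"; exonic_part_number "{c.index:03d}"\n'
                )
    return count_paths, gff_path
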