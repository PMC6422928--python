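"""Usage statistics: t-test, psi, Fisher exact, BH, and orchestration."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from csikit.annotation import GenomicInterval
from csikit.csi_build import CSI
from csikit.diffexp import (
    REASON_NOT_CONTIGUOUS,
    REASON_SINGLE_CSI,
    REASON_TOO_FEW_REPS,
    REASON_ZERO_TOTAL,
    bh_adjust,
    delta_psi,
    export_dexseq,
    pairwise_test,
    psi,
    run_pairwise,
    run_within,
    within_test,
)
from csikit.quantify import ComparisonDesign, CountMatrix


def fisher_oracle(a, sum_a, b, sum_b):
    """Two-sided Fisher p by exact-rational hypergeometric enumeration.

    Conditions on all margins of [[a, sum_a - a], [b, sum_b - b]] and
    sums P(k) over every table at least as extreme (pmf <= observed).
    Pure integer arithmetic; independent of scipy.
    """
    n = sum_a + sum_b
    col1 = a + b

    def pmf(k):
        return Fraction(
            math.comb(sum_a, k) * math.comb(sum_b, col1 - k),
            math.comb(n, col1),
        )

    k_lo, k_hi = max(0, col1 - sum_b), min(col1, sum_a)
    p_obs = pmf(a)
    return float(sum(pmf(k) for k in range(k_lo, k_hi + 1) if pmf(k) <= p_obs))


def bh_oracle(p):
    """Direct step-up: q_(i) = min_{j >= i} p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestPairwise:
    def test_identical_vectors_p_one(self):
        assert pairwise_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_degenerate_constant_equal(self):
        assert pairwise_test([10, 10], [10, 10]) == 1.0

    def test_degenerate_constant_different(self):
        assert pairwise_test([10, 10], [20, 20]) == 0.0

    def test_matches_closed_form_t(self):
        """Pooled-variance textbook formula computed by hand in the test."""
        v1, v2 = [5, 6, 7], [9, 10, 11]
        m, n = len(v1), len(v2)
        x1, x2 = np.mean(v1), np.mean(v2)
        s2 = (np.var(v1, ddof=1) * (m - 1) + np.var(v2, ddof=1) * (n - 1)) / (
            m + n - 2
        )
        t = (x1 - x2) / math.sqrt(s2 * (1 / m + 1 / n))
        assert t == pytest.approx(-4 / math.sqrt(2 / 3))
        from scipy.stats import t as tdist

        p_closed = 2 * tdist.sf(abs(t), m + n - 2)
        assert pairwise_test(v1, v2) == pytest.approx(p_closed, rel=1e-12)

    def test_too_few_replicates_raises(self):
        with pytest.raises(ValueError):
            pairwise_test([1], [2, 3])


class TestPsi:
    def test_arithmetic(self):
        assert psi([30, 10]).tolist() == [0.75, 0.25]

    def test_single_csi(self):
        assert psi([7]).tolist() == [1.0]

    def test_zero_component(self):
        assert psi([0, 5]).tolist() == [0.0, 1.0]

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            psi([0, 0])

    def test_sums_to_one_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            v = rng.integers(0, 50, size=rng.integers(1, 9))
            if v.sum() == 0:
                v[0] = 1
            assert psi(v).sum() == pytest.approx(1.0, abs=1e-12)


class TestDeltaPsi:
    def test_example(self):
        assert delta_psi([0.75, 0.25], [0.5, 0.5]).tolist() == [0.25, -0.25]

    def test_identical_zero(self):
        assert delta_psi([0.4, 0.6], [0.4, 0.6]).tolist() == [0.0, 0.0]

    def test_conservation_sums_to_zero(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a = psi(rng.integers(1, 50, size=5))
            b = psi(rng.integers(1, 50, size=5))
            assert delta_psi(a, b).sum() == pytest.approx(0.0, abs=1e-12)


class TestWithin:
    def test_symmetric_table(self):
        assert within_test(1, 2, 1, 2) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "a,sa,b,sb",
        [(10, 20, 2, 20), (0, 10, 10, 10), (5, 9, 3, 17), (1, 40, 39, 40)],
    )
    def test_matches_enumeration_oracle(self, a, sa, b, sb):
        assert within_test(a, sa, b, sb) == pytest.approx(
            fisher_oracle(a, sa, b, sb), abs=1e-12
        )

    def test_zero_condition_total_untestable(self):
        with pytest.raises(ValueError):
            within_test(0, 0, 3, 10)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            within_test(11, 10, 0, 10)


class TestBH:
    def test_derived_step_up_example(self):
        # computed by the direct step-up rule: q_(i) = min_j>=i p_j n/j
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_adjust([0.3]).tolist() == [0.3]

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            p = rng.random(size=int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def toy_matrix(counts_by_gene, samples):
    """Build a CountMatrix from {gene: [[counts per sample] per csi]}."""
    csis, rows = [], []
    for gene, gene_counts in counts_by_gene.items():
        start = 100
        for k, per_sample in enumerate(gene_counts, start=1):
            iv = GenomicInterval("chr1", start + 100 * (k - 1), start + 100 * k, "+")
            csis.append(CSI(gene, gene, k, iv, start))
            rows.append(per_sample)
    raw = pd.DataFrame(rows, index=[c.identifier for c in csis], columns=samples)
    # library size 1e6 => CPM == raw counts; statistics see the counts
    sizes = pd.Series({s: 1_000_000 for s in samples})
    return CountMatrix(csis, raw, sizes)


DESIGN = ComparisonDesign(
    "A", "B", {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
)


class TestRunWithin:
    def test_reason_codes(self):
        matrix = toy_matrix(
            {
                "single": [[5, 5, 5, 5]],
                "gap": [[5, 5, 5, 5], [0, 0, 0, 0], [4, 4, 4, 4]],
                "zeroB": [[5, 5, 0, 0], [5, 5, 0, 0]],
            },
            ["a1", "a2", "b1", "b2"],
        )
        res = run_within(matrix, DESIGN)
        by_id = res.set_index("csi_id")
        assert by_id.loc["single:100_100-200", "reason"] == REASON_SINGLE_CSI
        gap = res[res.gene_id == "gap"].sort_values("csi_id")
        assert (
            by_id.loc["gap:100_200-300", "reason"] == REASON_NOT_CONTIGUOUS
        )
        assert (
            by_id.loc["gap:100_300-400", "reason"] == REASON_NOT_CONTIGUOUS
        )
        assert by_id.loc["gap:100_100-200", "reason"] == REASON_SINGLE_CSI
        assert (by_id.loc[
            ["zeroB:100_100-200", "zeroB:100_200-300"], "reason"
        ] == REASON_ZERO_TOTAL).all()

    def test_psi_sums_to_one_per_gene_condition(self):
        rng = np.random.default_rng(12)
        counts = {
            f"g{i}": rng.integers(1, 80, size=(4, 4)).tolist()
            for i in range(10)
        }
        res = run_within(toy_matrix(counts, ["a1", "a2", "b1", "b2"]), DESIGN)
        tested = res[res.reason == ""]
        sums = tested.groupby("gene_id")[["psi_A", "psi_B"]].sum()
        assert np.allclose(sums, 1.0)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(13)
        counts = {
            f"g{i}": rng.integers(0, 60, size=(3, 4)).tolist()
            for i in range(12)
        }
        res = run_within(toy_matrix(counts, ["a1", "a2", "b1", "b2"]), DESIGN)
        tested = res.dropna(subset=["p_value"])
        assert (tested.q_value >= tested.p_value - 1e-12).all()
        assert (tested.q_value <= 1.0).all()


class TestRunPairwise:
    def test_insufficient_replicates_reason(self):
        design = ComparisonDesign("A", "B", {"a1": "A", "b1": "B", "b2": "B"})
        matrix = toy_matrix({"g": [[5, 9, 9], [5, 2, 3]]}, ["a1", "b1", "b2"])
        res = run_pairwise(matrix, design)
        assert (res.reason == REASON_TOO_FEW_REPS).all()

    def test_direction_agrees_with_within_for_single_changed_csi(self):
        # gene expression flat; only CSI_1 usage shifts up in A
        matrix = toy_matrix(
            {"g": [[60, 58, 30, 32], [20, 22, 50, 48]]},
            ["a1", "a2", "b1", "b2"],
        )
        within = run_within(matrix, DESIGN).set_index("csi_id")
        pairwise = run_pairwise(matrix, DESIGN).set_index("csi_id")
        for csi_id in within.index:
            mean_diff = pairwise.loc[csi_id, "psi_A"] - pairwise.loc[csi_id, "psi_B"]
            assert np.sign(within.loc[csi_id, "delta_psi"]) == np.sign(mean_diff)


class TestDexseqExport:
    def test_count_files_and_round_trip(self, tmp_path):
        matrix = toy_matrix(
            {"g1": [[3, 1, 0, 2], [4, 4, 4, 4]]}, ["a1", "a2", "b1", "b2"]
        )
        paths, gff = export_dexseq(matrix.raw, matrix.csis, str(tmp_path))
        assert len(paths) == 4
        lines = open(paths[0]).read().splitlines()
        assert lines == ["g1:001\t3", "g1:002\t4"]
        for line in lines:
            key = line.split("\t")[0]
            gene, idx = key.rsplit(":", 1)
            assert gene == "g1" and int(idx) in (1, 2)
        gff_lines = open(gff).read().splitlines()
        assert sum("aggregate_gene" in l for l in gff_lines) == 1
        assert sum("exonic_part" in l for l in gff_lines) == 2

    def test_empty_csi_set(self, tmp_path):
        raw = pd.DataFrame(columns=["s1"], dtype=int)
        paths, gff = export_dexseq(raw, [], str(tmp_path))
        assert open(paths[0]).read() == ""
        assert open(gff).read() == ""
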