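"""Codon counting, RSCU, CUP classes, CAM, interval summary, clustering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitocup.codon_usage import (
    CUP_CLASSES,
    CodonCountTable,
    cam,
    classify_cup,
    cluster_rscu,
    count_codons,
    interval_summary,
    mean_rscu,
    round_half_up,
    rscu,
    rscu_matrix,
)
from mitocup.genetic_code import CODON_ORDER, load_code

from conftest import make_cds, random_count_table


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_rscu(table: CodonCountTable, code) -> dict[str, float]:
    """RSCU straight from the definition, grouping codons by translation."""
    groups: dict[str, list[str]] = {}
    for c in CODON_ORDER:
        groups.setdefault(code.codon_to_aa[c], []).append(c)
    out = {}
    for codons in groups.values():
        n_total = sum(table.counts[c] for c in codons)
        for c in codons:
            out[c] = (
                len(codons) * table.counts[c] / n_total
                if n_total else math.nan
            )
    return out


def brute_force_agglomerate(points: np.ndarray):
    """Average-linkage agglomeration by full distance recomputation.

    Returns the merge heights and the partition (frozenset of frozensets
    of leaf indices) after each merge.
    """
    clusters = [frozenset([i]) for i in range(len(points))]
    heights, partitions = [], []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean(
                    [
                        np.linalg.norm(points[a] - points[b])
                        for a in clusters[i]
                        for b in clusters[j]
                    ]
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        heights.append(d)
        partitions.append(frozenset(clusters))
    return heights, partitions


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

class TestCountCodons:
    def test_counts_from_toy_cds(self, mito_code):
        table = count_codons(make_cds("ATGAAATAA"), mito_code)
        assert table.counts["AUG"] == 1
        assert table.counts["AAA"] == 1
        assert table.counts["UAA"] == 1
        assert table.total == 3

    def test_concatenation_adds(self, mito_code):
        a = count_codons(make_cds("ATGAAATAA", gene="ND1"), mito_code)
        b = count_codons(make_cds("ATGCCCTAA", gene="ND2"), mito_code)
        merged = a + b
        assert merged.counts["AUG"] == 2 and merged.counts["CCC"] == 1
        assert merged.total == a.total + b.total

    def test_matches_sliding_triplet_oracle(self, mito_code):
        rng = np.random.default_rng(5)
        sense = [c for c in CODON_ORDER if mito_code.codon_to_aa[c] != "*"]
        codons = ["AUG"] + list(rng.choice(sense, size=200)) + ["UAA"]
        seq = "".join(codons).replace("U", "T")
        table = count_codons(make_cds(seq), mito_code)
        # oracle: count triplets directly
        triplets = [seq[i: i + 3].replace("T", "U") for i in range(0, len(seq), 3)]
        for c in CODON_ORDER:
            assert table.counts[c] == triplets.count(c)


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------

class TestRSCU:
    def test_uniform_usage_gives_unity(self, mito_code):
        table = CodonCountTable("u", {c: 3 for c in CODON_ORDER})
        values = rscu(table, mito_code)
        for c in CODON_ORDER:
            assert values.rscu[c] == pytest.approx(1.0)

    def test_met_family_direct_evaluation(self, mito_code):
        table = CodonCountTable("m", {"AUA": 3, "AUG": 1})
        values = rscu(table, mito_code)
        assert values.rscu["AUA"] == pytest.approx(1.5)
        assert values.rscu["AUG"] == pytest.approx(0.5)

    def test_all_mass_on_one_codon(self, mito_code):
        table = CodonCountTable("x", {"GCA": 9})
        values = rscu(table, mito_code)
        assert values.rscu["GCA"] == pytest.approx(4.0)
        for sibling in ("GCU", "GCC", "GCG"):
            assert values.rscu[sibling] == 0.0
            assert sibling in cam(values)

    def test_family_absent_flagged_not_zero(self, mito_code):
        table = CodonCountTable("x", {"GCA": 9})
        values = rscu(table, mito_code)
        assert math.isnan(values.rscu["UGU"])  # no Cys observed
        assert "UGU" in values.family_absent
        assert "UGU" in cam(values)
        assert "UGU" not in cam(values, include_unobserved_families=False)

    def test_stop_pseudo_family_normalizes_to_four(self, mito_code):
        table = CodonCountTable("s", {"UAA": 3, "AGA": 1})
        values = rscu(table, mito_code)
        assert values.rscu["UAA"] == pytest.approx(3.0)
        assert values.rscu["AGA"] == pytest.approx(1.0)

    def test_duplication_invariance(self, mito_code):
        rng = np.random.default_rng(3)
        t = random_count_table(rng)
        doubled = CodonCountTable("d", {c: 2 * n for c, n in t.counts.items()})
        a, b = rscu(t, mito_code), rscu(doubled, mito_code)
        for c in CODON_ORDER:
            if not math.isnan(a.rscu[c]):
                assert a.rscu[c] == pytest.approx(b.rscu[c])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_family_sums_equal_family_size(self, seed):
        code = load_code("vertebrate-mito")
        table = random_count_table(np.random.default_rng(seed))
        values = rscu(table, code)
        for fam in code.families:
            total = sum(table.counts[c] for c in fam.codons)
            if total > 0:
                s = sum(values.rscu[c] for c in fam.codons)
                assert s == pytest.approx(fam.degeneracy, abs=1e-12)

    def test_split_sixfold_flag(self, mito_code):
        table = CodonCountTable("l", {"CUA": 2, "CUG": 2, "UUA": 4})
        strict = rscu(table, mito_code)
        split = rscu(table, mito_code, split_sixfold=True)
        assert strict.rscu["UUA"] == pytest.approx(6 * 4 / 8)
        assert split.rscu["UUA"] == pytest.approx(2.0)  # UUR two-fold box
        assert split.rscu["CUA"] == pytest.approx(2.0)  # CUN box: 4 * 2/4


class TestMeanRSCU:
    def test_idempotent_on_identical_tables(self, mito_code):
        t = rscu(CodonCountTable("g", {"AUA": 3, "AUG": 1, "GCA": 2}), mito_code)
        m = mean_rscu([t, t, t])
        for c in CODON_ORDER:
            if not math.isnan(t.rscu[c]):
                assert m.rscu[c] == pytest.approx(t.rscu[c])

    def test_simple_average(self, mito_code):
        a = rscu(CodonCountTable("g", {"AUA": 4}), mito_code)
        b = rscu(CodonCountTable("g", {"AUG": 4}), mito_code)
        m = mean_rscu([a, b])
        assert m.rscu["AUA"] == pytest.approx(1.0)  # (2 + 0) / 2

    def test_population_mean_near_single_pool(self, mito_code, full_population):
        """Mean RSCU across near-identical individuals tracks the pooled
        (single-ancestor) RSCU closely."""
        code = mito_code
        gene = "ND5"
        tables, pooled = [], None
        for rec in full_population.records:
            ct = count_codons(rec.gene(gene), code)
            tables.append(rscu(ct, code))
            pooled = ct if pooled is None else pooled + ct
        m = mean_rscu(tables, gene)
        pool_values = rscu(pooled, code)
        for c in CODON_ORDER:
            if not math.isnan(m.rscu[c]) and not math.isnan(pool_values.rscu[c]):
                assert m.rscu[c] == pytest.approx(pool_values.rscu[c], abs=0.1)


# ---------------------------------------------------------------------------
# CUP classes / interval summary
# ---------------------------------------------------------------------------

class TestCUPClassification:
    @pytest.mark.parametrize(
        "value,cls",
        [(0.0, "unused"), (0.3, "under"), (0.6, "unbiased"), (1.0, "unbiased"),
         (1.6, "unbiased"), (1.61, "over"), (math.nan, "unused")],
    )
    def test_threshold_boundaries(self, value, cls):
        assert classify_cup(value) == cls

    def test_classes_partition(self, mito_code):
        rng = np.random.default_rng(9)
        values = rscu(random_count_table(rng), mito_code)
        for c in values.codons:
            assert values.cup_class[c] in CUP_CLASSES


class TestIntervalSummary:
    def test_all_uniform_usage_is_all_unbiased(self, mito_code):
        tables = [
            rscu(CodonCountTable(f"g{i}", {c: 5 for c in CODON_ORDER}), mito_code)
            for i in range(13)
        ]
        summary = interval_summary(tables)
        assert summary.grand_total == 13 * 64
        assert summary.row_totals["unbiased"] == 832
        assert summary.row_percentage("unbiased") == 100.0

    def test_single_gene_extreme_bias(self, mito_code):
        counts = {fam.codons[0]: 10 for fam in mito_code.families}
        counts["UAA"] = 1
        t = rscu(CodonCountTable("g", counts), mito_code)
        summary = interval_summary([t])
        assert summary.row_totals["under"] == 0
        assert summary.row_totals["unbiased"] == 0
        assert summary.row_totals["unused"] + summary.row_totals["over"] == 64

    def test_layout_matches_printed_convention(self, mito_code):
        t = rscu(CodonCountTable("g", {c: 5 for c in CODON_ORDER}), mito_code)
        frame = interval_summary([t]).as_frame()
        assert list(frame.columns) == [
            "cup_class", "rscu_interval", "A", "G", "U", "C", "total", "percentage",
        ]
        assert list(frame["rscu_interval"]) == ["0", "0~0.6", "0.6~1.6", ">1.6"]

    def test_round_half_up(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(63.815, 2) == 63.82


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class TestClusterRSCU:
    def _tables_from_matrix(self, mat, mito_code):
        out = []
        for i, row in enumerate(mat):
            counts = {c: int(v) for c, v in zip(CODON_ORDER, row)}
            out.append(rscu(CodonCountTable(f"g{i}", counts), mito_code))
        return out

    def test_identical_vectors_merge_first_at_zero(self, mito_code):
        rng = np.random.default_rng(2)
        base = rng.integers(1, 30, size=64)
        tables = self._tables_from_matrix([base, base, base * 3 + 40], mito_code)
        result = cluster_rscu(tables)
        assert result.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert set(result.linkage_matrix[0, :2]) <= {0.0, 1.0}

    def test_outlier_joins_last(self, mito_code):
        rng = np.random.default_rng(4)
        a = rng.integers(10, 20, size=64)
        tables = self._tables_from_matrix([a, a + 1, a * 0 + 1], mito_code)
        result = cluster_rscu(tables)
        labels = result.cut(2)
        assert labels["g0"] == labels["g1"] != labels["g2"]

    def test_matches_brute_force_agglomeration(self, mito_code):
        rng = np.random.default_rng(7)
        tables = self._tables_from_matrix(rng.integers(1, 40, size=(6, 64)), mito_code)
        result = cluster_rscu(tables)
        points = rscu_matrix(tables).to_numpy().T
        heights, partitions = brute_force_agglomerate(points)
        assert np.allclose(result.linkage_matrix[:, 2], heights)
        for k, partition in zip(range(len(tables) - 1, 0, -1), partitions):
            labels = result.cut(k)
            ours = frozenset(
                frozenset(i for i, t in enumerate(tables) if labels[t.unit_id] == c)
                for c in set(labels.values())
            )
            assert ours == partition

    def test_k_larger_than_units_rejected(self, mito_code):
        rng = np.random.default_rng(1)
        tables = self._tables_from_matrix(rng.integers(1, 9, size=(3, 64)), mito_code)
        with pytest.raises(ValueError):
            cluster_rscu(tables).cut(5)

    def test_newick_contains_all_genes(self, mito_code):
        rng = np.random.default_rng(8)
        tables = self._tables_from_matrix(rng.integers(1, 9, size=(4, 64)), mito_code)
        tree = cluster_rscu(tables).newick()
        assert tree.endswith(";")
        for t in tables:
            assert t.unit_id in tree
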