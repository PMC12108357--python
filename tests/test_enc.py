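"""GC3, Wright's ENC, and the ENC-plot standard curve."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitocup.codon_usage import CodonCountTable
from mitocup.enc_analysis import (
    ENCError,
    enc,
    enc_plot_points,
    expected_enc,
    gc3,
    standard_curve,
)
from mitocup.genetic_code import CODON_ORDER, load_code

from conftest import random_count_table


def brute_force_family_F(table, code):
    """F per family from an expanded codon list, straight from Wright's
    definition: F = (n * sum(p_j^2) - 1) / (n - 1)."""
    expanded = [c for c in CODON_ORDER for _ in range(table.counts[c])]
    out = {}
    for fam in code.families:
        members = [c for c in expanded if c in fam.codons]
        n = len(members)
        if n < 2:
            continue
        p2 = sum((members.count(c) / n) ** 2 for c in fam.codons)
        F = (n * p2 - 1) / (n - 1)
        if F != 0:
            out[fam.amino_acid] = F
    return out


class TestGC3:
    def test_all_a_ending(self, mito_code):
        assert gc3(CodonCountTable("g", {"AAA": 10}), mito_code) == 0.0

    def test_half_gc(self, mito_code):
        t = CodonCountTable("g", {"GCG": 5, "GCA": 5})
        assert gc3(t, mito_code) == pytest.approx(0.5)

    def test_stop_codons_excluded_by_default(self, mito_code):
        t = CodonCountTable("g", {"AAA": 1, "UAG": 100})
        assert gc3(t, mito_code) == 0.0
        assert gc3(t, mito_code, include_stops=True) == pytest.approx(100 / 101)

    def test_matches_expansion_oracle(self, mito_code):
        rng = np.random.default_rng(12)
        t = random_count_table(rng)
        expanded = [
            c for c in CODON_ORDER
            if mito_code.codon_to_aa[c] != "*"
            for _ in range(t.counts[c])
        ]
        oracle = sum(1 for c in expanded if c[2] in "GC") / len(expanded)
        assert gc3(t, mito_code) == pytest.approx(oracle)

    def test_empty_table_rejected(self, mito_code):
        with pytest.raises(ENCError):
            gc3(CodonCountTable("g", {}), mito_code)


class TestExpectedENC:
    @pytest.mark.parametrize("x,value", [(0.0, 31.0), (0.5, 60.5), (1.0, 32.0)])
    def test_anchor_evaluations(self, x, value):
        assert expected_enc(x) == pytest.approx(value, abs=1e-12)

    @given(st.floats(0, 1))
    def test_symmetry_about_half(self, x):
        assert expected_enc(x) - x == pytest.approx(expected_enc(1 - x) - (1 - x))

    def test_peak_near_half(self):
        # the value at GC3 = 0.5 is exactly 60.5; the linear +GC3 term
        # nudges the true maximum just above it, at GC3 slightly > 0.5
        assert expected_enc(0.5) == 60.5
        xs = np.linspace(0, 1, 1001)
        ys = [expected_enc(x) for x in xs]
        assert max(ys) == pytest.approx(60.5, abs=2e-3)
        assert abs(xs[int(np.argmax(ys))] - 0.5) < 0.02

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expected_enc(1.5)


class TestStandardCurve:
    def test_default_grid_has_1001_points(self):
        curve = standard_curve()
        assert len(curve) == 1001
        assert curve["gc3"].iloc[0] == 0.0 and curve["gc3"].iloc[-1] == 1.0

    def test_coarse_grid_values(self):
        curve = standard_curve(0.5)
        assert list(curve["gc3"]) == [0.0, 0.5, 1.0]
        assert list(curve["expected_enc"]) == pytest.approx([31.0, 60.5, 32.0])

    def test_grid_strictly_increasing(self):
        curve = standard_curve(0.01)
        assert (np.diff(curve["gc3"]) > 0).all()

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError):
            standard_curve(0.5 + 1e9)


class TestENC:
    def test_uniform_large_counts_near_maximum(self, mito_code):
        t = CodonCountTable(
            "u", {c: 500 for c in CODON_ORDER if mito_code.codon_to_aa[c] != "*"}
        )
        res = enc(t, mito_code)
        assert res.enc == pytest.approx(60, abs=0.1)
        # standard-compat: the interpolated three-fold class keeps the
        # zero-bias limit a little under the printed ceiling of 61
        res61 = enc(t, mito_code, mode="standard-compat")
        assert 60.5 < res61.enc <= 61

    def test_one_codon_per_family_gives_20(self, mito_code):
        counts = {fam.codons[0]: 50 for fam in mito_code.families}
        res = enc(CodonCountTable("b", counts), mito_code)
        assert res.enc == pytest.approx(20.0, abs=1e-12)

    def test_family_F_matches_brute_force(self, mito_code):
        rng = np.random.default_rng(31)
        t = random_count_table(rng)
        res = enc(t, mito_code)
        oracle = brute_force_family_F(t, mito_code)
        assert set(res.family_F) == set(oracle)
        for aa, F in oracle.items():
            assert res.family_F[aa] == pytest.approx(F)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_bounds_after_capping(self, seed):
        code = load_code("vertebrate-mito")
        t = random_count_table(np.random.default_rng(seed), max_count=12)
        for mode, cap in (("code-derived", 60), ("standard-compat", 61)):
            res = enc(t, code, mode=mode)
            assert 20 <= res.enc <= cap
            for F in res.family_F.values():
                assert 0 <= F <= 1

    def test_stop_codons_never_enter(self, mito_code):
        base = {fam.codons[0]: 50 for fam in mito_code.families}
        with_stops = dict(base, UAA=30, AGA=30)
        a = enc(CodonCountTable("a", base), mito_code)
        b = enc(CodonCountTable("b", with_stops), mito_code)
        assert a.enc == b.enc

    def test_missing_class_interpolated_and_flagged(self, mito_code):
        # only two-fold and six-fold families observed: four-fold class
        # F-bar must be interpolated between its neighbours
        counts = {}
        for fam in mito_code.families:
            if fam.degeneracy in (2, 6):
                counts[fam.codons[0]] = 5
                counts[fam.codons[1]] = 5
        res = enc(CodonCountTable("m", counts), mito_code)
        assert res.interpolated_classes == (4,)
        assert res.quality_flag == "interpolated"

    def test_unestimable_table_errors(self, mito_code):
        with pytest.raises(ENCError):
            enc(CodonCountTable("e", {"AUG": 1}), mito_code)

    def test_enc_decreases_with_dirichlet_concentration(self, mito_code):
        """Stronger within-family skew (lower concentration) lowers ENC."""
        rng = np.random.default_rng(77)
        sense_fams = mito_code.families
        mean_encs = []
        for conc in (0.2, 1.0, 5.0, 25.0, 125.0):
            vals = []
            for _ in range(8):
                counts = {}
                for fam in sense_fams:
                    probs = rng.dirichlet([conc] * fam.degeneracy)
                    draws = rng.multinomial(60, probs)
                    for c, n in zip(fam.codons, draws):
                        counts[c] = int(n)
                vals.append(enc(CodonCountTable("x", counts), mito_code).enc)
            mean_encs.append(np.mean(vals))
        assert all(np.diff(mean_encs) > 0)


class TestENCPlot:
    def test_uniform_gene_near_curve(self, mito_code):
        t = CodonCountTable(
            "u", {c: 200 for c in CODON_ORDER if mito_code.codon_to_aa[c] != "*"}
        )
        pts = enc_plot_points([t], mito_code, margin=1.0)
        row = pts.iloc[0]
        assert row["gc3"] == pytest.approx(0.5)
        assert row["expected_enc"] == pytest.approx(60.5)
        assert not row["below_curve"]  # 60 vs 60.5 is within margin 1

    def test_selected_gene_far_below_curve(self, mito_code):
        counts = {fam.codons[0]: 50 for fam in mito_code.families}
        pts = enc_plot_points([CodonCountTable("s", counts)], mito_code)
        row = pts.iloc[0]
        assert row["below_curve"]
        assert row["expected_enc"] - row["enc"] > 10

    def test_mutation_only_gene_tracks_curve(self, mito_code):
        """Third positions drawn i.i.d. from a GC3-matched distribution:
        observed ENC stays near the mutation-only expectation."""
        rng = np.random.default_rng(123)
        third_probs = {"A": 0.35, "U": 0.25, "G": 0.2, "C": 0.2}
        counts = {c: 0 for c in CODON_ORDER}
        for fam in mito_code.families:
            for _ in range(4000 // 20):
                weights = np.array([third_probs[c[2]] for c in fam.codons])
                pick = rng.choice(len(fam.codons), p=weights / weights.sum())
                counts[fam.codons[pick]] += 1
        res = enc(CodonCountTable("m", counts), mito_code)
        assert abs(res.enc - expected_enc(res.gc3)) < 3.5
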