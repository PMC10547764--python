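"""Proportions, the relative binding-energy formula, comparisons, marginalization."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kascape import (
    compare_landscapes,
    emsa_statistic,
    kcal_to_log2,
    log2_to_kcal,
    marginal_counts,
    marginalize,
    proportions,
    relative_binding_energy,
    select_high_affinity,
    table_from_mapping,
)
from kascape.read_processing import empty_table

from conftest import small_design


def tables_n1(input_counts, bound_counts):
    d = small_design(1)
    inp = table_from_mapping(d, "input", dict(zip("ACGT", input_counts)))
    bnd = table_from_mapping(d, "bound", dict(zip("ACGT", bound_counts)))
    return inp, bnd


def brute_force_ddg(input_counts, bound_counts, pseudocount=0.0):
    """Independent scalar evaluation of ddG = -log2(P(bound)/P(input))."""
    r = [c + pseudocount for c in input_counts]
    b = [c + pseudocount for c in bound_counts]
    R, B = sum(r), sum(b)
    out = []
    for ri, bi in zip(r, b):
        if ri > 0 and bi > 0:
            out.append(-math.log2((bi / B) / (ri / R)))
        else:
            out.append(math.nan)
    return out


class TestProportions:
    @pytest.mark.parametrize(
        "counts,pc,expected",
        [
            ((25, 25, 25, 25), 0, (0.25, 0.25, 0.25, 0.25)),
            ((50, 25, 15, 10), 0, (0.5, 0.25, 0.15, 0.10)),
            ((1, 0, 0, 0), 1, (0.4, 0.2, 0.2, 0.2)),
        ],
    )
    def test_known_values(self, counts, pc, expected):
        inp, _ = tables_n1(counts, counts)
        assert proportions(inp, pc) == pytest.approx(expected, abs=1e-15)

    def test_all_zero_without_pseudocount_errors(self):
        with pytest.raises(ValueError):
            proportions(empty_table(small_design(1), "input"), 0)

    def test_negative_pseudocount_rejected(self):
        inp, _ = tables_n1((1, 1, 1, 1), (1, 1, 1, 1))
        with pytest.raises(ValueError):
            proportions(inp, -0.5)


class TestRelativeBindingEnergy:
    def test_identical_tables_give_zero(self):
        inp, bnd = tables_n1((7, 3, 9, 1), (7, 3, 9, 1))
        land = relative_binding_energy(inp, bnd)
        assert land.ddg == pytest.approx([0, 0, 0, 0], abs=1e-15)

    def test_closed_form_n1_example(self):
        inp, bnd = tables_n1((25, 25, 25, 25), (50, 25, 15, 10))
        land = relative_binding_energy(inp, bnd)
        assert land["A"] == pytest.approx(-1.0, abs=1e-12)
        assert land["G"] == pytest.approx(-math.log2(0.6), abs=1e-12)  # ~ +0.737

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            ri = rng.integers(1, 50, size=4)
            bi = rng.integers(1, 50, size=4)
            a = relative_binding_energy(*tables_n1(ri, bi))
            b = relative_binding_energy(*tables_n1(ri * 10, bi * 10))
            np.testing.assert_allclose(a.ddg, b.ddg, atol=1e-12)

    def test_monotone_in_bound_count(self):
        inp, bnd = tables_n1((10, 10, 10, 10), (5, 5, 5, 5))
        base = relative_binding_energy(inp, bnd)["A"]
        _, bnd2 = tables_n1((10, 10, 10, 10), (9, 5, 5, 5))
        assert relative_binding_energy(inp, bnd2)["A"] < base

    def test_zero_counts_flagged_undefined_not_fabricated(self):
        inp, bnd = tables_n1((10, 10, 10, 0), (5, 0, 5, 5))
        land = relative_binding_energy(inp, bnd, pseudocount=0)
        assert not np.isfinite(land["C"])  # zero bound
        assert not np.isfinite(land["T"])  # zero input
        assert land.defined.sum() == 2

    def test_design_mismatch_rejected(self, design4):
        inp = empty_table(small_design(1), "input")
        bnd = empty_table(design4, "bound")
        with pytest.raises(ValueError):
            relative_binding_energy(inp, bnd)

    def test_normalization_invariant(self):
        rng = np.random.default_rng(3)
        for pc in (0, 1):
            inp, bnd = tables_n1(rng.integers(0, 40, 4), rng.integers(0, 40, 4))
            land = relative_binding_energy(inp, bnd, pseudocount=pc)
            assert land.p_input.sum() == pytest.approx(1, abs=1e-9)
            assert land.p_bound.sum() == pytest.approx(1, abs=1e-9)

    @given(
        st.lists(st.integers(1, 1000), min_size=4, max_size=4),
        st.lists(st.integers(1, 1000), min_size=4, max_size=4),
        st.sampled_from([0.0, 0.5, 1.0]),
    )
    def test_matches_brute_force_oracle(self, ri, bi, pc):
        land = relative_binding_energy(*tables_n1(ri, bi), pseudocount=pc)
        np.testing.assert_allclose(land.ddg, brute_force_ddg(ri, bi, pc), atol=1e-12)

    def test_tsv_uses_na_for_undefined(self, tmp_path):
        inp, bnd = tables_n1((10, 10, 10, 10), (5, 0, 5, 5))
        land = relative_binding_energy(inp, bnd)
        land.to_tsv(tmp_path / "land.tsv")
        lines = (tmp_path / "land.tsv").read_text().splitlines()
        assert lines[0] == "sequence\tinput_count\tbound_count\tp_input\tp_bound\tddg_log2"
        assert lines[2].endswith("\tNA")  # the C row


class TestSelectHighAffinity:
    def test_threshold(self):
        inp, bnd = tables_n1((10, 10, 10, 10), (50, 25, 10, 4))
        land = relative_binding_energy(inp, bnd)
        # ddg: A ~ -1.17, C ~ -0.17, G ~ +1.15, T ~ +2.48
        assert select_high_affinity(land, cutoff=-1.0) == {"A"}
        assert select_high_affinity(land, cutoff=1e9) == {"A", "C", "G", "T"}

    def test_flat_landscape_selects_nothing(self):
        inp, bnd = tables_n1((5, 5, 5, 5), (5, 5, 5, 5))
        assert select_high_affinity(relative_binding_energy(inp, bnd), -1.0) == set()

    def test_infinite_cutoff_rejected(self):
        inp, bnd = tables_n1((5, 5, 5, 5), (5, 5, 5, 5))
        with pytest.raises(ValueError):
            select_high_affinity(relative_binding_energy(inp, bnd), math.inf)


class TestCompareLandscapes:
    def test_identity_and_negation(self):
        a = {"AA": 0.0, "AC": 1.0, "AG": 2.0, "AT": 0.5}
        assert compare_landscapes(a, a) == pytest.approx(1.0)
        neg = {k: -v for k, v in a.items()}
        assert compare_landscapes(a, neg) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # r = 3 / sqrt(2 * 42/9) = 0.98198...
        a = {"A": 0.0, "C": 1.0, "G": 2.0}
        b = {"A": 0.0, "C": 2.0, "G": 3.0}
        assert compare_landscapes(a, b) == pytest.approx(3 / math.sqrt(2 * 42 / 9), abs=1e-12)

    def test_spearman_option(self):
        a = {"A": 0.0, "C": 1.0, "G": 2.0, "T": 3.0}
        b = {"A": 0.0, "C": 10.0, "G": 20.0, "T": 25.0}
        assert compare_landscapes(a, b, method="spearman") == pytest.approx(1.0)

    def test_fewer_than_three_shared_points_errors(self):
        with pytest.raises(ValueError):
            compare_landscapes({"A": 1.0, "C": 2.0}, {"A": 1.0, "C": 3.0})

    def test_nan_values_excluded_from_intersection(self):
        a = {"A": 1.0, "C": 2.0, "G": 3.0, "T": math.nan}
        b = {"A": 1.0, "C": 2.5, "G": 2.9, "T": 5.0}
        assert compare_landscapes(a, b) == pytest.approx(
            compare_landscapes({k: a[k] for k in "ACG"}, {k: b[k] for k in "ACG"})
        )


class TestMarginalization:
    def test_window_sum_example(self):
        d = small_design(2)
        table = table_from_mapping(d, "input", {"AA": 3, "CG": 1})
        marg = marginal_counts(table)
        assert {s: int(c) for s, c in zip(marg.space.sequences, marg.counts)} == {
            "A": 6, "C": 1, "G": 1, "T": 0,
        }

    def test_marginal_totals_double(self, design4):
        rng = np.random.default_rng(1)
        table = empty_table(design4, "input")
        table.counts[:] = rng.integers(0, 9, size=256)
        assert marginal_counts(table).total_kept == 2 * table.total_kept

    def test_uniform_tables_give_flat_marginal_landscape(self):
        d = small_design(3)
        inp = empty_table(d, "input")
        bnd = empty_table(d, "bound")
        inp.counts[:] = 5
        bnd.counts[:] = 11
        land = marginalize(inp, bnd)
        np.testing.assert_allclose(land.ddg, 0.0, atol=1e-12)

    def test_additive_energy_model_recovered_up_to_offset(self):
        # bound counts prop. to 2^(-E(s)) with E(s) = sum_i e(s_i): marginal
        # consistency is exact for position-additive energies
        d = small_design(3)
        g = {"A": 1, "C": 2, "G": 4, "T": 8}  # weights 2^(-e), e = -log2 g
        inp = empty_table(d, "input")
        inp.counts[:] = 1
        bnd = empty_table(d, "bound")
        for i, s in enumerate(bnd.space.sequences):
            bnd.counts[i] = g[s[0]] * g[s[1]] * g[s[2]]
        land = marginalize(inp, bnd)
        truth = np.array([-math.log2(g[s[0]] * g[s[1]]) for s in land.space.sequences])
        offsets = land.ddg - truth
        np.testing.assert_allclose(offsets, offsets[0], atol=1e-9)

    def test_prefix_energy_model_recovered_with_prefix_windows(self):
        d = small_design(2)
        g = {"A": 1, "C": 2, "G": 4, "T": 8}
        inp = empty_table(d, "input")
        inp.counts[:] = 1
        bnd = empty_table(d, "bound")
        for i, s in enumerate(bnd.space.sequences):
            bnd.counts[i] = g[s[0]]  # energy depends on the first base only
        land = marginalize(inp, bnd, windows="prefix")
        truth = np.array([-math.log2(g[s]) for s in land.space.sequences])
        offsets = land.ddg - truth
        np.testing.assert_allclose(offsets, offsets[0], atol=1e-9)

    def test_cannot_marginalize_below_length_one(self):
        d = small_design(1)
        with pytest.raises(ValueError):
            marginal_counts(empty_table(d, "input"))


class TestEmsaAndUnits:
    @pytest.mark.parametrize("bound,unbound,expected", [(3.0, 3.0, 0.0), (6.0, 3.0, -1.0), (1.0, 4.0, 2.0)])
    def test_emsa_statistic(self, bound, unbound, expected):
        assert emsa_statistic(bound, unbound) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            emsa_statistic(0.0, 1.0)

    def test_unit_conversion_roundtrip(self):
        x = np.array([0.5, 5.0])
        np.testing.assert_allclose(log2_to_kcal(kcal_to_log2(x)), x, atol=1e-12)
        # 0.5-5 kcal/mol spans about 1.2-12.2 log2 units at 298 K
        np.testing.assert_allclose(kcal_to_log2(x), [1.216, 12.164], atol=5e-3)
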