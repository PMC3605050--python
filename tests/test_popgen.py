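"""Allele frequencies, Weir-Cockerham F_ST, map distance, exact tests,
phenotype-coded clines."""

import math
from collections import defaultdict

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from clinekit import (
    F2CrossCounts,
    GenotypePanel,
    ValidationError,
    allele_frequencies,
    fisher_exact,
    fst_between_groups,
    map_distance,
    phenotype_to_cline_counts,
    simulate_ecotype_panel,
)


def panel_from_dosages(groups):
    """groups: mapping group label -> {locus: list of dosages (None = missing)}."""
    records = []
    for group, loci in groups.items():
        n = len(next(iter(loci.values())))
        for i in range(n):
            dosages = {
                locus: (np.nan if vals[i] is None else float(vals[i]))
                for locus, vals in loci.items()
            }
            records.append((f"{group}{i}", group, group, dosages))
    return GenotypePanel.from_records(records)


class TestAlleleFrequencies:
    def test_fixed_group(self):
        panel = panel_from_dosages({"g": {"L": [2, 2, 2]}})
        assert allele_frequencies(panel).loc["g", "L"] == 1.0

    def test_mixed_dosages(self):
        panel = panel_from_dosages({"g": {"L": [2, 1, 0]}})
        assert allele_frequencies(panel).loc["g", "L"] == 0.5

    def test_fixed_difference_panel(self):
        # 267 individuals fixed R against 107 fixed Y
        panel = panel_from_dosages({"red": {"L": [2] * 267}, "yellow": {"L": [0] * 107}})
        freq = allele_frequencies(panel)
        assert freq.loc["red", "L"] == 1.0 and freq.loc["yellow", "L"] == 0.0

    def test_missing_excluded_pairwise(self):
        panel = panel_from_dosages({"g": {"L": [2, None, 0, 1]}})
        assert allele_frequencies(panel).loc["g", "L"] == pytest.approx(0.5)

    def test_all_missing_reported_missing_not_zero(self):
        panel = panel_from_dosages({"a": {"L": [None, None]}, "b": {"L": [1, 1]}})
        freq = allele_frequencies(panel)
        assert np.isnan(freq.loc["a", "L"]) and freq.loc["b", "L"] == 0.5


class TestFst:
    def test_fixed_difference_is_exactly_one(self):
        panel = panel_from_dosages({"red": {"L": [2] * 267}, "yellow": {"L": [0] * 107}})
        assert fst_between_groups(panel)["L"] == 1.0

    def test_identical_groups_near_zero(self):
        dosages = [2, 1, 1, 0, 2, 0, 1, 1]
        panel = panel_from_dosages({"a": {"L": dosages}, "b": {"L": dosages}})
        theta = fst_between_groups(panel)["L"]
        assert theta <= 0.0  # no differentiation; slightly negative is expected

    def test_hand_computed_weir_cockerham_oracle(self):
        # A: dosages 2,2,1,1  B: 0,0,1,1 — components worked by hand:
        # n1=n2=4, p1=0.75, p2=0.25, h1=h2=0.5, nbar=nc=4, pbar=0.5,
        # s2=0.125, hbar=0.5
        # a = 0.125 - (1/3)(0.25 - 0.0625 - 0.125) = 0.10416667
        # b = (4/3)(0.25 - 0.0625 - 0.5*7/16)      = -0.04166667
        # c = 0.25             theta = a/(a+b+c) = 1/3
        panel = panel_from_dosages({"a": {"L": [2, 2, 1, 1]}, "b": {"L": [0, 0, 1, 1]}})
        assert abs(fst_between_groups(panel)["L"] - 1.0 / 3.0) < 1e-10

    def test_invariant_to_group_label_swap_and_allele_relabel(self):
        da, db = [2, 1, 1, 0, 2], [0, 0, 1, 2, 1]
        base = fst_between_groups(panel_from_dosages({"a": {"L": da}, "b": {"L": db}}))["L"]
        swapped = fst_between_groups(panel_from_dosages({"a": {"L": db}, "b": {"L": da}}))["L"]
        relabeled = fst_between_groups(
            panel_from_dosages({"a": {"L": [2 - d for d in da]}, "b": {"L": [2 - d for d in db]}})
        )["L"]
        assert base == pytest.approx(swapped, abs=1e-14)
        assert base == pytest.approx(relabeled, abs=1e-14)

    def test_monotone_approach_to_fixation(self):
        # theta rises toward 1 as the two groups' frequencies diverge
        thetas = []
        for f in (0.6, 0.75, 0.9, 1.0):
            panel = simulate_ecotype_panel(f, 1.0 - f, 600, 600, seed=17)
            thetas.append(fst_between_groups(panel)["L1"])
        assert all(a < b for a, b in zip(thetas, thetas[1:]))
        assert thetas[-1] == 1.0

    def test_monomorphic_locus_reported_missing(self):
        panel = panel_from_dosages({"a": {"L": [0, 0, 0]}, "b": {"L": [0, 0, 0]}})
        assert np.isnan(fst_between_groups(panel)["L"])

    def test_requires_exactly_two_groups(self):
        panel = panel_from_dosages({"a": {"L": [1, 1]}, "b": {"L": [1, 0]}, "c": {"L": [2, 1]}})
        with pytest.raises(ValidationError, match="two groups"):
            fst_between_groups(panel)


class TestMapDistance:
    def test_f2_cross_direct_distance(self):
        # 79 recombinant gametes among 359 F2s: r = 79/718, direct = 11 cM
        cm = map_distance(F2CrossCounts(n_individuals=359, n_recombinant=79), "direct")
        assert cm == pytest.approx(11.0, abs=0.01)
        assert round(cm) == 11

    def test_zero_recombinants(self):
        cross = F2CrossCounts(n_individuals=100, n_recombinant=0)
        for fn in ("direct", "haldane", "kosambi"):
            assert map_distance(cross, fn) == 0.0

    def test_haldane_closed_form(self):
        cross = F2CrossCounts(n_individuals=100, n_recombinant=22)  # r = 0.11
        assert map_distance(cross, "haldane") == pytest.approx(-50.0 * math.log(0.78), rel=1e-12)
        assert map_distance(cross, "haldane") == pytest.approx(12.42, abs=0.005)

    def test_map_function_domain_error(self):
        cross = F2CrossCounts(n_individuals=100, n_recombinant=100)  # r = 0.5
        for fn in ("haldane", "kosambi"):
            with pytest.raises(ValidationError, match=fn):
                map_distance(cross, fn)
        assert map_distance(cross, "direct") == 50.0

    @pytest.mark.parametrize("n_rec", [1, 10, 40, 70, 95])
    def test_map_function_ordering(self, n_rec):
        cross = F2CrossCounts(n_individuals=100, n_recombinant=n_rec)
        direct = map_distance(cross, "direct")
        kosambi = map_distance(cross, "kosambi")
        haldane = map_distance(cross, "haldane")
        assert direct <= kosambi <= haldane

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            F2CrossCounts(n_individuals=10, n_recombinant=21)


class TestFisherExact:
    def test_diagonal_three_by_three_counts(self):
        # full enumeration: only the two diagonal tables have P <= 1/20
        assert fisher_exact([[3, 0], [0, 3]]).p_value == pytest.approx(0.1, rel=1e-12)

    def test_identical_rows(self):
        assert fisher_exact([[4, 6], [4, 6]]).p_value == 1.0

    def test_symmetric_table(self):
        assert fisher_exact([[10, 10], [10, 10]]).p_value == 1.0

    def test_zero_margin_degenerate(self):
        res = fisher_exact([[0, 0], [3, 5]])
        assert res.p_value == 1.0 and res.degenerate

    @given(
        st.lists(st.integers(0, 8), min_size=4, max_size=4).filter(
            lambda t: (t[0] + t[1]) * (t[2] + t[3]) * (t[0] + t[2]) * (t[1] + t[3]) > 0
        )
    )
    def test_two_by_two_matches_scipy(self, flat):
        table = [[flat[0], flat[1]], [flat[2], flat[3]]]
        assert fisher_exact(table).p_value == pytest.approx(
            scipy_fisher(table)[1], abs=1e-10
        )

    def test_two_by_three_matches_r(self):
        # frozen oracle: R's fisher.test(matrix(c(8,3,2,5,1,6), nrow=2))
        assert fisher_exact([[8, 2, 1], [3, 5, 6]]).p_value == pytest.approx(
            0.0535395073361, abs=1e-9
        )

    @given(st.lists(st.integers(0, 6), min_size=6, max_size=6))
    def test_invariant_under_row_and_column_permutation(self, flat):
        table = np.array(flat).reshape(2, 3)
        base = fisher_exact(table).p_value
        assert fisher_exact(table[::-1]).p_value == pytest.approx(base, abs=1e-12)
        assert fisher_exact(table[:, [2, 0, 1]]).p_value == pytest.approx(base, abs=1e-12)

    def test_monte_carlo_agrees_with_enumeration(self):
        table = [[30, 18, 12], [15, 25, 20]]
        exact = fisher_exact(table).p_value
        mc = fisher_exact(table, max_support=10, n_resamples=200_000, seed=3)
        assert mc.method == "monte-carlo"
        assert mc.p_value == pytest.approx(exact, abs=0.01)


class TestPhenotypeCoding:
    def test_all_red_population(self):
        data = phenotype_to_cline_counts([("p1", "red")] * 3, {"p1": 0.0})
        assert data.samples[0].k == 6 and data.samples[0].n == 6

    def test_three_category_mix(self):
        data = phenotype_to_cline_counts(
            [("p1", "red"), ("p1", "orange"), ("p1", "yellow")], {"p1": 2.0}
        )
        assert data.samples[0].k == 3 and data.samples[0].n == 6

    def test_multi_population_tally_matches_brute_force(self):
        rng = np.random.default_rng(5)
        cats = ["red", "red-orange", "orange", "yellow"]
        dosage = {"red": 2, "red-orange": 1, "orange": 1, "yellow": 0}
        records = [(f"p{rng.integers(1, 5)}", cats[rng.integers(0, 4)]) for _ in range(60)]
        positions = {f"p{i}": float(i) for i in range(1, 5)}
        data = phenotype_to_cline_counts(records, positions)
        expected = defaultdict(lambda: [0, 0])
        for pop, cat in records:
            expected[pop][0] += dosage[cat]
            expected[pop][1] += 2
        for s in data.samples:
            assert [s.k, s.n] == expected[s.population_id]

    def test_unknown_category_lists_valid_labels(self):
        with pytest.raises(ValidationError, match="red-orange"):
            phenotype_to_cline_counts([("p1", "magenta")], {"p1": 0.0})


class TestGenotypePanelIO:
    def test_tsv_genotype_codes(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(
            "id\tpopulation\tgroup\tM1\tM2\n"
            "i1\tpopA\tred\tRR\t2\n"
            "i2\tpopA\tred\tRY\t1\n"
            "i3\tpopB\tyellow\tYY\t\n"
        )
        panel = GenotypePanel.from_tsv(path)
        assert panel.loci == ("M1", "M2")
        assert panel.data.loc["i1", "M1"] == 2.0
        assert panel.data.loc["i2", "M1"] == 1.0
        assert np.isnan(panel.data.loc["i3", "M2"])

    def test_bad_genotype_code_rejected(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text("id\tpopulation\tgroup\tM1\ni1\tpopA\tred\tRX\n")
        with pytest.raises(ValidationError, match="RX"):
            GenotypePanel.from_tsv(path)

    def test_invalid_dosage_rejected(self):
        df = pd.DataFrame(
            {"population": ["a"], "group": ["a"], "L": [3.0]}, index=pd.Index(["i1"], name="id")
        )
        with pytest.raises(ValidationError, match="dosages"):
            GenotypePanel(df)
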