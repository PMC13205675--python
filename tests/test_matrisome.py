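"""Matrisome categorization, overlap algebra, DEG filter and nine-quadrant."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovamat.errors import FormatError, ParameterError
from ovamat.matrisome import (
    ALL_CATEGORIES,
    annotate_list,
    deg_filter,
    load_reference,
    nine_quadrant,
    overlap_sets,
    pearson_r,
)
from ovamat.synthetic import OmicsTableSpec, gen_omics_table

REF_PATH = "src/ovamat/data/matrisome_reference_synthetic.csv"


@pytest.fixture(scope="module")
def ref():
    from importlib import resources

    return load_reference(
        resources.files("ovamat.data").joinpath(
            "matrisome_reference_synthetic.csv"
        )
    )


class TestReference:
    def test_bundled_fixture_has_all_six_categories(self, ref):
        cats = {cat for _, cat in ref.entries.values()}
        assert cats == set(ALL_CATEGORIES)
        assert len(ref.entries) == 30

    def test_category_typo_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "identifier,division,category\n"
            "Col1a1,core matrisome,collagns\n"
        )
        with pytest.raises(FormatError):
            load_reference(p)

    def test_division_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "identifier,division,category\n"
            "Mmp2,core matrisome,ECM regulators\n"
        )
        with pytest.raises(FormatError):
            load_reference(p)

    def test_duplicates_rejected_naming_them(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "identifier,division,category\n"
            "Fn1,core matrisome,glycoproteins\n"
            "FN1,core matrisome,glycoproteins\n"
        )
        with pytest.raises(FormatError, match="fn1"):
            load_reference(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("identifier,division,category\n")
        with pytest.raises(FormatError):
            load_reference(p)


class TestAnnotate:
    def test_constructed_composition_recovered(self, ref):
        ids = (
            ["Col1a1", "Col1a2", "Col3a1", "Col4a1", "Col4a2"]  # 5 collagens
            + ["Fn1", "Lama1", "Lamb1", "Tgfbi", "Thbs4"]       # 5 glyco
            + ["FAKE1", "FAKE2", "FAKE3"]                        # 3 unmapped
        )
        res = annotate_list(ids, ref)
        assert res.counts["collagens"] == 5
        assert res.counts["glycoproteins"] == 5
        assert res.non_matrisome == 3
        assert res.percentages["collagens"] == pytest.approx(50.0)
        assert sum(res.percentages.values()) == pytest.approx(100.0)

    def test_matching_is_case_insensitive(self, ref):
        res = annotate_list(["COL1A1", "col1a2"], ref)
        assert res.counts["collagens"] == 2

    def test_disjoint_list_all_non_matrisome(self, ref):
        res = annotate_list(["xx1", "xx2"], ref)
        assert res.non_matrisome == 2
        assert res.matrisome_total == 0

    def test_full_reference_recovers_its_composition(self, ref):
        res = annotate_list(list(ref.entries), ref)
        assert res.non_matrisome == 0
        assert all(res.counts[c] == 5 for c in ALL_CATEGORIES)

    def test_duplicates_collapsed_and_size_conserved(self, ref):
        res = annotate_list(["Fn1", "FN1", "fn1", "zz"], ref)
        assert res.duplicates_collapsed == 2
        assert res.matrisome_total + res.non_matrisome == res.input_size == 2

    def test_empty_input_rejected(self, ref):
        with pytest.raises(ParameterError):
            annotate_list([], ref)


def brute_force_regions(lists):
    """Per-element membership-pattern oracle for Venn regions."""
    sets = {k: {str(i).casefold() for i in v} for k, v in lists.items()}
    names = sorted(sets)
    regions = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(sets[c] for c in combo))
            outside = set().union(
                *(sets[n] for n in names if n not in combo), set()
            )
            regions[combo] = len(inter - outside)
    return regions


class TestOverlap:
    def test_disjoint_sets(self):
        res = overlap_sets({"a": {"x"}, "b": {"y"}, "c": {"z"}})
        assert res["regions"][("a", "b", "c")] == 0
        assert res["regions"][("a",)] == 1
        assert res["union_size"] == 3

    def test_identical_sets_full_triple_overlap(self):
        s = {f"g{i}" for i in range(50)}
        res = overlap_sets({"a": s, "b": set(s), "c": set(s)})
        assert res["regions"][("a", "b", "c")] == 50
        assert sum(res["regions"].values()) == 50

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_species=st.integers(2, 4))
    def test_matches_per_element_oracle(self, seed, n_species):
        rng = np.random.default_rng(seed)
        universe = [f"id{i}" for i in range(60)]
        lists = {
            f"sp{j}": set(
                rng.choice(universe, size=rng.integers(5, 40), replace=False)
            )
            for j in range(n_species)
        }
        res = overlap_sets(lists)
        assert res["regions"] == brute_force_regions(lists)
        assert sum(res["regions"].values()) == res["union_size"]


class TestDegFilter:
    def test_boundary_is_strict(self):
        table = pd.DataFrame(
            {"log2fc": [1.0, 1.0001, -1.0], "p": [0.01, 0.01, 0.04]}
        )
        out = deg_filter(table)
        assert out["n"] == 1
        assert out["up"] == 1 and out["down"] == 0

    def test_down_regulated_included(self):
        table = pd.DataFrame({"log2fc": [-1.5], "p": [0.049]})
        out = deg_filter(table)
        assert out["n"] == 1 and out["down"] == 1

    def test_p_boundary_is_strict(self):
        table = pd.DataFrame({"log2fc": [2.0], "p": [0.05]})
        assert deg_filter(table)["n"] == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame(
            {"log2fc": rng.normal(0, 1.5, 200), "p": rng.uniform(0, 1, 200)}
        )
        out = deg_filter(table)
        want = sum(
            1 for fc, p in zip(table["log2fc"], table["p"])
            if abs(fc) > 1.0 and p < 0.05
        )
        assert out["n"] == want == len(out["subset"])


def make_pairs(rows):
    return pd.DataFrame(
        rows,
        columns=["log2fc_mrna", "p_mrna", "log2fc_protein", "p_protein"],
    )


class TestNineQuadrant:
    def test_all_unchanged_in_quadrant_5(self):
        pairs = make_pairs([[0.0, 0.5, 0.0, 0.5]] * 7)
        out = nine_quadrant(pairs)
        assert out["counts"][5] == 7
        assert sum(out["counts"].values()) == 7

    def test_nine_state_table_hits_every_quadrant_once(self):
        states = {  # (log2fc, p) per axis state
            0: (-2.0, 0.01),  # down
            1: (0.0, 0.9),    # unchanged
            2: (2.0, 0.01),   # up
        }
        rows = [
            list(states[m]) + list(states[p])
            for m in (0, 1, 2) for p in (0, 1, 2)
        ]
        out = nine_quadrant(make_pairs(rows))
        assert out["counts"] == {q: 1 for q in range(1, 10)}
        # ordering: 1 = both down, 9 = both up
        assigns = out["assignments"]
        both_down = assigns[
            (assigns.log2fc_mrna < 0) & (assigns.log2fc_protein < 0)
        ]
        assert both_down["quadrant"].tolist() == [1]

    def test_axis_states_consistent_with_deg_filter(self):
        spec = OmicsTableSpec(n_genes=500, fraction_significant=0.4, seed=3)
        pairs = gen_omics_table(spec)
        out = nine_quadrant(pairs)
        assigns = out["assignments"]
        mrna_extreme = assigns[assigns.quadrant.isin([1, 2, 3, 7, 8, 9])]
        deg = deg_filter(
            pairs, fc_col="log2fc_mrna", p_col="p_mrna"
        )["subset"]
        assert set(mrna_extreme["identifier"]) == set(deg["identifier"])

    def test_counts_invariant_to_input_order(self):
        pairs = gen_omics_table(OmicsTableSpec(n_genes=300, seed=8))
        a = nine_quadrant(pairs)["counts"]
        b = nine_quadrant(pairs.sample(frac=1, random_state=0))["counts"]
        assert a == b

    def test_boundary_fc_exactly_one_is_unchanged(self):
        out = nine_quadrant(make_pairs([[1.0, 0.001, -1.0, 0.001]]))
        assert out["counts"][5] == 1


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        # by hand: sum dx*dy = 8, sum dx^2 = sum dy^2 = 10 -> r = 0.8
        assert pearson_r(x, y) == pytest.approx(0.8, abs=1e-12)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ParameterError):
            pearson_r([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ParameterError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
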