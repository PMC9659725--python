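import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from emosig import proteomics
from emosig.errors import SchemaError, StatsPreconditionError
from emosig.proteomics import (
    assemble_counts,
    bh_adjust,
    filter_identifications,
    group_proteins,
    pairwise_contrasts,
    poisson_group_test,
)

from _oracles import bh_by_hand, brute_force_filter, poisson_lrt_two_group, union_find_groups
from conftest import psm_rows_to_frame


def make_peptide_frame(entries, n_samples=1):
    """entries: (peptide, evalue, 'A;B') triples -> long table."""
    rows = []
    for pep, e, prots in entries:
        for j in range(n_samples):
            rows.append(
                {"peptide": pep, "evalue": e, "proteins": prots, "sample": f"s{j + 1}", "spectra": 1}
            )
    return pd.DataFrame(rows)


class TestIdentificationFilter:
    def test_two_good_peptides_retained(self):
        frame = make_peptide_frame([("p1", 1e-3, "A"), ("p2", 1e-3, "A")])
        _, evidence = filter_identifications(frame)
        assert evidence.loc["A", "retained"]
        assert evidence.loc["A", "evalue_product"] == pytest.approx(1e-6)

    def test_single_peptide_fails_two_peptide_rule(self):
        frame = make_peptide_frame([("p1", 1e-9, "A")])
        _, evidence = filter_identifications(frame)
        assert not evidence.loc["A", "retained"]

    def test_peptide_over_evalue_cut_not_counted(self):
        frame = make_peptide_frame([("p1", 5e-3, "A"), ("p2", 5e-2, "A")])
        retained, evidence = filter_identifications(frame)
        assert not evidence.loc["A", "retained"]
        assert evidence.loc["A", "n_peptides"] == 1
        assert "p2" not in set(retained["peptide"])

    def test_product_of_unique_peptide_evalues(self):
        # two peptides just under the cut: product 9.8e-5 < 1e-4, kept —
        # with the 0.01 peptide cut the product rule can only bind at
        # the exact 1e-4 boundary, which the strict inequality excludes
        frame = make_peptide_frame([("p1", 9.9e-3, "A"), ("p2", 9.9e-3, "A")])
        _, evidence = filter_identifications(frame)
        assert evidence.loc["A", "evalue_product"] == pytest.approx(9.9e-3**2)
        assert evidence.loc["A", "retained"]

    def test_matches_brute_force_on_random_fixture(self, random_psm_rows):
        frame = psm_rows_to_frame(random_psm_rows)
        _, evidence = filter_identifications(frame)
        got = set(evidence.index[evidence["retained"]])
        assert got == brute_force_filter(random_psm_rows)

    def test_order_independent_and_idempotent(self, random_psm_rows):
        frame = psm_rows_to_frame(random_psm_rows)
        shuffled = frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
        _, ev_a = filter_identifications(frame)
        _, ev_b = filter_identifications(shuffled)
        pd.testing.assert_frame_equal(ev_a, ev_b)
        retained, _ = filter_identifications(frame)
        retained2, ev2 = filter_identifications(
            retained.assign(proteins=retained["proteins"].map(lambda s: ";".join(sorted(s))))
        )
        assert set(ev2.index[ev2["retained"]]) <= set(ev_a.index[ev_a["retained"]])
        assert len(retained2) == len(retained)

    def test_duplicate_rows_collapse_with_warning(self):
        frame = make_peptide_frame([("p1", 1e-3, "A"), ("p1", 2e-3, "A"), ("p2", 1e-3, "A")])
        with pytest.warns(UserWarning, match="collapsed"):
            _, evidence = filter_identifications(frame)
        assert evidence.loc["A", "evalue_product"] == pytest.approx(1e-6)

    def test_nonpositive_evalue_rejected(self):
        with pytest.raises(SchemaError):
            filter_identifications(make_peptide_frame([("p1", 0.0, "A")]))


class TestGrouping:
    def grouping_of(self, entries):
        frame = make_peptide_frame(entries)
        retained = frame.copy()
        retained["proteins"] = retained["proteins"].map(
            lambda s: frozenset(s.split(";"))
        )
        return group_proteins(retained)

    def test_shared_peptide_groups_pair_disjoint_alone(self):
        groups = self.grouping_of(
            [("p1", 1e-3, "A;B"), ("p2", 1e-3, "A"), ("p3", 1e-3, "B"), ("p4", 1e-3, "C")]
        )
        assert [g.members for g in groups] == [("A", "B"), ("C",)]
        assert groups[0].group_id == "A"

    def test_transitive_chain_merges(self):
        groups = self.grouping_of([("p1", 1e-3, "A;B"), ("p2", 1e-3, "B;C")])
        assert [g.members for g in groups] == [("A", "B", "C")]

    def test_subgroups_require_specific_peptides(self):
        groups = self.grouping_of([("p1", 1e-3, "A;B"), ("p3", 1e-3, "A")])
        (g,) = groups
        assert g.subgroups == ("A",)
        assert g.specific_peptides["A"] == frozenset({"p3"})
        assert g.specific_peptides["B"] == frozenset()
        assert g.shared_peptides == frozenset({"p1"})

    def test_all_shared_yields_no_subgroups(self):
        groups = self.grouping_of([("p1", 1e-3, "A;B"), ("p2", 1e-3, "A;B")])
        (g,) = groups
        assert g.subgroups == ()

    def test_disjoint_proteins_one_group_each(self):
        groups = self.grouping_of([("p1", 1e-3, "A"), ("p2", 1e-3, "B")])
        assert [g.members for g in groups] == [("A",), ("B",)]

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_partition_matches_union_find(self, data):
        n_prot = data.draw(st.integers(2, 8))
        n_pep = data.draw(st.integers(1, 12))
        proteins = [f"X{i}" for i in range(n_prot)]
        pep_map = {}
        for j in range(n_pep):
            owners = data.draw(
                st.sets(st.sampled_from(proteins), min_size=1, max_size=min(3, n_prot))
            )
            pep_map[f"p{j}"] = owners
        entries = [(pep, 1e-3, ";".join(sorted(owners))) for pep, owners in pep_map.items()]
        groups = self.grouping_of(entries)
        got = frozenset(frozenset(g.members) for g in groups)
        assert got == union_find_groups(pep_map)


class TestAssembleCounts:
    def test_specific_counts_sum_per_sample(self):
        frame = pd.DataFrame(
            [
                {"peptide": "p1", "evalue": 1e-3, "proteins": frozenset({"A"}), "sample": "s1", "spectra": 3},
                {"peptide": "p2", "evalue": 1e-3, "proteins": frozenset({"A"}), "sample": "s1", "spectra": 2},
                {"peptide": "p1", "evalue": 1e-3, "proteins": frozenset({"A"}), "sample": "s2", "spectra": 1},
            ]
        )
        groups = group_proteins(frame)
        counts, row_info = assemble_counts(groups, frame)
        assert counts.loc["A", "s1"] == 5
        assert counts.loc["A", "s2"] == 1
        assert row_info.loc["A", "level"] == "subgroup"

    def test_shared_only_peptide_goes_to_group_row(self):
        frame = pd.DataFrame(
            [
                {"peptide": "ps", "evalue": 1e-3, "proteins": frozenset({"A", "B"}), "sample": "s1", "spectra": 7},
                {"peptide": "pa", "evalue": 1e-3, "proteins": frozenset({"A"}), "sample": "s1", "spectra": 2},
                {"peptide": "pb", "evalue": 1e-3, "proteins": frozenset({"B"}), "sample": "s1", "spectra": 4},
            ]
        )
        groups = group_proteins(frame)
        counts, row_info = assemble_counts(groups, frame)
        assert counts.loc["A", "s1"] == 2
        assert counts.loc["B", "s1"] == 4
        assert counts.loc["A/shared", "s1"] == 7
        assert row_info.loc["A/shared", "level"] == "group"
        # total spectra conserved, nothing double-counted
        assert counts["s1"].sum() == 13

    def test_empty_sample_dropped_with_warning(self):
        frame = pd.DataFrame(
            [
                {"peptide": "p1", "evalue": 1e-3, "proteins": frozenset({"A"}), "sample": "s1", "spectra": 3},
                {"peptide": "p2", "evalue": 1e-3, "proteins": frozenset({"A"}), "sample": "s1", "spectra": 1},
                {"peptide": "p1", "evalue": 1e-3, "proteins": frozenset({"A"}), "sample": "s2", "spectra": 0},
            ]
        )
        groups = group_proteins(frame)
        with pytest.warns(UserWarning, match="zero total spectra"):
            counts, _ = assemble_counts(groups, frame)
        assert list(counts.columns) == ["s1"]


def two_group_matrix(rows, n_per_group=3):
    cols = [f"a{i}" for i in range(n_per_group)] + [f"b{i}" for i in range(n_per_group)]
    counts = pd.DataFrame(rows, columns=cols)
    counts.index = [f"P{i}" for i in range(len(counts))]
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=cols)
    return counts, groups


class TestPoissonGroupTest:
    def test_identical_counts_give_unit_p(self):
        counts, groups = two_group_matrix([[5, 5, 5, 5, 5, 5]])
        res = poisson_group_test(counts, groups, offset=False)
        assert res.iloc[0]["deviance"] == pytest.approx(0.0, abs=1e-10)
        assert res.iloc[0]["pvalue"] == pytest.approx(1.0)

    def test_matches_closed_form_two_group_deviance(self):
        cases = [
            [10, 10, 10, 20, 20, 20],
            [3, 7, 5, 9, 12, 11],
            [0, 1, 0, 4, 6, 3],
        ]
        counts, groups = two_group_matrix(cases)
        res = poisson_group_test(counts, groups, offset=False)
        for i, row in enumerate(cases):
            expected = poisson_lrt_two_group(row[:3], row[3:])
            assert res.iloc[i]["deviance"] == pytest.approx(expected, abs=1e-8)
            assert res.iloc[i]["pvalue"] == pytest.approx(stats.chi2.sf(expected, 1), abs=1e-8)

    def test_all_zero_row_untestable_not_unit_p(self):
        counts, groups = two_group_matrix([[0, 0, 0, 0, 0, 0], [1, 2, 3, 4, 5, 6]])
        res = poisson_group_test(counts, groups, offset=False)
        assert not res.iloc[0]["testable"]
        assert np.isnan(res.iloc[0]["pvalue"])
        assert res.iloc[1]["testable"]

    def test_offset_absorbs_library_size(self):
        # counts proportional to per-sample depth: no group effect left
        counts, groups = two_group_matrix([[10, 10, 10, 30, 30, 30], [100, 100, 100, 300, 300, 300]])
        res = poisson_group_test(counts, groups, offset=True)
        assert (res["pvalue"] > 0.9).all()

    def test_three_level_factor_uses_two_df(self):
        cols = ["a1", "a2", "b1", "b2", "c1", "c2"]
        counts = pd.DataFrame([[5, 6, 9, 11, 19, 22]], columns=cols, index=["P0"])
        groups = pd.Series(["A", "A", "B", "B", "C", "C"], index=cols)
        res = poisson_group_test(counts, groups, offset=False)
        assert res.iloc[0]["df"] == 2
        assert res.iloc[0]["pvalue"] < 0.05

    def test_single_group_rejected(self):
        counts = pd.DataFrame([[1, 2, 3]], columns=["a1", "a2", "a3"], index=["P0"])
        groups = pd.Series(["A", "A", "A"], index=counts.columns)
        with pytest.raises(StatsPreconditionError):
            poisson_group_test(counts, groups)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_nan_propagates_without_joining_family(self):
        adj = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(adj[1])
        assert adj[0] == pytest.approx(0.02)  # m = 2, not 3

    def test_out_of_range_rejected(self):
        with pytest.raises(SchemaError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=80, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=25)
    )
    def test_matches_hand_step_up_and_is_monotone(self, pvals):
        adj = bh_adjust(pvals)
        assert adj == pytest.approx(bh_by_hand(pvals), abs=1e-12)
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=2, max_size=15),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        adj = bh_adjust(pvals)
        adj_perm = bh_adjust([pvals[i] for i in perm])
        assert adj_perm == pytest.approx([adj[i] for i in perm], abs=1e-12)


class TestPairwiseContrasts:
    def test_direction_up_when_alternative_higher(self):
        counts, groups = two_group_matrix([[10, 11, 9, 20, 21, 19]])
        results, summary = pairwise_contrasts(counts, groups, contrasts=[("A", "B")])
        row = results.iloc[0]
        assert row["significant"] and row["direction"] == "up"
        assert summary.set_index("contrast").loc["B vs A", "n_up"] == 1

    def test_direction_down_when_alternative_lower(self):
        counts, groups = two_group_matrix([[20, 21, 19, 10, 11, 9]])
        results, _ = pairwise_contrasts(counts, groups, contrasts=[("A", "B")])
        assert results.iloc[0]["direction"] == "down"

    def test_zero_variance_both_groups_untestable(self):
        counts, groups = two_group_matrix([[5, 5, 5, 5, 5, 5]])
        results, _ = pairwise_contrasts(counts, groups, contrasts=[("A", "B")])
        assert np.isnan(results.iloc[0]["pvalue"])
        assert not results.iloc[0]["significant"]

    def test_null_matrix_rejects_near_nominal_rate(self):
        rng = np.random.default_rng(14)
        counts, groups = two_group_matrix(rng.poisson(10, size=(800, 6)))
        results, _ = pairwise_contrasts(counts, groups, contrasts=[("A", "B")])
        rate = results["significant"].mean()
        # t-test on Poisson counts at n=3: roughly nominal
        assert rate < 0.1

    def test_unknown_contrast_group_rejected(self):
        counts, groups = two_group_matrix([[1, 2, 3, 4, 5, 6]])
        with pytest.raises(SchemaError):
            pairwise_contrasts(counts, groups, contrasts=[("A", "Z")])
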