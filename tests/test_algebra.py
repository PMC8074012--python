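import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from interarray.algebra import (DirectionalGeneList, assemble_B, build_A1,
                                build_B1, build_B2, build_B3, build_C,
                                build_list5, build_list6, build_list9,
                                build_list10, build_list_A,
                                classify_genes, direction_tallies,
                                directional_overlap, venn_counts)


def dgl(name, *entries, flags=()):
    lst = DirectionalGeneList(name)
    for gene, direction in entries:
        lst.add(gene, direction, flags=flags)
    return lst


UP, DOWN = "induced", "repressed"


class TestDirectionalOverlap:
    def test_same_direction_kept(self):
        out = directional_overlap(dgl("x", ("g", UP)), dgl("y", ("g", UP)),
                                  "same")
        assert out.pairs() == {("g", UP)}

    def test_opposite_modes(self):
        x, y = dgl("x", ("g", UP)), dgl("y", ("g", DOWN))
        assert directional_overlap(x, y, "same").pairs() == set()
        both = directional_overlap(x, y, "opposite")
        assert both.pairs() == {("g", UP), ("g", DOWN)}
        assert directional_overlap(x, y, "opposite", keep="y").pairs() == \
            {("g", DOWN)}

    def test_disjoint_lists_empty_in_all_modes(self):
        x, y = dgl("x", ("a", UP)), dgl("y", ("b", DOWN))
        for mode in ("same", "opposite", "any"):
            assert len(directional_overlap(x, y, mode)) == 0


class TestListConstruction:
    def test_list_A_keeps_merged_entries(self):
        a = build_list_A(dgl("L1", ("g", UP)))
        assert a.name == "A" and ("g", UP) in a

    def test_list_A_empty_input(self):
        assert len(build_list_A(dgl("L1"))) == 0

    def test_splice_discordant_gene_in_both_directions(self):
        l1 = dgl("L1", ("g", UP), ("g", DOWN), flags=("splice_conflict",))
        a = build_list_A(l1)
        assert a.directions_of("g") == {UP, DOWN}

    def test_unflagged_dual_direction_rejected(self):
        with pytest.raises(ValueError, match="both directions"):
            build_list_A(dgl("L1", ("g", UP), ("g", DOWN)))

    def test_A1_same_direction_only(self):
        l1 = dgl("L1", ("g", UP), ("h", UP), ("i", UP))
        l2 = dgl("L2", ("g", UP), ("h", DOWN))
        a1 = build_A1(l1, l2)
        assert a1.pairs() == {("g", UP)}
        # opposite-direction gene lands in L6 instead
        assert build_list6(l1, l2).pairs() == {("h", DOWN)}

    def test_B1_from_treated_insult_only(self):
        l2 = dgl("L2", ("g", UP))
        empty = dgl("e")
        b1 = build_B1(l2, empty, empty, empty, empty, empty)
        assert ("g", UP) in b1

    def test_B1_subtracts_shared_and_insensitive(self):
        l2 = dgl("L2", ("g", UP), ("h", UP))
        l1 = dgl("L1", ("g", UP))
        a1 = build_A1(l1, l2)
        l11 = dgl("L11", ("h", UP))
        b1 = build_B1(l2, dgl("L3"), l1, dgl("L7"), a1, l11)
        assert len(b1) == 0

    def test_B1_subtracts_amplified_entries(self):
        l7 = dgl("L7", ("g", UP))
        l10 = dgl("L10", ("g", UP))
        empty = dgl("e")
        b1 = build_B1(empty, empty, empty, l7, empty, empty, l10=l10)
        assert len(b1) == 0

    def test_B2_members_and_direction(self):
        l3 = dgl("L3", ("g", UP), ("h", UP), ("i", UP))
        l2 = dgl("L2", ("g", DOWN), ("i", DOWN))
        a1 = dgl("A1", ("i", DOWN))
        b2 = build_B2(l2, l3, dgl("L7"), a1, equivalent={"h"})
        # reversal direction is the treatment's modulation (opposite of L3)
        assert ("g", DOWN) in b2      # via opposite overlap
        assert ("h", DOWN) in b2      # via one-color equivalence
        assert ("i", DOWN) not in b2  # removed with A1

    def test_B3_requires_same_sign_direct_contrast(self):
        l3 = dgl("L3", ("g", UP), ("h", UP))
        l7 = dgl("L7", ("g", UP), ("h", UP))
        l2 = dgl("L2", ("g", UP))   # h silent in the direct contrast
        b3 = build_B3(l3, l7, l2, dgl("A1"))
        c = build_C(l3, l7, l2)
        assert b3.pairs() == {("g", UP)}
        assert c.pairs() == {("h", UP)}

    def test_C_requires_same_sense(self):
        l3 = dgl("L3", ("g", DOWN))
        l7 = dgl("L7", ("g", UP))
        assert len(build_C(l3, l7, dgl("L2"))) == 0

    def test_C_ignores_one_color_only_genes(self):
        c = build_C(dgl("L3"), dgl("L7", ("g", UP)), dgl("L2"))
        assert len(c) == 0

    def test_list5_is_gene_level_subtraction(self):
        l2 = dgl("L2", ("g", UP), ("h", UP))
        l3 = dgl("L3", ("g", DOWN))   # any direction removes the gene
        assert build_list5(l2, l3).pairs() == {("h", UP)}

    def test_list9_flips_direction(self):
        l9 = build_list9(dgl("L3", ("g", UP)), {"g"})
        assert l9.pairs() == {("g", DOWN)}

    def test_list10_all_three_same_sign(self):
        l3 = dgl("L3", ("g", UP))
        l7 = dgl("L7", ("g", UP))
        assert build_list10(l3, l7, dgl("L2", ("g", UP))).pairs() == \
            {("g", UP)}
        assert len(build_list10(l3, l7, dgl("L2", ("g", DOWN)))) == 0


class TestAssembleB:
    def test_union_with_provenance(self):
        b = assemble_B(dgl("B1", ("g1", UP)), dgl("B2", ("g2", DOWN)),
                       dgl("B3", ("g3", UP)))
        assert len(b) == 3
        assert "B2" in b.sources("g2", DOWN)

    def test_empty_sublists(self):
        assert len(assemble_B(dgl("B1"), dgl("B2"), dgl("B3"))) == 0

    def test_overlap_is_a_hard_error(self):
        with pytest.raises(AssertionError, match="g"):
            assemble_B(dgl("B1", ("g", UP)), dgl("B2", ("g", UP)),
                       dgl("B3"))


class TestClassification:
    def lists(self):
        return {
            "A": dgl("A", ("mg", UP), ("shared", UP)),
            "A1": dgl("A1", ("shared", UP)),
            "B1": dgl("B1", ("denovo", UP)),
            "B2": dgl("B2", ("rev", DOWN)),
            "B3": dgl("B3", ("amp", UP)),
            "C": dgl("C", ("ins", DOWN)),
        }

    def test_each_entry_gets_expected_category(self):
        out = classify_genes(self.lists(), universe={"mg", "shared",
                                                     "denovo", "rev", "amp",
                                                     "ins", "null"})
        cat = dict(zip(out["gene"], out["category"]))
        assert cat == {"mg": "MG_ONLY", "shared": "SHARED",
                       "denovo": "DE_NOVO", "rev": "REVERSED",
                       "amp": "AMPLIFIED", "ins": "INSENSITIVE",
                       "null": "UNAFFECTED"}

    def test_provenance_lists_every_hit(self):
        out = classify_genes(self.lists(), universe=set())
        row = out[out["gene"] == "shared"].iloc[0]
        assert row["provenance"] == "A1;A"


class TestVennCounts:
    def test_disjoint_lists(self):
        counts = venn_counts({"L1": dgl("L1", ("a", UP)),
                              "L2": dgl("L2", ("b", UP)),
                              "L3": dgl("L3", ("c", UP))})
        overlaps = counts[counts["lists"].str.contains("&")]
        assert (overlaps["n_genes"] == 0).all()

    def test_identical_lists(self):
        counts = venn_counts({k: dgl(k, ("g", UP)) for k in
                              ("L1", "L2", "L3")})
        assert (counts["n_genes"] == 1).all()

    @given(st.lists(st.tuples(st.sampled_from("abcdefgh"),
                              st.sampled_from([UP, DOWN])),
                    max_size=12),
           st.lists(st.tuples(st.sampled_from("abcdefgh"),
                              st.sampled_from([UP, DOWN])),
                    max_size=12),
           st.lists(st.tuples(st.sampled_from("abcdefgh"),
                              st.sampled_from([UP, DOWN])),
                    max_size=12))
    def test_counts_equal_brute_force(self, e1, e2, e3):
        lists = {"L1": dgl("L1", *e1), "L2": dgl("L2", *e2),
                 "L3": dgl("L3", *e3)}
        counts = venn_counts(lists)
        lookup = dict(zip(counts["lists"], counts["n_genes"]))
        genes = {n: {g for g, _ in lst.pairs()} for n, lst in lists.items()}
        for r in (1, 2, 3):
            for combo in itertools.combinations(lists, r):
                expected = sum(
                    1 for g in "abcdefgh"
                    if all(g in genes[n] for n in combo))
                assert lookup["&".join(combo)] == expected


class TestTallies:
    def test_distinct_identity_with_dual_genes(self):
        lst = dgl("A", ("g1", UP), ("g2", DOWN), ("g3", UP), ("g3", DOWN),
                  flags=("biphasic",))
        row = direction_tallies({"A": lst}).iloc[0]
        assert row["n_induced"] == 2
        assert row["n_repressed"] == 2
        assert row["n_dual"] == 1
        assert row["n_distinct"] == 3
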