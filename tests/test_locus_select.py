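import numpy as np
import pytest
from hypothesis import given, strategies as st

import dendropy

from cpedit import (
    AlignmentMatrix,
    concatenate,
    count_pic,
    is_parsimony_informative,
    nj_tree,
    rank_genes_by_pic,
)
from cpedit.errors import FormatError, InputError
from cpedit.locus_select import (
    p_distance_matrix,
    write_nexus,
    write_phylip,
    write_raxml_partitions,
    write_supermatrix_fasta,
)

from _oracles import pic_by_exhaustive_parsimony


def _aln(gene, rows, taxa=None):
    taxa = taxa or [f"t{i}" for i in range(len(rows))]
    return AlignmentMatrix.single_gene(gene, taxa, rows)


class TestPic:
    def test_textbook_informative_column(self):
        assert is_parsimony_informative("AATT") is True

    def test_all_singletons(self):
        assert is_parsimony_informative("ATCG") is False

    def test_gaps_and_n_are_missing(self):
        assert is_parsimony_informative("AA--TT") is True
        assert is_parsimony_informative("AANNT-") is False

    def test_empty_column_rejected(self):
        with pytest.raises(InputError):
            is_parsimony_informative("")

    @given(
        st.integers(min_value=4, max_value=7),
        st.data(),
    )
    def test_matches_exhaustive_parsimony_oracle(self, n_taxa, data):
        column = data.draw(
            st.text(alphabet="ACGT-N", min_size=n_taxa, max_size=n_taxa)
        )
        assert is_parsimony_informative(column) == pic_by_exhaustive_parsimony(column)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            col = "".join(rng.choice(list("ACGT-"), size=6))
            perm = "".join(rng.permutation(list(col)))
            assert is_parsimony_informative(col) == is_parsimony_informative(perm)


class TestRanking:
    def test_constant_gene_not_selected(self):
        aln = _aln("flat", ["AAAA", "AAAA", "AAAA", "AAAA"])
        scores, selected = rank_genes_by_pic({"flat": aln})
        assert scores[0].pic_count == 0 and selected == set()

    def test_forced_ratio(self):
        # 4 informative columns of 10 -> ratio 0.40 > 0.3
        rows = ["AAAACCCCCC", "AAAACCCCCC", "TTTTCCCCCC", "TTTTCCCCCC"]
        scores, selected = rank_genes_by_pic({"g": _aln("g", rows)})
        assert scores[0].pic_count == 4
        assert scores[0].pic_ratio == pytest.approx(0.4)
        assert selected == {"g"}

    def test_strict_vs_inclusive_threshold(self):
        rows = ["AAACCCCCCC", "AAACCCCCCC", "TTTCCCCCCC", "TTTCCCCCCC"]  # ratio 0.3
        _, strict = rank_genes_by_pic({"g": _aln("g", rows)}, threshold=0.3)
        _, incl = rank_genes_by_pic({"g": _aln("g", rows)}, threshold=0.3, inclusive=True)
        assert strict == set() and incl == {"g"}

    def test_ranking_matches_per_column_recount(self):
        rng = np.random.default_rng(17)
        alignments = {}
        for gi in range(5):
            L = int(rng.integers(10, 40))
            rows = ["".join(rng.choice(list("ACGT-"), size=L)) for _ in range(6)]
            alignments[f"g{gi}"] = _aln(f"g{gi}", rows)
        scores, _ = rank_genes_by_pic(alignments)
        for s in scores:
            aln = alignments[s.gene_id]
            recount = sum(
                is_parsimony_informative("".join(r[j] for r in aln.rows))
                for j in range(aln.length)
            )
            assert s.pic_count == recount
        ratios = [s.pic_ratio for s in scores]
        assert ratios == sorted(ratios, reverse=True)


class TestConcatenate:
    def test_two_genes_partitions(self):
        a = _aln("g1", ["ACACAC", "ACACAA"], taxa=["t1", "t2"])
        b = _aln("g2", ["GGGTTTCCC", "GGGTTTCCA"], taxa=["t1", "t2"])
        sm = concatenate({"g1": a, "g2": b}, order=["g1", "g2"])
        assert sm.length == 15
        assert sm.partitions == [("g1", 1, 6), ("g2", 7, 15)]

    def test_missing_taxon_filled_with_gaps(self):
        a = _aln("g1", ["ACACAC", "ACACAA"], taxa=["t1", "t2"])
        b = _aln("g2", ["GGGTTTCCC"], taxa=["t1"])
        sm = concatenate({"g1": a, "g2": b})
        row_t2 = sm.rows[sm.taxa.index("t2")]
        assert row_t2.endswith("-" * 9)

    def test_duplicate_taxon_rejected(self):
        with pytest.raises(FormatError):
            AlignmentMatrix.single_gene("g", ["t1", "t1"], ["AAA", "CCC"])

    def test_pic_total_conserved_under_gene_order_shuffle(self):
        rng = np.random.default_rng(23)
        alignments = {
            f"g{i}": _aln(
                f"g{i}",
                ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(5)],
            )
            for i in range(4)
        }
        order = list(alignments)
        total = sum(count_pic(a) for a in alignments.values())
        for perm in ([3, 1, 0, 2], [2, 0, 3, 1]):
            sm = concatenate(alignments, order=[order[i] for i in perm])
            assert count_pic(sm) == total

    def test_export_formats(self, tmp_path):
        sm = concatenate(
            {
                "g1": _aln("g1", ["ACACAC", "ACACAA"], taxa=["t1", "t2"]),
                "g2": _aln("g2", ["GGG", "GGA"], taxa=["t1", "t2"]),
            }
        )
        write_supermatrix_fasta(sm, tmp_path / "sm.fasta")
        write_phylip(sm, tmp_path / "sm.phy")
        write_nexus(sm, tmp_path / "sm.nex")
        write_raxml_partitions(sm, tmp_path / "sm.part")
        assert (tmp_path / "sm.phy").read_text().splitlines()[0].split() == ["2", "9"]
        assert "charset g2 = 7-9;" in (tmp_path / "sm.nex").read_text()
        assert "DNA, g1 = 1-6" in (tmp_path / "sm.part").read_text()


def _topology(newick: str) -> set[frozenset]:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    taxa = {t.label for t in tree.taxon_namespace}
    splits = set()
    for edge in tree.preorder_edge_iter():
        if edge.bipartition:
            side = {
                t.label
                for t in tree.taxon_namespace
                if edge.bipartition.leafset_bitmask & tree.taxon_namespace.taxon_bitmask(t)
            }
            if 1 < len(side) < len(taxa) - 1:
                splits.add(frozenset(side))
    return splits


class TestNjTree:
    def test_two_cherries_recovered(self):
        base = "ACGT" * 25
        a = base
        b = base[:-1] + "A"
        c = "TGCA" * 25
        d = c[:-1] + "G"
        aln = AlignmentMatrix.single_gene("g", ["A", "B", "C", "D"], [a, b, c, d])
        splits = _topology(nj_tree(aln))
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_identical_sequences_star_with_zero_lengths(self):
        aln = AlignmentMatrix.single_gene("g", ["a", "b", "c", "d"], ["ACGT"] * 4)
        tree = dendropy.Tree.get(data=nj_tree(aln), schema="newick")
        assert all((e.length or 0.0) == pytest.approx(0.0) for e in tree.edges())

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(InputError):
            nj_tree(AlignmentMatrix.single_gene("g", ["a", "b"], ["AC", "AC"]))

    def test_six_taxon_simulated_topology_recovered(self):
        # mutate along a fixed 6-taxon tree at low divergence
        rng = np.random.default_rng(41)
        L = 600

        def mutate(seq, n):
            seq = list(seq)
            for i in rng.choice(len(seq), size=n, replace=False):
                seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
            return "".join(seq)

        root = "".join(rng.choice(list("ACGT"), size=L))
        ab = mutate(root, 30)
        cd = mutate(root, 30)
        ef = mutate(root, 30)
        taxa = {
            "A": mutate(ab, 5),
            "B": mutate(ab, 5),
            "C": mutate(cd, 5),
            "D": mutate(cd, 5),
            "E": mutate(ef, 5),
            "F": mutate(ef, 5),
        }
        aln = AlignmentMatrix.single_gene("g", list(taxa), list(taxa.values()))
        splits = _topology(nj_tree(aln))
        for pair in ({"A", "B"}, {"C", "D"}, {"E", "F"}):
            assert frozenset(pair) in splits

    def test_p_distance_matches_direct_count(self):
        aln = AlignmentMatrix.single_gene(
            "g", ["x", "y", "z"], ["ACGTAC", "ACGTAA", "TTGTAA"]
        )
        d = p_distance_matrix(aln)
        assert d[0, 1] == pytest.approx(1 / 6)
        assert d[0, 2] == pytest.approx(3 / 6)
        assert d[1, 2] == pytest.approx(2 / 6)
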