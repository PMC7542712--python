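"""Gene-tree/table parsing, validation, pruning, and indfile round trips."""

import numpy as np
import pytest

from copolphase.search import AllelePartition
from copolphase.treeio import (
    TreeParseError,
    ValidationError,
    parse_accession_table,
    parse_gene_trees,
    prune_nonfocal_polyploids,
    read_indfile,
    write_accession_table,
    write_gene_trees,
    write_indfile,
)

from conftest import gts_from_newicks, t


class TestParseGeneTrees:
    def test_single_tree_single_locus(self, tmp_path):
        path = tmp_path / "trees.nwk"
        path.write_text("((a1,a2),(b1,b2));\n")
        gts = parse_gene_trees(path)
        assert gts.loci == ["L1"]
        assert gts.n_trees == 1
        assert gts.allele_universe == {"a1", "a2", "b1", "b2"}

    def test_leaf_set_mismatch_within_locus_rejected(self, tmp_path):
        path = tmp_path / "trees.nwk"
        path.write_text("((a,b),(c,d));\n((a,b),(c,e));\n")
        with pytest.raises(ValidationError, match="L1"):
            parse_gene_trees(path, loci_spec=2)

    def test_posterior_sample_layout_10x100(self, tmp_path):
        path = tmp_path / "trees.nwk"
        path.write_text("((a,b),(c,d));\n" * 1000)
        gts = parse_gene_trees(path, loci_spec=100)
        assert len(gts.loci) == 10
        assert gts.n_trees == 1000

    def test_unrooted_tree_rejected_not_rerooted(self, tmp_path):
        path = tmp_path / "trees.nwk"
        path.write_text("(a,b,(c,d));\n")
        with pytest.raises(ValidationError, match="[Uu]nrooted"):
            parse_gene_trees(path)

    def test_malformed_newick_reports_line(self, tmp_path):
        path = tmp_path / "trees.nwk"
        path.write_text("((a,b),(c,d));\n((a,b),(c,d);\n")
        with pytest.raises(TreeParseError, match="line 2"):
            parse_gene_trees(path, loci_spec=[("L1", 2)])

    def test_duplicate_leaf_rejected(self, tmp_path):
        path = tmp_path / "trees.nwk"
        path.write_text("((a,a),(c,d));\n")
        with pytest.raises((TreeParseError, ValidationError), match="uplicate"):
            parse_gene_trees(path)

    def test_roundtrip(self, tmp_path):
        gts = gts_from_newicks({
            "locA": ["((x_1,y_1),(z_1,w_1));", "((x_1,z_1),(y_1,w_1));"],
            "locB": ["(((x_1,y_1),z_1),w_1);"],
        })
        path = tmp_path / "out.nwk"
        spec = write_gene_trees(gts, path)
        back = parse_gene_trees(path, loci_spec=spec)
        assert back.loci == gts.loci
        for locus in gts.loci:
            for t1, t2 in zip(gts.trees_by_locus[locus], back.trees_by_locus[locus]):
                assert {l.taxon.label for l in t1.leaf_node_iter()} == {
                    l.taxon.label for l in t2.leaf_node_iter()
                }


class TestAccessionTable:
    def test_parse_basic_rows(self, tmp_path):
        path = tmp_path / "tab.tsv"
        path.write_text(
            "acc1\tTaxA\t2\tL1\ta1,a2\n"
            "acc9\tPolyX\t4\tL1\tx1,x2,x3,x4\n"
        )
        tab = parse_accession_table(path)
        assert tab.records[0].ploidy == 2
        assert tab.records[1].alleles["L1"] == ["x1", "x2", "x3", "x4"]
        assert tab.polyploid_taxa == ["PolyX"]

    @pytest.mark.parametrize("row,msg", [
        ("acc1\tTaxA\t3\tL1\ta1,a2", "ploidy"),
        ("acc1\tTaxA\t4\tL1\ta1,a2,a3,a4,a5", "exceed ploidy"),
    ])
    def test_invalid_rows_rejected(self, tmp_path, row, msg):
        path = tmp_path / "tab.tsv"
        path.write_text(row + "\n")
        with pytest.raises(ValidationError, match=msg):
            parse_accession_table(path)

    def test_duplicate_allele_across_accessions_rejected(self, tmp_path):
        path = tmp_path / "tab.tsv"
        path.write_text("acc1\tA\t2\tL1\ta1,a2\nacc2\tB\t2\tL1\ta2,b2\n")
        with pytest.raises(ValidationError, match="a2"):
            parse_accession_table(path)

    def test_roundtrip(self, tmp_path, toy_table):
        path = tmp_path / "tab.tsv"
        write_accession_table(toy_table, path)
        back = parse_accession_table(path)
        assert [(r.accession_id, r.taxon_id, r.ploidy, r.alleles)
                for r in back.records] == [
            (r.accession_id, r.taxon_id, r.ploidy, r.alleles)
            for r in toy_table.records
        ]


def _rooted_clades(tree):
    out = set()
    for node in tree.postorder_internal_node_iter():
        out.add(frozenset(l.taxon.label for l in node.leaf_iter()))
    return out


class TestPruneNonfocalPolyploids:
    def test_identity_when_no_other_polyploids(self, toy_gts, toy_table):
        assert prune_nonfocal_polyploids(toy_gts, toy_table, "X") is toy_gts

    def test_other_polyploid_leaves_removed(self):
        from copolphase.treeio import AccessionRecord, AccessionTable

        tab = AccessionTable(records=[
            AccessionRecord("aX", "X", 4, {"L1": ["x1"]}),
            AccessionRecord("aY", "Y", 4, {"L1": ["y1"]}),
            AccessionRecord("aA", "A", 2, {"L1": ["a1", "a2"]}),
        ]).validate()
        gts = gts_from_newicks({"L1": ["((x1,y1),(a1,a2));"]})
        pruned = prune_nonfocal_polyploids(gts, tab, "X")
        assert pruned.allele_universe == {"x1", "a1", "a2"}

    def test_topology_preserved_matches_leaf_restriction(self):
        """Pruned tree's clades equal the restriction of the original's."""
        from copolphase.treeio import AccessionRecord, AccessionTable

        nw = ("(((x1,(y1,a1)),((y2,a2),(x2,b1))),"
              "(((y3,c1),(x3,c2)),((y4,d1),(x4,d2))));")
        keep = {"x1", "x2", "x3", "x4", "a1", "a2", "b1", "c1", "c2", "d1", "d2"}
        tab = AccessionTable(records=[
            AccessionRecord("aX", "X", 8,
                            {"L1": ["x1", "x2", "x3", "x4"]}),
            AccessionRecord("aY", "Y", 8,
                            {"L1": ["y1", "y2", "y3", "y4"]}),
            AccessionRecord("aA", "A", 2, {"L1": ["a1", "a2"]}),
            AccessionRecord("aB", "B", 2, {"L1": ["b1"]}),
            AccessionRecord("aC", "C", 2, {"L1": ["c1", "c2"]}),
            AccessionRecord("aDD", "D", 2, {"L1": ["d1", "d2"]}),
        ]).validate()
        gts = gts_from_newicks({"L1": [nw]})
        pruned = prune_nonfocal_polyploids(gts, tab, "X")
        tree = pruned.trees_by_locus["L1"][0]
        assert {l.taxon.label for l in tree.leaf_node_iter()} == keep
        # independent restriction: intersect original clades with kept leaves
        original = gts_from_newicks({"L1": [nw]}).trees_by_locus["L1"][0]
        expected = {c & frozenset(keep) for c in _rooted_clades(original)}
        expected = {c for c in expected if len(c) > 1}
        assert _rooted_clades(tree) <= expected

    def test_idempotent(self):
        from copolphase.treeio import AccessionRecord, AccessionTable

        tab = AccessionTable(records=[
            AccessionRecord("aX", "X", 4, {"L1": ["x1", "x2"]}),
            AccessionRecord("aY", "Y", 4, {"L1": ["y1", "y2"]}),
            AccessionRecord("aA", "A", 2, {"L1": ["a1", "a2"]}),
        ]).validate()
        gts = gts_from_newicks({"L1": ["(((x1,y1),(x2,y2)),(a1,a2));"]})
        once = prune_nonfocal_polyploids(gts, tab, "X")
        twice = prune_nonfocal_polyploids(once, tab, "X")
        assert {l.taxon.label for l in once.trees_by_locus["L1"][0].leaf_node_iter()} == {
            l.taxon.label for l in twice.trees_by_locus["L1"][0].leaf_node_iter()
        }

    def test_error_when_pruning_leaves_too_few(self):
        from copolphase.treeio import AccessionRecord, AccessionTable

        tab = AccessionTable(records=[
            AccessionRecord("aX", "X", 4, {"L1": ["x1"]}),
            AccessionRecord("aY", "Y", 4, {"L1": ["y1", "y2", "y3"]}),
        ]).validate()
        gts = gts_from_newicks({"L1": ["((y1,y2),(y3,x1));"]})
        with pytest.raises(ValidationError, match="<2 leaves"):
            prune_nonfocal_polyploids(gts, tab, "X")


class TestIndfile:
    def _partitions(self, n, alleles=("a", "b", "c", "d"), k=2, seed=0):
        import random

        rng = random.Random(seed)
        return [
            AllelePartition("X", k, {a: rng.randrange(k) + 1 for a in alleles})
            for _ in range(n)
        ]

    def test_blocks_rows_columns(self, tmp_path):
        parts = self._partitions(2)
        path = tmp_path / "f.indfile"
        write_indfile(parts, path)
        mats, alleles = read_indfile(path)
        assert len(mats) == 2
        assert mats[0].shape == (4, 2)
        assert alleles == ["a", "b", "c", "d"]
        for m in mats:
            assert np.all(m.sum(axis=1) == 1)

    def test_single_partition_binary(self, tmp_path):
        path = tmp_path / "f.indfile"
        write_indfile(self._partitions(1), path)
        mats, _ = read_indfile(path)
        assert len(mats) == 1
        assert set(np.unique(mats[0])) <= {0.0, 1.0}

    def test_96_replicates(self, tmp_path):
        path = tmp_path / "f.indfile"
        write_indfile(self._partitions(96), path)
        mats, _ = read_indfile(path)
        assert len(mats) == 96

    def test_inconsistent_allele_sets_rejected(self, tmp_path):
        parts = self._partitions(1) + [
            AllelePartition("X", 2, {"a": 1, "b": 2, "c": 1, "e": 2})
        ]
        with pytest.raises(ValidationError):
            write_indfile(parts, tmp_path / "f.indfile")
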