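import itertools

import numpy as np
import pytest

from mitocomp import gene_content as gcx
from mitocomp import genome_io as gio
from mitocomp.genome_io import Feature, GenomeRecord, Interval


def record_with_genes(rid, genes, kind="CDS"):
    seq = "A" * (10 * max(1, len(genes)) + 10)
    feats = [Feature(kind=kind, name=g, intervals=[Interval(10 * i, 10 * i + 9, 1)])
             for i, g in enumerate(genes)]
    return GenomeRecord(id=rid, sequence=seq, features=feats)


class TestNormalize:
    def test_case_and_suffix(self):
        assert gcx.normalize_gene_name("Rps3_a") == "rps3"
        assert gcx.normalize_gene_name("NAD4L") == "nad4l"

    def test_synonyms_applied_once(self):
        syn = {"yejr": "ccmf"}
        assert gcx.normalize_gene_name("yejR", syn) == "ccmf"
        assert gcx.normalize_gene_name("ccmF", syn) == "ccmf"


class TestPresenceMatrix:
    def test_identical_records_identical_rows(self):
        a = record_with_genes("a", ["cob", "cox1"])
        b = record_with_genes("b", ["cob", "cox1"])
        m = gcx.build_presence_matrix([a, b])
        assert (m.present[0] == m.present[1]).all()

    def test_split_gene_collapses(self):
        rec = record_with_genes("t", ["rps3_a", "rps3_b"])
        m = gcx.build_presence_matrix([rec])
        assert m.genes == ["rps3"]
        assert m.gene_set("t") == {"rps3"}

    def test_orfs_excluded(self):
        rec = record_with_genes("t", ["cob"])
        rec.features.append(Feature(kind="ORF", name="orf123",
                                    intervals=[Interval(50, 60, 1)]))
        m = gcx.build_presence_matrix([rec])
        assert m.genes == ["cob"]


# ---------------------------------------------------------------------------
# Dollo oracle: exhaustive minimal loss-edge search

def all_edges(tree):
    return [n for n in tree.preorder_node_iter() if n.parent_node is not None]


def leaves_under(node):
    return {l.taxon.label for l in node.leaf_iter()}


def min_losses_brute(tree, holders, gain_node):
    """Minimum number of loss edges reproducing the leaf pattern, with a
    single gain at ``gain_node`` and losses only below it."""
    scope = [n for n in gain_node.preorder_iter() if n is not gain_node]
    in_gain = leaves_under(gain_node)
    if not holders <= in_gain:
        raise AssertionError("gain node does not cover holders")
    for k in range(len(scope) + 1):
        for subset in itertools.combinations(scope, k):
            lost = set()
            for e in subset:
                lost |= leaves_under(e)
            # a leaf has the gene iff under the gain and under no loss edge
            pattern = in_gain - lost
            # disallow nested losses (same gene twice on a path)
            nested = any(leaves_under(a) < leaves_under(b)
                         for a in subset for b in subset if a is not b)
            if pattern == holders and not nested:
                return k
    raise AssertionError("unreachable")


@pytest.mark.parametrize("newick", [
    "((A,B),(C,D));",
    "(((A,B),C),(D,(E,F)));",
    "((A,B,C),(D,E));",          # polytomy
    "(A,(B,(C,(D,E))));",
])
def test_dollo_matches_brute_force_on_all_patterns(newick):
    tree = gio.read_tree(newick)
    labels = sorted(gio.leaf_labels(tree))
    for bits in range(1, 2 ** len(labels)):
        holders = {l for i, l in enumerate(labels) if bits >> i & 1}
        present = np.array([[l in holders] for l in labels], dtype=bool)
        m = gcx.PresenceMatrix(taxa=labels, genes=["g"], present=present)
        # forced root (ancestral set)
        lm = gcx.dollo_map(m, tree, ancestral_set={"g"})
        exp = min_losses_brute(tree, holders, tree.seed_node)
        assert lm.total_losses() == exp, (newick, holders)
        # gain at LCA (no ancestral set)
        lm2 = gcx.dollo_map(m, tree)
        gain = gcx._lca_of(tree, holders)
        exp2 = min_losses_brute(tree, holders, gain)
        assert lm2.total_losses() == exp2, (newick, holders)


class TestDolloExamples:
    def test_gene_in_all_leaves_no_losses(self):
        tree = gio.read_tree("((A,B),(C,D));")
        m = gcx.PresenceMatrix(taxa=list("ABCD"), genes=["g"],
                               present=np.ones((4, 1), dtype=bool))
        assert gcx.dollo_map(m, tree, ancestral_set={"g"}).total_losses() == 0

    def test_single_loss_on_sister_clade(self):
        tree = gio.read_tree("((A,B),(C,D));")
        m = gcx.PresenceMatrix(taxa=list("ABCD"), genes=["g"],
                               present=np.array([[1], [1], [0], [0]], bool))
        lm = gcx.dollo_map(m, tree, ancestral_set={"g"})
        (branch, genes), = lm.per_branch.items()
        node = next(n for n in tree.preorder_node_iter() if n.label == branch)
        assert leaves_under(node) == {"C", "D"}
        assert genes == {"g"}

    def test_missing_leaf_in_matrix_is_error(self):
        tree = gio.read_tree("((A,B),(C,E));")
        m = gcx.PresenceMatrix(taxa=list("ABCD"), genes=["g"],
                               present=np.ones((4, 1), dtype=bool))
        with pytest.raises(ValueError, match="E"):
            gcx.dollo_map(m, tree)

    def test_leaf_consistency_sets(self):
        tree = gio.read_tree("((A,B),(C,D));")
        m = gcx.PresenceMatrix(taxa=list("ABCD"), genes=["g", "h"],
                               present=np.array([[1, 0], [1, 1], [0, 1], [0, 1]],
                                                bool))
        lm = gcx.dollo_map(m, tree, ancestral_set={"g", "h"})
        for leaf in "ABCD":
            assert lm.ancestral_sets.get(leaf, set()) == m.gene_set(leaf)


class TestMissingGeneReport:
    def test_self_is_empty(self):
        rec = record_with_genes("t", ["a", "b"])
        r = gcx.missing_gene_report(rec, rec)
        assert r.proteins == [] and r.trnas == []

    def test_hand_set_difference(self):
        q = record_with_genes("q", ["a", "b", "c"])
        ref = record_with_genes("r", ["a", "b", "c", "d", "e"])
        assert gcx.missing_gene_report(q, ref).proteins == ["d", "e"]

    def test_trnas_reported_separately(self):
        q = record_with_genes("q", ["cob"])
        ref = record_with_genes("r", ["cob"])
        ref.features.append(Feature(kind="tRNA", name="trnW",
                                    intervals=[Interval(30, 40, 1)]))
        r = gcx.missing_gene_report(q, ref)
        assert r.proteins == [] and r.trnas == ["trnw"]
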