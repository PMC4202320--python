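import itertools

import numpy as np
import pytest

from mitocomp.genome_io import GeneOrder
from mitocomp.synteny import cluster_presence, shared_blocks


def order(taxon, names, circ=True, strands=None):
    strands = strands or [1] * len(names)
    return GeneOrder(taxon, list(zip(names, strands)), circ)


# ---------------------------------------------------------------------------
# Brute-force oracle: all maximal common circular substrings

def circular_slices(genes, circular):
    n = len(genes)
    out = set()
    max_len = n if circular else n
    for i in range(n):
        for L in range(1, n + 1):
            if not circular and i + L > n:
                continue
            out.add((i, L))
    return out


def slice_of(genes, i, L, circular):
    n = len(genes)
    if circular:
        return tuple(genes[(i + k) % n] for k in range(L))
    return tuple(genes[i:i + L])


def occurs(sub, genes, circular):
    n = len(genes)
    for j in range(n):
        if not circular and j + len(sub) > n:
            continue
        if slice_of(genes, j, len(sub), circular) == sub:
            return True
    return False


def flip(genes):
    return tuple((g, -s) for g, s in reversed(genes))


def oracle_blocks(a, b, min_block):
    """All maximal (genes, orientation) shared runs by exhaustive search."""
    found = set()
    for mode, bb in (("same", tuple(b.genes)), ("inverted", flip(b.genes))):
        for i, L in circular_slices(a.genes, a.circular):
            if L < min_block or L > len(b.genes):
                continue
            sub = slice_of(a.genes, i, L, a.circular)
            if not occurs(sub, list(bb), b.circular):
                continue
            # maximal: no extension on either side also occurs
            if L < len(a.genes) and L < len(b.genes):
                left = slice_of(a.genes, (i - 1) % len(a.genes), L + 1, a.circular) \
                    if (a.circular or i > 0) else None
                right = slice_of(a.genes, i, L + 1, a.circular) \
                    if (a.circular or i + L < len(a.genes)) else None
                if left and occurs(left, list(bb), b.circular):
                    continue
                if right and occurs(right, list(bb), b.circular):
                    continue
            names = tuple(g for g, _ in sub)
            found.add((names, mode))
    return found


class TestSharedBlocksExamples:
    def test_identical_circular_orders_single_full_block(self):
        names = [f"x{i}" for i in range(6)]
        blocks = shared_blocks(order("a", names), order("b", names))
        assert len(blocks) == 1
        assert blocks[0].genes == tuple(names)
        assert blocks[0].orientation == "same"

    def test_transposition_leaves_wrapped_block(self):
        a = order("a", ["x1", "x2", "x3", "x4", "x5"])
        b = order("b", ["x1", "x3", "x2", "x4", "x5"])
        blocks = shared_blocks(a, b, min_block=2)
        assert [blk.genes for blk in blocks] == [("x4", "x5", "x1")]

    def test_inverted_block_requires_flipped_strands(self):
        a = order("a", ["x1", "x2", "x3"], circ=False)
        flipped = GeneOrder("b", [("x3", -1), ("x2", -1), ("x1", -1)], False)
        same_strands = GeneOrder("b", [("x3", 1), ("x2", 1), ("x1", 1)], False)
        assert [b.orientation for b in shared_blocks(a, flipped)] == ["inverted"]
        assert shared_blocks(a, same_strands) == []

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        names = [f"g{i}" for i in range(8)]
        for _ in range(5):
            pa = list(rng.permutation(names))
            pb = list(rng.permutation(names))
            ab = {(b.genes, b.orientation) for b in
                  shared_blocks(order("a", pa), order("b", pb))}
            ba = {(b.genes, b.orientation) for b in
                  shared_blocks(order("b", pb), order("a", pa))}
            # a block of (a,b) appears in (b,a) with the same gene content,
            # possibly traversed from the other end when inverted
            def canon(s):
                return {(min(g, g[::-1]), o) for g, o in s}
            assert canon(ab) == canon(ba)

    def test_empty_order(self):
        assert shared_blocks(order("a", []), order("b", ["x"])) == []


@pytest.mark.parametrize("n,seed", [(5, 1), (8, 2), (10, 3), (12, 4)])
def test_blocks_match_brute_force_oracle(n, seed):
    rng = np.random.default_rng(seed)
    names = [f"g{i}" for i in range(n)]
    for trial in range(6):
        pa = list(rng.permutation(names))
        pb = list(rng.permutation(names))
        sa = [int(s) for s in rng.choice([1, -1], size=n)]
        sb = [int(s) for s in rng.choice([1, -1], size=n)]
        a = order("a", pa, strands=sa)
        b = order("b", pb, strands=sb)
        got = {(blk.genes, blk.orientation)
               for blk in shared_blocks(a, b, min_block=2)}
        want = {x for x in oracle_blocks(a, b, 2)}
        assert got == want, (pa, pb, sa, sb)


class TestClusterPresence:
    CLUSTER = ["rpl14", "rpl5", "rps14", "rps8", "rpl6"]

    def test_intact_verbatim(self):
        o = order("t", ["cob"] + self.CLUSTER + ["cox1"])
        hit = cluster_presence([o], self.CLUSTER)["t"]
        assert hit.status == "intact"
        assert hit.interrupting == ()

    def test_interrupted_run_reports_inserted_genes(self):
        o = order("t", ["cob", "rpl14", "rpl5", "atp1", "orf9",
                        "rps14", "rps8", "rpl6", "cox1"])
        hit = cluster_presence([o], self.CLUSTER)["t"]
        assert hit.status == "partial"
        assert set(hit.interrupting) == {"atp1", "orf9"}
        hit_k = cluster_presence([o], self.CLUSTER, k_insertions=2)["t"]
        assert hit_k.status == "intact"

    def test_scattered_is_absent(self):
        o = order("t", ["rpl14", "x1", "rps14", "x2", "rpl6", "x3",
                        "rps8", "x4", "rpl5", "x5"])
        assert cluster_presence([o], self.CLUSTER)["t"].status == "absent"

    def test_reverse_reading_direction_counts(self):
        o = order("t", ["cox1"] + list(reversed(self.CLUSTER)) + ["cob"])
        assert cluster_presence([o], self.CLUSTER)["t"].status == "intact"
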