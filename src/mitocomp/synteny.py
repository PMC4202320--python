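"""Gene-order synteny at the gene-name level.

Synteny between (possibly circular) mitochondrial genomes is computed on
normalized gene-name orders rather than nucleotide alignments: a shared
block is a maximal run of genes occurring consecutively (circularly) in
both orders, either in identical order with identical relative
orientations, or in exactly reversed order with flipped orientations
(an inverted block).
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import GeneOrder

Gene = tuple[str, int]


@dataclass(frozen=True)
class SyntenyBlock:
    genes: tuple[str, ...]
    pos_a: tuple[int, int]   # (start index in a, length)
    pos_b: tuple[int, int]   # (start index in b, length); for inverted blocks
    orientation: str         # "same" | "inverted"

    def __len__(self) -> int:
        return len(self.genes)


def _full_cycle_blocks(a: list[Gene], b: list[Gene], inverted: bool,
                       b_len: int) -> list[SyntenyBlock]:
    n = len(a)
    out = []
    if n != len(b) or n == 0:
        return out
    for d in range(n):
        if all(a[k] == b[(k + d) % n] for k in range(n)):
            out.append(_make_block(a, 0, d, n, inverted, b_len))
    return out


def _make_block(a: list[Gene], i: int, j: int, L: int, inverted: bool,
                b_len: int) -> SyntenyBlock:
    genes = tuple(a[(i + k) % len(a)][0] for k in range(L))
    if inverted:
        # j indexes the reversed+flipped copy of b; map back to original b:
        # reversed index j corresponds to original b_len-1-j, and the run
        # extends backwards in original coordinates.
        start_orig = (b_len - 1 - (j + L - 1)) % b_len
        pos_b = (start_orig, L)
    else:
        pos_b = (j, L)
    return SyntenyBlock(genes=genes, pos_a=(i, L), pos_b=pos_b,
                        orientation="inverted" if inverted else "same")


def _runs(a: list[Gene], b: list[Gene], a_circ: bool, b_circ: bool,
          inverted: bool, b_len: int) -> list[SyntenyBlock]:
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return []
    out: list[SyntenyBlock] = []
    if a_circ and b_circ:
        cycles = _full_cycle_blocks(a, b, inverted, b_len)
        if cycles:
            return cycles
    maxlen = min(n, m)
    for i in range(n):
        for j in range(m):
            if a[i] != b[j]:
                continue
            pi = (i - 1) % n if a_circ else i - 1
            pj = (j - 1) % m if b_circ else j - 1
            if pi >= 0 and pj >= 0 and a[pi] == b[pj]:
                continue  # not a maximal start
            L = 1
            while L < maxlen:
                ni = i + L if not a_circ else (i + L) % n
                nj = j + L if not b_circ else (j + L) % m
                if ni >= n or nj >= m:
                    break
                if a[ni] != b[nj]:
                    break
                L += 1
            out.append(_make_block(a, i, j, L, inverted, b_len))
    return out


def _flip(order: list[Gene]) -> list[Gene]:
    return [(g, -s) for g, s in reversed(order)]


def shared_blocks(a: GeneOrder, b: GeneOrder, min_block: int = 2,
                  ) -> list[SyntenyBlock]:
    """All maximal shared (circular) gene runs of length >= ``min_block``.

    Forward blocks require identical gene order and orientations; inverted
    blocks require exactly reversed order with flipped orientations.
    Duplicate gene names are allowed and each occurrence is distinct.
    """
    ga, gb = list(a.genes), list(b.genes)
    blocks: list[SyntenyBlock] = []
    seen: set[tuple] = set()
    for inverted, gb_view in ((False, gb), (True, _flip(gb))):
        for blk in _runs(ga, gb_view, a.circular, b.circular, inverted, len(gb)):
            if len(blk) < min_block:
                continue
            key = (blk.genes, blk.pos_a, blk.pos_b, blk.orientation)
            if key not in seen:
                seen.add(key)
                blocks.append(blk)
    # an inverted block identical to a forward block (palindrome) is rare in
    # gene orders; both are reported if genuinely maximal
    blocks.sort(key=lambda blk: (-len(blk), blk.pos_a))
    return blocks


# ---------------------------------------------------------------------------
# Named-cluster conservation

@dataclass
class ClusterHit:
    taxon: str
    status: str               # "intact" | "partial" | "absent"
    matched: tuple[str, ...]  # cluster genes found in the best run
    interrupting: tuple[str, ...]  # non-cluster genes inside the span


def _scan_direction(names: list[str], circular: bool, cluster: list[str],
                    k_insertions: int) -> tuple[str, tuple, tuple]:
    """Best status for one reading direction of one order."""
    n = len(names)
    cset = set(cluster)
    limit = n if not circular else 2 * n
    doubled = names + names if circular else names
    best = ("absent", (), ())

    def better(a, b):
        rank = {"absent": 0, "partial": 1, "intact": 2}
        if rank[a[0]] != rank[b[0]]:
            return a if rank[a[0]] > rank[b[0]] else b
        return a if len(a[1]) >= len(b[1]) else b

    # intact: cluster as an in-order subsequence within a window, counting
    # interleaved non-cluster genes as insertions
    for start in range(n):
        if doubled[start] != cluster[0]:
            continue
        ci = 1
        inserted: list[str] = []
        pos = start + 1
        while ci < len(cluster) and pos < limit and pos - start < n:
            g = doubled[pos]
            if g == cluster[ci]:
                ci += 1
            elif g in cset:
                break  # cluster gene out of order: not this occurrence
            else:
                inserted.append(g)
            pos += 1
        if ci == len(cluster):
            if len(inserted) <= k_insertions:
                cand = ("intact", tuple(cluster), tuple(inserted))
            else:
                cand = ("partial", tuple(cluster), tuple(inserted))
            best = better(cand, best)
    # partial: longest strictly-consecutive sub-run (no insertions)
    for start in range(n):
        for ci in range(len(cluster)):
            L = 0
            while (L < len(cluster) - ci and start + L < limit
                   and L < n and doubled[start + L] == cluster[ci + L]):
                L += 1
            if L >= 2:
                cand = ("partial", tuple(cluster[ci:ci + L]), ())
                best = better(best, cand)
    return best


def cluster_presence(orders: list[GeneOrder], cluster: list[str],
                     k_insertions: int = 0) -> dict[str, ClusterHit]:
    """Classify each taxon's order as intact / partial / absent for a cluster.

    Intact means all cluster genes occur consecutively in cluster order
    (circularly, in either reading direction) with at most ``k_insertions``
    interleaved foreign genes; partial means a contiguous sub-run of length
    >= 2 survives, or the whole cluster is present but interrupted by more
    than ``k_insertions`` foreign genes (these are reported by name).
    """
    out: dict[str, ClusterHit] = {}
    for order in orders:
        names = order.names()
        results = []
        for direction in (cluster, list(reversed(cluster))):
            results.append(_scan_direction(names, order.circular, direction,
                                           k_insertions))
        rank = {"absent": 0, "partial": 1, "intact": 2}
        best = max(results, key=lambda r: (rank[r[0]], len(r[1])))
        out[order.taxon] = ClusterHit(taxon=order.taxon, status=best[0],
                                      matched=best[1], interrupting=best[2])
    return out
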