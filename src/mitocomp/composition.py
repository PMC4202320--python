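"""Sequence- and annotation-level composition descriptors.

Covers the whole-genome summary row (AT content by region class, AT/GC
skew, size portions, largest noncoding run), positional GC of coding
sequences, pooled amino-acid p-distances and tRNA acceptor-stem checks.

Conventions: skews are computed on the deposited strand over the full
molecule; N bases are excluded from every denominator; when features
overlap, positions are classified with precedence protein-coding > RNA >
noncoding so that the three size portions always form a true partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import genetic_code as gc
from .genome_io import GenomeRecord

PCG_KINDS = ("CDS", "ORF")
RNA_KINDS = ("tRNA", "rRNA")


@dataclass
class CompositionProfile:
    size: int
    at_overall: float
    at_pcg: float | None
    at_rna: float | None
    at_noncoding: float | None
    at_skew: float
    gc_skew: float
    portion_pcg: float
    portion_rna: float
    portion_noncoding: float
    largest_noncoding_bp: int

    @property
    def coding_fraction(self) -> float:
        """Fraction of the molecule annotated as coding (protein + RNA)."""
        return self.portion_pcg + self.portion_rna


def _at_fraction(seq: np.ndarray, mask: np.ndarray | None = None) -> float | None:
    """AT/(A+C+G+T) over masked positions; None if no unambiguous base."""
    s = seq if mask is None else seq[mask]
    n_at = np.count_nonzero((s == b"A") | (s == b"T"))
    n_acgt = np.count_nonzero(s != b"N")
    if n_acgt == 0:
        return None
    return n_at / n_acgt


def _skews(seq: np.ndarray) -> tuple[float, float]:
    a = np.count_nonzero(seq == b"A")
    t = np.count_nonzero(seq == b"T")
    g = np.count_nonzero(seq == b"G")
    c = np.count_nonzero(seq == b"C")
    at_skew = (a - t) / (a + t) if (a + t) else 0.0
    gc_skew = (g - c) / (g + c) if (g + c) else 0.0
    return at_skew, gc_skew


def _class_array(record: GenomeRecord) -> np.ndarray:
    """Per-position class labels: 0 noncoding, 1 protein-coding, 2 RNA.

    Wrap-aware: a feature interval is applied modulo the length on circular
    records. Precedence protein-coding > RNA.
    """
    L = len(record)
    cls = np.zeros(L, dtype=np.int8)
    for kinds, label in ((RNA_KINDS, 2), (PCG_KINDS, 1)):
        for f in record.features_of_kind(*kinds):
            for iv in f.intervals:
                if iv.end <= L:
                    cls[iv.start:iv.end] = label
                elif record.circular:
                    cls[iv.start:L] = label
                    cls[0:iv.end % L] = label
                else:
                    raise ValueError(f"feature {f.name!r} wraps a linear record")
    return cls


def _longest_zero_run(cls: np.ndarray, circular: bool) -> int:
    """Longest run of noncoding positions, joined across the origin if circular."""
    if np.all(cls == 0):
        return len(cls)
    if np.all(cls != 0):
        return 0
    zero = (cls == 0).astype(np.int8)
    # split on annotated positions, measure runs
    edges = np.flatnonzero(np.diff(np.concatenate(([0], zero, [0]))))
    runs = edges[1::2] - edges[::2]
    best = int(runs.max()) if runs.size else 0
    if circular and zero[0] and zero[-1]:
        head = int(np.argmax(zero == 0))
        tail = int(np.argmax(zero[::-1] == 0))
        best = max(best, head + tail)
    return best


def composition_profile(record: GenomeRecord) -> CompositionProfile:
    """Whole-genome composition summary for one record."""
    seq = np.frombuffer(record.sequence.encode(), dtype="S1")
    at_skew, gc_skew = _skews(seq)
    if not record.features:
        warnings.warn(f"{record.id}: no features; size portions are 0/0/1")
        cls = np.zeros(len(record), dtype=np.int8)
    else:
        cls = _class_array(record)
    L = len(record)
    n_pcg = int(np.count_nonzero(cls == 1))
    n_rna = int(np.count_nonzero(cls == 2))
    n_non = L - n_pcg - n_rna
    return CompositionProfile(
        size=L,
        at_overall=_at_fraction(seq),
        at_pcg=_at_fraction(seq, cls == 1),
        at_rna=_at_fraction(seq, cls == 2),
        at_noncoding=_at_fraction(seq, cls == 0),
        at_skew=at_skew, gc_skew=gc_skew,
        portion_pcg=n_pcg / L, portion_rna=n_rna / L,
        portion_noncoding=n_non / L,
        largest_noncoding_bp=_longest_zero_run(cls, record.circular),
    )


# ---------------------------------------------------------------------------
# Positional GC

@dataclass
class PositionalGC:
    gc_overall: float
    gc1: float
    gc2: float
    gc3: float
    gc3s: float
    heterogeneity: tuple[float, float, float]


def positional_gc(cds: str, code: int = 1) -> PositionalGC:
    """GC content at the three codon positions, plus GC3s.

    GC3s is restricted to third positions of codons from synonymously
    variable families: codons of single-codon amino acids and stop codons
    are excluded under the declared code. Codons containing N are skipped.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    pos_gc = [0, 0, 0]
    pos_n = [0, 0, 0]
    syn_gc = 0
    syn_n = 0
    syn_universe = gc.synonymous_codons(code)
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        for p, b in enumerate(codon):
            if b in "GC":
                pos_gc[p] += 1
                pos_n[p] += 1
            elif b in "AT":
                pos_n[p] += 1
        if codon in syn_universe:
            syn_n += 1
            if codon[2] in "GC":
                syn_gc += 1
    if not any(pos_n):
        raise ValueError("empty or all-ambiguous coding sequence")
    gc123 = [g / n if n else 0.0 for g, n in zip(pos_gc, pos_n)]
    overall = sum(pos_gc) / sum(pos_n)
    return PositionalGC(
        gc_overall=overall, gc1=gc123[0], gc2=gc123[1], gc3=gc123[2],
        gc3s=(syn_gc / syn_n) if syn_n else 0.0,
        heterogeneity=tuple(abs(overall - g) for g in gc123),
    )


# ---------------------------------------------------------------------------
# Protein divergence

def p_distance(a: str, b: str) -> float | None:
    """Amino-acid p-distance over columns where neither sequence has a gap."""
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    comp = mism = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-." or y in "-.":
            continue
        comp += 1
        if x != y:
            mism += 1
    if comp == 0:
        return None
    return mism / comp


def protein_divergence(alignments, taxon_a: str, taxon_b: str) -> float | None:
    """Pooled p-distance between two taxa across several gene alignments.

    ``alignments`` is an iterable of {taxon: aligned protein} mappings.
    Mismatches and comparable columns are pooled over the concatenation,
    which is what an "overall" divergence across genes means here.
    """
    comp = mism = 0
    for aln in alignments:
        if taxon_a not in aln or taxon_b not in aln:
            continue
        a, b = aln[taxon_a].upper(), aln[taxon_b].upper()
        if len(a) != len(b):
            raise ValueError("aligned sequences must have equal length")
        for x, y in zip(a, b):
            if x in "-." or y in "-.":
                continue
            comp += 1
            if x != y:
                mism += 1
    if comp == 0:
        return None
    return mism / comp


# ---------------------------------------------------------------------------
# tRNA acceptor stem

_WC = {("A", "T"), ("T", "A"), ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G"), ("G", "U"), ("U", "G")}


def _pair_map(structure: str) -> dict[int, int]:
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced structure string: unmatched ')'")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif ch not in ".":
            raise ValueError(f"unexpected structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced structure string: unmatched '('")
    return pairs


def trna_acceptor_mismatches(trna_seq: str, structure: str,
                             allow_gu: bool = True) -> list[int]:
    """Non-Watson-Crick pairs among the first three acceptor-stem base pairs.

    The acceptor stem's first three pairs are the first three ``(`` positions
    of the dot-bracket string, paired by nesting. G:U wobble counts as valid
    by default. Returns the offending pair indices (1-based, subset of
    {1, 2, 3}).
    """
    if len(trna_seq) != len(structure):
        raise ValueError("sequence and structure must have equal length")
    pairs = _pair_map(structure)
    opens = [i for i, ch in enumerate(structure) if ch == "("][:3]
    seq = trna_seq.upper()
    valid = _WC | (_WOBBLE if allow_gu else set())
    bad = []
    for idx, i in enumerate(opens, start=1):
        j = pairs[i]
        if (seq[i], seq[j]) not in valid:
            bad.append(idx)
    return bad
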