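"""Genetic-code structure used by the codon-usage statistics.

Degeneracy-class structure (which amino acids form 2-, 3-, 4- or 6-fold
synonymous families) is derived from the declared NCBI translation table at
run time, never hard-wired, so mitochondrial codes reshape the family
structure automatically.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

NUCS = "ACGT"
CODONS = tuple(a + b + c for a in NUCS for b in NUCS for c in NUCS)


@lru_cache(maxsize=None)
def table(code: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[code]


@lru_cache(maxsize=None)
def stop_codons(code: int) -> frozenset[str]:
    return frozenset(table(code).stop_codons)


@lru_cache(maxsize=None)
def sense_codons(code: int) -> tuple[str, ...]:
    stops = stop_codons(code)
    return tuple(c for c in CODONS if c not in stops)


def translate_codon(codon: str, code: int) -> str:
    """Single-letter amino acid, or '*' for a stop codon."""
    if codon in stop_codons(code):
        return "*"
    return table(code).forward_table[codon]


@lru_cache(maxsize=None)
def families(code: int) -> dict[str, tuple[str, ...]]:
    """Amino acid -> synonymous sense codons, under the declared code."""
    fams: dict[str, list[str]] = {}
    for codon in sense_codons(code):
        fams.setdefault(translate_codon(codon, code), []).append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in sorted(fams.items())}


@lru_cache(maxsize=None)
def degeneracy_classes(code: int) -> dict[int, tuple[str, ...]]:
    """Degeneracy k -> amino acids whose family has exactly k codons (k >= 2)."""
    out: dict[int, list[str]] = {}
    for aa, cs in families(code).items():
        if len(cs) >= 2:
            out.setdefault(len(cs), []).append(aa)
    return {k: tuple(sorted(v)) for k, v in sorted(out.items())}


def n_single_codon_families(code: int) -> int:
    return sum(1 for cs in families(code).values() if len(cs) == 1)


def max_nc(code: int) -> int:
    """The code's maximum effective number of codons (= number of sense codons)."""
    return len(sense_codons(code))


@lru_cache(maxsize=None)
def synonymous_codons(code: int) -> frozenset[str]:
    """Sense codons belonging to a family with >= 2 members (GC3s universe)."""
    return frozenset(c for cs in families(code).values() if len(cs) >= 2 for c in cs)
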