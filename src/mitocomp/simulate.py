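"""Seeded synthetic mitochondrial genomes, clades, transcripts and tRNAs.

The generator emulates the regime of compact, highly AT-rich (default 83%)
circular mitochondrial genomes with weak codon bias, gene content evolving
by loss-only events on a rooted tree, short intergenic spacers, planted
C-to-U editing sites (genomic C, transcript T) and tRNAs with planted
acceptor-stem mismatches — so every analysis stage is testable without any
download. Between-leaf sequence divergence is deliberately not modelled:
no in-scope analysis consumes nucleotide homology between taxa.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
spec + seed gives byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from scipy.optimize import brentq

from . import genetic_code as gc
from .genome_io import (Feature, GenomeRecord, Interval, ensure_internal_labels,
                        revcomp)

# Default gene roster: the compact heterolobosean-style complement used when
# the caller does not supply one.
DEFAULT_GENES = (
    "atp1", "atp3", "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "nad8", "nad10",
    "sdh3", "sdh4", "rpl5", "rpl6", "rpl14", "rps3", "rps8", "rps12",
)


@dataclass
class SimSpec:
    """Study conditions for the generator.

    Defaults emulate the compact AT-rich mitogenome regime: overall AT
    around 0.83, weak synonymous bias (Nc' in the 50-61 range), ten unknown
    ORFs, geometric spacers, loss-only gene-content evolution.
    """

    seed: int = 0
    tree: dendropy.Tree | None = None
    ancestral_genes: tuple[str, ...] = DEFAULT_GENES
    branch_losses: dict[str, frozenset[str]] | None = None
    loss_rate: float = 0.0
    at_target: float = 0.83
    gc3s_target: float = 0.10
    bias_strength: float = 0.0
    n_orfs: int = 10
    n_trnas: int = 11
    spacer_mean: float = 60.0
    gene_length_range: tuple[int, int] = (300, 1500)
    orf_length_range: tuple[int, int] = (210, 1200)
    code: int = 1
    edits: tuple[tuple[str, int], ...] = ()
    trna_mismatches: tuple[tuple[str, tuple[int, ...]], ...] = ()


# ---------------------------------------------------------------------------
# Coding-sequence simulation

def _third_pos_probs(gc3s_target: float) -> dict[str, float]:
    g = gc3s_target
    return {"A": (1 - g) / 2, "T": (1 - g) / 2, "G": g / 2, "C": g / 2}


def _family_weights(code: int, gc3s_target: float,
                    bias_strength: float) -> dict[str, np.ndarray]:
    """Within-family synonymous codon probabilities.

    Base weights multiply a GC3s-controlled single-nucleotide distribution
    over the positions at which the family's codons vary, so that expected
    third-position GC among degenerate codons equals ``gc3s_target``.
    ``bias_strength`` exponentially favours one deterministic codon per
    family; 0 leaves the base distribution, infinity collapses to one codon.
    """
    probs = _third_pos_probs(gc3s_target)
    weights: dict[str, np.ndarray] = {}
    for aa, codons in gc.families(code).items():
        varying = [p for p in range(3)
                   if len({c[p] for c in codons}) > 1]
        w = []
        for codon in codons:
            x = 1.0
            for p in varying:
                x *= probs[codon[p]]
            w.append(x)
        w = np.array(w, dtype=float)
        if w.sum() == 0:
            warnings.warn(f"family {aa}: GC3s target unreachable; using uniform")
            w = np.ones(len(codons), dtype=float)
        if bias_strength > 0 and len(codons) > 1:
            w = w * np.exp(bias_strength *
                           np.array([1.0 if i == 0 else 0.0
                                     for i in range(len(codons))]))
        weights[aa] = w / w.sum()
    return weights


def _aa_distribution(code: int, weights: dict[str, np.ndarray],
                     at_target: float, warn: bool = True,
                     ) -> tuple[list[str], np.ndarray]:
    """Amino-acid sampling distribution tilted to hit an overall AT target.

    Exponential tilting of a uniform distribution over residues by each
    residue's expected codon AT fraction; the tilt parameter is solved so
    the expected coding AT equals ``at_target`` (closest achievable with a
    warning if the target lies outside the attainable range).
    """
    aas = list(gc.families(code))
    at_aa = []
    for aa in aas:
        codons = gc.families(code)[aa]
        w = weights[aa]
        at = sum(w[i] * sum(b in "AT" for b in c) / 3.0
                 for i, c in enumerate(codons))
        at_aa.append(at)
    at_aa = np.array(at_aa)

    def expected(lmbda: float) -> float:
        p = np.exp(lmbda * at_aa)
        p /= p.sum()
        return float(p @ at_aa)

    lo, hi = -200.0, 200.0
    if at_target <= expected(lo):
        if warn:
            warnings.warn(f"AT target {at_target} below attainable minimum")
        lmbda = lo
    elif at_target >= expected(hi):
        if warn:
            warnings.warn(f"AT target {at_target} above attainable maximum")
        lmbda = hi
    else:
        lmbda = brentq(lambda l: expected(l) - at_target, lo, hi, xtol=1e-10)
    p = np.exp(lmbda * at_aa)
    return aas, p / p.sum()


def _expected_gc3s(code: int, weights: dict[str, np.ndarray],
                   aa_freq: dict[str, float]) -> float:
    """Expected measured GC3s under given codon weights and residue usage."""
    fams = gc.families(code)
    num = den = 0.0
    for aa, freq in aa_freq.items():
        codons = fams[aa]
        if len(codons) < 2:
            continue
        w = weights[aa]
        num += freq * sum(w[i] for i, c in enumerate(codons) if c[2] in "GC")
        den += freq
    return num / den if den else 0.0


def _solve_weights(code: int, gc3s_target: float, bias_strength: float,
                   at_target: float, protein: str | None,
                   ) -> tuple[dict[str, np.ndarray], list[str], np.ndarray]:
    """Codon weights whose *measured* GC3s expectation equals the target.

    Families whose third-position alphabet is incomplete (e.g. the 3-fold
    Ile family) pull the realised GC3s away from the naive per-position
    parameter, so the parameter is solved numerically against the exact
    expectation under the realised amino-acid usage.
    """
    fams = gc.families(code)

    def setup(g: float, warn: bool = False):
        w = _family_weights(code, g, bias_strength)
        if protein is not None:
            residues = [aa for aa in protein.upper() if aa not in "*-"]
            freq = {aa: residues.count(aa) / len(residues) for aa in set(residues)}
            aas, p = list(freq), np.array([freq[a] for a in freq])
        else:
            aas, p = _aa_distribution(code, w, at_target, warn=warn)
            freq = dict(zip(aas, p))
        return w, aas, p, freq

    def err(g: float) -> float:
        w, _, _, freq = setup(g)
        return _expected_gc3s(code, w, freq) - gc3s_target

    lo, hi = 1e-9, 1.0 - 1e-9
    if err(lo) >= 0:
        g = lo
        if gc3s_target > 0:
            warnings.warn("gc3s target below attainable range; using minimum")
    elif err(hi) <= 0:
        g = hi
        warnings.warn("gc3s target above attainable range; using maximum")
    else:
        g = brentq(err, lo, hi, xtol=1e-9)
    w, aas, p, _ = setup(g, warn=True)
    return w, aas, p


def sim_coding_sequence(length_codons: int, protein: str | None = None,
                        at_target: float = 0.83, gc3s_target: float = 0.10,
                        bias_strength: float = 0.0, seed: int = 0,
                        code: int = 1, rng: np.random.Generator | None = None,
                        ) -> str:
    """Simulate one coding sequence (ATG start, TAA stop included).

    If ``protein`` is given, codons are sampled conditionally on each
    residue; otherwise residues are drawn from an AT-tilted distribution.
    ``length_codons`` counts the internal (non start/stop) codons when no
    protein is supplied.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    weights, aas, p = _solve_weights(code, gc3s_target, bias_strength,
                                     at_target, protein)
    fams = gc.families(code)
    if protein is not None:
        residues = [aa for aa in protein.upper() if aa not in "*-"]
    else:
        residues = list(rng.choice(aas, size=length_codons, p=p))
    codons = []
    for aa in residues:
        cs = fams[aa]
        codons.append(cs[rng.choice(len(cs), p=weights[aa])])
    return "ATG" + "".join(codons) + "TAA"


# ---------------------------------------------------------------------------
# tRNA with planted acceptor-stem mismatches

_STEM5 = "GCGGATT"
_MISMATCH_FOR = {"G": "A", "C": "T", "A": "G", "T": "C"}  # never WC nor G:U


def plant_trna(name: str = "trnX", mismatch_pairs: tuple[int, ...] = (),
               loop_len: int = 35, at: float = 0.83, seed: int = 0,
               rng: np.random.Generator | None = None) -> tuple[str, str]:
    """A synthetic tRNA-like sequence and dot-bracket structure.

    The 7-bp acceptor stem pairs the first and last 7 positions; the
    detector's pairs 1-3 are mismatched exactly where requested.
    """
    if any(p not in (1, 2, 3) for p in mismatch_pairs):
        raise ValueError("mismatch pairs must be within {1, 2, 3}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    stem5 = _STEM5
    stem3 = [revcomp(b) for b in stem5][::-1]  # pairwise complements, reversed
    # stem3[k] pairs with stem5[6-k]; detector pair i uses stem5[i-1]
    for p in mismatch_pairs:
        stem3[7 - p] = _MISMATCH_FOR[stem5[p - 1]]
    loop = "".join(rng.choice(list("ATGC"),
                              p=[at / 2, at / 2, (1 - at) / 2, (1 - at) / 2],
                              size=loop_len))
    seq = stem5 + loop + "".join(stem3)
    struct = "(" * 7 + "." * loop_len + ")" * 7
    return seq, struct


# ---------------------------------------------------------------------------
# Whole-genome simulation

@dataclass
class SimulatedGenome:
    record: GenomeRecord
    transcripts: dict[str, str]
    trna_structures: dict[str, str]
    edits: tuple[tuple[str, int], ...]


def _spacer(rng: np.random.Generator, mean: float, at: float) -> str:
    if mean <= 0:
        return ""
    n = int(rng.geometric(1.0 / (1.0 + mean)) - 1)
    if n <= 0:
        return ""
    return "".join(rng.choice(list("ATGC"),
                              p=[at / 2, at / 2, (1 - at) / 2, (1 - at) / 2],
                              size=n))


def _apply_edits(cds: str, codon_indices: list[int], code: int,
                 ) -> tuple[str, str, list[int]]:
    """Force Ser TCA codons at the edit positions; transcript reads Leu TTA.

    Returns (genomic cds, transcript cds, 1-based cds positions edited).
    """
    genomic = list(cds)
    transcript = list(cds)
    positions = []
    for ci in codon_indices:
        # ci is 1-based over internal codons; offset by the ATG start codon
        idx = ci * 3  # start of that codon in the full CDS
        if idx + 3 > len(cds) - 3:
            raise ValueError(f"edit codon {ci} beyond gene length")
        genomic[idx:idx + 3] = "TCA"
        transcript[idx:idx + 3] = "TTA"
        positions.append(idx + 2)  # the C sits at codon position 2
    return "".join(genomic), "".join(transcript), positions


def sim_genome(spec: SimSpec, gene_set: tuple[str, ...] | None = None,
               seed: int | None = None) -> SimulatedGenome:
    """Simulate one annotated circular genome plus its transcripts.

    Genes and ORFs get independently simulated coding sequences; spacers
    are geometric with mean ``spec.spacer_mean``; planted edits appear as C
    in the genome and T in the emitted transcript.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    genes = list(gene_set if gene_set is not None else spec.ancestral_genes)
    lo, hi = spec.gene_length_range
    olo, ohi = spec.orf_length_range
    edits_by_gene: dict[str, list[int]] = {}
    for g, ci in spec.edits:
        edits_by_gene.setdefault(g, []).append(ci)

    chunks: list[str] = []
    features: list[Feature] = []
    transcripts: dict[str, str] = {}
    trna_structures: dict[str, str] = {}
    pos = 0

    def add(seq_part: str) -> int:
        nonlocal pos
        chunks.append(seq_part)
        start = pos
        pos += len(seq_part)
        return start

    entries: list[tuple[str, str]] = [("CDS", g) for g in genes]
    entries += [("ORF", f"orf{i + 1}") for i in range(spec.n_orfs)]
    mism = dict(spec.trna_mismatches)
    trna_names = [f"trn{chr(ord('A') + i)}" for i in range(spec.n_trnas)]
    entries += [("tRNA", t) for t in trna_names]

    for kind, name in entries:
        add(_spacer(rng, spec.spacer_mean, spec.at_target))
        if kind in ("CDS", "ORF"):
            rng_lo, rng_hi = (lo, hi) if kind == "CDS" else (olo, ohi)
            n_codons = int(rng.integers(rng_lo // 3, rng_hi // 3 + 1))
            if name in edits_by_gene:
                # genes carrying planted edits must reach the edit codon
                n_codons = max(n_codons, max(edits_by_gene[name]) + 2)
            cds = sim_coding_sequence(
                n_codons, at_target=spec.at_target,
                gc3s_target=spec.gc3s_target,
                bias_strength=spec.bias_strength, code=spec.code, rng=rng)
            transcript = cds
            if name in edits_by_gene:
                cds, transcript, _ = _apply_edits(cds, edits_by_gene[name],
                                                  spec.code)
            start = add(cds)
            features.append(Feature(kind=kind, name=name,
                                    intervals=[Interval(start, start + len(cds), 1)]))
            transcripts[name] = transcript
        else:
            seq, struct = plant_trna(name, mism.get(name, ()),
                                     at=spec.at_target, rng=rng)
            start = add(seq)
            features.append(Feature(kind="tRNA", name=name,
                                    intervals=[Interval(start, start + len(seq), 1)]))
            trna_structures[name] = struct
    add(_spacer(rng, spec.spacer_mean, spec.at_target))

    sequence = "".join(chunks)
    record = GenomeRecord(id=f"sim{spec.seed if seed is None else seed}",
                          sequence=sequence, circular=True, features=features,
                          transl_table=spec.code)
    return SimulatedGenome(record=record, transcripts=transcripts,
                           trna_structures=trna_structures, edits=spec.edits)


# ---------------------------------------------------------------------------
# Clade simulation (loss-only gene content on a rooted tree)

def _leaf_gene_sets(spec: SimSpec, rng: np.random.Generator,
                    ) -> tuple[dict[str, tuple[str, ...]], dict[str, frozenset[str]]]:
    tree = spec.tree
    ensure_internal_labels(tree)
    losses: dict[str, frozenset[str]] = {}
    if spec.branch_losses is not None:
        losses = {k: frozenset(v) for k, v in spec.branch_losses.items()}
    leaf_sets: dict[str, tuple[str, ...]] = {}

    def walk(node, genes: tuple[str, ...]):
        for child in node.child_nodes():
            label = child.label if not child.is_leaf() else child.taxon.label
            if spec.branch_losses is not None:
                lost = losses.get(label, frozenset())
            else:
                mask = rng.random(len(genes)) < spec.loss_rate
                lost = frozenset(g for g, m in zip(genes, mask) if m)
                if lost:
                    losses[label] = lost
            bad = lost - set(genes)
            if bad:
                raise ValueError(
                    f"gene(s) {sorted(bad)} lost twice on the path to {label}")
            remaining = tuple(g for g in genes if g not in lost)
            if child.is_leaf():
                leaf_sets[child.taxon.label] = remaining
            else:
                walk(child, remaining)

    walk(tree.seed_node, tuple(spec.ancestral_genes))
    return leaf_sets, losses


def sim_clade(spec: SimSpec) -> tuple[dict[str, SimulatedGenome],
                                      dict[str, frozenset[str]]]:
    """Simulate one genome per leaf of ``spec.tree`` under loss-only content.

    Each leaf's gene set is the ancestral set minus the union of losses on
    its root path (explicit per-branch sets or a per-branch loss rate);
    sequences are re-simulated independently per leaf. Returns the genomes
    and the realised per-branch loss sets (keyed by child-node label).
    """
    if spec.tree is None:
        raise ValueError("SimSpec.tree is required for clade simulation")
    rng = np.random.default_rng(spec.seed)
    leaf_sets, losses = _leaf_gene_sets(spec, rng)
    genomes: dict[str, SimulatedGenome] = {}
    for leaf in sorted(leaf_sets):
        leaf_seed = int(rng.integers(0, 2 ** 31 - 1))
        leaf_spec = replace(spec, seed=leaf_seed)
        sim = sim_genome(leaf_spec, gene_set=leaf_sets[leaf])
        sim.record.id = leaf
        genomes[leaf] = sim
    return genomes, losses
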