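"""Codon-usage-bias statistics for AT-rich organellar genomes.

The suite mirrors the classical toolchain for asking whether weak codon
bias is explained by mutation pressure alone:

* ``enc_observed`` — Wright's effective number of codons Nc, from the mean
  codon homozygosity of each degeneracy class.
* ``enc_expected`` — the null curve Nc = 2 + S + 29/[S^2 + (1-S)^2] giving
  the Nc of a gene shaped only by its GC content at synonymous third
  positions (S = GC3s).
* ``enc_prime`` — the background-corrected variant Nc', replacing the
  homozygosity with a chi-square deviation of observed codon counts from
  the counts expected under the gene's own positional nucleotide
  composition.
* ``cdc`` — the codon deviation coefficient, one minus the cosine
  similarity between observed codon usage and usage expected from
  positional GC and purine content, with bootstrap significance.
* ``compare_bias`` — a two-sided Wilcoxon rank-sum comparison of per-gene
  statistics between two gene sets (e.g. annotated genes vs unknown ORFs).

All class multiplicities (9 two-fold, 1 three-fold, 5 four-fold and
3 six-fold families for the standard code) are derived from the declared
genetic code at run time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import genetic_code as gc

log = logging.getLogger(__name__)


@dataclass
class CodonCountTable:
    """64-cell codon counts bound to a genetic-code table.

    Also accumulates per-codon-position nucleotide counts over the counted
    codons so that Nc' and CDC backgrounds can be estimated from the gene
    itself without revisiting the sequence.
    """

    counts: dict[str, int]
    code: int = 1
    source: str = "pooled"
    n_skipped: int = 0
    n_internal_stops: int = 0
    positional: np.ndarray = field(
        default_factory=lambda: np.zeros((3, 4), dtype=float))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        if self.code != other.code:
            raise ValueError("cannot pool tables with different genetic codes")
        counts = dict(self.counts)
        for c, n in other.counts.items():
            counts[c] = counts.get(c, 0) + n
        return CodonCountTable(
            counts=counts, code=self.code, source="pooled",
            n_skipped=self.n_skipped + other.n_skipped,
            n_internal_stops=self.n_internal_stops + other.n_internal_stops,
            positional=self.positional + other.positional,
        )

    def positional_frequencies(self) -> np.ndarray:
        """3x4 (position x ACGT) nucleotide frequencies of counted codons."""
        totals = self.positional.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValueError("empty codon table has no positional composition")
        return self.positional / totals


_NT_INDEX = {n: i for i, n in enumerate(gc.NUCS)}


def count_codons(cds: str, code: int = 1, source: str = "gene") -> CodonCountTable:
    """Count codons of a coding sequence.

    The terminal stop codon is excluded; internal stops are counted and
    flagged (edited/extended genes legitimately contain them before RNA
    editing); codons containing N are skipped with a tally.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"{source}: CDS length {len(cds)} is not a multiple of 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in gc.stop_codons(code):
        codons = codons[:-1]
    counts: dict[str, int] = {}
    n_skipped = 0
    n_internal_stops = 0
    positional = np.zeros((3, 4), dtype=float)
    stops = gc.stop_codons(code)
    for codon in codons:
        if any(b not in "ACGT" for b in codon):
            n_skipped += 1
            continue
        if codon in stops:
            n_internal_stops += 1
        counts[codon] = counts.get(codon, 0) + 1
        for p, b in enumerate(codon):
            positional[p, _NT_INDEX[b]] += 1
    if n_internal_stops:
        log.warning("%s: %d internal stop codon(s) counted", source, n_internal_stops)
    return CodonCountTable(counts=counts, code=code, source=source,
                           n_skipped=n_skipped, n_internal_stops=n_internal_stops,
                           positional=positional)


def pooled_table(cdss, code: int = 1) -> CodonCountTable:
    """Pool per-gene codon counts (each gene's terminal stop excluded)."""
    tables = [count_codons(cds, code=code, source=f"gene{i}")
              for i, cds in enumerate(cdss)]
    if not tables:
        raise ValueError("no coding sequences to pool")
    out = tables[0]
    for t in tables[1:]:
        out = out + t
    return out


# ---------------------------------------------------------------------------
# Nc (observed) and the null curve

def _family_counts(table: CodonCountTable, aa: str) -> np.ndarray:
    fams = gc.families(table.code)
    return np.array([table.counts.get(c, 0) for c in fams[aa]], dtype=float)


def _class_mean_F(table: CodonCountTable, f_hat) -> tuple[dict[int, float], dict[int, list[float]]]:
    """Mean homozygosity per degeneracy class, using estimator ``f_hat``.

    Families with n < 2 or with a non-positive estimate are excluded from
    the class mean (codonW convention).
    """
    per_class: dict[int, list[float]] = {}
    for k, aas in gc.degeneracy_classes(table.code).items():
        vals = []
        for aa in aas:
            counts = _family_counts(table, aa)
            n = counts.sum()
            if n < 2:
                continue
            F = f_hat(counts)
            if F is not None and F > 0:
                vals.append(F)
        per_class[k] = vals
    means = {k: float(np.mean(v)) for k, v in per_class.items() if v}
    return means, per_class


def _assemble_nc(table: CodonCountTable, means: dict[int, float]) -> float | None:
    """Combine class means into Nc; class-3 imputation and code-maximum cap."""
    classes = gc.degeneracy_classes(table.code)
    nc = float(gc.n_single_codon_families(table.code))
    for k, aas in classes.items():
        if k in means:
            Fk = means[k]
        elif k == 3 and 2 in means and 4 in means:
            Fk = (means[2] + means[4]) / 2.0
        else:
            log.warning("%s: degeneracy class %d has no usable family; Nc undefined",
                        table.source, k)
            return None
        nc += len(aas) / Fk
    return min(nc, float(gc.max_nc(table.code)))


def _f_hat_homozygosity(counts: np.ndarray) -> float | None:
    n = counts.sum()
    p = counts / n
    return float((n * np.sum(p ** 2) - 1.0) / (n - 1.0))


def enc_observed(table: CodonCountTable) -> float | None:
    """Wright's effective number of codons Nc of a codon count table.

    Returns None when a needed degeneracy class has no family with n >= 2
    (after the standard class-3 imputation from classes 2 and 4).
    """
    means, _ = _class_mean_F(table, _f_hat_homozygosity)
    return _assemble_nc(table, means)


def enc_expected(S: float) -> float:
    """Null-curve Nc expected from GC3s alone: 2 + S + 29/[S^2 + (1-S)^2]."""
    if not 0.0 <= S <= 1.0:
        raise ValueError(f"S must lie in [0, 1], got {S}")
    return 2.0 + S + 29.0 / (S ** 2 + (1.0 - S) ** 2)


# ---------------------------------------------------------------------------
# Nc' (background-corrected)

def _family_expected(table: CodonCountTable, aa: str,
                     background: np.ndarray) -> np.ndarray:
    """Expected within-family codon probabilities from positional background.

    The product runs over all three codon positions; positions invariant
    within the family contribute a common factor that cancels in the
    within-family renormalisation.
    """
    fams = gc.families(table.code)
    e = []
    for codon in fams[aa]:
        p = 1.0
        for pos, b in enumerate(codon):
            p *= background[pos, _NT_INDEX[b]]
        e.append(p)
    e = np.array(e, dtype=float)
    s = e.sum()
    if s == 0:
        return e
    return e / s


def enc_prime(table: CodonCountTable,
              background: np.ndarray | None = None) -> float | None:
    """Background-corrected effective number of codons (Nc').

    ``background`` is a 3x4 matrix of per-codon-position nucleotide
    frequencies (rows: positions, columns: ACGT). By default it is the
    positional composition of the counted codons themselves; pass a
    genome-wide matrix to use a shared background.
    """
    if background is None:
        background = table.positional_frequencies()
    background = np.asarray(background, dtype=float)
    per_class: dict[int, list[float]] = {}
    for k, aas in gc.degeneracy_classes(table.code).items():
        vals = []
        for aa in aas:
            counts = _family_counts(table, aa)
            n = counts.sum()
            m = len(counts)
            if n < 2:
                continue
            e = _family_expected(table, aa, background)
            if np.any((e == 0) & (counts > 0)):
                log.warning("%s: family %s has observed codons with zero expected "
                            "frequency; skipped", table.source, aa)
                continue
            mask = e > 0
            chi2 = float(np.sum((counts[mask] - n * e[mask]) ** 2 / (n * e[mask])))
            F = (chi2 + n - m) / (m * (n - 1.0))
            if F > 0:
                vals.append(F)
        per_class[k] = vals
    means = {k: float(np.mean(v)) for k, v in per_class.items() if v}
    return _assemble_nc(table, means)


# ---------------------------------------------------------------------------
# CDC

def _cdc_expected(table: CodonCountTable, full_model: bool = False) -> np.ndarray:
    """Expected sense-codon probabilities from positional composition.

    Default parameterisation uses per-position GC and purine content only
    (two parameters per position); ``full_model=True`` uses the full
    per-position 4-nucleotide frequencies.
    """
    freqs = table.positional_frequencies()  # 3x4 over ACGT
    if full_model:
        pos_probs = freqs
    else:
        pos_probs = np.zeros_like(freqs)
        for p in range(3):
            a, c, g, t = freqs[p]
            gc_content = g + c
            purine = a + g
            pos_probs[p, _NT_INDEX["A"]] = (1 - gc_content) * purine
            pos_probs[p, _NT_INDEX["G"]] = gc_content * purine
            pos_probs[p, _NT_INDEX["C"]] = gc_content * (1 - purine)
            pos_probs[p, _NT_INDEX["T"]] = (1 - gc_content) * (1 - purine)
    sense = gc.sense_codons(table.code)
    e = np.array([
        pos_probs[0, _NT_INDEX[c[0]]] *
        pos_probs[1, _NT_INDEX[c[1]]] *
        pos_probs[2, _NT_INDEX[c[2]]]
        for c in sense
    ])
    total = e.sum()
    if total == 0:
        raise ValueError("degenerate positional composition: all expected "
                         "codon probabilities are zero")
    return e / total


def _cosine_distance(obs: np.ndarray, exp: np.ndarray) -> float:
    no, ne = np.linalg.norm(obs), np.linalg.norm(exp)
    if no == 0 or ne == 0:
        raise ValueError("cannot compute CDC of an empty usage vector")
    cos = float(np.dot(obs, exp) / (no * ne))
    return 1.0 - min(cos, 1.0)


def cdc(table: CodonCountTable, reps: int = 10_000, seed: int = 0,
        full_model: bool = False) -> tuple[float, float]:
    """Codon deviation coefficient and its bootstrap p-value.

    CDC = 1 - cosine similarity between observed sense-codon frequencies and
    frequencies expected from positional nucleotide composition. The p-value
    is the fraction of ``reps`` bootstrap datasets (n codons resampled from
    the expected distribution) whose CDC is at least the observed one.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    sense = gc.sense_codons(table.code)
    n = sum(table.counts.get(c, 0) for c in sense)
    if n == 0:
        raise ValueError(f"{table.source}: no sense codons; CDC undefined")
    obs = np.array([table.counts.get(c, 0) for c in sense], dtype=float) / n
    exp = _cdc_expected(table, full_model=full_model)
    value = _cosine_distance(obs, exp)
    rng = np.random.default_rng(seed)
    boot = rng.multinomial(n, exp, size=reps) / n
    # vectorised cosine distance per replicate
    dots = boot @ exp
    norms = np.linalg.norm(boot, axis=1) * np.linalg.norm(exp)
    boot_cdc = 1.0 - np.minimum(dots / norms, 1.0)
    p = float(np.mean(boot_cdc >= value))
    return value, p


# ---------------------------------------------------------------------------
# Rank-sum comparison

def compare_bias(set_a, set_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two per-gene value sets.

    Exact null for combined n <= 20 with no ties, normal approximation with
    continuity correction otherwise. Two identical constant samples give 1.
    """
    a = [float(x) for x in set_a]
    b = [float(x) for x in set_b]
    if not a or not b:
        raise ValueError("both sets must be non-empty")
    if len(set(a + b)) == 1:
        return 1.0
    ties = len(a + b) != len(set(a + b))
    method = "exact" if (len(a) + len(b) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# Per-gene report

@dataclass
class BiasReport:
    """All bias statistics for one gene (or a pooled concatenation)."""

    source: str
    n_codons: int
    S: float
    nc_observed: float | None
    nc_expected: float
    nc_prime: float | None
    class_homozygosity: dict[int, float]
    cdc: float
    cdc_p: float


def bias_report(cds: str, code: int = 1, source: str = "gene",
                reps: int = 10_000, seed: int = 0,
                background: np.ndarray | None = None) -> BiasReport:
    """Compute the full bias suite for one coding sequence."""
    from .composition import positional_gc  # local import to avoid a cycle

    table = count_codons(cds, code=code, source=source)
    pos = positional_gc(cds, code=code)
    means, _ = _class_mean_F(table, _f_hat_homozygosity)
    value, p = cdc(table, reps=reps, seed=seed)
    return BiasReport(
        source=source, n_codons=table.total, S=pos.gc3s,
        nc_observed=enc_observed(table),
        nc_expected=enc_expected(pos.gc3s),
        nc_prime=enc_prime(table, background=background),
        class_homozygosity=means, cdc=value, cdc_p=p,
    )
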