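"""C-to-U mRNA editing candidate prediction and confirmation.

C-to-U editing restores evolutionarily conserved codons: a genomic C reads
as T in the transcript, changing the encoded amino acid to the residue
conserved in related taxa. Candidates are therefore enumerated as single
C->T substitutions inside query codons whose edited translation matches a
panel of reference orthologs where the unedited one does not, scored by the
fraction of informative references supporting the edit. Confirmed status
comes from comparing genomic and cDNA-derived sequence at the site.
A scan for the PG-box motif of DYW-type PPR editing factors is included.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from . import genetic_code as gc

PG_BOX = re.compile(r"(?=PG.SWIEV.G..H.F)")


@dataclass
class EditingCandidate:
    gene: str
    cds_pos: int            # 1-based within CDS
    codon_index: int        # 1-based codon number
    unedited_codon: str
    edited_codon: str
    aa_change: tuple[str, str]
    support: float
    status: str             # candidate | strong | confirmed | rejected | error

    def __post_init__(self):
        diff = [p for p in range(3)
                if self.unedited_codon[p] != self.edited_codon[p]]
        if len(diff) != 1 or self.unedited_codon[diff[0]] != "C" \
                or self.edited_codon[diff[0]] != "T":
            raise ValueError("candidate codons must differ by a single C->T")


def name_site(candidate: EditingCandidate) -> str:
    """Site name in <gene>eU<cds_pos><fromAA><toAA> form, e.g. atp6eU722SL."""
    frm, to = candidate.aa_change
    return f"{candidate.gene}eU{candidate.cds_pos}{frm}{to}"


@dataclass
class ReferenceSet:
    """Query-anchored reference panel for one gene.

    ``query_aligned`` and every member sequence have equal length; columns
    are alignment columns. Build with :func:`build_reference_set` from
    unaligned reference proteins, or supply a pre-made alignment.
    """

    gene: str
    members: list[tuple[str, str]]
    query_aligned: str

    def __post_init__(self):
        for taxon, seq in self.members:
            if len(seq) != len(self.query_aligned):
                raise ValueError(
                    f"reference {taxon} length {len(seq)} != query "
                    f"{len(self.query_aligned)}")

    def column_of_residue(self, aa_index: int) -> int:
        """Alignment column of the query's aa_index-th (1-based) residue."""
        seen = 0
        for col, ch in enumerate(self.query_aligned):
            if ch not in "-.":
                seen += 1
                if seen == aa_index:
                    return col
        raise IndexError(f"query has fewer than {aa_index} residues")


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def build_reference_set(gene: str, query_protein: str,
                        references: dict[str, str]) -> ReferenceSet:
    """Align each reference globally to the query (BLOSUM62, affine gaps)
    and project onto query coordinates, giving a query-anchored panel."""
    aligner = _global_aligner()
    members = []
    q = query_protein.replace("*", "").upper()
    for taxon, ref in references.items():
        r = ref.replace("*", "").upper()
        aln = aligner.align(q, r)[0]
        projected = ["-"] * len(q)
        for (qs, qe), (rs, re_) in zip(*aln.aligned):
            projected[qs:qe] = list(r[rs:re_])
        members.append((taxon, "".join(projected)))
    return ReferenceSet(gene=gene, members=members, query_aligned=q)


def predict_sites(cds: str, refs: ReferenceSet, code: int = 1,
                  strong_threshold: float = 0.8) -> list[EditingCandidate]:
    """Enumerate single C->T edits that restore reference-conserved residues.

    For every codon containing a C and every single C->T substitution in it,
    the site is predicted against a reference iff the edited codon's amino
    acid equals the reference residue at that alignment column while the
    unedited amino acid differs from it. Support is the fraction of
    references with a non-gap residue at the column that predict the site;
    synonymous edits are never emitted. One candidate per CDS position.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    n_codons = len(cds) // 3
    out: list[EditingCandidate] = []
    for ci in range(1, n_codons + 1):
        codon = cds[(ci - 1) * 3: ci * 3]
        if "C" not in codon:
            continue
        unedited_aa = gc.translate_codon(codon, code) if codon in gc.CODONS else None
        if unedited_aa is None:
            continue
        try:
            col = refs.column_of_residue(ci)
        except IndexError:
            break  # query protein shorter than CDS (terminal stop etc.)
        column = [seq[col] for _, seq in refs.members]
        informative = [r for r in column if r not in "-."]
        if not informative:
            continue
        for p in range(3):
            if codon[p] != "C":
                continue
            edited = codon[:p] + "T" + codon[p + 1:]
            edited_aa = gc.translate_codon(edited, code)
            if edited_aa in ("*", unedited_aa):
                continue
            n_pred = sum(1 for r in informative
                         if r == edited_aa and r != unedited_aa)
            if n_pred == 0:
                continue
            support = n_pred / len(informative)
            out.append(EditingCandidate(
                gene=refs.gene, cds_pos=(ci - 1) * 3 + p + 1, codon_index=ci,
                unedited_codon=codon, edited_codon=edited,
                aa_change=(unedited_aa, edited_aa), support=support,
                status="strong" if support >= strong_threshold else "candidate",
            ))
    return out


def confirm_sites(candidates: list[EditingCandidate], genomic: str,
                  cdna: str) -> list[EditingCandidate]:
    """Set confirmed/rejected status from genomic vs cDNA base identity.

    ``genomic`` and ``cdna`` must be ungapped, equal-length sequences in CDS
    coordinates. Genomic C with cDNA T confirms the edit; genomic C with
    cDNA C rejects it; a non-C genomic base flags the site as inconsistent
    rather than failing silently.
    """
    genomic, cdna = genomic.upper(), cdna.upper()
    if len(genomic) != len(cdna):
        raise ValueError("genomic and cDNA sequences must have equal length")
    for cand in candidates:
        if cand.cds_pos > len(genomic):
            raise ValueError(
                f"site {name_site(cand)}: position {cand.cds_pos} beyond "
                f"sequence length {len(genomic)}")
        g = genomic[cand.cds_pos - 1]
        d = cdna[cand.cds_pos - 1]
        if g != "C":
            cand.status = "error"
        elif d == "T":
            cand.status = "confirmed"
        elif d == "C":
            cand.status = "rejected"
        else:
            cand.status = "error"
    return candidates


def pg_box_scan(protein: str) -> list[int]:
    """1-based start positions of the 15-residue PG box PGxSWIEVxGxxHxF."""
    return [m.start() + 1 for m in PG_BOX.finditer(protein.upper())]


def translate(cds: str, code: int = 1) -> str:
    """Conceptual translation (terminal stop stripped, internal stops '*')."""
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        if any(b not in "ACGT" for b in codon):
            aas.append("X")
        else:
            aas.append(gc.translate_codon(codon, code))
    if aas and aas[-1] == "*":
        aas.pop()
    return "".join(aas)
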