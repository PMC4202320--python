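"""Genome model and file I/O.

Internal coordinates are 0-based half-open throughout; every file dialect
touched here (GenBank, gene-table TSV) is 1-based inclusive at the boundary.
Circular genomes are stored as a single linear sequence with wrap-aware
features: a feature crossing the origin is an ordered list of non-wrapping
intervals, and position arithmetic goes modulo the length only inside
operations that declare themselves wrap-aware.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "ORF", "other")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval on one strand."""

    start: int
    end: int
    strand: int = 1

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1/-1, got {self.strand}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Feature:
    """One annotated feature; multi-interval when split or origin-wrapping."""

    kind: str
    name: str
    intervals: list[Interval]
    product: str | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.intervals:
            raise ValueError(f"feature {self.name!r} has no intervals")

    @property
    def strand(self) -> int:
        return self.intervals[0].strand

    @property
    def start(self) -> int:
        return self.intervals[0].start

    def length(self) -> int:
        return sum(len(iv) for iv in self.intervals)


@dataclass
class GenomeRecord:
    """One annotated (possibly circular) mitochondrial genome."""

    id: str
    sequence: str
    circular: bool = False
    features: list[Feature] = field(default_factory=list)
    transl_table: int = 1

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"record {self.id!r} has non-ACGTN characters: {sorted(bad)}")
        for f in self.features:
            for iv in f.intervals:
                if iv.end > len(self.sequence):
                    raise ValueError(
                        f"feature {f.name!r} extends beyond record {self.id!r} "
                        f"(end {iv.end} > length {len(self.sequence)})"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]


@dataclass
class GeneOrder:
    """Ordered (name, orientation) list of genes around one genome."""

    taxon: str
    genes: list[tuple[str, int]]
    circular: bool = True

    def __len__(self) -> int:
        return len(self.genes)

    def names(self) -> list[str]:
        return [g for g, _ in self.genes]


# ---------------------------------------------------------------------------
# GenBank

def _classify(key: str, name: str, product: str | None) -> str | None:
    """Map a GenBank feature key to the internal kind; None means skip."""
    if key in ("source", "gene", "misc_feature"):
        return None
    if key == "CDS":
        label = (name or "").lower()
        prod = (product or "").lower()
        if label.startswith("orf") or prod.startswith("orf") or (
                not label and "hypothetical" in prod):
            return "ORF"
        return "CDS"
    if key in ("tRNA", "rRNA"):
        return key
    return "other"


def _feature_name(feat: SeqFeature) -> str:
    for q in ("gene", "product", "locus_tag", "label", "note"):
        if q in feat.qualifiers:
            return str(feat.qualifiers[q][0])
    return feat.type


def read_genbank(path) -> GenomeRecord:
    """Read a GenBank flat file into a :class:`GenomeRecord`.

    1-based inclusive coordinates become 0-based half-open; ``join()`` and
    ``complement()`` locations become multi-interval features; topology is
    taken from the LOCUS line. CDS features whose label/product looks like an
    unidentified ORF get kind ``ORF``.
    """
    rec = SeqIO.read(str(path), "genbank")
    seq = str(rec.seq).upper()
    if not seq or set(seq) == {"N"} and len(seq) < 2:
        raise ValueError(f"{path}: GenBank record has no sequence (ORIGIN block missing?)")
    circular = rec.annotations.get("topology", "linear") == "circular"
    transl_table = 1
    features: list[Feature] = []
    for feat in rec.features:
        name = _feature_name(feat)
        product = feat.qualifiers.get("product", [None])[0]
        kind = _classify(feat.type, name, product)
        if kind is None:
            continue
        if feat.type == "CDS" and "transl_table" in feat.qualifiers:
            transl_table = int(feat.qualifiers["transl_table"][0])
        ivs = []
        for part in feat.location.parts:
            strand = part.strand if part.strand in (1, -1) else 1
            ivs.append(Interval(int(part.start), int(part.end), strand))
        if len(ivs) > 1 and all(iv.strand == -1 for iv in ivs):
            # Biopython lists complement(join(...)) parts in extraction
            # order; store them in file order — extraction reverse-
            # complements the concatenation as a whole.
            ivs.reverse()
        for iv in ivs:
            if iv.end > len(seq) and not circular:
                raise ValueError(
                    f"{path}: feature {name!r} beyond sequence length on a linear record"
                )
        features.append(Feature(kind=kind, name=name, intervals=ivs, product=product))
    record = GenomeRecord(
        id=rec.id or rec.name, sequence=seq, circular=circular,
        features=features, transl_table=transl_table,
    )
    _flag_cds_lengths(record)
    return record


def _flag_cds_lengths(record: GenomeRecord) -> None:
    for f in record.features_of_kind("CDS", "ORF"):
        if f.length() % 3 != 0:
            f.flags.append("length_not_multiple_of_3")
            log.warning("%s: CDS %s length %d not a multiple of 3",
                        record.id, f.name, f.length())


def write_genbank(record: GenomeRecord, path) -> None:
    """Write a :class:`GenomeRecord` back out as a GenBank flat file."""
    rec = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                    description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if record.circular else "linear"
    for f in record.features:
        ivs = list(f.intervals)
        if len(ivs) > 1 and all(iv.strand == -1 for iv in ivs):
            ivs.reverse()  # Biopython expects extraction order (see read)
        locs = [SimpleLocation(iv.start, iv.end, iv.strand) for iv in ivs]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        key = "CDS" if f.kind == "ORF" else ("misc_feature" if f.kind == "other" else f.kind)
        quals = {"gene": [f.name]}
        if f.product:
            quals["product"] = [f.product]
        if f.kind in ("CDS", "ORF"):
            quals["transl_table"] = [str(record.transl_table)]
        rec.features.append(SeqFeature(loc, type=key, qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# CDS extraction

def extract_cds(record: GenomeRecord, feature: Feature) -> str:
    """Coding sequence of a (possibly wrapping, possibly reverse-strand) feature.

    Intervals are concatenated in listed order; if the feature lies on the
    reverse strand the concatenation is reverse-complemented as a whole,
    reproducing GenBank ``complement(join(...))`` semantics.
    """
    chunks = [record.sequence[iv.start:iv.end] for iv in feature.intervals]
    seq = "".join(chunks)
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"feature {feature.name!r}: non-ACGTN characters {sorted(bad)}")
    if feature.strand == -1:
        seq = revcomp(seq)
    return seq.upper()


# ---------------------------------------------------------------------------
# Gene order

def gene_order_from_record(record: GenomeRecord,
                           kinds: Sequence[str] = ("CDS", "ORF", "tRNA", "rRNA"),
                           ) -> GeneOrder:
    """Deterministic gene order: features sorted by start of first interval."""
    feats = sorted(record.features_of_kind(*kinds), key=lambda f: f.start)
    return GeneOrder(taxon=record.id,
                     genes=[(f.name, f.strand) for f in feats],
                     circular=record.circular)


def read_gene_order(path, taxon: str | None = None, circular: bool = True) -> GeneOrder:
    """Read a gene-table TSV (taxon, gene, start, end, strand; 1-based inclusive).

    Rows are sorted by start; duplicate gene names are kept distinct
    (e.g. split genes annotated ``rps3_a`` / ``rps3_b``).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"taxon", "gene", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene table missing columns {sorted(missing)}")
    if taxon is not None:
        df = df[df["taxon"] == taxon]
    taxa = df["taxon"].unique()
    if len(taxa) != 1:
        raise ValueError(f"{path}: expected one taxon per gene order, got {list(taxa)}")
    df = df.sort_values("start", kind="mergesort")
    # overlapping rows with identical names are suspicious but tolerated
    dup = df[df.duplicated(subset=["gene", "start"], keep=False)]
    if not dup.empty:
        warnings.warn(f"{path}: overlapping identically-named rows: "
                      f"{sorted(set(dup['gene']))}")
    genes = [(str(r.gene), 1 if str(r.strand) in ("+", "1", "+1") else -1)
             for r in df.itertuples()]
    return GeneOrder(taxon=str(taxa[0]), genes=genes, circular=circular)


def write_gene_table(record: GenomeRecord, path,
                     kinds: Sequence[str] = ("CDS", "ORF", "tRNA", "rRNA")) -> None:
    """Write the 1-based-inclusive gene-table TSV for a record."""
    rows = []
    for f in sorted(record.features_of_kind(*kinds), key=lambda f: f.start):
        rows.append({
            "taxon": record.id, "gene": f.name,
            "start": f.intervals[0].start + 1, "end": f.intervals[-1].end,
            "strand": "+" if f.strand == 1 else "-", "kind": f.kind,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees

def read_tree(path_or_string) -> dendropy.Tree:
    """Read a rooted Newick tree with unique leaf labels.

    Branch lengths are permitted and ignored downstream; basal polytomies
    are allowed. Internal nodes without labels get deterministic labels
    N1, N2, ... in preorder so that edges can be addressed by child label.
    """
    s = str(path_or_string)
    try:
        if s.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=s, schema="newick",
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(path=s, schema="newick",
                                     preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"unreadable Newick input: {exc}") from exc
    tree.is_rooted = True  # trees here are rooted; stops dendropy derooting
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dups = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels in tree: {dups}")
    ensure_internal_labels(tree)
    return tree


def ensure_internal_labels(tree: dendropy.Tree) -> dendropy.Tree:
    n = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            if node.label is None:
                node.label = node.taxon.label
        elif not node.label:
            n += 1
            node.label = f"N{n}"
    return tree


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def mrca_label(tree: dendropy.Tree, labels: Iterable[str]) -> str:
    """Label of the most recent common ancestor of the named leaves."""
    taxa = [lf.taxon for lf in tree.leaf_node_iter()
            if lf.taxon.label in set(labels)]
    return tree.mrca(taxa=taxa).label
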