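"""Gene presence/absence and Dollo-parsimony loss mapping.

Mitochondrial gene content in this clade evolves essentially by loss: a
gene present in the organellar ancestor is lost independently on different
branches but never regained (Dollo assumption). Presence/absence of
normalized gene names across taxa is therefore mapped onto a rooted
species tree as single-gain / multiple-loss characters, yielding per-branch
loss sets and ancestral gene sets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .genome_io import GenomeRecord, ensure_internal_labels

log = logging.getLogger(__name__)

_SPLIT_SUFFIX = re.compile(r"_(?:[a-e]|i+|[0-9])$")


def normalize_gene_name(name: str, synonyms: dict[str, str] | None = None) -> str:
    """Lower-case, strip split-gene suffixes (rps3_a -> rps3), apply synonyms.

    The synonym table is applied exactly once, after case folding and suffix
    stripping. Unmappable labels are returned verbatim (lower-cased) —
    never dropped.
    """
    n = name.strip().lower()
    n = _SPLIT_SUFFIX.sub("", n)
    if synonyms:
        n = synonyms.get(n, n)
    return n


@dataclass
class PresenceMatrix:
    taxa: list[str]
    genes: list[str]
    present: np.ndarray  # bool, taxa x genes

    def __post_init__(self):
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.taxa), len(self.genes)):
            raise ValueError("presence matrix shape mismatch")

    def gene_set(self, taxon: str) -> set[str]:
        i = self.taxa.index(taxon)
        return {g for g, p in zip(self.genes, self.present[i]) if p}

    def taxa_with(self, gene: str) -> set[str]:
        j = self.genes.index(gene)
        return {t for t, p in zip(self.taxa, self.present[:, j]) if p}

    def counts(self) -> dict[str, int]:
        return {t: int(self.present[i].sum()) for i, t in enumerate(self.taxa)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.present.astype(int), index=self.taxa,
                            columns=self.genes)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PresenceMatrix":
        return cls(taxa=list(df.index.astype(str)),
                   genes=list(df.columns.astype(str)),
                   present=df.to_numpy(dtype=bool))


def build_presence_matrix(records: list[GenomeRecord],
                          synonyms: dict[str, str] | None = None,
                          ) -> PresenceMatrix:
    """Presence matrix over normalized CDS gene names.

    ORFs of unknown function are excluded; split genes (``rps3_a`` +
    ``rps3_b``) collapse onto one presence via suffix normalization.
    """
    per_taxon: dict[str, set[str]] = {}
    for rec in records:
        names = set()
        for f in rec.features_of_kind("CDS"):
            norm = normalize_gene_name(f.name, synonyms)
            if synonyms is not None and norm == normalize_gene_name(f.name, None) \
                    and norm not in synonyms.values() and not _known_gene(norm):
                log.warning("%s: unmapped gene label %r kept verbatim", rec.id, norm)
            names.add(norm)
        per_taxon[rec.id] = names
    taxa = list(per_taxon)
    genes = sorted(set().union(*per_taxon.values())) if per_taxon else []
    present = np.array([[g in per_taxon[t] for g in genes] for t in taxa], dtype=bool)
    return PresenceMatrix(taxa=taxa, genes=genes, present=present)


_KNOWN_PREFIXES = ("atp", "cob", "cox", "nad", "sdh", "rps", "rpl", "rpo",
                   "tat", "sec", "ccm", "tufa", "rnl", "rns", "trn")


def _known_gene(name: str) -> bool:
    return any(name.startswith(p) for p in _KNOWN_PREFIXES)


# ---------------------------------------------------------------------------
# Dollo mapping

@dataclass
class LossMap:
    """Per-branch gene losses and per-node ancestral gene sets.

    Branches are keyed by the label of their child node (internal nodes get
    deterministic N1, N2, ... labels in preorder).
    """

    per_branch: dict[str, set[str]] = field(default_factory=dict)
    ancestral_sets: dict[str, set[str]] = field(default_factory=dict)

    def branch_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.per_branch.items() if v}

    def total_losses(self) -> int:
        return sum(len(v) for v in self.per_branch.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"branch": k, "n_lost": len(v), "genes": ",".join(sorted(v))}
                for k, v in sorted(self.per_branch.items()) if v]
        return pd.DataFrame(rows, columns=["branch", "n_lost", "genes"])


def dollo_map(matrix: PresenceMatrix, tree: dendropy.Tree,
              ancestral_set: set[str] | None = None) -> LossMap:
    """Map gene losses onto tree branches under Dollo parsimony.

    For each gene, every node is present iff at least one descendant leaf
    carries the gene; genes in ``ancestral_set`` are forced present at the
    root even when a whole side of the tree lacks them. Without an
    ancestral set, the single gain sits at the LCA of the possessing leaves
    and no losses are counted above it. A loss is an edge whose parent is
    present and whose child is not; under this construction no gene is lost
    twice on one root-to-leaf path, and the number of loss edges is minimal
    for a single-gain character.
    """
    ensure_internal_labels(tree)
    if ancestral_set is not None:
        ancestral_set = {normalize_gene_name(g) for g in ancestral_set}
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    extra = leaves - set(matrix.taxa)
    if extra:
        raise ValueError(f"tree leaves missing from matrix: {sorted(extra)}")

    losses: dict[str, set[str]] = {}
    node_sets: dict[str, set[str]] = {}
    genes = list(matrix.genes)
    if ancestral_set:
        unseen = set(ancestral_set) - set(genes)
        genes = genes + sorted(unseen)

    for gene in genes:
        holders = matrix.taxa_with(gene) if gene in matrix.genes else set()
        holders &= leaves
        rooted = ancestral_set is not None and gene in ancestral_set
        if not holders and not rooted:
            log.warning("gene %s absent from all leaves and not ancestral; skipped",
                        gene)
            continue
        present: dict[int, bool] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                present[id(node)] = node.taxon.label in holders
            else:
                present[id(node)] = any(present[id(ch)] for ch in node.child_nodes())
        root = tree.seed_node
        if rooted:
            present[id(root)] = True
            in_scope = {id(n) for n in tree.preorder_node_iter()}
        else:
            # single gain at the LCA of possessing leaves; above it the
            # character does not exist, so no losses are counted there
            lca = _lca_of(tree, holders)
            in_scope = {id(n) for n in lca.preorder_iter()}
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            par = node.parent_node
            if id(par) in in_scope and present[id(par)] and not present[id(node)]:
                losses.setdefault(node.label, set()).add(gene)
        for node in tree.preorder_node_iter():
            if id(node) in in_scope and present[id(node)]:
                node_sets.setdefault(node.label, set()).add(gene)

    lm = LossMap(per_branch=losses, ancestral_sets=node_sets)
    _check_consistency(lm, matrix, tree)
    return lm


def _lca_of(tree: dendropy.Tree, labels: set[str]):
    nodes = [lf for lf in tree.leaf_node_iter() if lf.taxon.label in labels]
    if len(nodes) == 1:
        return nodes[0]
    return tree.mrca(taxa=[n.taxon for n in nodes])


def _check_consistency(lm: LossMap, matrix: PresenceMatrix,
                       tree: dendropy.Tree) -> None:
    """Root set minus path losses must reproduce every leaf's gene set."""
    for leaf in tree.leaf_node_iter():
        expected = lm.ancestral_sets.get(leaf.taxon.label, set())
        observed = matrix.gene_set(leaf.taxon.label) & _mapped_genes(lm)
        if expected != observed:
            raise AssertionError(
                f"Dollo consistency violated at leaf {leaf.taxon.label}")


def _mapped_genes(lm: LossMap) -> set[str]:
    out: set[str] = set()
    for s in lm.ancestral_sets.values():
        out |= s
    for s in lm.per_branch.values():
        out |= s
    return out


# ---------------------------------------------------------------------------
# Missing-gene report

@dataclass
class MissingGenes:
    proteins: list[str]
    trnas: list[str]


def missing_gene_report(query: GenomeRecord, reference: GenomeRecord,
                        synonyms: dict[str, str] | None = None) -> MissingGenes:
    """Genes annotated in the reference but absent from the query.

    Pure set difference of normalized names; protein-coding genes and tRNAs
    are reported separately, unknown ORFs ignored.
    """
    def names(rec: GenomeRecord, *kinds: str) -> set[str]:
        return {normalize_gene_name(f.name, synonyms)
                for f in rec.features_of_kind(*kinds)}

    return MissingGenes(
        proteins=sorted(names(reference, "CDS") - names(query, "CDS")),
        trnas=sorted(names(reference, "tRNA") - names(query, "tRNA")),
    )
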