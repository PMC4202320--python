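#!/usr/bin/env python
"""Simulate a ten-taxon discobid-style clade under the curated loss history.

The per-branch gene losses realised by Dollo mapping of the curated
presence matrix (20 on the Heterolobosea+Tsukubamonadida stem, 6 on the
Tsukubamonas branch, 5 on the Acrasis+Naegleria stem, 16 on the Acrasis
branch, plus small jakobid terminal losses) are replayed as the planted
loss history of a synthetic clade: one compact AT-rich circular genome per
leaf, written as GenBank + FASTA + gene tables under results/sim_clade/.
"""

from pathlib import Path

from mitocomp import datasets, gene_content as gcx, genome_io as gio
from mitocomp.simulate import SimSpec, sim_clade

OUT = Path("results/sim_clade")
SEED = 2014


def main() -> None:
    matrix = datasets.load_discoba_presence()
    tree = datasets.load_discoba_tree()
    ancestral = datasets.load_jakobid_ancestral_genes()
    lm = gcx.dollo_map(matrix, tree, ancestral_set=ancestral)
    losses = {branch: frozenset(genes)
              for branch, genes in lm.per_branch.items() if genes}

    # lay the Spc-operon r-protein cluster down contiguously in the
    # ancestral gene order so cluster conservation is observable downstream
    spc = ["rpl14", "rpl5", "rps14", "rps8", "rpl6"]
    roster = [g for g in sorted(ancestral) if g not in spc]
    roster[10:10] = spc
    spec = SimSpec(seed=SEED, tree=tree, ancestral_genes=tuple(roster),
                   branch_losses=losses, n_orfs=10, n_trnas=11)
    genomes, realised = sim_clade(spec)

    OUT.mkdir(parents=True, exist_ok=True)
    for taxon, sim in genomes.items():
        gio.write_genbank(sim.record, OUT / f"{taxon}.gb")
        gio.write_gene_table(sim.record, OUT / f"{taxon}_genes.tsv")
        gio.write_fasta(sim.transcripts, OUT / f"{taxon}_transcripts.fasta")

    print(f"simulated {len(genomes)} genomes under the curated loss history")
    for branch, genes in sorted(realised.items(), key=lambda kv: -len(kv[1])):
        print(f"  {branch}: {len(genes)} genes lost")


if __name__ == "__main__":
    main()
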