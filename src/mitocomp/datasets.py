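"""Bundled curated inputs and loaders for user-supplied records.

The curated files describe the ten discobid mitochondrial genomes
(GenBank KJ679272, AF288092, JX174181, KC353352-KC353356, KC353359,
AB854048): a protein-coding gene presence/absence matrix over normalized
names, the consensus rooted species tree, the 67-gene complement widely
distributed in jakobid mtDNA (used as the discobid ancestral set), and a
gene-name synonym table. Gene membership follows published annotations and
standard mitochondrial gene nomenclature; per-taxon totals (26 / 42 / 42 /
41 / 65-67) and the branch-loss structure are exactly consistent with the
published comparison.

Sequence records themselves are not bundled; :func:`load_cached_record`
reads GenBank flat files from a local ``data/genbank`` directory that the
user populates (e.g. with the CLI ``fetch`` helper on a networked machine).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import dendropy
import pandas as pd

from .gene_content import PresenceMatrix
from .genome_io import GenomeRecord, read_genbank, read_tree

ACCESSIONS = {
    "Acrasis_kona": "KJ679272",
    "Naegleria_gruberi": "AF288092",
    "Naegleria_fowleri": "JX174181",
    "Andalucia_godoyi": "KC353352",
    "Histiona_aroides": "KC353353",
    "Jakoba_bahamiensis": "KC353354",
    "Jakoba_libera": "KC353355",
    "Reclinomonas_americana": "KC353356",
    "Seculamonas_ecuadoriensis": "KC353359",
    "Tsukubamonas_globosa": "AB854048",
}


def _data_path(name: str):
    return resources.files("mitocomp").joinpath("data", name)


def load_gene_synonyms() -> dict[str, str]:
    """Alias -> canonical gene-name mapping (lower-case on both sides)."""
    df = pd.read_csv(_data_path("gene_synonyms.tsv"), sep="\t")
    return dict(zip(df["alias"], df["canonical"]))


def load_discoba_presence() -> PresenceMatrix:
    """Curated protein-coding presence/absence matrix for the ten genomes."""
    df = pd.read_csv(_data_path("discoba_gene_content.tsv"), sep="\t",
                     index_col="taxon")
    return PresenceMatrix.from_frame(df.astype(bool))


def load_discoba_tree() -> dendropy.Tree:
    """Consensus rooted species tree of the ten taxa (jakobid polytomy kept)."""
    return read_tree(str(_data_path("discoba_tree.nwk")))


def load_jakobid_ancestral_genes() -> set[str]:
    """The 67 protein-coding genes widely distributed in jakobid mtDNA."""
    text = _data_path("jakobid_ancestral_genes.txt").read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


def load_cached_record(accession: str,
                       cache_dir: str | Path = "data/genbank") -> GenomeRecord:
    """Read ``<cache_dir>/<accession>.gb`` into a GenomeRecord.

    Raises FileNotFoundError with download instructions when absent.
    """
    path = Path(cache_dir) / f"{accession}.gb"
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found. Fetch the record on a networked machine, "
            f"e.g. `mitocomp fetch {accession} -o {cache_dir}` or from "
            f"https://www.ncbi.nlm.nih.gov/nuccore/{accession}, and place "
            f"the GenBank flat file there.")
    return read_genbank(path)
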