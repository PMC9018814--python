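"""Published copy-number and presence/absence reference data.

These are the printed clade-level intact-gene counts for 19 vertebrate
genomes, the lineage-level presence/absence summary of the four major
V2R clades, and the reference species trees (an 11-taxon representative
vertebrate tree with approximate divergence times in MY, and a
7-lineage tree).  They serve as worked-example inputs for the
tabulation and reconstruction code; they are not recomputed from
assemblies here.
"""

from __future__ import annotations

from importlib import resources

import dendropy
import pandas as pd

from .phylogeny import read_tree

CLADE_COLUMNS = ["V2R2", "ancV2R", "tV2R", "fV2R"]

#: intact-gene totals quoted in the running text for selected species
IN_TEXT_TOTALS = {
    "western_clawed_frog": 691,
    "mouse": 154,
    "caecilian": 275,
    "zebrafish": 72,
    "reedfish": 188,
    "sterlet": 46,
    "spotted_gar": 49,
}


def _data_text(name: str) -> str:
    return (resources.files("v2rscan") / "data" / name).read_text()


def load_printed_copy_numbers() -> pd.DataFrame:
    """Clade-level intact V2R counts per species (indexed by common name)."""
    import io

    df = pd.read_csv(io.StringIO(_data_text("printed_copy_numbers.tsv")), sep="\t")
    df = df.set_index("common_name")
    df["total"] = df[CLADE_COLUMNS].sum(axis=1)
    return df


def load_printed_presence_absence() -> pd.DataFrame:
    """Lineage x clade P/A matrix (columns V2R2, ancV2R, fV2R, tV2R)."""
    import io

    return pd.read_csv(
        io.StringIO(_data_text("printed_presence_absence.tsv")), sep="\t"
    ).set_index("lineage")


def load_vertebrate_tree() -> dendropy.Tree:
    """11 representative vertebrates, branch lengths in MY."""
    tree = read_tree(_data_text("vertebrate_11taxa.nwk"))
    tree.is_rooted = True
    return tree


def load_vertebrate_tree_with_agnathan() -> dendropy.Tree:
    """The 11-taxon tree plus a lamprey outgroup (agnathans carry no V2Rs;
    a zero count at that leaf anchors the jawed-vertebrate root)."""
    tree = read_tree(_data_text("vertebrate_with_agnathan.nwk"))
    tree.is_rooted = True
    return tree


def load_lineage_tree() -> dendropy.Tree:
    """Seven-lineage tree matching the presence/absence matrix rows."""
    tree = read_tree(_data_text("lineage_tree.nwk"))
    tree.is_rooted = True
    return tree
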