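"""Bundled gene sets.

The package ships the 82 nuclear-encoded mitochondrial ribosomal protein
(MRP) genes — 30 small-subunit (28S) and 52 large-subunit (39S) proteins of
the human mitoribosome — as the focal gene set of the dosage analysis.
Older aliases (MRPS29 = DAP3, MRPS39 = PTCD3, MRPL58 = ICT1,
MRPL59 = GADD45GIP1) are listed under their primary symbol.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_mrp_genes() -> pd.DataFrame:
    """Return the bundled MRP gene list (82 rows: symbol, subunit)."""
    ref = resources.files("scnadriver.data") / "mrp_genes.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def mrp_symbols() -> list[str]:
    """The 82 MRP gene symbols in bundled order."""
    return load_mrp_genes()["symbol"].tolist()
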