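"""Bundled reference tables.

The only bundled table is the transcribed list of genes commonly deregulated
in all three oncogene-addicted zebrafish liver tumor models (xmrk, kras,
Myc), with per-model fold-change magnitude and p-value. It serves as the
worked-example fixture for the model-intersection stage.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

MODELS = ("xmrk", "kras", "Myc")


def load_common_gene_table() -> pd.DataFrame:
    """Per-model FC magnitude and p-value for the commonly deregulated genes.

    Returns a DataFrame indexed by GI number with columns ``direction``
    (up/down), ``zebrafish_symbol``, ``human_symbol`` and, per model,
    ``<model>_fc`` / ``<model>_p``. Fold changes are magnitudes (>= 1) with
    the shared direction flag; '-' marks a missing human homolog symbol.
    """
    ref = resources.files("xsig.data").joinpath("common_deregulated_genes.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"gi": str})
    return df.set_index("gi")
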