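"""Map a zebrafish signature to human identifiers.

Applies the two collapsing rules: per gene cluster, the highest-expressed
transcript represents the cluster; per zebrafish cluster, the first human
homolog in the mapping resource's list represents it, with duplicates
merged and unmapped genes reported.
"""

import pandas as pd

from xsig import (
    ExpressionTable,
    SignatureGeneSet,
    collapse_transcripts,
    map_to_human,
)

transcripts = ExpressionTable(
    pd.DataFrame(
        {"tumor": [5.0, 12.0, 30.0], "control": [4.0, 2.0, 28.0]},
        index=["stmn1a_tv1", "stmn1a_tv2", "fbp1b_tv1"],
    ),
    "tpm",
)
clusters = collapse_transcripts(
    transcripts,
    {"stmn1a_tv1": "Dr.stmn1a", "stmn1a_tv2": "Dr.stmn1a",
     "fbp1b_tv1": "Dr.fbp1b"},
)
print("cluster-level TPM (max over transcripts, per sample):")
print(clusters.data)

signature = SignatureGeneSet(
    "xmrk_up", "zebrafish", ("Dr.stmn1a", "Dr.fbp1b", "Dr.orphan")
)
homologs = {
    "Dr.stmn1a": ["Hs.STMN1", "Hs.STMN2"],  # first entry wins
    "Dr.fbp1b": ["Hs.FBP1"],
}
mapped = map_to_human(signature, homologs)
print(f"\nhuman signature members: {mapped.human_members}")
print(f"unmapped zebrafish genes: {mapped.dropped}")
print("(Hs.STMN2 is never used: only the first human cluster represents "
      "each zebrafish gene)")
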