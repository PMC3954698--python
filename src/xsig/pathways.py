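"""Signed pathway-score matrix and hierarchical pathway clustering.

Per (pathway, condition) the score is the signed log-transformed FDR,
sign(NES) x min(-log10(q), cap): positive for up-regulated pathways,
negative for down-regulated, 0 when q = 1 and NaN when the pathway was not
scored in that condition. Pathways that are missing or at q = 1 in more
than ``max_missing`` conditions are excluded before clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusteringConfig:
    distance: str = "euclidean"  # or 'correlation'
    linkage: str = "average"  # or 'complete', 'single'
    missing_fill: float = 0.0
    fdr_zero_cap: float = 4.0  # q = 0 scored as 1e-4

    def __post_init__(self) -> None:
        if self.distance not in ("euclidean", "correlation"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.linkage not in ("average", "complete", "single"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if not self.fdr_zero_cap > 0:
            raise ValueError("fdr_zero_cap must be > 0")


def build_signed_matrix(
    enrichments: Mapping[str, pd.DataFrame],
    fdr_zero_cap: float = 4.0,
) -> pd.DataFrame:
    """Assemble the pathway x condition signed score matrix.

    ``enrichments`` maps condition name -> enrichment result frame (columns
    set_name, nes, fdr_q, as produced by the GSEA drivers). Cell value =
    sign(nes) x min(-log10(fdr_q), cap); q = 0 hits the cap; pathways absent
    from a condition's frame are NaN (not detected).
    """
    conditions = list(enrichments)
    pathways: list[str] = []
    for cond in conditions:
        for name in enrichments[cond]["set_name"]:
            if name not in pathways:
                pathways.append(name)
    matrix = pd.DataFrame(np.nan, index=pathways, columns=conditions)
    for cond in conditions:
        frame = enrichments[cond]
        for _, row in frame.iterrows():
            q = row["fdr_q"]
            nes = row["nes"]
            if np.isnan(nes):
                continue
            mag = fdr_zero_cap if q <= 0 else min(-np.log10(q), fdr_zero_cap)
            matrix.loc[row["set_name"], cond] = float(np.sign(nes) * mag)
    return matrix


def filter_pathways(
    matrix: pd.DataFrame, max_missing: int = 5
) -> pd.DataFrame:
    """Exclude weakly observed pathways.

    A pathway is dropped when the number of conditions in which it is
    either not detected (NaN) or at FDR = 1 (signed score exactly 0)
    exceeds ``max_missing``. Retained cell values are unchanged.
    """
    bad = matrix.isna() | (matrix == 0)
    keep = bad.sum(axis=1) <= max_missing
    dropped = int((~keep).sum())
    if dropped:
        log.info("pathway filter: excluded %d of %d pathways", dropped, len(matrix))
    return matrix.loc[keep]


@dataclass
class PathwayDendrogram:
    linkage_matrix: np.ndarray  # scipy (n-1) x 4 merge table
    leaf_names: list[str]  # input order after name sort
    leaf_order: list[str]  # dendrogram left-to-right order

    def to_newick(self) -> str:
        """Serialize the merge tree as a Newick string with branch lengths."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def _fmt(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_names[node.id]}:{length:.6g}"
            left = _fmt(node.left, node.dist)
            right = _fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return _fmt(tree, tree.dist) + ";"


def cluster_pathways(
    matrix: pd.DataFrame, config: ClusteringConfig = ClusteringConfig()
) -> PathwayDendrogram:
    """Agglomerative clustering of pathway rows.

    Rows are sorted by pathway name before linkage so that tie-breaking
    (equal distances, e.g. a constant matrix) resolves deterministically by
    name. Missing cells enter the distance computation as
    ``config.missing_fill``.
    """
    if len(matrix) < 2:
        raise ValueError("clustering requires >= 2 pathways")
    ordered = matrix.sort_index()
    values = ordered.fillna(config.missing_fill).to_numpy(dtype=float)
    if np.allclose(values, values[0]):
        log.info("constant matrix: all distances 0, merge order falls back to name order")
    dists = pdist(values, metric=config.distance)
    dists = np.nan_to_num(dists, nan=0.0)  # correlation of constant rows
    linkage_matrix = hierarchy.linkage(dists, method=config.linkage)
    leaves = hierarchy.leaves_list(linkage_matrix)
    names = list(ordered.index)
    return PathwayDendrogram(
        linkage_matrix=linkage_matrix,
        leaf_names=names,
        leaf_order=[names[i] for i in leaves],
    )
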