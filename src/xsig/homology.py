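"""Cross-species and cross-platform identifier collapsing and mapping.

Two rules carry expression values between identifier spaces:

* many-to-one collapsing (transcripts -> gene cluster, microarray probes ->
  gene cluster) keeps, per cluster and sample, the maximum expression value;
* one-to-many homolog mapping (zebrafish cluster -> ordered human cluster
  list) keeps only the first human cluster of each list, deduplicating the
  result and recording unmapped inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io import ExpressionTable
from .sage import SignatureGeneSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MappedSignature:
    """A zebrafish signature expressed in human identifiers.

    ``human_members`` is deduplicated and ordered by first occurrence;
    ``dropped`` lists input identifiers with no homolog entry.
    """

    name: str
    human_members: tuple[str, ...]
    dropped: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.human_members)) != len(self.human_members):
            raise ValueError("human_members must be unique")

    def __len__(self) -> int:
        return len(self.human_members)

    def member_set(self) -> frozenset[str]:
        return frozenset(self.human_members)


def collapse_by_max(
    table: ExpressionTable, feature_to_cluster: Mapping[str, str]
) -> ExpressionTable:
    """Collapse feature-level rows to cluster-level rows by per-sample max.

    Features absent from the mapping are dropped (count logged). Cluster
    rows are ordered by first appearance of their features in the input,
    so the reader's no-reorder guarantee carries through.
    """
    keep = [g for g in table.gene_ids if g in feature_to_cluster]
    n_dropped = table.n_genes - len(keep)
    if n_dropped:
        log.info("collapse: dropped %d unmapped feature(s)", n_dropped)
    if not keep:
        raise ValueError("no features map to any cluster")
    sub = table.data.loc[keep]
    clusters = pd.Series([feature_to_cluster[g] for g in keep], index=sub.index)
    collapsed = sub.groupby(clusters, sort=False).max()
    return ExpressionTable(collapsed, table.value_kind)


def collapse_transcripts(
    transcript_tpm: ExpressionTable, transcript_to_cluster: Mapping[str, str]
) -> ExpressionTable:
    """Represent each gene cluster by its highest-TPM transcript, per sample."""
    return collapse_by_max(transcript_tpm, transcript_to_cluster)


def collapse_probes(
    probe_intensities: ExpressionTable, probe_to_cluster: Mapping[str, str]
) -> ExpressionTable:
    """Represent each gene cluster by its maximum probe signal, per sample."""
    return collapse_by_max(probe_intensities, probe_to_cluster)


def map_to_human(
    signature: SignatureGeneSet,
    homolog_table: Mapping[str, Sequence[str]],
) -> MappedSignature:
    """Map a zebrafish signature to human identifiers.

    Each member maps to the *first* human cluster in its homolog list (the
    list order is authoritative input); the output is deduplicated because
    distinct zebrafish genes may share a first human homolog. Members with
    no entry are recorded in ``dropped``.
    """
    human: dict[str, None] = {}
    dropped: list[str] = []
    for member in signature.members:
        targets = homolog_table.get(member)
        if not targets:
            dropped.append(member)
            continue
        human.setdefault(targets[0], None)
    if dropped:
        log.info(
            "signature %r: %d member(s) had no human homolog",
            signature.name,
            len(dropped),
        )
    return MappedSignature(signature.name, tuple(human), tuple(dropped))
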