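"""One-vs-rest classification of cohort samples against tumor signatures.

Each sample (or stage group) of a human cohort is treated as a singleton
phenotype class, the genes are ranked by how much the sample deviates from
the rest of the cohort, and each zebrafish-derived signature is scored by
the running-sum enrichment statistic. The phenotype-permutation null for a
singleton class is the set of rankings obtained by letting every other
sample play the singleton role; with n samples there are exactly n distinct
arrangements, so the null is enumerated exhaustively whenever n is within
the permutation budget. A sample is called "correlated" with a signature
when FDR q < 0.25 with positive NES.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gsea import (
    GseaConfig,
    _class_scores,
    _sorted_ranking,
    batch_random_set_es,
    enrichment_score,
    normalize_and_fdr,
)
from .homology import MappedSignature
from .io import ExpressionTable, PhenotypeLabels
from .sage import SignatureGeneSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassificationCriteria:
    """Significance rule for calling a sample correlated with a signature."""

    fdr_max: float = 0.25
    require_positive: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must be in (0, 1)")


def _signature_members(sig) -> tuple[str, frozenset[str]]:
    if isinstance(sig, (MappedSignature, SignatureGeneSet)):
        return sig.name, sig.member_set()
    name, members = sig
    return name, frozenset(members)


def _singleton_es_matrix(
    expr: ExpressionTable,
    signatures: Sequence,
    config: GseaConfig,
) -> tuple[np.ndarray, list[str], list[frozenset[str]], dict, np.ndarray]:
    """ES of every signature on every singleton-vs-rest ranking.

    Returns (es matrix n_samples x n_signatures, names, member sets,
    per-(sample, signature) leading edges, per-sample sorted ranking
    scores). Signatures whose overlap with the platform universe is below
    ``config.min_set_overlap`` get NaN columns (no-result marker).
    """
    x = expr.data.to_numpy(dtype=float)
    gene_ids = np.asarray(expr.gene_ids, dtype=object)
    universe = set(expr.gene_ids)
    n = expr.n_samples
    if n < 4:
        raise ValueError("singleton-vs-rest requires >= 4 samples")
    names: list[str] = []
    member_sets: list[frozenset[str]] = []
    scorable: list[bool] = []
    for sig in signatures:
        name, members = _signature_members(sig)
        overlap = members & universe
        names.append(name)
        member_sets.append(frozenset(overlap))
        ok = len(overlap) >= config.min_set_overlap
        if not ok:
            log.info(
                "signature %r: overlap %d below minimum %d (no-result)",
                name,
                len(overlap),
                config.min_set_overlap,
            )
        scorable.append(ok)

    es = np.full((n, len(names)), np.nan)
    leads: dict[tuple[int, int], tuple[str, ...]] = {}
    sorted_scores = np.empty((n, expr.n_genes))
    for i in range(n):
        mask = np.zeros(n, dtype=bool)
        mask[i] = True
        scores = _class_scores(x, mask, config.ranking_metric)
        ranked = _sorted_ranking(gene_ids, scores)
        sorted_scores[i] = ranked.scores
        for j, members in enumerate(member_sets):
            if not scorable[j]:
                continue
            e, _, lead = enrichment_score(ranked, members, config.weight_exponent)
            es[i, j] = e
            leads[(i, j)] = lead
    return es, names, member_sets, leads, sorted_scores


def classify_cohort(
    expr: ExpressionTable,
    signatures: Sequence,
    config: GseaConfig = GseaConfig(),
    criteria: ClassificationCriteria = ClassificationCriteria(),
    dataset_id: str = "dataset",
) -> pd.DataFrame:
    """Classify every sample of a cohort against every signature.

    Returns one row per (sample, signature) with es, nes, fdr_q, the
    correlated flag, and a reason code ('ok' or 'low_overlap').

    The null follows ``config.permutation_mode``. In ``gene_set`` mode
    (the established recommendation for singleton phenotype classes) each
    run's null is the ES of random same-size gene sets on that sample's own
    ranking. In ``phenotype`` mode the null is the singleton-arrangement
    null (which sample plays the singleton role), shared across the cohort
    and exhaustive whenever n <= config.n_permutations; note that with a
    strongly structured cohort this null contains the other correlated
    samples, which makes it conservative for subgroup recovery.
    """
    es, names, member_sets, leads, sorted_scores = _singleton_es_matrix(
        expr, signatures, config
    )
    n = expr.n_samples
    gene_set_mode = config.permutation_mode == "gene_set"
    exhaustive = (not gene_set_mode) and n <= config.n_permutations
    rng = np.random.default_rng(config.rng_seed)
    rows = []
    for j, name in enumerate(names):
        col = es[:, j]
        if np.all(np.isnan(col)):
            for i, sample in enumerate(expr.sample_ids):
                rows.append(
                    (dataset_id, sample, name, np.nan, np.nan, np.nan, False,
                     "low_overlap")
                )
            continue
        if not gene_set_mode:
            if exhaustive:
                shared_null = col
            else:
                shared_null = col[
                    rng.choice(n, size=config.n_permutations, replace=False)
                ]
        for i, sample in enumerate(expr.sample_ids):
            obs = col[i]
            if gene_set_mode:
                null = batch_random_set_es(
                    sorted_scores[i],
                    len(member_sets[j]),
                    config.n_permutations,
                    config.weight_exponent,
                    rng,
                )
            else:
                null = shared_null
            stat = normalize_and_fdr(
                {name: obs}, {name: null}, {name: leads.get((i, j), ())},
                {name: len(member_sets[j])}, exhaustive=exhaustive,
            )[0]
            correlated = bool(
                stat.fdr_q < criteria.fdr_max
                and (stat.nes > 0 or not criteria.require_positive)
                and not np.isnan(stat.nes)
            )
            rows.append(
                (dataset_id, sample, name, stat.es, stat.nes, stat.fdr_q,
                 correlated, "ok")
            )
    return pd.DataFrame(
        rows,
        columns=[
            "dataset_id",
            "sample_id",
            "signature",
            "es",
            "nes",
            "fdr_q",
            "correlated",
            "reason",
        ],
    )


def classify_sample(
    expr: ExpressionTable,
    sample_id: str,
    signature,
    config: GseaConfig = GseaConfig(),
):
    """Full enrichment statistic for one sample against one signature.

    Returns an EnrichmentStat, or None (no-result marker) when the
    signature's overlap with the platform is below the configured minimum.
    """
    if sample_id not in expr.sample_ids:
        raise KeyError(f"unknown sample {sample_id!r}")
    es, names, member_sets, leads, sorted_scores = _singleton_es_matrix(
        expr, [signature], config
    )
    if np.all(np.isnan(es[:, 0])):
        return None
    i = expr.sample_ids.index(sample_id)
    n = expr.n_samples
    col = es[:, 0]
    if config.permutation_mode == "gene_set":
        exhaustive = False
        null = batch_random_set_es(
            sorted_scores[i],
            len(member_sets[0]),
            config.n_permutations,
            config.weight_exponent,
            np.random.default_rng(config.rng_seed),
        )
    else:
        exhaustive = n <= config.n_permutations
        null = col if exhaustive else col[: config.n_permutations]
    return normalize_and_fdr(
        {names[0]: col[i]},
        {names[0]: null},
        {names[0]: leads.get((i, 0), ())},
        {names[0]: len(member_sets[0])},
        exhaustive=exhaustive,
    )[0]


@dataclass
class RepresentationSummary:
    """Percentages of samples flagged per signature and in combination."""

    per_dataset: pd.DataFrame  # rows: dataset; columns: see overall keys
    overall: dict[str, float]
    n_samples: int

    def __getitem__(self, key: str) -> float:
        return self.overall[key]


def _summary_for_flags(flags: pd.DataFrame) -> dict[str, float]:
    """flags: samples x signatures boolean frame -> percentage summary."""
    n = len(flags)
    sigs = list(flags.columns)
    out: dict[str, float] = {}
    for s in sigs:
        out[f"pct_{s}"] = 100.0 * flags[s].sum() / n
    out["pct_any"] = 100.0 * flags.any(axis=1).sum() / n
    for i, a in enumerate(sigs):
        for b in sigs[i + 1 :]:
            out[f"pct_{a}+{b}"] = 100.0 * (flags[a] & flags[b]).sum() / n
    if len(sigs) >= 3:
        out["pct_all"] = 100.0 * flags.all(axis=1).sum() / n
    return out


def summarize_representation(
    table: pd.DataFrame, dataset_weighted: bool = True
) -> RepresentationSummary:
    """Summarize a classification table into representation percentages.

    Per dataset: percentage of samples correlated with each signature, with
    at least one ('pct_any'), with each unordered pair, and with all three.
    The overall row is sample-weighted across datasets by default (total
    flagged / total samples); set ``dataset_weighted=False`` to average the
    per-dataset percentages instead. Samples with no-result markers remain
    in denominators.
    """
    if table.empty:
        raise ValueError("empty classification table")
    flags = table.pivot_table(
        index=["dataset_id", "sample_id"],
        columns="signature",
        values="correlated",
        aggfunc="first",
    ).fillna(False).astype(bool)
    per_rows = {}
    for ds, sub in flags.groupby(level="dataset_id"):
        per_rows[ds] = _summary_for_flags(sub)
    per_dataset = pd.DataFrame(per_rows).T
    if dataset_weighted:
        overall = _summary_for_flags(flags)
    else:
        overall = per_dataset.mean(axis=0).to_dict()
    _check_summary(overall)
    return RepresentationSummary(per_dataset, overall, n_samples=len(flags))


def _check_summary(summary: Mapping[str, float]) -> None:
    per_sig = [v for k, v in summary.items()
               if k.startswith("pct_") and "+" not in k and k not in ("pct_any", "pct_all")]
    if per_sig and summary.get("pct_any", 100.0) < max(per_sig) - 1e-9:
        raise AssertionError("pct_any below a per-signature percentage")
    pairs = [v for k, v in summary.items() if "+" in k]
    if pairs and "pct_all" in summary and summary["pct_all"] > min(pairs) + 1e-9:
        raise AssertionError("triple percentage exceeds a pairwise percentage")


def stage_enrichment(
    expr: ExpressionTable,
    stage_labels: PhenotypeLabels,
    signature,
    config: GseaConfig = GseaConfig(),
    stage_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Stage-vs-rest enrichment profile across ordered disease stages.

    One enrichment run per stage (the stage's samples vs all others), in
    the given stage order. Stages with >= 2 samples use the two-class
    ranking statistic; singleton stages fall back to the singleton rule.
    Returns a DataFrame with stage, n_samples, es, nes, fdr_q, significant.
    """
    if list(expr.sample_ids) != list(stage_labels.sample_ids):
        raise ValueError("expression samples and stage labels differ")
    labels = np.asarray(stage_labels.labels, dtype=object)
    present = list(dict.fromkeys(labels))
    if stage_order is None:
        stage_order = present
    unknown = [s for s in stage_order if s not in present]
    if unknown:
        raise ValueError(f"unknown stage label(s): {unknown}")
    if len(present) < 2:
        raise ValueError("stage analysis requires >= 2 distinct stages")
    name, members = _signature_members(signature)
    overlap = members & set(expr.gene_ids)
    if len(overlap) < config.min_set_overlap:
        raise ValueError(f"signature {name!r} overlap below minimum")
    x = expr.data.to_numpy(dtype=float)
    gene_ids = np.asarray(expr.gene_ids, dtype=object)
    rows = []
    for stage in stage_order:
        mask = labels == stage
        scores = _class_scores(x, mask, config.ranking_metric)
        ranked = _sorted_ranking(gene_ids, scores)
        es, _, _ = enrichment_score(ranked, overlap, config.weight_exponent)
        from .gsea import phenotype_null_es  # local import to avoid cycle noise

        null, exhaustive = phenotype_null_es(
            expr, stage_labels, stage, [overlap], config
        )
        stat = normalize_and_fdr(
            {name: es}, {name: null[:, 0]}, {name: ()}, {name: len(overlap)},
            exhaustive=exhaustive,
        )[0]
        rows.append(
            (stage, int(mask.sum()), stat.es, stat.nes, stat.fdr_q,
             bool(stat.fdr_q < 0.25 and stat.nes > 0))
        )
    return pd.DataFrame(
        rows, columns=["stage", "n_samples", "es", "nes", "fdr_q", "significant"]
    )
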