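"""From-scratch gene-set enrichment engine.

Implements the running-sum enrichment statistic: walking a ranked gene list,
the sum increments at gene-set hits (by |score|^w normalized over hits) and
decrements at misses (by 1/(N - n_hits)); the enrichment score (ES) is the
signed maximum deviation from zero. Significance comes from permutation
nulls — phenotype permutation (relabel samples and re-rank) or gene-set
permutation (random sets of equal size on a fixed ranking) — normalized
enrichment scores (NES), add-one-smoothed nominal p-values, and a
pooled-null NES-ratio FDR q.

Ranking metrics: a two-sample t statistic for class-vs-rest comparisons
(with a singleton-class variant), a signal-to-noise option, and a
signed -log10(p) metric for pre-ranked analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionTable, GeneSetCollection, PhenotypeLabels

log = logging.getLogger(__name__)

_TINY_P = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class GseaConfig:
    """Knobs of the enrichment engine.

    weight_exponent
        Exponent w on |ranking score| in hit increments. w = 1 is the
        established default of the weighted statistic; w = 0 gives the
        classic Kolmogorov-Smirnov form with analytic extreme cases.
    n_permutations
        Null sample size (1000 reproduces the study-scale setting; tests
        use fewer). If the number of distinct label arrangements is at most
        this, the null is enumerated exhaustively instead.
    permutation_mode
        'phenotype' (relabel samples, re-rank, re-score: the cohort
        classification null) or 'gene_set' (random same-size sets on the
        fixed ranking: the pre-ranked null).
    rng_seed
        Seed for the permutation RNG; identical seeds give identical nulls.
    min_set_overlap
        Minimum members of a set present in the ranked universe for the set
        to be scored.
    ranking_metric
        'ttest' (as used for class-vs-rest ranking here) or
        'signal_to_noise' (difference of class means over sum of class
        standard deviations).
    """

    weight_exponent: float = 1.0
    n_permutations: int = 1000
    permutation_mode: str = "phenotype"
    rng_seed: int = 0
    min_set_overlap: int = 5
    ranking_metric: str = "ttest"

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.permutation_mode not in ("phenotype", "gene_set"):
            raise ValueError(f"unknown permutation_mode {self.permutation_mode!r}")
        if self.ranking_metric not in ("ttest", "signal_to_noise"):
            raise ValueError(f"unknown ranking_metric {self.ranking_metric!r}")


@dataclass
class RankedGeneList:
    """Genes ordered best-to-worst with their (non-increasing) scores."""

    gene_ids: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.gene_ids.shape != self.scores.shape:
            raise ValueError("gene_ids and scores must have equal length")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("ranked gene ids must be unique")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentStat:
    """Full enrichment result for one (ranked list, gene set) pair."""

    set_name: str
    es: float
    nes: float  # NaN when undefined (no same-sign nulls)
    p_nominal: float
    fdr_q: float
    leading_edge: tuple[str, ...]
    overlap_size: int


def _sorted_ranking(gene_ids: Sequence[str], scores: np.ndarray) -> RankedGeneList:
    """Sort descending by score, ties broken lexicographically by gene id."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    scores = np.asarray(scores, dtype=float)
    order = np.lexsort((gene_ids.astype(str), -scores))
    return RankedGeneList(gene_ids[order], scores[order])


def _class_scores(
    x: np.ndarray, in_target: np.ndarray, metric: str
) -> np.ndarray:
    """Per-gene ranking score for target-class vs rest.

    x: genes x samples; in_target: boolean sample mask. Zero-variance genes
    get a variance floor (smallest nonzero pooled variance) so their score
    is defined.
    """
    nt = int(in_target.sum())
    nr = int((~in_target).sum())
    if nt < 1:
        raise ValueError("target class has no samples")
    if nr < 3:
        raise ValueError("rest class needs >= 3 samples for a stable sd")
    xt = x[:, in_target]
    xr = x[:, ~in_target]
    mt, mr = xt.mean(axis=1), xr.mean(axis=1)
    vr = xr.var(axis=1, ddof=1)
    if nt == 1:
        # singleton class: studentize against the rest-only spread
        sd = np.sqrt(_floor(vr))
        return (xt[:, 0] - mr) / sd
    vt = xt.var(axis=1, ddof=1)
    if metric == "signal_to_noise":
        denom = np.sqrt(_floor(vt)) + np.sqrt(_floor(vr))
        return (mt - mr) / denom
    pooled = ((nt - 1) * vt + (nr - 1) * vr) / (nt + nr - 2)
    pooled = _floor(pooled)
    return (mt - mr) / np.sqrt(pooled * (1 / nt + 1 / nr))


def _floor(var: np.ndarray) -> np.ndarray:
    var = np.asarray(var, dtype=float).copy()
    nonzero = var[var > 0]
    var[var == 0] = float(nonzero.min()) if nonzero.size else 1.0
    return var


def _binarize(labels: PhenotypeLabels, target_class: str) -> np.ndarray:
    lab = np.asarray(labels.labels, dtype=object)
    if target_class not in lab:
        raise ValueError(f"target class {target_class!r} not present in labels")
    return lab == target_class


def rank_by_ttest(
    expr: ExpressionTable,
    labels: PhenotypeLabels,
    target_class: str,
    metric: str = "ttest",
) -> RankedGeneList:
    """Rank all genes by a target-class-vs-rest test statistic.

    With >= 2 target samples the score is the two-sample (pooled) t
    statistic, target minus rest; a singleton target uses
    (x_target - mean_rest) / sd_rest. Sorted descending, ties broken by
    gene id.
    """
    if list(expr.sample_ids) != list(labels.sample_ids):
        raise ValueError("expression samples and phenotype samples differ")
    in_target = _binarize(labels, target_class)
    scores = _class_scores(expr.data.to_numpy(dtype=float), in_target, metric)
    return _sorted_ranking(expr.gene_ids, scores)


def rank_preranked(signed_pvalues: pd.DataFrame) -> RankedGeneList:
    """Rank genes by signed log10 p-value.

    Input: DataFrame with columns ``gene_id``, ``p_value``, ``direction``
    (up/down). Score = -log10(p) for up-regulated genes and +log10(p)
    (a negative value) for down-regulated ones; p = 0 is clamped to the
    smallest positive float with a warning.
    """
    p = signed_pvalues["p_value"].to_numpy(dtype=float).copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        log.warning("clamped %d zero p-value(s)", int((p == 0).sum()))
        p[p == 0] = _TINY_P
    direction = signed_pvalues["direction"].to_numpy(dtype=object)
    if not set(direction) <= {"up", "down"}:
        raise ValueError("direction must be 'up' or 'down'")
    sign = np.where(direction == "up", 1.0, -1.0)
    scores = sign * (-np.log10(p))
    return _sorted_ranking(signed_pvalues["gene_id"].to_numpy(dtype=object), scores)


def enrichment_score(
    ranked: RankedGeneList,
    set_members: Iterable[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray, tuple[str, ...]]:
    """Running-sum enrichment score of a gene set along a ranked list.

    Returns (es, running_sum, leading_edge). The running sum increments by
    |score|^w / sum_hits(|score|^w) at each hit and decrements by
    1/(N - n_hits) at each miss; ES is the value of the running sum at its
    maximum absolute deviation (first such position on ties). The leading
    edge is the hits at or before the extremum for positive ES, at or after
    it for negative ES. Zero overlap returns (nan, empty, ()).
    """
    members = set(set_members)
    hit = np.fromiter((g in members for g in ranked.gene_ids), bool, len(ranked))
    n = len(ranked)
    n_hits = int(hit.sum())
    if n_hits == 0:
        return float("nan"), np.array([]), ()
    if n_hits == n:
        raise ValueError("gene set covers the whole ranked universe")
    weights = np.abs(ranked.scores) ** weight_exponent
    hit_w = weights[hit]
    norm = hit_w.sum()
    if norm == 0:  # all hit scores exactly 0 at w > 0: fall back to equal steps
        hit_w = np.ones(n_hits)
        norm = float(n_hits)
    steps = np.full(n, -1.0 / (n - n_hits))
    steps[hit] = hit_w / norm
    running = np.cumsum(steps)
    # first position within tolerance of the max deviation; the tolerance
    # makes exact positive/negative ties resolve identically across
    # summation orders
    max_abs = float(np.abs(running).max())
    extremum = int(np.argmax(np.abs(running) >= max_abs - 1e-12))
    es = float(running[extremum])
    hit_idx = np.flatnonzero(hit)
    if es >= 0:
        lead = hit_idx[hit_idx <= extremum]
    else:
        lead = hit_idx[hit_idx >= extremum]
    leading_edge = tuple(ranked.gene_ids[lead])
    return es, running, leading_edge


# ---------------------------------------------------------------------------
# permutation nulls


def _n_singleton_arrangements(n: int) -> int:
    return n


def _two_class_arrangements(n: int, k: int) -> int:
    return math.comb(n, k)


def phenotype_null_es(
    expr: ExpressionTable,
    labels: PhenotypeLabels,
    target_class: str,
    set_members_list: Sequence[Iterable[str]],
    config: GseaConfig,
) -> tuple[np.ndarray, bool]:
    """Null ES samples under phenotype (sample-label) permutation.

    Re-ranks the genes for every relabeling and scores every set on the
    shared permuted ranking. Returns (null matrix of shape
    n_arrangements x n_sets, exhaustive flag). When the number of distinct
    arrangements is at most ``config.n_permutations``, all arrangements are
    enumerated (including the observed one); otherwise arrangements are
    sampled uniformly with the seeded RNG.
    """
    in_target = _binarize(labels, target_class)
    n = len(in_target)
    k = int(in_target.sum())
    x = expr.data.to_numpy(dtype=float)
    gene_ids = np.asarray(expr.gene_ids, dtype=object)
    n_distinct = _two_class_arrangements(n, k)
    rng = np.random.default_rng(config.rng_seed)

    if n_distinct <= config.n_permutations:
        arrangements = [np.array(c) for c in combinations(range(n), k)]
        exhaustive = True
        log.info(
            "exhaustive phenotype null: %d distinct arrangements", n_distinct
        )
    else:
        arrangements = [
            rng.permutation(n)[:k] for _ in range(config.n_permutations)
        ]
        exhaustive = False

    member_sets = [set(m) for m in set_members_list]
    null = np.empty((len(arrangements), len(member_sets)))
    for i, idx in enumerate(arrangements):
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        scores = _class_scores(x, mask, config.ranking_metric)
        ranked = _sorted_ranking(gene_ids, scores)
        for j, members in enumerate(member_sets):
            es, _, _ = enrichment_score(ranked, members, config.weight_exponent)
            null[i, j] = es
    return null, exhaustive


def batch_random_set_es(
    sorted_scores: np.ndarray,
    set_size: int,
    n_sets: int,
    weight_exponent: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """ES of ``n_sets`` uniformly random gene sets of ``set_size`` on a
    fixed ranking, vectorized. ``sorted_scores`` are the ranking scores in
    rank order (best first)."""
    n = len(sorted_scores)
    k = set_size
    if not 0 < k < n:
        raise ValueError("set_size must be in (0, n)")
    weights = np.abs(sorted_scores) ** weight_exponent
    keys = rng.random((n_sets, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    hit = np.zeros((n_sets, n), dtype=bool)
    hit[np.repeat(np.arange(n_sets), k), idx.ravel()] = True
    w = np.where(hit, weights[None, :], 0.0)
    norm = w.sum(axis=1, keepdims=True)
    flat = norm[:, 0] == 0  # all-zero hit weights: fall back to equal steps
    if flat.any():
        w[flat] = hit[flat].astype(float)
        norm = w.sum(axis=1, keepdims=True)
    steps = np.where(hit, w / norm, -1.0 / (n - k))
    running = np.cumsum(steps, axis=1)
    abs_running = np.abs(running)
    max_abs = abs_running.max(axis=1, keepdims=True)
    extremum = np.argmax(abs_running >= max_abs - 1e-12, axis=1)
    return running[np.arange(n_sets), extremum]


def gene_set_null_es(
    ranked: RankedGeneList,
    overlap_sizes: Sequence[int],
    config: GseaConfig,
) -> np.ndarray:
    """Null ES by resampling random gene sets of matched size on a fixed
    ranking (the pre-ranked null). Returns n_permutations x n_sets."""
    rng = np.random.default_rng(config.rng_seed)
    null = np.empty((config.n_permutations, len(overlap_sizes)))
    for j, size in enumerate(overlap_sizes):
        null[:, j] = batch_random_set_es(
            ranked.scores, size, config.n_permutations, config.weight_exponent, rng
        )
    return null


def permutation_null(
    expr: ExpressionTable,
    labels: PhenotypeLabels,
    target_class: str,
    set_members: Iterable[str],
    config: GseaConfig,
) -> np.ndarray:
    """Null ES sample for one gene set (see phenotype_null_es /
    gene_set_null_es for the two modes)."""
    members = set(set_members)
    if config.permutation_mode == "phenotype":
        null, _ = phenotype_null_es(expr, labels, target_class, [members], config)
        return null[:, 0]
    ranked = rank_by_ttest(expr, labels, target_class, config.ranking_metric)
    overlap = sum(1 for g in ranked.gene_ids if g in members)
    return gene_set_null_es(ranked, [overlap], config)[:, 0]


# ---------------------------------------------------------------------------
# normalization, nominal p, FDR


def _same_sign(null: np.ndarray, es: float) -> np.ndarray:
    if es >= 0:
        return null[null >= 0]
    return null[null < 0]


def nominal_p(es: float, null: np.ndarray, exhaustive: bool = False) -> float:
    """Empirical same-sign tail probability of the observed ES.

    Sampled nulls use add-one smoothing (never returns 0); exhaustive nulls
    contain the observed arrangement, so the plain count ratio is already
    positive and is used unsmoothed.
    """
    ss = _same_sign(null, es)
    hits = int(np.sum(np.abs(ss) >= abs(es)))
    if len(ss) == 0:
        return 1.0 / (len(null) + 1)
    if exhaustive:
        return max(hits, 1) / len(ss)
    return (1 + hits) / (1 + len(ss))


def normalize_and_fdr(
    observed: Mapping[str, float],
    nulls: Mapping[str, np.ndarray],
    leading_edges: Mapping[str, tuple[str, ...]] | None = None,
    overlap_sizes: Mapping[str, int] | None = None,
    exhaustive: bool = False,
) -> list[EnrichmentStat]:
    """NES, nominal p and FDR q for a batch of sets sharing a null scheme.

    NES = ES / mean(|same-sign null ES|) per set; null ES are normalized the
    same way by their own set's sign means. FDR q for a positive NES is

        [frac. of pooled normalized null NES >= NES] /
        [frac. of observed NES >= NES]

    (mirrored for negative NES), clipped to [0, 1] and made monotone
    non-increasing in |NES| within each sign.
    """
    names = list(observed)
    nes: dict[str, float] = {}
    pnom: dict[str, float] = {}
    pooled: list[np.ndarray] = []
    for name in names:
        es = observed[name]
        null = np.asarray(nulls[name], dtype=float)
        null = null[~np.isnan(null)]
        pos = null[null >= 0]
        neg = null[null < 0]
        pos_mean = float(np.mean(pos)) if pos.size else np.nan
        neg_mean = float(np.mean(np.abs(neg))) if neg.size else np.nan
        norm_null = np.concatenate(
            [
                pos / pos_mean if (pos.size and pos_mean > 0) else pos * np.nan,
                neg / neg_mean if neg.size else neg,
            ]
        )
        pooled.append(norm_null[~np.isnan(norm_null)])
        if np.isnan(es):
            nes[name] = np.nan
            pnom[name] = 1.0
            continue
        pnom[name] = nominal_p(es, null, exhaustive)
        if es >= 0:
            nes[name] = es / pos_mean if (pos.size and pos_mean > 0) else np.nan
        else:
            nes[name] = es / neg_mean if neg.size else np.nan

    pooled_all = np.concatenate(pooled) if pooled else np.array([])
    obs_nes = np.array([nes[n] for n in names], dtype=float)

    def _fdr(value: float) -> float:
        if np.isnan(value):
            return 1.0
        if value >= 0:
            null_pos = pooled_all[pooled_all >= 0]
            obs_pos = obs_nes[(~np.isnan(obs_nes)) & (obs_nes >= 0)]
            num = np.mean(null_pos >= value) if null_pos.size else 0.0
            den = np.mean(obs_pos >= value) if obs_pos.size else 1.0
        else:
            null_neg = pooled_all[pooled_all < 0]
            obs_neg = obs_nes[(~np.isnan(obs_nes)) & (obs_nes < 0)]
            num = np.mean(null_neg <= value) if null_neg.size else 0.0
            den = np.mean(obs_neg <= value) if obs_neg.size else 1.0
        return float(np.clip(num / den if den > 0 else 1.0, 0.0, 1.0))

    q = {n: _fdr(nes[n]) for n in names}
    # monotone within each sign: a larger |NES| never has larger q, so each
    # set takes the running minimum over itself and all less extreme sets
    # (processed in increasing |NES| order)
    for sign in (1, -1):
        sel = [
            n
            for n in names
            if not np.isnan(nes[n]) and (nes[n] >= 0 if sign == 1 else nes[n] < 0)
        ]
        sel.sort(key=lambda n: abs(nes[n]))
        best = math.inf
        for n in sel:
            best = min(best, q[n])
            q[n] = best

    leading_edges = leading_edges or {}
    overlap_sizes = overlap_sizes or {}
    return [
        EnrichmentStat(
            set_name=n,
            es=float(observed[n]) if not np.isnan(observed[n]) else float("nan"),
            nes=float(nes[n]),
            p_nominal=float(pnom[n]),
            fdr_q=float(q[n]),
            leading_edge=tuple(leading_edges.get(n, ())),
            overlap_size=int(overlap_sizes.get(n, 0)),
        )
        for n in names
    ]


# ---------------------------------------------------------------------------
# top-level drivers


def _usable_sets(
    collection: GeneSetCollection, universe: Sequence[str], min_overlap: int
) -> dict[str, set[str]]:
    uni = set(universe)
    usable: dict[str, set[str]] = {}
    for gs in collection:
        overlap = set(gs.members) & uni
        if len(overlap) >= max(min_overlap, 1):
            usable[gs.name] = overlap
        else:
            log.info(
                "set %r skipped: overlap %d below minimum %d",
                gs.name,
                len(overlap),
                min_overlap,
            )
    return usable


def gsea(
    expr: ExpressionTable,
    labels: PhenotypeLabels,
    target_class: str,
    gene_sets: GeneSetCollection,
    config: GseaConfig = GseaConfig(),
) -> pd.DataFrame:
    """Phenotype-permutation GSEA of a target class vs the rest.

    Returns one row per scorable gene set: es, nes, p_nominal, fdr_q,
    overlap_size, leading_edge ('|'-joined).
    """
    ranked = rank_by_ttest(expr, labels, target_class, config.ranking_metric)
    usable = _usable_sets(gene_sets, ranked.gene_ids, config.min_set_overlap)
    if not usable:
        return _empty_result_frame()
    names = list(usable)
    observed: dict[str, float] = {}
    leads: dict[str, tuple[str, ...]] = {}
    sizes: dict[str, int] = {}
    for name in names:
        es, _, lead = enrichment_score(ranked, usable[name], config.weight_exponent)
        observed[name] = es
        leads[name] = lead
        sizes[name] = len(usable[name])
    if config.permutation_mode == "phenotype":
        null, exhaustive = phenotype_null_es(
            expr, labels, target_class, [usable[n] for n in names], config
        )
    else:
        null = gene_set_null_es(ranked, [sizes[n] for n in names], config)
        exhaustive = False
    stats = normalize_and_fdr(
        observed,
        {n: null[:, j] for j, n in enumerate(names)},
        leads,
        sizes,
        exhaustive,
    )
    return _stats_frame(stats)


def gsea_preranked(
    ranked: RankedGeneList,
    gene_sets: GeneSetCollection,
    config: GseaConfig = GseaConfig(),
) -> pd.DataFrame:
    """Pre-ranked GSEA with a gene-set permutation null on a fixed ranking."""
    usable = _usable_sets(gene_sets, ranked.gene_ids, config.min_set_overlap)
    if not usable:
        return _empty_result_frame()
    names = list(usable)
    observed: dict[str, float] = {}
    leads: dict[str, tuple[str, ...]] = {}
    sizes: dict[str, int] = {}
    for name in names:
        es, _, lead = enrichment_score(ranked, usable[name], config.weight_exponent)
        observed[name] = es
        leads[name] = lead
        sizes[name] = len(usable[name])
    null = gene_set_null_es(ranked, [sizes[n] for n in names], config)
    stats = normalize_and_fdr(
        observed,
        {n: null[:, j] for j, n in enumerate(names)},
        leads,
        sizes,
        exhaustive=False,
    )
    return _stats_frame(stats)


def _stats_frame(stats: Sequence[EnrichmentStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [s.set_name for s in stats],
            "es": [s.es for s in stats],
            "nes": [s.nes for s in stats],
            "p_nominal": [s.p_nominal for s in stats],
            "fdr_q": [s.fdr_q for s in stats],
            "overlap_size": [s.overlap_size for s in stats],
            "leading_edge": ["|".join(s.leading_edge) for s in stats],
        }
    )


def _empty_result_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "set_name",
            "es",
            "nes",
            "p_nominal",
            "fdr_q",
            "overlap_size",
            "leading_edge",
        ]
    )
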