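"""Self-contained evaluation studies of the pipeline's statistical behavior.

Each function generates its own inputs (bundled worked-example table or
seeded synthetic data), runs the relevant pipeline stage, and returns the
measured quantities: worked-example counts, oracle agreement of the
running-sum statistic, permutation-test calibration, planted-truth recovery
for both the differential-expression stage and the per-sample cohort
classifier, and the pathway-filter boundary behavior. The test suite
asserts on these numbers; the acceptance script reports them.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .classify import classify_cohort
from .gsea import (
    GseaConfig,
    RankedGeneList,
    enrichment_score,
    gsea,
)
from .io import ExpressionTable, GeneSet, GeneSetCollection, PhenotypeLabels
from .pathways import filter_pathways
from .sage import (
    de_test_replicated,
    de_test_unreplicated,
    intersect_common_table,
    normalize_tpm,
    qpcr_log2fc,
    select_deregulated,
)
from .simulate import (
    HumanCohortSimConfig,
    ZebrafishSimConfig,
    random_signatures,
    simulate_human_cohort,
    simulate_sage_counts,
)

MODELS = ("xmrk", "kras", "Myc")
_NULL_REGIONS = [
    ("xmrk",), ("kras",), ("Myc",),
    ("xmrk", "kras"), ("xmrk", "Myc"), ("kras", "Myc"),
    ("xmrk", "kras", "Myc"),
]
NULL_DESIGN = {
    "up": {r: 0 for r in _NULL_REGIONS},
    "down": {r: 0 for r in _NULL_REGIONS},
}


def running_sum_oracle(scores, hit_flags, weight: float) -> float:
    """Step-by-step running-sum enumeration, independent of the engine."""
    n = len(scores)
    n_hits = sum(hit_flags)
    norm = sum(abs(s) ** weight for s, h in zip(scores, hit_flags) if h)
    run = 0.0
    profile = []
    for s, h in zip(scores, hit_flags):
        if h:
            run += (abs(s) ** weight) / norm if norm > 0 else 1.0 / n_hits
        else:
            run -= 1.0 / (n - n_hits)
        profile.append(run)
    max_abs = max(abs(v) for v in profile)
    # first position within tolerance of the max deviation (exact
    # positive/negative ties resolve to the earlier extremum)
    return next(v for v in profile if abs(v) >= max_abs - 1e-12)


def common_gene_intersection() -> dict:
    """Model intersection on the bundled common-gene worked example."""
    result = intersect_common_table()
    return {
        "common_up": len(result.common_up),
        "common_down": len(result.common_down),
        "n_genes": result.up.union_size + result.down.union_size,
    }


def es_oracle_agreement(seed: int, sizes=(5, 8, 12)) -> dict:
    """Exhaustive subset comparison of the ES against brute-force enumeration.

    For each universe size, draws one random ranked list and scores every
    non-empty proper subset at weights 0 and 1; also checks the analytic
    extremes (all hits at the top / bottom at weight 0 give ES = +/-1).
    Returns the maximum absolute deviation over all comparisons and the
    number of instances checked.
    """
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    n_checked = 0
    for n in sizes:
        scores = np.sort(rng.normal(size=n))[::-1]
        gene_ids = np.array([f"g{i:02d}" for i in range(n)], dtype=object)
        ranked = RankedGeneList(gene_ids, scores)
        for k in range(1, n):
            for combo in combinations(range(n), k):
                flags = [i in combo for i in range(n)]
                members = {gene_ids[i] for i in combo}
                for w in (0.0, 1.0):
                    es, _, _ = enrichment_score(ranked, members, w)
                    dev = abs(es - running_sum_oracle(scores, flags, w))
                    max_dev = max(max_dev, dev)
                    n_checked += 1
    extreme_dev = 0.0
    for n in range(3, 13):
        scores = np.linspace(1.0, -1.0, n)
        gene_ids = np.array([f"g{i:02d}" for i in range(n)], dtype=object)
        ranked = RankedGeneList(gene_ids, scores)
        for k in range(1, n):
            top, _, _ = enrichment_score(ranked, set(gene_ids[:k]), 0.0)
            bottom, _, _ = enrichment_score(ranked, set(gene_ids[-k:]), 0.0)
            extreme_dev = max(extreme_dev, abs(top - 1.0), abs(bottom + 1.0))
            n_checked += 2
    return {"max_abs_dev": max_dev, "extreme_dev": extreme_dev,
            "n_checked": n_checked}


def permutation_calibration(
    seed: int,
    n_seeds: int = 10,
    n_genes: int = 300,
    n_samples: int = 12,
    n_sets: int = 20,
    set_size: int = 15,
    n_permutations: int = 200,
) -> dict:
    """Null calibration of the phenotype-permutation test.

    Label-independent Gaussian data, two balanced classes, random gene
    sets. Returns the one-sided KS excess of the pooled nominal p-values
    over the uniform CDF (super-uniformity check) and the fraction of
    results with FDR q below 0.25.
    """
    pvals, qvals = [], []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 1000 * s)
        genes = [f"g{i:04d}" for i in range(n_genes)]
        expr = ExpressionTable(
            pd.DataFrame(
                rng.normal(8.0, 1.0, size=(n_genes, n_samples)),
                index=genes,
                columns=[f"s{j}" for j in range(n_samples)],
            ),
            "intensity",
        )
        labels = PhenotypeLabels(
            expr.sample_ids,
            ["t"] * (n_samples // 2) + ["n"] * (n_samples - n_samples // 2),
        )
        sets = GeneSetCollection(
            [
                GeneSet(
                    f"set{i}",
                    "",
                    tuple(rng.choice(genes, size=set_size, replace=False)),
                )
                for i in range(n_sets)
            ]
        )
        out = gsea(
            expr, labels, "t", sets,
            GseaConfig(n_permutations=n_permutations, rng_seed=seed + s),
        )
        pvals.extend(out["p_nominal"].tolist())
        qvals.extend(out["fdr_q"].tolist())
    p = np.sort(np.asarray(pvals))
    n = len(p)
    ecdf_excess = float(np.max(np.arange(1, n + 1) / n - p))
    q = np.asarray(qvals)
    return {
        "n_results": n,
        "ecdf_excess": ecdf_excess,
        "ks_critical_1pct": float(np.sqrt(np.log(100) / (2 * n))
                                  + 1.0 / (n_permutations + 1)),
        "fdr_lt_025_fraction": float(np.mean(q < 0.25)),
        "fdr_bound": float(0.25 + 3 * np.sqrt(0.25 * 0.75 / n)),
    }


def cohort_recovery(
    seed: int,
    n_seeds: int = 10,
    n_samples: int = 100,
    n_genes: int = 1200,
    effect_size: float = 3.0,
    n_permutations: int = 200,
) -> dict:
    """Planted-subgroup recovery of the per-sample classifier.

    Cohorts with three overlapping signature subgroups (independent 20%
    membership) at the given additive effect size; classification at
    FDR < 0.25 with the gene-set permutation null. Returns pooled
    sensitivity/specificity and the largest deviation of the recovered
    representation percentages (per signature, pairwise, triple, any)
    from the planted truth, in percentage points.
    """
    tp = fp = fn = tn = 0
    max_repr_err = 0.0
    pct_any_values = []
    for s in range(n_seeds):
        sigs = random_signatures(
            n_genes, {"xmrk": 60, "kras": 50, "Myc": 40}, rng_seed=seed + s
        )
        cohort, truth = simulate_human_cohort(
            HumanCohortSimConfig(
                n_samples=n_samples,
                n_genes=n_genes,
                effect_size=effect_size,
                rng_seed=seed + 7919 * (s + 1),
            ),
            sigs,
        )
        table = classify_cohort(
            cohort,
            sigs,
            GseaConfig(
                n_permutations=n_permutations,
                permutation_mode="gene_set",
                rng_seed=seed + s,
            ),
        )
        flags = table.pivot_table(
            index="sample_id", columns="signature", values="correlated",
            aggfunc="first",
        ).astype(bool)
        memb = truth.human_membership.loc[flags.index, flags.columns]
        tp += int((flags & memb).to_numpy().sum())
        fp += int((flags & ~memb).to_numpy().sum())
        fn += int((~flags & memb).to_numpy().sum())
        tn += int((~flags & ~memb).to_numpy().sum())

        def pct(frame):
            out = {}
            cols = list(frame.columns)
            for c in cols:
                out[c] = 100 * frame[c].mean()
            out["any"] = 100 * frame.any(axis=1).mean()
            for i, a in enumerate(cols):
                for b in cols[i + 1:]:
                    out[f"{a}+{b}"] = 100 * (frame[a] & frame[b]).mean()
            out["all"] = 100 * frame.all(axis=1).mean()
            return out

        got, want = pct(flags), pct(memb)
        max_repr_err = max(
            max_repr_err, max(abs(got[k] - want[k]) for k in want)
        )
        pct_any_values.append(got["any"])
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "max_representation_error_pts": max_repr_err,
        "mean_pct_any": float(np.mean(pct_any_values)),
        "n_sample_signature_pairs": tp + fp + fn + tn,
    }


def de_calibration(seed: int, n_genes: int = 2000) -> dict:
    """Type-I error of the replicated t-test on effect-free SAGE data."""
    tables, _ = simulate_sage_counts(
        ZebrafishSimConfig(n_genes=n_genes, design=NULL_DESIGN, rng_seed=seed)
    )
    tpm = normalize_tpm(tables["kras"])
    de = de_test_replicated(
        tpm,
        [f"kras_tumor{i}" for i in (1, 2, 3)],
        [f"kras_control{i}" for i in (1, 2, 3)],
    )
    frac = float((de["p_value"] < 0.05).mean())
    half_width = float(2.576 * np.sqrt(0.05 * 0.95 / n_genes))
    return {
        "type1_rate": frac,
        "nominal_level": 0.05,
        "binomial_99_half_width": half_width,
        "n_genes": n_genes,
    }


def de_recovery(seed: int, n_seeds: int = 3) -> dict:
    """Sensitivity for planted 8-fold genes at default generator settings.

    Runs the one-sample design (xmrk: single tumor vs 3 controls) and the
    replicated design (kras: 3 vs 3) and pools recovery over seeds.
    """
    found = total = 0
    for s in range(n_seeds):
        tables, truth = simulate_sage_counts(
            ZebrafishSimConfig(rng_seed=seed + s)
        )
        tz = truth.zebrafish
        for model in ("xmrk", "kras"):
            tpm = normalize_tpm(tables[model])
            controls = [f"{model}_control{i}" for i in (1, 2, 3)]
            if model == "xmrk":
                de = de_test_unreplicated(tpm, "xmrk_tumor1", controls)
            else:
                de = de_test_replicated(
                    tpm, [f"kras_tumor{i}" for i in (1, 2, 3)], controls
                )
            up, down = select_deregulated(de, name=model)
            selected = set(up.members if up else ()) | set(
                down.members if down else ()
            )
            planted = set(tz[tz.model == model].gene_id)
            found += len(planted & selected)
            total += len(planted)
    return {"sensitivity": found / total, "n_planted": total}


def null_selection_rate(seed: int, n_seeds: int = 10,
                        dispersion: float = 0.01) -> dict:
    """Fraction of genes passing the full DE selection on effect-free data
    at low biological dispersion (both designs pooled)."""
    frac = []
    for s in range(n_seeds):
        tables, _ = simulate_sage_counts(
            ZebrafishSimConfig(design=NULL_DESIGN, dispersion=dispersion,
                               rng_seed=seed + s)
        )
        tpm = normalize_tpm(tables["kras"])
        de = de_test_replicated(
            tpm,
            [f"kras_tumor{i}" for i in (1, 2, 3)],
            [f"kras_control{i}" for i in (1, 2, 3)],
        )
        up, down = select_deregulated(de)
        n_sel = len(up.members if up else ()) + len(down.members if down else ())
        frac.append(n_sel / tpm.n_genes)
    return {"selection_fraction": float(np.mean(frac))}


def pathway_filter_boundary(seed: int, n_random: int = 200) -> dict:
    """Exclusion-filter boundary: > 5 of 30 weak cells excludes a pathway;
    exactly 5 retains it; random patterns must match a counting oracle."""
    row6 = np.ones(30)
    row6[:6] = np.nan
    row5 = np.ones(30)
    row5[:5] = np.nan
    boundary = pd.DataFrame({"p_miss6": row6, "p_miss5": row5}).T
    kept = set(filter_pathways(boundary, max_missing=5).index)
    rng = np.random.default_rng(seed)
    values = rng.choice(
        [np.nan, 0.0, 1.5, -2.0], size=(n_random, 30), p=[0.15, 0.1, 0.4, 0.35]
    )
    m = pd.DataFrame(values, index=[f"p{i}" for i in range(n_random)])
    out = set(filter_pathways(m, max_missing=5).index)
    oracle = {
        f"p{i}"
        for i in range(n_random)
        if np.sum(np.isnan(values[i]) | (values[i] == 0.0)) <= 5
    }
    return {
        "excluded_at_6_of_30": "p_miss6" not in kept,
        "retained_at_5_of_30": "p_miss5" in kept,
        "n_retained_random": len(out),
        "random_matches_oracle": out == oracle,
    }


def ddct_worked_example() -> dict:
    """The -ddCT worked example and its sample-swap antisymmetry."""
    forward = qpcr_log2fc(20, 15, 24, 15)
    backward = qpcr_log2fc(24, 15, 20, 15)
    return {"log2fc": forward, "swapped": backward,
            "antisymmetric": forward == -backward}
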