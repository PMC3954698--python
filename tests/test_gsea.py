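"""Enrichment engine: ranking metrics, running-sum ES, nulls, NES/FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xsig import (
    ExpressionTable,
    GeneSetCollection,
    GseaConfig,
    PhenotypeLabels,
    RankedGeneList,
    enrichment_score,
    gsea,
    gsea_preranked,
    normalize_and_fdr,
    permutation_null,
    rank_by_ttest,
    rank_preranked,
)
from xsig.gsea import batch_random_set_es
from xsig.io import GeneSet


def es_oracle(scores, hit_flags, weight):
    """Independent step-by-step running-sum enumeration."""
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
    return next(v for v in profile if abs(v) >= max_abs - 1e-12)


def _ranked(scores, prefix="g"):
    scores = np.sort(np.asarray(scores, dtype=float))[::-1]
    return RankedGeneList(
        np.array([f"{prefix}{i:03d}" for i in range(len(scores))], dtype=object),
        scores,
    )


class TestRanking:
    def _expr(self, values, samples):
        genes = [f"g{i}" for i in range(values.shape[0])]
        return ExpressionTable(
            pd.DataFrame(values, index=genes, columns=samples), "intensity"
        )

    def test_constant_gene_scores_zero_and_tie_break_by_id(self):
        values = np.array([[5.0] * 6, [5.0] * 6, [1, 1, 1, 9, 9, 9.0]])
        expr = self._expr(values, list("abcdef"))
        labels = PhenotypeLabels(list("abcdef"), ["t"] * 3 + ["n"] * 3)
        ranked = rank_by_ttest(expr, labels, "t")
        # g0 and g1 are constant -> score 0, ordered lexicographically
        i0 = list(ranked.gene_ids).index("g0")
        i1 = list(ranked.gene_ids).index("g1")
        assert i0 < i1
        assert ranked.scores[i0] == 0.0

    def test_perfect_separation_ranks_first(self):
        values = np.array([[10, 10, 10, 0, 0, 0.0], [1, 2, 1, 2, 1, 2.0]])
        expr = self._expr(values, list("abcdef"))
        labels = PhenotypeLabels(list("abcdef"), ["t"] * 3 + ["n"] * 3)
        ranked = rank_by_ttest(expr, labels, "t")
        assert ranked.gene_ids[0] == "g0"

    def test_matches_independent_t_formula(self, rng):
        values = rng.normal(8, 2, size=(50, 10))
        expr = self._expr(values, [f"s{j}" for j in range(10)])
        labels = PhenotypeLabels(expr.sample_ids, ["t"] * 5 + ["n"] * 5)
        ranked = rank_by_ttest(expr, labels, "t")
        t_ref, _ = stats.ttest_ind(values[:, :5], values[:, 5:], axis=1,
                                   equal_var=True)
        by_gene = dict(zip(ranked.gene_ids, ranked.scores))
        for i in range(50):
            assert by_gene[f"g{i}"] == pytest.approx(t_ref[i], abs=1e-10)

    def test_singleton_uses_rest_only_sd(self, rng):
        values = rng.normal(8, 1, size=(20, 6))
        expr = self._expr(values, list("abcdef"))
        labels = PhenotypeLabels(list("abcdef"), ["t"] + ["n"] * 5)
        ranked = rank_by_ttest(expr, labels, "t")
        rest = values[:, 1:]
        expected = (values[:, 0] - rest.mean(axis=1)) / rest.std(axis=1, ddof=1)
        by_gene = dict(zip(ranked.gene_ids, ranked.scores))
        for i in range(20):
            assert by_gene[f"g{i}"] == pytest.approx(expected[i], abs=1e-10)

    def test_small_rest_class_rejected(self, rng):
        expr = self._expr(rng.uniform(1, 10, size=(5, 4)), list("abcd"))
        labels = PhenotypeLabels(list("abcd"), ["t", "t", "n", "n"])
        with pytest.raises(ValueError, match="rest"):
            rank_by_ttest(expr, labels, "t")


class TestPreranked:
    def test_signed_log10_scores(self):
        frame = pd.DataFrame(
            {
                "gene_id": ["up1", "down1", "flat"],
                "p_value": [0.01, 0.01, 1.0],
                "direction": ["up", "down", "up"],
            }
        )
        ranked = rank_preranked(frame)
        by_gene = dict(zip(ranked.gene_ids, ranked.scores))
        assert by_gene["up1"] == pytest.approx(2.0)
        assert by_gene["down1"] == pytest.approx(-2.0)
        assert by_gene["flat"] == 0.0

    def test_zero_p_clamped_not_fatal(self):
        frame = pd.DataFrame(
            {"gene_id": ["a", "b"], "p_value": [0.0, 0.5],
             "direction": ["up", "down"]}
        )
        ranked = rank_preranked(frame)
        assert np.isfinite(ranked.scores).all()
        assert ranked.gene_ids[0] == "a"

    def test_ordering_matches_sort_oracle(self, rng):
        n = 100
        frame = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "p_value": rng.uniform(1e-6, 1, n),
                "direction": rng.choice(["up", "down"], n),
            }
        )
        ranked = rank_preranked(frame)
        signed = np.where(frame["direction"] == "up", 1, -1) * (
            -np.log10(frame["p_value"])
        )
        assert list(ranked.scores) == sorted(signed, reverse=True)


class TestEnrichmentScore:
    def test_top_placement_weight0_gives_plus_one(self):
        ranked = _ranked(np.linspace(5, -5, 10))
        members = set(ranked.gene_ids[:3])
        es, running, lead = enrichment_score(ranked, members, 0.0)
        assert es == pytest.approx(1.0)
        assert set(lead) == members

    def test_bottom_placement_weight0_gives_minus_one(self):
        ranked = _ranked(np.linspace(5, -5, 10))
        members = set(ranked.gene_ids[-3:])
        es, _, lead = enrichment_score(ranked, members, 0.0)
        assert es == pytest.approx(-1.0)
        assert set(lead) == members

    def test_hand_enumerated_positions(self):
        # N = 10, hits at rank positions 2, 5, 9 (1-based), weight 0
        ranked = _ranked(np.linspace(3, -3, 10))
        members = {ranked.gene_ids[1], ranked.gene_ids[4], ranked.gene_ids[8]}
        hit_flags = [g in members for g in ranked.gene_ids]
        expected = es_oracle(ranked.scores, hit_flags, 0.0)
        es, _, _ = enrichment_score(ranked, members, 0.0)
        assert es == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("weight", [0.0, 1.0])
    def test_all_subsets_match_oracle_small_universe(self, weight, rng):
        for n in (4, 7):
            scores = np.sort(rng.normal(size=n))[::-1]
            ranked = _ranked(scores)
            for k in range(1, n):
                for combo in itertools.combinations(range(n), k):
                    members = {ranked.gene_ids[i] for i in combo}
                    flags = [i in combo for i in range(n)]
                    es, _, _ = enrichment_score(ranked, members, weight)
                    assert es == pytest.approx(
                        es_oracle(scores, flags, weight), abs=1e-10
                    )

    def test_running_sum_ends_at_zero(self, rng):
        ranked = _ranked(rng.normal(size=50))
        members = set(np.asarray(ranked.gene_ids)[rng.choice(50, 8, replace=False)])
        for w in (0.0, 1.0):
            es, running, _ = enrichment_score(ranked, members, w)
            assert running[-1] == pytest.approx(0.0, abs=1e-12)
            assert -1 <= es <= 1

    def test_reversed_list_negates_es_weight0(self, rng):
        scores = np.linspace(2, -2, 20)
        ranked = _ranked(scores)
        idx = rng.choice(20, 5, replace=False)
        members = {ranked.gene_ids[i] for i in idx}
        es, _, _ = enrichment_score(ranked, members, 0.0)
        rev = RankedGeneList(ranked.gene_ids[::-1].copy(), np.sort(-scores)[::-1])
        members_rev = {rev.gene_ids[19 - i] for i in idx}
        es_rev, _, _ = enrichment_score(rev, members_rev, 0.0)
        assert es_rev == pytest.approx(-es, abs=1e-12)

    def test_zero_overlap_returns_marker(self):
        ranked = _ranked(np.linspace(1, -1, 5))
        es, running, lead = enrichment_score(ranked, {"absent"}, 1.0)
        assert np.isnan(es) and lead == ()

    def test_batch_random_sets_match_scalar_path(self, rng):
        ranked = _ranked(rng.normal(size=40))
        es_batch = batch_random_set_es(ranked.scores, 6, 50,
                                       1.0, np.random.default_rng(7))
        assert np.all(np.abs(es_batch) <= 1)
        # distribution check: scalar path on fresh random sets is similar
        scalar = []
        r2 = np.random.default_rng(8)
        for _ in range(50):
            members = set(ranked.gene_ids[r2.choice(40, 6, replace=False)])
            scalar.append(enrichment_score(ranked, members, 1.0)[0])
        assert abs(np.mean(es_batch) - np.mean(scalar)) < 0.2


class TestPermutationNull:
    def _toy(self, rng, n_genes=30, n_samples=6):
        expr = ExpressionTable(
            pd.DataFrame(
                rng.normal(8, 1, size=(n_genes, n_samples)),
                index=[f"g{i}" for i in range(n_genes)],
                columns=[f"s{j}" for j in range(n_samples)],
            ),
            "intensity",
        )
        labels = PhenotypeLabels(expr.sample_ids, ["t"] + ["n"] * (n_samples - 1))
        return expr, labels

    def test_singleton_six_samples_enumerates_six_arrangements(self, rng):
        expr, labels = self._toy(rng)
        config = GseaConfig(n_permutations=100, min_set_overlap=2, rng_seed=1)
        null = permutation_null(expr, labels, "t",
                                set(expr.gene_ids[:5]), config)
        assert len(null) == 6

    def test_same_seed_reproduces_null(self, rng):
        expr, labels = self._toy(rng, n_samples=12)
        config = GseaConfig(n_permutations=50, min_set_overlap=2, rng_seed=42)
        members = set(expr.gene_ids[:6])
        a = permutation_null(expr, labels, "t", members, config)
        b = permutation_null(expr, labels, "t", members, config)
        np.testing.assert_array_equal(a, b)

    def test_gene_set_mode_null_size(self, rng):
        expr, labels = self._toy(rng, n_samples=8)
        config = GseaConfig(n_permutations=37, min_set_overlap=2,
                            permutation_mode="gene_set", rng_seed=3)
        null = permutation_null(expr, labels, "t", set(expr.gene_ids[:5]), config)
        assert len(null) == 37


class TestNormalizeAndFdr:
    def test_nes_identity_at_null_mean(self):
        null = np.array([0.2, 0.4, 0.6, -0.3, -0.5])
        stats_out = normalize_and_fdr({"s": 0.4}, {"s": null})
        assert stats_out[0].nes == pytest.approx(1.0)

    def test_extreme_observation_gets_minimal_p(self):
        null = np.array([0.1, 0.2, 0.3, -0.1])
        stat = normalize_and_fdr({"s": 0.95}, {"s": null})[0]
        assert stat.p_nominal == pytest.approx(1 / 4)  # add-one over 3 same-sign

    def test_no_same_sign_nulls_handled(self):
        null = np.array([-0.1, -0.2, -0.3])
        stat = normalize_and_fdr({"s": 0.5}, {"s": null})[0]
        assert np.isnan(stat.nes)
        assert 0 < stat.p_nominal <= 1

    def test_q_monotone_within_sign(self, rng):
        observed = {f"s{i}": float(v) for i, v in
                    enumerate(rng.uniform(-0.8, 0.8, 12))}
        nulls = {k: rng.uniform(-0.6, 0.6, 200) for k in observed}
        out = normalize_and_fdr(observed, nulls)
        pos = sorted((s for s in out if not np.isnan(s.nes) and s.nes >= 0),
                     key=lambda s: s.nes, reverse=True)
        qs = [s.fdr_q for s in pos]
        assert qs == sorted(qs)


class TestDrivers:
    def test_gsea_flags_planted_set(self, rng):
        n_genes, n_samples = 120, 12
        values = rng.normal(8, 1, size=(n_genes, n_samples))
        planted = list(range(15))
        values[np.ix_(planted, range(6))] += 3.0
        expr = ExpressionTable(
            pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)],
                         columns=[f"s{j}" for j in range(n_samples)]),
            "intensity",
        )
        labels = PhenotypeLabels(expr.sample_ids, ["t"] * 6 + ["n"] * 6)
        sets = GeneSetCollection(
            [
                GeneSet("planted", "", tuple(f"g{i}" for i in planted)),
                GeneSet("random", "", tuple(f"g{i}" for i in range(50, 70))),
            ]
        )
        out = gsea(expr, labels, "t", sets,
                   GseaConfig(n_permutations=100, rng_seed=5))
        planted_row = out[out.set_name == "planted"].iloc[0]
        assert planted_row["es"] > 0.5
        assert planted_row["fdr_q"] < 0.25

    def test_preranked_driver_runs_and_orders(self, rng):
        n = 200
        frame = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "p_value": rng.uniform(1e-5, 1, n),
                "direction": ["up"] * (n // 2) + ["down"] * (n // 2),
            }
        )
        ranked = rank_preranked(frame)
        sets = GeneSetCollection(
            [GeneSet("top", "", tuple(ranked.gene_ids[:10]))]
        )
        out = gsea_preranked(ranked, sets,
                             GseaConfig(n_permutations=100, rng_seed=2,
                                        permutation_mode="gene_set"))
        assert out.iloc[0]["es"] > 0.8
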