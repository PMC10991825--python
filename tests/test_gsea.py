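"""Pre-ranked enrichment: weighted KS statistic, permutation FDR, PoD gene."""

import numpy as np
import pytest

from txqivive import gsea, simulate


def brute_force_es(genes, scores, members, weight):
    """Independent recomputation of the weighted-KS enrichment score from
    its definition (running hit/miss walk, signed max deviation)."""
    members = set(members)
    n = len(genes)
    n_hit = sum(g in members for g in genes)
    denom = sum(abs(s) ** weight for g, s in zip(genes, scores)
                if g in members)
    run, profile = 0.0, []
    for g, s in zip(genes, scores):
        if g in members:
            run += (abs(s) ** weight) / denom
        else:
            run -= 1.0 / (n - n_hit)
        profile.append(run)
    peak = int(np.argmax(np.abs(profile)))
    return profile[peak], profile, peak


def _ranked(scores, genes=None):
    scores = np.asarray(scores, dtype=float)
    genes = genes or [f"g{i}" for i in range(len(scores))]
    return gsea.RankedGeneList(list(genes), scores)


class TestCollapseProbes:
    def test_duplicates_averaged(self):
        out = gsea.collapse_probes(
            {"p1": 1.0, "p2": 3.0, "p3": 2.0},
            {"p1": "A", "p2": "A", "p3": "B"},
        )
        assert out == {"A": 2.0, "B": 2.0}

    def test_no_duplicates_identity(self):
        table = {"p1": 1.5, "p2": 0.3}
        assert gsea.collapse_probes(table) == table

    def test_unmapped_probes_dropped_and_sentinels_propagate(self):
        out = gsea.collapse_probes(
            {"p1": 1.0, "p2": np.inf, "p3": np.inf, "p4": 2.0},
            {"p1": "A", "p2": "A", "p3": "B", "p4": None},
        )
        assert out["A"] == 1.0          # finite probe dominates
        assert np.isinf(out["B"])       # all-undefined symbol stays undefined
        assert "p4" not in out and len(out) == 2

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gsea.collapse_probes({})


class TestRankingScore:
    def test_reference_values(self):
        s = gsea.ranking_score(np.array([0.25, 1.0]))
        assert s[0] == pytest.approx(0.60206, abs=1e-5)
        assert s[1] == 0.0

    def test_monotone_decreasing_in_bmdl(self):
        rng = np.random.default_rng(0)
        bmdl = np.exp(rng.uniform(-3, 3, 50))
        s = gsea.ranking_score(bmdl)
        order_b = np.argsort(bmdl)
        order_s = np.argsort(-s)
        np.testing.assert_array_equal(order_b, order_s)

    def test_sentinels_rank_last(self):
        s = gsea.ranking_score(np.array([0.5, np.inf, 2.0]))
        assert s[1] < s.min() + 1e-12 and s[1] < s[2] < s[0]

    def test_nonpositive_bmdl_rejected(self):
        with pytest.raises(ValueError):
            gsea.ranking_score(np.array([0.0, 1.0]))


class TestEnrichmentScore:
    def test_perfect_concordance(self):
        rl = _ranked([5, 4, 3, 2, 1])
        es, profile, peak = gsea.enrichment_score(rl, ["g0", "g1"], weight=0)
        assert es == pytest.approx(1.0)
        assert peak == 1

    def test_perfect_discordance_mirror(self):
        rl = _ranked([5, 4, 3, 2, 1])
        es, profile, peak = gsea.enrichment_score(rl, ["g3", "g4"], weight=0)
        assert es == pytest.approx(-1.0)
        assert peak == 2  # trough right before the set members start

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(5, 13))
            scores = np.sort(rng.normal(0, 1, n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            k = int(rng.integers(1, n))
            members = list(rng.choice(genes, size=k, replace=False))
            for w in (0.0, 1.0, 2.0):
                rl = _ranked(scores, genes)
                es, prof, peak = gsea.enrichment_score(rl, members, weight=w)
                es_b, prof_b, peak_b = brute_force_es(genes, scores,
                                                      members, w)
                np.testing.assert_allclose(prof, prof_b, atol=1e-12)
                assert abs(es) == pytest.approx(abs(es_b), abs=1e-12)
                # the sign is only determined when the peak/trough tie gap
                # exceeds float noise
                if abs(max(prof_b) + min(prof_b)) > 1e-9:
                    assert es == pytest.approx(es_b, abs=1e-12)

    def test_profile_sums_to_zero(self):
        rng = np.random.default_rng(1)
        scores = np.sort(rng.normal(0, 1, 30))[::-1]
        rl = _ranked(scores)
        es, prof, _ = gsea.enrichment_score(rl, [f"g{i}" for i in (2, 9, 20)])
        assert prof[-1] == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_monotone_transform_at_weight_zero(self):
        rng = np.random.default_rng(2)
        scores = np.sort(rng.uniform(1, 5, 20))[::-1]
        rl1 = _ranked(scores)
        rl2 = _ranked(np.log(scores))
        members = [f"g{i}" for i in (0, 3, 11, 17)]
        es1, _, _ = gsea.enrichment_score(rl1, members, weight=0)
        es2, _, _ = gsea.enrichment_score(rl2, members, weight=0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_disjoint_set_errors(self):
        rl = _ranked([3, 2, 1])
        with pytest.raises(ValueError):
            gsea.enrichment_score(rl, ["absent"])


class TestLeadingEdge:
    def test_forced_by_peak(self):
        rl = _ranked([5, 4, 3, 2, 1])
        es, prof, peak = gsea.enrichment_score(rl, ["g0", "g1"], weight=0)
        assert gsea.leading_edge(rl, ["g0", "g1"], prof, peak) == ["g0", "g1"]

    def test_member_after_peak_excluded(self):
        rl = _ranked([10, 1, 0.9, 0.8, 0.7])
        es, prof, peak = gsea.enrichment_score(rl, ["g0", "g4"], weight=1)
        le = gsea.leading_edge(rl, ["g0", "g4"], prof, peak)
        assert le == ["g0"]

    def test_leading_edge_subset_of_set(self):
        rng = np.random.default_rng(3)
        scores = np.sort(rng.normal(0, 1, 40))[::-1]
        rl = _ranked(scores)
        members = [f"g{i}" for i in rng.choice(40, 8, replace=False)]
        es, prof, peak = gsea.enrichment_score(rl, members)
        assert set(gsea.leading_edge(rl, members, prof, peak)) <= set(members)


class TestSignificance:
    def test_same_seed_identical_results(self, small_synthetic):
        _, truth = small_synthetic
        sets = simulate.generate_gene_sets(truth, n_sets=10,
                                           set_size_range=(6, 12),
                                           enriched_sets=2, seed=0)
        rng = np.random.default_rng(0)
        bmdl = np.exp(rng.uniform(-2, 2, 60))
        rl = gsea.build_ranked_list(
            [_FakeRecord(g, b) for g, b in
             zip(truth.genes["gene_id"], bmdl)]
        )
        r1 = gsea.significance(rl, sets, n_perm=200, seed=149, min_size=5)
        r2 = gsea.significance(rl, sets, n_perm=200, seed=149, min_size=5)
        assert [(r.name, r.q) for r in r1] == [(r.name, r.q) for r in r2]

    def test_enriched_set_attains_minimum_q(self):
        ds, truth = simulate.generate_expression_matrix(
            n_genes=300, responsive_fraction=0.15, seed=31
        )
        sets = simulate.generate_gene_sets(truth, n_sets=15,
                                           set_size_range=(15, 30),
                                           enriched_sets=1, seed=31)
        # rank genes by generator truth (true BMC; nulls to the bottom)
        bmdl = truth.genes["true_bmc"].fillna(np.inf).to_numpy()
        recs = [_FakeRecord(g, b) for g, b in
                zip(truth.genes["gene_id"], bmdl)]
        rl = gsea.build_ranked_list(recs)
        res = gsea.significance(rl, sets, n_perm=500, seed=149)
        assert res[0].name == "ENR_SET_00"
        assert res[0].es > 0
        assert res[0].q == min(r.q for r in res)

    def test_q_monotone_within_sign_class(self, small_synthetic):
        _, truth = small_synthetic
        sets = simulate.generate_gene_sets(truth, n_sets=12,
                                           set_size_range=(6, 12),
                                           enriched_sets=2, seed=5)
        bmdl = truth.genes["true_bmc"].fillna(np.inf).to_numpy()
        rl = gsea.build_ranked_list(
            [_FakeRecord(g, b) for g, b in
             zip(truth.genes["gene_id"], bmdl)]
        )
        res = gsea.significance(rl, sets, n_perm=300, seed=1, min_size=5)
        for sign in (1, -1):
            side = [r for r in res if np.sign(r.nes) == sign]
            side.sort(key=lambda r: -abs(r.nes))
            qs = [r.q for r in side]
            assert qs == sorted(qs)


class _FakeRecord:
    """Minimal record carrying the two attributes ranking consumes."""

    def __init__(self, gene_id, bmdl):
        self.gene_id = gene_id
        self.bmdl_for_ranking = float(bmdl)


class TestMostSensitiveGene:
    def _results(self):
        return [
            gsea.EnrichmentResult("P1", 0.8, 2.0, 0.001, 0.01, 3, []),
            gsea.EnrichmentResult("P2", 0.7, 1.8, 0.01, 0.05, 3, []),
            gsea.EnrichmentResult("P3", 0.5, 1.2, 0.2, 0.5, 3, []),
        ]

    def _ranked(self):
        genes = ["a", "b", "c", "d", "e"]
        bmdl = {"a": 3.0, "b": 1.0, "c": 2.0, "d": 0.5, "e": 1.0}
        scores = gsea.ranking_score(np.array([bmdl[g] for g in genes]))
        order = np.argsort(-scores)
        return gsea.RankedGeneList([genes[i] for i in order],
                                   np.sort(scores)[::-1],
                                   bmdl)

    def test_lowest_bmdl_member_selected(self):
        sets = {"P1": ["a", "b", "c"], "P2": ["a", "c"], "P3": ["d"]}
        per, pod = gsea.most_sensitive_gene(self._results(), self._ranked(),
                                            sets)
        assert per["P1"] == ("b", 1.0)
        assert per["P2"] == ("c", 2.0)
        assert "P3" not in per          # q = 0.5 not significant
        assert pod == ("P1", "b", 1.0)  # lowest member BMDL overall

    def test_bmdl_tie_breaks_lexicographically(self):
        sets = {"P1": ["b", "e"], "P2": ["a"], "P3": ["a"]}
        per, _ = gsea.most_sensitive_gene(self._results(), self._ranked(),
                                          sets)
        assert per["P1"] == ("b", 1.0)  # b and e tie at 1.0

    def test_no_significant_pathway_no_pod(self):
        results = [gsea.EnrichmentResult("P", 0.5, 1.0, 0.5, 0.9, 3, [])]
        per, pod = gsea.most_sensitive_gene(results, self._ranked(),
                                            {"P": ["a"]})
        assert per == {} and pod is None
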