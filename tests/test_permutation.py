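import numpy as np
import pytest

from clockrank.graphlets import GDVSimilarityRecord, gdv_matrix, seed_similarities
from clockrank.network_io import map_seeds, transition_operator
from clockrank.permutation import (
    NullEnsembleConfig,
    PermutationResult,
    degree_preserving_ensemble,
    filter_significant,
    gdv_permutation_fdr,
    random_seed_sets,
    rwr_permutation_fdr,
)
from clockrank.rwr import RWRConfig, initial_distribution, rwr_iterate, threshold_raw_candidates
from clockrank.synthetic import GeneratorConfig, generate

from conftest import net_from


class TestRandomSeedSets:
    def test_full_size_returns_all_nodes(self, triangle):
        cfg = NullEnsembleConfig(n_permutations=5, rng_seed=1)
        for s in random_seed_sets(triangle, 3, cfg):
            assert sorted(s) == sorted(triangle.nodes)

    def test_deterministic_from_seed(self, karate):
        cfg = NullEnsembleConfig(n_permutations=20, rng_seed=42)
        a = random_seed_sets(karate, 5, cfg)
        b = random_seed_sets(karate, 5, cfg)
        assert a == b

    def test_oversized_errors(self, k2):
        with pytest.raises(ValueError):
            random_seed_sets(k2, 3, NullEnsembleConfig(n_permutations=1))

    def test_inclusion_frequency_binomial(self):
        net = net_from((f"n{i}", f"n{(i + 1) % 10}") for i in range(10))
        cfg = NullEnsembleConfig(n_permutations=1000, rng_seed=3)
        sets = random_seed_sets(net, 3, cfg)
        freq = {g: 0 for g in net.nodes}
        for s in sets:
            for g in s:
                freq[g] += 1
        p = 3 / 10
        sigma = np.sqrt(1000 * p * (1 - p))
        for g, f in freq.items():
            assert abs(f - 1000 * p) < 5 * sigma


class TestRwrPermutation:
    def test_unbeatable_candidate_has_p_zero(self, karate):
        W = transition_operator(karate)
        seeds = map_seeds(karate, ["n0"])
        cfg = NullEnsembleConfig(n_permutations=50, rng_seed=0)
        # observed probability 1.0 cannot be exceeded by any null walk
        results = rwr_permutation_fdr(
            karate, W, [("n1", 1.0)], cfg, seeds=seeds
        )
        assert results[0].theta == 0 and results[0].p_value == 0.0

    def test_p_value_formula(self):
        r = PermutationResult(node="g", branch="RWR", theta=50, n_permutations=1000)
        assert r.p_value == 0.05

    def test_deterministic(self, karate):
        W = transition_operator(karate)
        seeds = map_seeds(karate, ["n0", "n33"])
        p = rwr_iterate(W, initial_distribution(karate, seeds)).probabilities
        raw = threshold_raw_candidates(karate, p, 1e-5, seeds=seeds)[:10]
        cfg = NullEnsembleConfig(n_permutations=40, rng_seed=9)
        a = rwr_permutation_fdr(karate, W, raw, cfg, seeds=seeds)
        b = rwr_permutation_fdr(karate, W, raw, cfg, seeds=seeds)
        assert a == b

    def test_planted_module_beats_background(self):
        # planted-module members should look far less null than random nodes
        inst = generate(
            GeneratorConfig(
                n_nodes=250, module_size=20, n_seeds=6,
                n_go_terms=20, n_pathway_terms=10, rng_seed=5,
            )
        )
        net = inst.network
        W = transition_operator(net)
        seeds = map_seeds(net, inst.seeds)
        p = rwr_iterate(W, initial_distribution(net, seeds)).probabilities
        rng = np.random.default_rng(5)
        others = [
            g
            for g in rng.choice(net.nodes, 30, replace=False)
            if g not in inst.planted and g not in inst.seeds
        ]
        probe = [(g, float(p[net.index[g]])) for g in list(inst.planted) + others]
        cfg = NullEnsembleConfig(n_permutations=200, rng_seed=5)
        results = {r.node: r.p_value for r in rwr_permutation_fdr(net, W, probe, cfg, seeds=seeds)}
        planted_med = np.median([results[g] for g in inst.planted])
        other_med = np.median([results[g] for g in others])
        assert planted_med < other_med


class TestDegreePreservingEnsemble:
    def test_degree_sequence_and_edge_count_preserved(self, karate):
        cfg = NullEnsembleConfig(n_permutations=5, rng_seed=2)
        deg = dict(zip(karate.nodes, karate.degree_array()))
        for null in degree_preserving_ensemble(karate, cfg):
            assert null.n_edges == karate.n_edges
            assert dict(zip(null.nodes, null.degree_array())) == deg

    def test_triangle_swaps_always_rejected(self, triangle):
        # any two K3 edges share a node, so every proposal self-loops or
        # duplicates; the output equals the input
        cfg = NullEnsembleConfig(n_permutations=3, rng_seed=0)
        for null in degree_preserving_ensemble(triangle, cfg):
            assert {frozenset(e) for e in null.edges()} == {
                frozenset(e) for e in triangle.edges()
            }

    def test_reproducible_stream(self, karate):
        cfg = NullEnsembleConfig(n_permutations=4, rng_seed=13)
        a = [sorted(map(sorted, n.edges())) for n in degree_preserving_ensemble(karate, cfg)]
        b = [sorted(map(sorted, n.edges())) for n in degree_preserving_ensemble(karate, cfg)]
        assert a == b

    def test_actually_rewires(self, karate):
        cfg = NullEnsembleConfig(n_permutations=1, rng_seed=7)
        null = next(iter(degree_preserving_ensemble(karate, cfg)))
        assert {frozenset(e) for e in null.edges()} != {
            frozenset(e) for e in karate.edges()
        }


class TestGdvPermutation:
    def test_similarity_one_never_beaten(self, karate):
        rec = [GDVSimilarityRecord(seed="n0", node="n1", s_gdv=1.0)]
        cfg = NullEnsembleConfig(n_permutations=20, rng_seed=1)
        (res,) = gdv_permutation_fdr(karate, rec, cfg)
        assert res.theta == 0

    def test_theta_equals_n_gives_p_one(self, karate):
        # a real similarity below every possible value is always beaten
        rec = [GDVSimilarityRecord(seed="n0", node="n1", s_gdv=-1.0)]
        cfg = NullEnsembleConfig(n_permutations=15, rng_seed=1)
        (res,) = gdv_permutation_fdr(karate, rec, cfg)
        assert res.theta == 15 and res.p_value == 1.0

    def test_missing_seed_pair_errors(self, karate):
        rec = [GDVSimilarityRecord(seed="", node="n1", s_gdv=0.5)]
        with pytest.raises(ValueError):
            gdv_permutation_fdr(karate, rec, NullEnsembleConfig(n_permutations=2))

    def test_null_calibration_approximately_uniform(self):
        # exchangeability check: take the "real" network itself from the
        # rewiring null, then p-values of random pairs should be ~uniform
        import networkx as nx
        from scipy.stats import kstest

        g = nx.barabasi_albert_graph(150, 3, seed=4)
        base = net_from(
            ((f"n{u}", f"n{v}") for u, v in g.edges()),
            nodes=[f"n{v}" for v in g.nodes()],
        )
        real = next(
            iter(degree_preserving_ensemble(base, NullEnsembleConfig(n_permutations=1, rng_seed=100)))
        )
        rng = np.random.default_rng(0)
        pairs = rng.choice(real.nodes, size=(25, 2), replace=True)
        pairs = [(a, b) for a, b in pairs if a != b]
        gdv = gdv_matrix(real)
        sims = seed_similarities(gdv, sorted({a for a, _ in pairs}))
        recs = [
            GDVSimilarityRecord(seed=a, node=b, s_gdv=float(sims.loc[a, b]))
            for a, b in pairs
        ]
        cfg = NullEnsembleConfig(n_permutations=60, rng_seed=8)
        pvals = [r.p_value for r in gdv_permutation_fdr(real, recs, cfg)]
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestFilterSignificant:
    def test_strict_inequality_at_alpha(self):
        kept = PermutationResult("a", "RWR", 49, 1000)
        dropped = PermutationResult("b", "RWR", 50, 1000)
        out = filter_significant([kept, dropped], alpha=0.05)
        assert out == [kept]

    def test_bad_alpha_errors(self):
        with pytest.raises(ValueError):
            filter_significant([], alpha=1.5)


class TestGdvMatchModes:
    def test_any_seed_mode_yields_theta_at_least_best(self, karate):
        rec = [GDVSimilarityRecord(seed="n0", node="n12", s_gdv=0.6)]
        cfg = NullEnsembleConfig(n_permutations=30, rng_seed=4)
        (best,) = gdv_permutation_fdr(karate, rec, cfg, match="best")
        (anym,) = gdv_permutation_fdr(
            karate, rec, cfg, match="any", seeds=["n0", "n33", "n5"]
        )
        assert anym.theta >= best.theta

    def test_any_mode_requires_seed_list(self, karate):
        rec = [GDVSimilarityRecord(seed="n0", node="n1", s_gdv=0.5)]
        with pytest.raises(ValueError):
            gdv_permutation_fdr(
                karate, rec, NullEnsembleConfig(n_permutations=2), match="any"
            )
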