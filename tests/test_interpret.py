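import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import devclock as dc
from devclock.interpret import CoexpressionNetwork, _auroc

from conftest import make_pseudobulk


def pair_count_auroc(scores, labels):
    """Independent AUROC oracle: explicit pair counting with half-ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def enumeration_ranks(values):
    """Average-tie ranks by explicit counting (independent of rankdata)."""
    values = list(values)
    out = []
    for v in values:
        less = sum(x < v for x in values)
        equal = sum(x == v for x in values)
        out.append(less + (equal + 1) / 2)
    return np.array(out)


class TestPermutationImportance:
    def test_zero_coefficient_genes_have_zero_importance(self, tiny_clock, tiny_pb):
        imp = dc.permutation_importance(tiny_clock, tiny_pb, n_perm=2, seed=0)
        zero = np.asarray(tiny_clock.coef_std) == 0
        assert (imp.to_numpy()[zero] == 0).all()

    def test_deterministic_under_seed(self, tiny_clock, tiny_pb):
        a = dc.permutation_importance(tiny_clock, tiny_pb, n_perm=3, seed=4)
        b = dc.permutation_importance(tiny_clock, tiny_pb, n_perm=3, seed=4)
        pd.testing.assert_series_equal(a, b)

    def test_sole_informative_gene_carries_the_model(self):
        rng = np.random.default_rng(0)
        ages = np.linspace(6, 30, 12)
        values = rng.normal(0, 1, (10, 12))
        values[0] = ages
        pb = make_pseudobulk(values, ages)
        model = dc.train_clock(pb, lambda_policy=0.2)
        imp = dc.permutation_importance(model, pb, n_perm=20, seed=1)
        null_mae = np.mean(np.abs(ages - ages.mean()))
        model_mae = dc.evaluate(dc.predict_age(model, pb)).mae
        assert imp["g0"] > 0.5 * (null_mae - model_mae)
        assert imp["g0"] == imp.max()

    def test_rejects_zero_permutations(self, tiny_clock, tiny_pb):
        with pytest.raises(ValueError):
            dc.permutation_importance(tiny_clock, tiny_pb, n_perm=0)


class TestFeatureStability:
    def test_frequencies_bounded(self, tiny_pb):
        freq = dc.feature_stability(tiny_pb, n_resamples=4, fraction=0.8, seed=0, lambda_policy=0.3)
        assert ((freq >= 0) & (freq <= 1)).all()

    def test_full_fraction_gives_binary_frequencies(self, tiny_pb):
        freq = dc.feature_stability(tiny_pb, n_resamples=3, fraction=1.0, seed=0, lambda_policy=0.3)
        assert set(np.unique(freq)) <= {0.0, 1.0}

    def test_informative_genes_more_stable(self, tiny_data, tiny_pb):
        _, truth = tiny_data
        freq = dc.feature_stability(tiny_pb, n_resamples=8, fraction=0.7, seed=2, lambda_policy=0.3)
        informative = freq.to_numpy()[truth.gene_slopes != 0]
        noise = freq.to_numpy()[truth.gene_slopes == 0]
        assert np.median(informative) - np.median(noise) > 0.5


class TestAgeCorrelatedGenes:
    def test_perfect_gene_and_constant_gene(self):
        ages = np.linspace(6, 30, 6)
        values = np.vstack([ages, np.full(6, 3.0), np.random.default_rng(0).normal(size=(3, 6))])
        pb = make_pseudobulk(values, ages)
        tables = dc.age_correlated_genes(pb)
        tab = tables["s0"].set_index("gene")
        assert tab.loc["g0", "r"] == pytest.approx(1.0)
        assert tab.loc["g0", "q"] < 1e-6
        assert np.isnan(tab.loc["g1", "r"]) and np.isnan(tab.loc["g1", "q"])

    def test_too_few_groups_rejected(self):
        pb = make_pseudobulk(np.ones((3, 2)), [5, 10])
        with pytest.raises(ValueError):
            dc.age_correlated_genes(pb)


class TestAggregateCoexpression:
    def _oracle(self, study_values):
        """Brute-force: Spearman per pair, enumerate ranks, average studies."""
        n = study_values[0].shape[0]
        mats = []
        for vals in study_values:
            corr = np.full((n, n), np.nan)
            for i, j in itertools.combinations(range(n), 2):
                corr[i, j] = stats.spearmanr(vals[i], vals[j]).statistic
            flat = [corr[i, j] for i, j in itertools.combinations(range(n), 2)]
            ranks = enumeration_ranks(flat) / len(flat)
            std = np.eye(n)
            for (i, j), r in zip(itertools.combinations(range(n), 2), ranks):
                std[i, j] = std[j, i] = r
            mats.append(std)
        return np.mean(mats, axis=0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        s1 = rng.normal(size=(4, 5))
        s2 = rng.normal(size=(4, 5))
        values = np.concatenate([s1, s2], axis=1)
        pb = make_pseudobulk(values, list(range(5)) * 2, studies=["a"] * 5 + ["b"] * 5)
        net = dc.aggregate_coexpression(pb)
        np.testing.assert_allclose(net.matrix, self._oracle([s1, s2]), atol=1e-12)

    def test_perfectly_correlated_pair_gets_max_rank(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(5, 12))
        values[1] = 2 * values[0] + 3  # monotone transform of gene 0
        pb = make_pseudobulk(values, list(range(6)) * 2, studies=["a"] * 6 + ["b"] * 6)
        net = dc.aggregate_coexpression(pb)
        off = net.matrix[~np.eye(5, dtype=bool)]
        assert net.matrix[0, 1] == off.max() == 1.0

    def test_mean_of_identical_studies_is_idempotent(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=(4, 6))
        pb1 = make_pseudobulk(s, range(6))
        pb2 = make_pseudobulk(np.concatenate([s, s], axis=1), list(range(6)) * 2,
                              studies=["a"] * 6 + ["b"] * 6)
        np.testing.assert_allclose(
            dc.aggregate_coexpression(pb1).matrix, dc.aggregate_coexpression(pb2).matrix
        )

    def test_monotone_per_gene_transform_invariance(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(1, 5, size=(4, 8))
        pb1 = make_pseudobulk(s, range(8))
        pb2 = make_pseudobulk(s**3, range(8))
        np.testing.assert_allclose(
            dc.aggregate_coexpression(pb1).matrix, dc.aggregate_coexpression(pb2).matrix
        )

    def test_symmetry_and_range(self, tiny_pb):
        net = dc.aggregate_coexpression(tiny_pb, genes=tiny_pb.genes[:20])
        m = net.matrix
        np.testing.assert_allclose(m, m.T)
        assert np.nanmin(m) >= 0 and np.nanmax(m) <= 1


class TestDetectModules:
    def _block_network(self, sizes=(5, 5), within=0.9, between=0.1):
        n = sum(sizes)
        m = np.full((n, n), between)
        start = 0
        for s in sizes:
            m[start : start + s, start : start + s] = within
            start += s
        np.fill_diagonal(m, 1.0)
        return CoexpressionNetwork(matrix=m, genes=[f"g{i}" for i in range(n)], n_datasets=1)

    def test_two_blocks_found_at_intermediate_height(self):
        ms = dc.detect_modules(self._block_network(), height=2.0)
        assert ms.n_modules == 2
        labels = ms.assignments.to_numpy()
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1

    def test_tiny_height_gives_singletons(self):
        ms = dc.detect_modules(self._block_network(), height=1e-9)
        assert ms.n_modules == 10

    def test_huge_height_gives_one_module(self):
        ms = dc.detect_modules(self._block_network(), height=1e9)
        assert ms.n_modules == 1

    def test_planted_module_recovery(self):
        """Strongly planted module factors are recovered (ARI > 0.8) at
        the default clustering settings."""
        from sklearn.metrics import adjusted_rand_score

        config = dc.SimulationConfig(
            n_studies=4, samples_per_study=8, cells_per_sample=200,
            n_genes=500, n_positive_genes=40, n_negative_genes=40,
            n_modules=6, module_sd=0.8, seed=21,
        )
        ds, truth = dc.simulate_multistudy(config)
        pb = dc.pseudobulk(ds, "sample_class")
        pos = [ds.genes[i] for i in range(40)]
        net = dc.aggregate_coexpression(pb, genes=pos)
        ms = dc.detect_modules(net, sign_stratum="positive")
        ari = adjusted_rand_score(truth.gene_module[:40], ms.assignments.to_numpy())
        assert ari > 0.8


class TestEnrichment:
    def test_hypergeometric_matches_enumeration(self):
        # universe 10, set of 5, module of 4, overlap 4: p = C(5,4)C(5,0)/C(10,4)
        universe = [f"g{i}" for i in range(10)]
        res = dc.module_set_enrichment(
            {1: universe[:4]}, {"set": universe[:5]}, universe, test="hypergeometric"
        )
        assert res.loc[0, "p"] == pytest.approx(5 / 210, abs=1e-12)

    @pytest.mark.parametrize("test_name", ["hypergeometric", "fisher"])
    def test_pvalues_match_tail_enumeration(self, test_name):
        """p-values equal explicit enumeration over tables with margins <= 30."""
        rng = np.random.default_rng(9)
        universe = [f"g{i}" for i in range(30)]
        for _ in range(10):
            m, K = rng.integers(3, 15), rng.integers(3, 15)
            module = list(rng.choice(universe, m, replace=False))
            geneset = list(rng.choice(universe, K, replace=False))
            res = dc.module_set_enrichment({1: module}, {"s": geneset}, universe, test=test_name)
            k = res.loc[0, "overlap"]
            N = 30
            lo, hi = max(0, m + K - N), min(m, K)
            probs = {
                i: math.comb(K, i) * math.comb(N - K, m - i) / math.comb(N, m)
                for i in range(lo, hi + 1)
            }
            if test_name == "hypergeometric":
                expected = sum(p for i, p in probs.items() if i >= k)
            else:
                expected = sum(p for p in probs.values() if p <= probs[k] * (1 + 1e-9))
            assert res.loc[0, "p"] == pytest.approx(expected, abs=1e-10)

    def test_set_size_filter(self):
        universe = [f"g{i}" for i in range(100)]
        res = dc.module_set_enrichment(
            {1: universe[:10]},
            {"small": universe[:5], "ok": universe[:20]},
            universe,
            set_size_range=(10, 200),
        )
        assert set(res["gene_set"]) == {"ok"}

    def test_bh_correction_monotone(self):
        universe = [f"g{i}" for i in range(50)]
        rng = np.random.default_rng(0)
        modules = {i: list(rng.choice(universe, 10, replace=False)) for i in range(5)}
        sets = {f"s{i}": list(rng.choice(universe, 15, replace=False)) for i in range(4)}
        res = dc.module_set_enrichment(modules, sets, universe)
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            dc.module_set_enrichment({1: []}, {"s": []}, [])


class TestNeighborVoting:
    def _net(self, matrix):
        n = matrix.shape[0]
        return CoexpressionNetwork(matrix=matrix, genes=[f"g{i}" for i in range(n)], n_datasets=1)

    def test_perfect_block_scores_one(self):
        m = np.full((8, 8), 0.0)
        m[:4, :4] = 1.0
        np.fill_diagonal(m, 1.0)
        net = self._net(m)
        assert dc.neighbor_voting_auroc(net, [f"g{i}" for i in range(4)], n_folds=2, seed=0) == 1.0

    def test_matches_mann_whitney_oracle_with_singleton_folds(self):
        """With one hidden gene per fold the fold split is deterministic, so
        scores and AUROC can be recomputed by brute force."""
        rng = np.random.default_rng(4)
        m = rng.uniform(0, 1, (8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        net = self._net(m)
        module = ["g0", "g2", "g5"]
        got = dc.neighbor_voting_auroc(net, module, n_folds=3, seed=0)
        module_idx = [0, 2, 5]
        degree = m.sum(axis=1)
        aurocs = []
        for hidden in module_idx:
            train = [i for i in module_idx if i != hidden]
            candidates = [i for i in range(8) if i not in train]
            scores = [sum(m[c, t] for t in train) / degree[c] for c in candidates]
            labels = [c in module_idx for c in candidates]
            aurocs.append(pair_count_auroc(scores, labels))
        assert got == pytest.approx(np.mean(aurocs), abs=1e-14)

    def test_random_module_scores_near_half(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(0, 1, (40, 40))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        net = self._net(m)
        module = [f"g{i}" for i in rng.choice(40, 9, replace=False)]
        auroc = dc.neighbor_voting_auroc(net, module, n_folds=3, n_repeats=20, seed=1)
        assert abs(auroc - 0.5) < 0.1

    def test_module_covering_network_rejected(self):
        net = self._net(np.eye(3))
        with pytest.raises(ValueError):
            dc.neighbor_voting_auroc(net, ["g0", "g1", "g2"], n_folds=3)


class TestSignDiscriminability:
    def _tables(self, rs, genes=None):
        genes = genes or [f"g{i}" for i in range(len(rs))]
        return {"s0": pd.DataFrame({"gene": genes, "r": rs, "p": 0.5, "q": 0.5, "n": 5})}

    def test_perfectly_separated_signs(self):
        tabs = self._tables([0.5, 0.8, -0.3, -0.6])
        auroc = dc.gene_sign_discriminability(tabs, ["g0", "g1"], ["g2", "g3"], mode="signed")
        assert auroc["s0"] == 1.0

    def test_symmetric_magnitudes_give_half(self):
        # model genes (g0-g2) and background (g3-g5) have identical |r|
        rs = [0.2, -0.4, 0.6, -0.2, 0.4, -0.6]
        tabs = self._tables(rs)
        auroc = dc.gene_sign_discriminability(tabs, ["g0", "g2"], ["g1"], mode="abs")
        assert auroc["s0"] == pytest.approx(0.5)

    def test_matches_rank_sum_oracle(self):
        rs = [0.9, 0.1, 0.5, -0.2, 0.3, -0.7]
        tabs = self._tables(rs)
        pos, neg = ["g0", "g1", "g2"], ["g3", "g4", "g5"]
        got = dc.gene_sign_discriminability(tabs, pos, neg, mode="signed")["s0"]
        expected = pair_count_auroc(rs, [1, 1, 1, 0, 0, 0])
        assert got == pytest.approx(expected, abs=1e-14)

    def test_empty_class_rejected(self):
        tabs = self._tables([0.1, 0.2])
        with pytest.raises(ValueError):
            dc.gene_sign_discriminability(tabs, [], ["g0"])
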