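import numpy as np
import pytest
from scipy.stats import pearsonr, rankdata

from driverank.evaluation import (
    CVConfig,
    DEFAULT_C_GRID,
    _partition,
    build_gene_kernel,
    cross_validate,
    degree_rank_correlation,
    disease_cv,
    roc_auc,
    shuffle_benchmark,
    tune_C,
)
from driverank.io_formats import PPINetwork
from driverank.kernels import KernelMatrix
from driverank.ocsvm import RankedGeneList
from driverank.synthetic_data import SyntheticConfig, generate


def ranking_from(scores):
    return RankedGeneList.from_scores(scores)


class TestRocAuc:
    def test_perfect_ranking(self):
        r = ranking_from({"p1": 3.0, "p2": 2.0, "n1": 1.0, "n2": 0.0})
        res = roc_auc(r, ["p1", "p2"], ["n1", "n2"])
        assert res.auc == 1.0 and res.ce == 0.0 and res.n_negatives == 2

    def test_inverted_ranking(self):
        r = ranking_from({"p1": 0.0, "n1": 1.0, "n2": 2.0, "n3": 3.0})
        res = roc_auc(r, ["p1"], ["n1", "n2", "n3"])
        assert res.auc == 0.0 and res.ce == 3.0

    def test_ce_identity_and_trapezoid_agreement(self, rng):
        genes = [f"g{i}" for i in range(60)]
        for _ in range(10):
            scores = dict(zip(genes, rng.normal(size=60)))
            r = ranking_from(scores)
            pos, neg = genes[:15], genes[15:]
            res = roc_auc(r, pos, neg)
            assert res.ce == pytest.approx(res.n_negatives * (1 - res.auc), abs=1e-9)
            fpr, tpr = zip(*res.roc_points)
            assert res.auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-9)

    def test_ties_half_credit(self):
        r = ranking_from({"p": 1.0, "n": 1.0})
        assert roc_auc(r, ["p"], ["n"]).auc == 0.5

    def test_random_near_half(self, rng):
        genes = [f"g{i}" for i in range(520)]
        aucs = []
        for _ in range(30):
            r = ranking_from(dict(zip(genes, rng.normal(size=520))))
            aucs.append(roc_auc(r, genes[:20], genes[20:]).ce)
        assert np.mean(aucs) == pytest.approx(500 / 2, rel=0.1)

    def test_overlap_rejected(self):
        r = ranking_from({"a": 1.0, "b": 0.0})
        with pytest.raises(ValueError, match="overlap"):
            roc_auc(r, ["a"], ["a", "b"])

    def test_empty_class_rejected(self):
        r = ranking_from({"a": 1.0})
        with pytest.raises(ValueError, match="non-empty"):
            roc_auc(r, [], ["a"])


class TestPartition:
    def test_partition_properties(self, rng):
        items = [f"g{i}" for i in range(23)]
        folds = _partition(items, 5, rng)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(g for f in folds for g in f) == sorted(items)


def oracle_kernel(gold, universe):
    """Gold genes mutually similar, everything else dissimilar."""
    items = tuple(sorted(universe))
    v = np.array([1.0 if g in gold else 0.0 for g in items])
    return KernelMatrix(items, np.outer(v, v) + 1e-3 * np.eye(len(items)))


class TestCrossValidate:
    universe = [f"g{i:02d}" for i in range(40)]
    gold = universe[:10]

    def test_oracle_kernel_gives_zero_ce(self):
        K = oracle_kernel(set(self.gold), self.universe)
        res = cross_validate(self.gold, K, self.universe, CVConfig(k=5, repeats=1, seed=0))
        assert res.mean_ce == 0.0

    def test_leave_one_out_fold_count(self):
        K = oracle_kernel(set(self.gold), self.universe)
        cfg = CVConfig(k=len(self.gold), repeats=1, seed=0)
        res = cross_validate(self.gold, K, self.universe, cfg)
        assert len(res.folds) == len(self.gold)

    def test_reproducible(self):
        K = oracle_kernel(set(self.gold), self.universe)
        cfg = CVConfig(k=5, repeats=2, seed=3)
        a = cross_validate(self.gold, K, self.universe, cfg)
        b = cross_validate(self.gold, K, self.universe, cfg)
        assert [f.ce for f in a.folds] == [f.ce for f in b.folds]
        assert a.chosen_C == b.chosen_C

    def test_too_small_gold(self):
        K = oracle_kernel(set(self.gold), self.universe)
        with pytest.raises(ValueError, match="smaller k"):
            cross_validate(self.gold[:3], K, self.universe, CVConfig(k=5))


class TestTuneC:
    def test_default_grid(self):
        assert len(DEFAULT_C_GRID) == 11
        assert DEFAULT_C_GRID[0] == pytest.approx(2 ** (-5 / 2))
        assert DEFAULT_C_GRID[-1] == pytest.approx(2 ** (5 / 2))

    def test_returns_grid_member(self, rng):
        universe = [f"g{i}" for i in range(30)]
        gold = universe[:8]
        X = rng.normal(size=(30, 5))
        K = KernelMatrix(tuple(universe), X @ X.T)
        c = tune_C(gold, K, universe, CVConfig(seed=1))
        assert c in DEFAULT_C_GRID

    def test_degenerate_returns_smallest(self):
        universe = [f"g{i}" for i in range(30)]
        gold = universe[:8]
        K = oracle_kernel(set(gold), universe)
        # perfect separation: every C ties at CE 0 -> smallest C
        assert tune_C(gold, K, universe, CVConfig(seed=0)) == DEFAULT_C_GRID[0]


class TestDegreeRankCorrelation:
    def test_degree_ordered_ranking(self, rng):
        nodes = tuple(f"n{i:02d}" for i in range(20))
        edges = set()
        for i in range(20):
            for j in range(i + 1, min(i + 1 + i // 3 + 1, 20)):
                edges.add(frozenset({nodes[i], nodes[j]}))
        net = PPINetwork(nodes=nodes, edges=frozenset(edges))
        deg = net.degree
        ranking = ranking_from({g: float(deg[g]) + 1e-6 * i for i, g in enumerate(nodes)})
        rho = degree_rank_correlation(ranking, net, [0])
        # rank 1 = best, so a degree-ordered ranking is strongly anti-
        # correlated with rank position (|rho| < 1 only through degree ties)
        assert rho[0] <= -0.9

    def test_matches_rank_then_pearson_oracle(self, rng):
        nodes = tuple(f"n{i:02d}" for i in range(30))
        edges = {
            frozenset({nodes[i], nodes[int(rng.integers(30))]})
            for i in range(30)
            if nodes[i] != nodes[int(rng.integers(30))]
        }
        edges = frozenset(e for e in edges if len(e) == 2)
        net = PPINetwork(nodes=nodes, edges=edges)
        ranking = ranking_from(dict(zip(nodes, rng.normal(size=30))))
        rho = degree_rank_correlation(ranking, net, [0, 5])
        deg = net.degree
        for t in (0, 5):
            rest = [g for g in ranking.items if g in deg][t:]
            expected = pearsonr(
                rankdata([deg[g] for g in rest]), rankdata(range(len(rest)))
            )[0]
            assert rho[t] == pytest.approx(expected, abs=1e-9)

    def test_too_many_removed(self, path_net):
        ranking = ranking_from({"A": 3.0, "B": 2.0, "C": 1.0})
        with pytest.raises(ValueError):
            degree_rank_correlation(ranking, path_net, [3])


@pytest.fixture(scope="module")
def one_disease_data():
    cfg = SyntheticConfig(n_genes=80, n_samples=30, n_drivers=6, n_diseases=1, seed=5)
    return generate(cfg)


class TestDiseaseCV:

    def test_one_disease_multitask_equals_single_task(self, one_disease_data):
        table, net, truth, desc = one_disease_data
        pairs = [(g, d) for d in truth.diseases for g in truth.tsg[d]]
        cfg = CVConfig(k=2, repeats=1, seed=5)
        single = disease_cv("single_task", pairs, table, net, desc, cfg)
        multi = disease_cv("multitask", pairs, table, net, desc, cfg)
        assert len(single) == len(multi) == 1
        assert single[0]["mean_ce"] == pytest.approx(multi[0]["mean_ce"], abs=1e-9)

    def test_small_disease_skipped(self, one_disease_data):
        table, net, truth, desc = one_disease_data
        pairs = [(g, "D1") for g in truth.tsg["D1"][:3]]  # below min_drivers=4
        rows = disease_cv("single_task", pairs, table, net, desc, CVConfig(k=2, seed=0))
        assert rows == []

    def test_unknown_variant(self, one_disease_data):
        table, net, truth, desc = one_disease_data
        with pytest.raises(ValueError, match="variant"):
            disease_cv("bogus", [], table, net, desc, CVConfig(k=2))

    def test_missing_disease_labels_rejected(self, tiny_table, path_net):
        with pytest.raises(ValueError, match="disease labels"):
            disease_cv("multitask", [("GENE1", "D1")], tiny_table, path_net, None, CVConfig(k=2))


class TestShuffleBenchmark:
    def test_zero_shuffles(self):
        cfg = SyntheticConfig(n_genes=60, n_samples=20, n_drivers=5, seed=2)
        table, net, truth, _ = generate(cfg)
        res = shuffle_benchmark(
            truth.all_tsg(), table, net, n_shuffles=0, cfg=CVConfig(k=5, repeats=1, seed=2)
        )
        assert res["shuffled_ces"] == []
        assert np.isnan(res["fraction_worse"])


def test_build_gene_kernel_unknown_choice(tiny_table):
    with pytest.raises(ValueError, match="kernel choice"):
        build_gene_kernel(tiny_table, None, choice="bogus")
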