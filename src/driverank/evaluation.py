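"""Ranking evaluation: consistency error, cross-validation, diagnostics.

The consistency error of a ranking is ``CE = #N * (1 - AUC)`` where #N
is the number of negative genes — the mean number of non-driver genes
ranked above known drivers.  A perfect ranking has CE 0; a random one
has CE near #N/2.

Model assessment uses repeated k-fold cross-validation over the gold
standard, with the regularization parameter C tuned on each training
set by inner cross-validation over a fixed geometric grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import rankdata, spearmanr
from sklearn.metrics import roc_curve

from driverank.io_formats import MutationTable, PPINetwork
from driverank.kernels import (
    KernelMatrix,
    align_items,
    degree_kernel,
    integrated_kernel,
    mutation_kernel,
    ppi_kernel,
)
from driverank.mutation_features import og_features, tsg_features
from driverank.multitask import (
    DiseaseDescriptor,
    DiseaseKernel,
    GeneDiseasePair,
    cancer_kernel,
    dirac_kernel,
    multitask_kernel,
    pair_kernel,
)
from driverank.ocsvm import RankedGeneList, fit, score

logger = logging.getLogger(__name__)

#: Default C grid: {2^(-5/2), 2^(-4/2), ..., 2^(5/2)}, 11 values.
DEFAULT_C_GRID = tuple(2.0 ** (e / 2.0) for e in range(-5, 6))

DISEASE_CV_VARIANTS = ("single_task", "aggregation", "multitask", "multitask2")


@dataclass
class EvaluationResult:
    """AUC, consistency error, and the ROC curve of one evaluated ranking."""

    auc: float
    ce: float
    n_negatives: int
    roc_points: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class CVConfig:
    k: int = 5
    repeats: int = 2
    seed: int = 0
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    inner_k: int = 5

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        self.c_grid = tuple(sorted(self.c_grid))


@dataclass
class CVResult:
    folds: list[EvaluationResult]
    chosen_C: list[float]

    @property
    def mean_ce(self) -> float:
        return float(np.mean([f.ce for f in self.folds]))

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f.auc for f in self.folds]))


def roc_auc(
    ranking: RankedGeneList,
    positives: Sequence[str],
    negatives: Sequence[str],
) -> EvaluationResult:
    """Evaluate a ranking against disjoint positive and negative gene sets.

    AUC is computed by Mann-Whitney pair counting with ties credited 1/2;
    CE = #N * (1 - AUC).  ``roc_points`` holds the empirical ROC curve.
    """
    pos = set(positives)
    neg = set(negatives)
    if not pos or not neg:
        raise ValueError("positives and negatives must both be non-empty")
    if pos & neg:
        raise ValueError(f"positives and negatives overlap: {sorted(pos & neg)}")
    scores = ranking.as_dict()
    missing = (pos | neg) - set(scores)
    if missing:
        raise ValueError(f"items absent from the ranking: {sorted(missing)}")
    pos_list = sorted(pos)
    neg_list = sorted(neg)
    y_score = np.array([scores[g] for g in pos_list] + [scores[g] for g in neg_list])
    n_pos, n_neg = len(pos_list), len(neg_list)
    ranks = rankdata(y_score)  # average ranks give the tie-1/2 convention
    auc = (ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    y_true = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
    fpr, tpr, _ = roc_curve(y_true, y_score)
    return EvaluationResult(
        auc=float(auc),
        ce=float(n_neg * (1.0 - auc)),
        n_negatives=n_neg,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
    )


def _partition(items: Sequence[str], k: int, rng: np.random.Generator) -> list[list[str]]:
    """Seeded split into k folds with sizes differing by at most one."""
    shuffled = list(items)
    rng.shuffle(shuffled)
    folds: list[list[str]] = [[] for _ in range(k)]
    for i, g in enumerate(shuffled):
        folds[i % k].append(g)
    return folds


def _fit_rank_evaluate(
    kernel: KernelMatrix,
    train: Sequence[str],
    positives: Sequence[str],
    negatives: Sequence[str],
    C: float,
) -> EvaluationResult:
    # candidates = everything not trained on; positives stay scoreable even
    # when they entered the training set through another disease's drivers
    train = sorted(train)
    candidates = sorted((set(kernel.items) - set(train)) | set(positives))
    model = fit(kernel.restrict(tuple(train)), C)
    ranking = score(model, kernel.rows(candidates, train), candidates)
    return roc_auc(ranking, positives, negatives)


def tune_C(
    gold_train: Sequence[str],
    kernel: KernelMatrix,
    universe: Sequence[str],
    cfg: CVConfig,
    fixed_train: Sequence[str] = (),
) -> float:
    """Pick the grid C minimizing the mean inner-CV consistency error.

    Inner folds split ``gold_train``; ``fixed_train`` genes (e.g. other
    diseases' drivers in the aggregation regime) stay in every inner
    training set.  Negatives are the universe minus all training gold.
    Ties (including the fully degenerate case where all C give the same
    CE) resolve to the smallest C.
    """
    gold_train = sorted(set(gold_train))
    if len(gold_train) < 5:  # too few genes for a meaningful inner CV
        return cfg.c_grid[0]
    inner_k = min(cfg.inner_k, len(gold_train))
    rng = np.random.default_rng(cfg.seed)
    folds = _partition(gold_train, inner_k, rng)
    fixed = sorted(set(fixed_train) - set(gold_train))
    negatives = sorted(set(universe) - set(gold_train) - set(fixed))
    mean_ce = []
    uniform_ce: float | None = None  # all C <= 1 share the uniform solution
    for C in cfg.c_grid:
        if C <= 1.0 and uniform_ce is not None:
            mean_ce.append(uniform_ce)
            continue
        ces = []
        for i in range(inner_k):
            held_out = folds[i]
            train = fixed + [g for j, f in enumerate(folds) if j != i for g in f]
            res = _fit_rank_evaluate(kernel, train, held_out, negatives, C)
            ces.append(res.ce)
        mean_ce.append(float(np.mean(ces)))
        if C <= 1.0:
            uniform_ce = mean_ce[-1]
    best = int(np.argmin(mean_ce))  # first minimum = smallest C on the sorted grid
    if len(set(mean_ce)) == 1:
        logger.warning("inner CV degenerate: all C values give CE %.4f", mean_ce[0])
    return cfg.c_grid[best]


def cross_validate(
    gold: Sequence[str],
    kernel: KernelMatrix,
    universe: Sequence[str],
    cfg: CVConfig,
) -> CVResult:
    """Repeated k-fold cross-validation of the one-class SVM ranking.

    Each fold trains on the remaining gold genes (with inner C tuning),
    scores every non-training gene, and is evaluated with the held-out
    gold genes as positives and ``universe`` minus the whole gold
    standard as negatives.
    """
    gold = sorted(set(gold))
    if len(gold) < cfg.k:
        raise ValueError(
            f"gold standard has {len(gold)} genes, fewer than k={cfg.k}; use a smaller k"
        )
    negatives = sorted(set(universe) - set(gold))
    rng = np.random.default_rng(cfg.seed)
    folds_out: list[EvaluationResult] = []
    chosen: list[float] = []
    for _ in range(cfg.repeats):
        folds = _partition(gold, cfg.k, rng)
        for i in range(cfg.k):
            held_out = folds[i]
            train = [g for j, f in enumerate(folds) if j != i for g in f]
            C = tune_C(train, kernel, universe, cfg)
            chosen.append(C)
            folds_out.append(_fit_rank_evaluate(kernel, train, held_out, negatives, C))
    return CVResult(folds=folds_out, chosen_C=chosen)


def build_gene_kernel(
    table: MutationTable,
    net: Optional[PPINetwork],
    mode: str = "TSG",
    choice: str = "mutation+ppi",
    standardize: bool = True,
    restrict_to_disease: Optional[str] = None,
) -> KernelMatrix:
    """Assemble the requested gene kernel over the table's gene universe.

    ``choice`` is one of mutation, ppi, degree, mutation+ppi,
    mutation+degree.  Network kernels are aligned to the universe with
    the isolated-node convention (diagonal 1 for the diffusion kernel,
    0 for the degree kernel).
    """
    universe = table.gene_universe
    features_fn = og_features if mode == "OG" else tsg_features

    def k_mut() -> KernelMatrix:
        return mutation_kernel(features_fn(table, restrict_to_disease), standardize=standardize)

    def k_ppi() -> KernelMatrix:
        assert net is not None, "PPI network required for this kernel choice"
        return align_items(ppi_kernel(net), universe, fill_diag=1.0)

    def k_deg() -> KernelMatrix:
        assert net is not None, "PPI network required for this kernel choice"
        return align_items(degree_kernel(net), universe, fill_diag=0.0)

    if choice == "mutation":
        return k_mut()
    if choice == "ppi":
        return k_ppi()
    if choice == "degree":
        return k_deg()
    if choice == "mutation+ppi":
        return integrated_kernel(k_mut(), k_ppi())
    if choice == "mutation+degree":
        return integrated_kernel(k_mut(), k_deg())
    raise ValueError(
        f"unknown kernel choice {choice!r}; expected one of "
        "mutation, ppi, degree, mutation+ppi, mutation+degree"
    )


def _tune_C_multitask(
    K_gene: KernelMatrix,
    disease_kernel: DiseaseKernel,
    fixed_pairs: list[GeneDiseasePair],
    tunable_genes: list[str],
    disease: str,
    negatives: list[str],
    cfg: CVConfig,
) -> float:
    """Inner C tuning for pair-kernel models.

    Splits the query disease's own training genes into inner folds while
    keeping the other diseases' pairs in every inner training set.
    """
    tunable = sorted(tunable_genes)
    if len(tunable) < 5:
        return cfg.c_grid[0]
    inner_k = min(cfg.inner_k, len(tunable))
    rng = np.random.default_rng(cfg.seed)
    folds = _partition(tunable, inner_k, rng)
    mean_ce = []
    uniform_ce: float | None = None
    for C in cfg.c_grid:
        if C <= 1.0 and uniform_ce is not None:
            mean_ce.append(uniform_ce)
            continue
        ces = []
        for i in range(inner_k):
            held_out = folds[i]
            own = [g for j, f in enumerate(folds) if j != i for g in f]
            train_pairs = fixed_pairs + [GeneDiseasePair(g, disease) for g in own]
            candidates = sorted(set(K_gene.items) - set(own))
            ranking = _multitask_rank(K_gene, disease_kernel, train_pairs, disease, candidates, C)
            ces.append(roc_auc(ranking, held_out, negatives).ce)
        mean_ce.append(float(np.mean(ces)))
        if C <= 1.0:
            uniform_ce = mean_ce[-1]
    return cfg.c_grid[int(np.argmin(mean_ce))]


def _multitask_rank(
    K_gene: KernelMatrix,
    disease_kernel: DiseaseKernel,
    training_pairs: list[GeneDiseasePair],
    query_disease: str,
    candidates: list[str],
    C: float,
) -> RankedGeneList:
    K_train = pair_kernel(K_gene, disease_kernel, training_pairs)
    model = fit(K_train, C)
    query_pairs = [GeneDiseasePair(g, query_disease) for g in candidates]
    K_cross = pair_kernel(K_gene, disease_kernel, query_pairs, training_pairs)
    return score(model, K_cross, candidates)


def disease_cv(
    variant: str,
    pairs: Sequence[GeneDiseasePair | tuple[str, str]],
    mutation_table: MutationTable,
    net: Optional[PPINetwork],
    descriptors: Optional[Mapping[str, DiseaseDescriptor]],
    cfg: CVConfig,
    mode: str = "TSG",
    kernel_choice: str = "mutation+ppi",
    min_drivers: int = 4,
) -> list[dict]:
    """Per-disease 2-fold CV under one of the four training regimes.

    * ``single_task``  — gene features from the disease's own mutations;
      train and test only on the disease's drivers.
    * ``aggregation``  — features from the full table; each training set
      is all other diseases' drivers plus half of the disease's own.
    * ``multitask``    — pair kernel with the uniform+Dirac disease kernel.
    * ``multitask2``   — pair kernel with the descriptor disease kernel.

    Diseases with fewer than ``min_drivers`` known drivers are skipped.
    Returns one row per evaluated disease: disease, variant, n_drivers,
    mean_ce, mean_auc.
    """
    if variant not in DISEASE_CV_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {DISEASE_CV_VARIANTS}")
    if not mutation_table.has_disease_labels():
        raise ValueError("disease_cv requires disease labels on every mutation record")
    pairs = [p if isinstance(p, GeneDiseasePair) else GeneDiseasePair(*p) for p in pairs]
    by_disease: dict[str, list[str]] = {}
    for p in pairs:
        by_disease.setdefault(p.disease, [])
        if p.gene not in by_disease[p.disease]:
            by_disease[p.disease].append(p.gene)
    diseases = sorted(by_disease)
    all_gold = sorted({p.gene for p in pairs})
    universe = mutation_table.gene_universe
    negatives = sorted(set(universe) - set(all_gold))

    if variant == "multitask2":
        if descriptors is None:
            raise ValueError("multitask2 requires disease descriptors")
        dk: DiseaseKernel = cancer_kernel(descriptors)
    elif variant == "multitask":
        dk = multitask_kernel
    else:
        dk = dirac_kernel  # unused by the single-task variants

    shared_kernel: Optional[KernelMatrix] = None
    if variant != "single_task":
        shared_kernel = build_gene_kernel(mutation_table, net, mode=mode, choice=kernel_choice)

    rows: list[dict] = []
    for d in diseases:
        drivers = sorted(by_disease[d])
        if len(drivers) < min_drivers:
            logger.info("skipping %s: %d < %d known drivers", d, len(drivers), min_drivers)
            continue
        if variant == "single_task":
            kernel = build_gene_kernel(
                mutation_table, net, mode=mode, choice=kernel_choice, restrict_to_disease=d
            )
        else:
            kernel = shared_kernel
        assert kernel is not None
        other_pairs = [p for p in pairs if p.disease != d]
        rng = np.random.default_rng(cfg.seed)
        fold_results: list[EvaluationResult] = []
        for _ in range(cfg.repeats):
            halves = _partition(drivers, 2, rng)
            for i in range(2):
                test_half = halves[i]
                train_half = halves[1 - i]
                # identical positives for all variants: held-out drivers of
                # this disease that no variant's training set could contain
                # (drivers shared with other diseases would be ranked
                # trivially by the pooled regimes)
                positives = sorted(
                    set(test_half) - {p.gene for p in other_pairs} - set(train_half)
                )
                if not positives:
                    logger.info("%s: fold with no unseen positives skipped", d)
                    continue
                if variant == "single_task":
                    C = tune_C(train_half, kernel, universe, cfg)
                    res = _fit_rank_evaluate(kernel, train_half, positives, negatives, C)
                elif variant == "aggregation":
                    fixed_genes = sorted({p.gene for p in other_pairs} - set(train_half))
                    train = sorted(set(fixed_genes) | set(train_half))
                    C = tune_C(train_half, kernel, universe, cfg, fixed_train=fixed_genes)
                    res = _fit_rank_evaluate(kernel, train, positives, negatives, C)
                else:
                    fixed = other_pairs
                    C = _tune_C_multitask(kernel, dk, fixed, train_half, d, negatives, cfg)
                    train_pairs = fixed + [GeneDiseasePair(g, d) for g in train_half]
                    candidates = sorted(set(universe) - set(train_half))
                    ranking = _multitask_rank(kernel, dk, train_pairs, d, candidates, C)
                    res = roc_auc(ranking, positives, negatives)
                fold_results.append(res)
        if not fold_results:
            logger.info("skipping %s: no evaluable folds", d)
            continue
        rows.append(
            {
                "disease": d,
                "variant": variant,
                "n_drivers": len(drivers),
                "mean_ce": float(np.mean([r.ce for r in fold_results])),
                "mean_auc": float(np.mean([r.auc for r in fold_results])),
            }
        )
    return rows


def degree_rank_correlation(
    ranking: RankedGeneList,
    net: PPINetwork,
    top_removed: Sequence[int] = (0,),
) -> dict[int, float]:
    """Spearman correlation between network degree and rank position.

    For each t in ``top_removed``, the t best-ranked genes are dropped
    and the correlation is computed over the remaining ranked network
    genes (rank 1 = best).
    """
    deg = net.degree
    ranked_net_genes = [g for g in ranking.items if g in deg]
    out: dict[int, float] = {}
    for t in top_removed:
        if t >= len(ranked_net_genes):
            raise ValueError(f"cannot remove top {t} of {len(ranked_net_genes)} ranked genes")
        rest = ranked_net_genes[t:]
        degrees = [deg[g] for g in rest]
        positions = list(range(1, len(rest) + 1))
        rho, _ = spearmanr(degrees, positions)
        out[t] = float(rho)
    return out


def shuffle_benchmark(
    gold: Sequence[str],
    mutation_table: MutationTable,
    net: PPINetwork,
    n_shuffles: int = 100,
    cfg: Optional[CVConfig] = None,
    n_bins: int = 20,
) -> dict:
    """Compare the true PPI kernel with degree-binned network shuffles.

    Cross-validates once with the diffusion kernel of the true network,
    then once per shuffle (the shuffled kernel is the permuted true
    kernel, which is exactly the kernel of the relabeled network).
    Returns the true CE, the shuffled CEs, and the fraction of shuffles
    whose CE exceeds the true one.
    """
    from driverank.kernels import degree_binned_shuffle, permute_kernel

    cfg = cfg or CVConfig()
    universe = mutation_table.gene_universe
    K_true = align_items(ppi_kernel(net), universe, fill_diag=1.0)
    true_ce = cross_validate(gold, K_true, universe, cfg).mean_ce
    rng = np.random.default_rng(cfg.seed)
    shuffled_ces: list[float] = []
    for _ in range(n_shuffles):
        mapping = degree_binned_shuffle(net, n_bins=min(n_bins, len(net.nodes)), seed=rng)
        K_shuf = permute_kernel(K_true, mapping)
        shuffled_ces.append(cross_validate(gold, K_shuf, universe, cfg).mean_ce)
    worse = sum(1 for ce in shuffled_ces if ce > true_ce)
    return {
        "true_ce": true_ce,
        "shuffled_ces": shuffled_ces,
        "fraction_worse": (worse / n_shuffles) if n_shuffles else float("nan"),
    }
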