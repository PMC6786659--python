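"""One-class SVM on a precomputed kernel, and the ranking it induces.

The dual solved here is

    minimize   (1/2) a^T K a
    subject to sum(a) = 1,   0 <= a_i <= U(C),   U(C) = max(C, 1) / N.

For C <= 1 the box and simplex constraints force the uniform solution
a_i = 1/N.  For C > 1 the QP is solved by accelerated projected gradient
with an exact Euclidean projection onto the capped simplex, which is
deterministic and validated against a brute-force oracle in the tests.
Scores are f(g) = sum_i a_i K(g_i, g); only the ranking matters, so no
offset term is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from driverank.kernels import KernelMatrix
from driverank.multitask import DiseaseKernel, GeneDiseasePair, pair_kernel

KKT_TOL = 1e-6


@dataclass
class TrainedModel:
    """Weights of a fitted one-class SVM over its training items."""

    training_items: tuple[str, ...]
    alpha: np.ndarray
    C: float
    kernel_id: str = ""

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (len(self.training_items),):
            raise ValueError("alpha must have one weight per training item")
        if (self.alpha < -1e-12).any():
            raise ValueError("alpha must be non-negative")
        if abs(self.alpha.sum() - 1.0) > 1e-8:
            raise ValueError("alpha must sum to 1")

    @property
    def upper_bound(self) -> float:
        return max(self.C, 1.0) / len(self.training_items)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "training_items": list(self.training_items),
            "alpha": [float(a) for a in self.alpha],
            "C": self.C,
            "kernel_id": self.kernel_id,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            training_items=tuple(payload["training_items"]),
            alpha=np.array(payload["alpha"]),
            C=payload["C"],
            kernel_id=payload.get("kernel_id", ""),
        )


@dataclass
class RankedGeneList:
    """Items sorted by score descending, ties broken by identifier ascending."""

    items: tuple[str, ...]
    scores: np.ndarray
    rank: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not self.rank:
            self.rank = tuple(range(1, len(self.items) + 1))

    @classmethod
    def from_scores(cls, scores: Mapping[str, float]) -> "RankedGeneList":
        ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(
            items=tuple(g for g, _ in ordered),
            scores=np.array([s for _, s in ordered]),
        )

    def score_of(self, item: str) -> float:
        return float(self.scores[self.items.index(item)])

    def as_dict(self) -> dict[str, float]:
        return {g: float(s) for g, s in zip(self.items, self.scores)}

    def top(self, k: int) -> tuple[str, ...]:
        return self.items[:k]


def _project_capped_simplex(x: np.ndarray, upper: float) -> np.ndarray:
    """Euclidean projection onto {a : sum(a) = 1, 0 <= a_i <= upper}.

    Bisection on the dual shift tau of a = clip(x - tau, 0, upper);
    sum(a) is continuous and non-increasing in tau.
    """
    lo = float(x.min() - 1.0)
    hi = float(x.max())
    for _ in range(100):
        tau = (lo + hi) / 2.0
        s = np.clip(x - tau, 0.0, upper).sum()
        if s > 1.0:
            lo = tau
        else:
            hi = tau
    return np.clip(x - (lo + hi) / 2.0, 0.0, upper)


def _kkt_residual(K: np.ndarray, a: np.ndarray, upper: float, step: float) -> float:
    """Fixed-point residual of the projected-gradient map (0 at optimality)."""
    return float(np.max(np.abs(a - _project_capped_simplex(a - step * (K @ a), upper))))


def _polish_active_set(K: np.ndarray, a: np.ndarray, upper: float) -> np.ndarray | None:
    """Solve the reduced KKT system exactly for the active set guessed from ``a``.

    Variables within ``eps`` of a bound are pinned there; the free block
    solves an equality-constrained QP via one linear system.  Returns
    None when the guess is infeasible or the system is singular.
    """
    n = K.shape[0]
    eps = 1e-6 * max(upper, 1.0 / n)
    at_lower = a <= eps
    at_upper = a >= upper - eps
    free = ~(at_lower | at_upper)
    budget = 1.0 - upper * at_upper.sum()
    if not free.any():
        cand = np.where(at_upper, upper, 0.0)
        return cand if abs(cand.sum() - 1.0) < 1e-9 else None
    if budget < -1e-12 or budget > upper * free.sum() + 1e-12:
        return None
    idx = np.flatnonzero(free)
    Kff = K[np.ix_(idx, idx)]
    rhs_lin = -K[np.ix_(idx, np.flatnonzero(at_upper))].sum(axis=1) * upper
    m = len(idx)
    A = np.zeros((m + 1, m + 1))
    A[:m, :m] = Kff
    A[:m, m] = 1.0
    A[m, :m] = 1.0
    b = np.concatenate([rhs_lin, [budget]])
    sol, _, _, _ = np.linalg.lstsq(A, b, rcond=None)  # min-norm solution if Kff singular
    if np.max(np.abs(A @ sol - b)) > 1e-9:
        return None
    af = sol[:m]
    if (af < -1e-10).any() or (af > upper + 1e-10).any():
        return None
    out = np.where(at_upper, upper, 0.0)
    out[idx] = np.clip(af, 0.0, upper)
    return out


def _solve_qp(K: np.ndarray, upper: float, max_iter: int = 300_000) -> np.ndarray:
    """min 1/2 a^T K a over the capped simplex.

    Accelerated projected gradient with function-value restart, followed
    by an exact active-set polish.  Deterministic: fixed uniform start.
    """
    n = K.shape[0]
    lam = float(np.linalg.eigvalsh(K)[-1])
    step = 1.0 / lam if lam > 0 else 1.0
    a = _project_capped_simplex(np.full(n, 1.0 / n), upper)
    y = a.copy()
    t = 1.0
    f_prev = 0.5 * a @ K @ a
    for it in range(1, max_iter + 1):
        a_next = _project_capped_simplex(y - step * (K @ y), upper)
        f_next = 0.5 * a_next @ K @ a_next
        if f_next > f_prev:  # restart momentum on non-monotone step
            y = a.copy()
            t = 1.0
            a_next = _project_capped_simplex(y - step * (K @ y), upper)
            f_next = 0.5 * a_next @ K @ a_next
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        y = a_next + ((t - 1.0) / t_next) * (a_next - a)
        a, t, f_prev = a_next, t_next, f_next
        if it % 25 == 0:
            # once the active set settles, the exact polish finishes the job
            polished = _polish_active_set(K, a, upper)
            if polished is not None and (
                0.5 * polished @ K @ polished <= f_prev + 1e-12
                and _kkt_residual(K, polished, upper, step) < 1e-11
            ):
                return polished
            if _kkt_residual(K, a, upper, step) < 1e-10:
                break
    resid = _kkt_residual(K, a, upper, step)
    if resid > KKT_TOL:
        raise RuntimeError(f"QP did not converge: KKT residual {resid:.2e}")
    return a


def fit(K_train: KernelMatrix, C: float, kernel_id: str = "") -> TrainedModel:
    """Fit the one-class SVM dual on a PSD training kernel."""
    if C <= 0:
        raise ValueError("C must be positive")
    n = len(K_train.items)
    if n < 1:
        raise ValueError("need at least one training item")
    K_train.check_psd()
    upper = max(C, 1.0) / n
    if upper * n <= 1.0 + 1e-12:  # box + simplex force the uniform solution
        alpha = np.full(n, 1.0 / n)
    else:
        alpha = _solve_qp(K_train.values, upper)
        # snap the tiny projection slack so the simplex constraint holds exactly
        alpha = np.clip(alpha, 0.0, upper)
        alpha = alpha / alpha.sum()
    return TrainedModel(training_items=K_train.items, alpha=alpha, C=C, kernel_id=kernel_id)


def objective(model: TrainedModel, K_train: KernelMatrix) -> float:
    """Dual objective 1/2 a^T K a at the fitted weights."""
    K = K_train.restrict(model.training_items).values
    return float(0.5 * model.alpha @ K @ model.alpha)


def score(
    model: TrainedModel,
    K_cross: np.ndarray,
    candidates: Sequence[str],
) -> RankedGeneList:
    """Rank candidates by f(g) = sum_i alpha_i K(g_i, g).

    ``K_cross`` holds one row per candidate and one column per training
    item, in the model's training order.
    """
    K_cross = np.asarray(K_cross, dtype=float)
    if K_cross.shape != (len(candidates), len(model.training_items)):
        raise ValueError(
            f"cross-kernel must be ({len(candidates)}, {len(model.training_items)}),"
            f" got {K_cross.shape}"
        )
    values = K_cross @ model.alpha
    return RankedGeneList.from_scores(dict(zip(candidates, values)))


def fit_and_rank(
    K: KernelMatrix,
    training_genes: Sequence[str],
    candidate_genes: Sequence[str],
    C: float,
) -> RankedGeneList:
    """Train on the training genes and rank the candidates with one kernel."""
    model = fit(K.restrict(tuple(training_genes)), C)
    return score(model, K.rows(candidate_genes, list(training_genes)), candidate_genes)


def fit_score_multitask(
    K_gene: KernelMatrix,
    disease_kernel: DiseaseKernel,
    training_pairs: Sequence[GeneDiseasePair],
    query_disease: str,
    candidate_genes: Sequence[str],
    C: float,
) -> RankedGeneList:
    """Multitask ranking for one query disease.

    Trains the one-class SVM on the pair kernel over the training
    (gene, disease) pairs, then scores each candidate gene g as
    ``sum_i alpha_i K_gene(g_i, g) * K_disease(d_i, query_disease)``.
    """
    K_train = pair_kernel(K_gene, disease_kernel, training_pairs)
    model = fit(K_train, C)
    query_pairs = [GeneDiseasePair(g, query_disease) for g in candidate_genes]
    K_cross = pair_kernel(K_gene, disease_kernel, query_pairs, training_pairs)
    return score(
        TrainedModel(tuple(model.training_items), model.alpha, C),
        K_cross,
        candidate_genes,
    )
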