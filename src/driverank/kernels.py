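"""Gene kernels: mutation inner-product, PPI diffusion, degree, integrated.

All constructors return a :class:`KernelMatrix` — a symmetric,
numerically positive-semidefinite similarity matrix over an ordered item
list.  The diffusion kernel is exp(-L) for the normalized graph
Laplacian L; genes absent from the network enter as isolated nodes
(self-similarity 1, zero similarity to everything else) so that a single
gene universe can be shared across kernels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from driverank.io_formats import PPINetwork
from driverank.mutation_features import GeneFeatureTable

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-10
PSD_TOL = -1e-8


@dataclass
class KernelMatrix:
    """Symmetric PSD similarity matrix over an ordered, unique item list."""

    items: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.items = tuple(self.items)
        if len(set(self.items)) != len(self.items):
            raise ValueError("kernel items must be unique")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.items)
        if self.values.shape != (n, n):
            raise ValueError(f"kernel must be {n}x{n}, got {self.values.shape}")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"kernel not symmetric (max asymmetry {asym:.2e})")
        # exact symmetrization so downstream eigensolvers see a Hermitian matrix
        self.values = (self.values + self.values.T) / 2.0
        self._index = {g: i for i, g in enumerate(self.items)}

    def min_eigenvalue(self) -> float:
        if not self.items:
            return 0.0
        return float(np.linalg.eigvalsh(self.values)[0])

    def check_psd(self, tol: float = PSD_TOL) -> None:
        lam = self.min_eigenvalue()
        if lam < tol:
            raise ValueError(f"kernel not PSD: min eigenvalue {lam:.3e} < {tol:.1e}")

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def restrict(self, items: Sequence[str]) -> "KernelMatrix":
        idx = [self._index[g] for g in items]
        return KernelMatrix(tuple(items), self.values[np.ix_(idx, idx)])

    def rows(self, row_items: Sequence[str], col_items: Sequence[str]) -> np.ndarray:
        """Cross-kernel block K[row_items, col_items] (not necessarily square)."""
        ri = [self._index[g] for g in row_items]
        ci = [self._index[g] for g in col_items]
        return self.values[np.ix_(ri, ci)]

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=list(self.items), columns=list(self.items)).to_csv(
            path, sep="\t", index_label="item"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KernelMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column items differ")
        return cls(tuple(df.index), df.to_numpy(dtype=float))


@dataclass
class LaplacianMatrix:
    """Normalized graph Laplacian L = I - D^{-1/2} A D^{-1/2}.

    Rows and columns of isolated nodes are identically zero, which makes
    exp(-L) assign them self-similarity 1 and no similarity to any other
    node.
    """

    items: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.items = tuple(self.items)
        self.values = np.asarray(self.values, dtype=float)


def mutation_kernel(features: GeneFeatureTable, standardize: bool = True) -> KernelMatrix:
    """Linear kernel K(g, g') = Phi(g)^T Phi(g') over the feature table.

    With ``standardize`` each feature column is z-scored across genes
    first; zero-variance columns are centered only (with a warning).
    The result has rank at most 3.
    """
    if len(features.genes) < 1:
        raise ValueError("feature table must contain at least one gene")
    phi = features.phi.copy()
    if standardize:
        mean = phi.mean(axis=0)
        std = phi.std(axis=0)
        zero_var = std == 0
        if zero_var.any():
            logger.warning(
                "zero-variance feature column(s) %s: centered only",
                [features.feature_names[i] for i in np.flatnonzero(zero_var)],
            )
        std = np.where(zero_var, 1.0, std)
        phi = (phi - mean) / std
    return KernelMatrix(features.genes, phi @ phi.T)


def normalized_laplacian(net: PPINetwork) -> LaplacianMatrix:
    nodes = net.nodes
    n = len(nodes)
    index = {g: i for i, g in enumerate(nodes)}
    A = np.zeros((n, n))
    for e in net.edges:
        u, v = tuple(e)
        A[index[u], index[v]] = 1.0
        A[index[v], index[u]] = 1.0
    deg = A.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    L = -inv_sqrt[:, None] * A * inv_sqrt[None, :]
    L[np.diag_indices(n)] = np.where(deg > 0, 1.0, 0.0)
    return LaplacianMatrix(items=nodes, values=L)


def diffusion_kernel(L: LaplacianMatrix) -> KernelMatrix:
    """Diffusion kernel K = exp(-L), computed by scaling-and-squaring."""
    if len(L.items) == 0:
        return KernelMatrix((), np.zeros((0, 0)))
    K = expm(-L.values)
    K = (K + K.T) / 2.0
    return KernelMatrix(L.items, K)


def ppi_kernel(net: PPINetwork) -> KernelMatrix:
    """Convenience wrapper: diffusion kernel of the network's normalized Laplacian."""
    return diffusion_kernel(normalized_laplacian(net))


def degree_kernel(net: PPINetwork) -> KernelMatrix:
    """Rank-1 kernel K(i, j) = d_i * d_j of node degrees."""
    deg = net.degree
    d = np.array([deg[g] for g in net.nodes], dtype=float)
    return KernelMatrix(net.nodes, np.outer(d, d))


def integrated_kernel(K1: KernelMatrix, K2: KernelMatrix) -> KernelMatrix:
    """Entrywise average (K1 + K2) / 2; requires identical item ordering."""
    if K1.items != K2.items:
        diff = set(K1.items) ^ set(K2.items)
        if diff:
            raise ValueError(f"kernels cover different items; symmetric difference: {sorted(diff)}")
        raise ValueError("kernels have identical items but different ordering")
    return KernelMatrix(K1.items, (K1.values + K2.values) / 2.0)


def align_items(
    K: KernelMatrix,
    universe: Sequence[str],
    fill: str = "isolated",
    fill_diag: float = 1.0,
) -> KernelMatrix:
    """Extend ``K`` to ``universe`` by adding missing genes as isolated items.

    Missing genes get ``fill_diag`` on the diagonal (1 for diffusion-type
    kernels, 0 for the degree kernel) and 0 elsewhere, which preserves
    positive semidefiniteness (block-diagonal extension).  Idempotent.
    """
    if fill != "isolated":
        raise ValueError(f"unknown fill policy {fill!r}; only 'isolated' is supported")
    universe = tuple(universe)
    missing = set(K.items) - set(universe)
    if missing:
        raise ValueError(f"universe does not cover kernel items: {sorted(missing)}")
    n = len(universe)
    out = np.zeros((n, n))
    pos = {g: i for i, g in enumerate(universe)}
    idx = np.array([pos[g] for g in K.items], dtype=int)
    out[np.ix_(idx, idx)] = K.values
    for g in universe:
        if g not in K._index:
            out[pos[g], pos[g]] = fill_diag
    return KernelMatrix(universe, out)


def degree_binned_shuffle(
    net: PPINetwork, n_bins: int = 20, seed: int | np.random.Generator = 0
) -> dict[str, str]:
    """Degree-preserving node relabeling: shuffle genes within degree bins.

    Nodes are sorted by decreasing degree (ties broken by name), cut into
    ``n_bins`` contiguous bins whose sizes differ by at most one, and
    permuted uniformly at random within each bin.  Returns the gene ->
    gene permutation.
    """
    if n_bins < 1 or n_bins > len(net.nodes):
        raise ValueError(f"n_bins must be in [1, {len(net.nodes)}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    deg = net.degree
    ordered = sorted(net.nodes, key=lambda g: (-deg[g], g))
    n = len(ordered)
    base, extra = divmod(n, n_bins)
    mapping: dict[str, str] = {}
    start = 0
    for b in range(n_bins):
        size = base + (1 if b < extra else 0)
        bin_nodes = ordered[start : start + size]
        start += size
        perm = rng.permutation(len(bin_nodes))
        for src, j in zip(bin_nodes, perm):
            mapping[src] = bin_nodes[j]
    return mapping


def permute_kernel(K: KernelMatrix, mapping: dict[str, str]) -> KernelMatrix:
    """Kernel of the relabeled graph: K'(a, b) = K(pi^{-1}(a), pi^{-1}(b)).

    Equivalent to recomputing the diffusion kernel on the relabeled
    network, but O(n^2) instead of a fresh matrix exponential.
    """
    inverse = {v: k for k, v in mapping.items()}
    idx = np.array([K._index[inverse.get(g, g)] for g in K.items], dtype=int)
    return KernelMatrix(K.items, K.values[np.ix_(idx, idx)])
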