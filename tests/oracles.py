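"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the code paths they check: the QP oracle is a
pure grid search over the capped simplex, and the matrix-exponential
oracle is a truncated power series.
"""

import numpy as np


def _eval_objective(K, A):
    return 0.5 * np.einsum("ij,jk,ik->i", A, K, A)


def _grid(lo, hi, step):
    n = max(int(np.ceil((hi - lo) / step)) + 1, 2)
    return np.linspace(lo, hi, n)


def _enumerate_box(K, upper, lo, hi, step):
    """Grid-search the first n-1 coordinates; the last closes the simplex."""
    n = K.shape[0]
    axes = [_grid(lo[i], hi[i], step) for i in range(n - 1)]
    mesh = np.meshgrid(*axes, indexing="ij")
    A = np.stack([m.ravel() for m in mesh], axis=1)
    last = 1.0 - A.sum(axis=1)
    ok = (last >= -1e-12) & (last <= upper + 1e-12)
    if not ok.any():
        return None, np.inf
    A = np.column_stack([A[ok], np.clip(last[ok], 0.0, upper)])
    vals = _eval_objective(K, A)
    best = int(np.argmin(vals))
    return A[best], float(vals[best])


def brute_force_objective(K, upper, step=1e-3):
    """Minimum of 1/2 a^T K a over {sum a = 1, 0 <= a_i <= upper} by grid search.

    Dimensions up to 3 are enumerated exhaustively at ``step``; larger
    ones use a coarse exhaustive grid refined around the incumbent down
    to ``step`` (sound for this convex objective).
    """
    n = K.shape[0]
    lo = np.zeros(n)
    hi = np.full(n, upper)
    if n <= 3:
        _, val = _enumerate_box(K, upper, lo, hi, step)
        return val
    cur = (hi - lo).max() / 20.0
    best_point, best_val = _enumerate_box(K, upper, lo, hi, cur)
    # refine one decade past the nominal step so discretization error is
    # negligible against the comparison tolerance
    target = step / 10.0
    while cur > target:
        cur = max(cur / 5.0, target)
        lo = np.clip(best_point - 3.0 * cur, 0.0, upper)
        hi = np.clip(best_point + 3.0 * cur, 0.0, upper)
        point, val = _enumerate_box(K, upper, lo, hi, cur)
        if val < best_val:
            best_point, best_val = point, val
    return best_val


def series_expm(M, terms=30):
    """Truncated series sum_{k<=terms} M^k / k!."""
    n = M.shape[0]
    out = np.eye(n)
    term = np.eye(n)
    for k in range(1, terms + 1):
        term = term @ M / k
        out = out + term
    return out
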