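"""Independent oracles used by the test suite.

These deliberately avoid the package's estimation path: the JMLE check uses
an exhaustive profile-likelihood grid search with iterative refinement, and
small-sample statistics are recomputed by direct enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# complete dichotomous matrices: margin enumeration (Gale-Ryser)
# ---------------------------------------------------------------------------

def gale_ryser_ok(rows: tuple[int, ...], cols: tuple[int, ...]) -> bool:
    """Existence of a 0-1 matrix with the given row/column sums."""
    if sum(rows) != sum(cols):
        return False
    r = sorted(rows, reverse=True)
    c = list(cols)
    for k in range(1, len(r) + 1):
        if sum(r[:k]) > sum(min(cj, k) for cj in c):
            return False
    return True


def realize_binary_matrix(rows: tuple[int, ...], cols: tuple[int, ...]) -> np.ndarray:
    """Gale-Ryser greedy construction of one matrix with the given margins."""
    n, k = len(rows), len(cols)
    x = np.zeros((n, k), dtype=int)
    remaining = np.array(cols, dtype=int)
    order = np.argsort(-np.array(rows))
    for i in order:
        take = np.argsort(-remaining, kind="stable")[: rows[i]]
        x[i, take] = 1
        remaining[take] -= 1
    assert (x.sum(axis=0) == np.array(cols)).all() and (x.sum(axis=1) == np.array(rows)).all()
    return x


def enumerate_estimable_margins(max_persons: int = 5, max_items: int = 4):
    """All distinct non-extreme (row multiset, column multiset) margin pairs.

    For complete dichotomous data the joint likelihood depends on the matrix
    only through its margins, so these cases cover every estimable matrix up
    to the given size.
    """
    for n_p in range(2, max_persons + 1):
        for n_i in range(2, max_items + 1):
            row_opts = itertools.combinations_with_replacement(range(1, n_i), n_p)
            for rows in row_opts:
                total = sum(rows)
                for cols in itertools.combinations_with_replacement(range(1, n_p), n_i):
                    if sum(cols) != total:
                        continue
                    if gale_ryser_ok(rows, cols):
                        yield rows, cols


# ---------------------------------------------------------------------------
# profile-likelihood grid-search maximizer for the dichotomous Rasch model
# ---------------------------------------------------------------------------

def _profile_loglik(b_grid: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Joint log-likelihood profiled over person parameters.

    ``b_grid`` is (G, k) candidate item difficulties (sum need not be 0; the
    likelihood only depends on differences once thetas are profiled).  For
    each candidate the optimal theta for a person with raw score r solves
    sum_i logistic(theta - b_i) = r, found by vectorized Newton iterations.
    """
    g, k = b_grid.shape
    uniq, counts = np.unique(rows, return_counts=True)
    ll = np.zeros(g)
    for r, cnt in zip(uniq, counts):
        theta = np.zeros(g)
        for _ in range(60):
            p = 1.0 / (1.0 + np.exp(-(theta[:, None] - b_grid)))
            f = p.sum(axis=1) - r
            fp = (p * (1 - p)).sum(axis=1)
            step = f / np.maximum(fp, 1e-12)
            theta -= np.clip(step, -2, 2)
            if np.max(np.abs(step)) < 1e-12:
                break
        p = 1.0 / (1.0 + np.exp(-(theta[:, None] - b_grid)))
        ll += cnt * (r * theta - np.log1p(np.exp(theta[:, None] - b_grid)).sum(axis=1))
    # the -sum_i s_i b_i term is added by the caller (depends on col sums)
    return ll


def grid_search_difficulties(
    x: np.ndarray, half_width: float = 4.0, coarse_step: float = 0.5, final_step: float = 0.002
) -> np.ndarray:
    """Exhaustive-grid joint-likelihood maximizer, centred difficulties.

    Grids the (k-1)-dimensional free item space (last difficulty fixed by the
    sum-to-zero constraint at the end; during the search the last item is
    pinned at 0 and the result recentred, which spans the same model space),
    profiles persons out exactly, then refines around the maximum until the
    grid step is below ``final_step``.
    """
    n, k = x.shape
    rows = x.sum(axis=1)
    cols = x.sum(axis=0)
    free = k - 1
    centers = np.zeros(free)
    width = half_width
    step = coarse_step
    while True:
        axes = [np.arange(c - width, c + width + step / 2, step) for c in centers]
        mesh = np.meshgrid(*axes, indexing="ij")
        cand = np.stack([m.ravel() for m in mesh], axis=1)  # (G, free)
        b_grid = np.concatenate([cand, np.zeros((cand.shape[0], 1))], axis=1)
        ll = _profile_loglik(b_grid, rows) - b_grid @ cols
        best = int(np.argmax(ll))
        centers = cand[best]
        if step <= final_step:
            b = b_grid[best]
            return b - b.mean()
        width = step
        step = step / 5.0


def strongly_connected_items(x: np.ndarray) -> bool:
    """Finite-MLE condition for complete dichotomous data.

    The item-comparison digraph (edge i -> j when some person answered i
    correctly and j incorrectly) must be strongly connected; otherwise the
    joint likelihood increases without bound as the disconnected item groups
    separate.
    """
    k = x.shape[1]
    adj = np.zeros((k, k), dtype=bool)
    for i, j in itertools.permutations(range(k), 2):
        adj[i, j] = bool(np.any((x[:, i] == 1) & (x[:, j] == 0)))
    reach = adj.copy()
    for _ in range(k):
        reach = reach | (reach @ reach)
    return bool(np.all(reach | np.eye(k, dtype=bool)))
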