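"""Brute-force grid-search reference minimizer for tiny instances.

Exhaustively enumerates internal-node dates on a regular grid, subject to
the same constraint system as :mod:`chronocorrect.correction` (topology,
relative constraints, fixed leaves), and returns the grid point with the
smallest objective value. Exponential in the number of internal nodes —
intended only as an independent cross-check of the optimizer on trees
with a handful of leaves.

Internal nodes are visited in breadth-first id order (parents before
children). All but the last two are enumerated scalar with parent-bound
and constraint pruning; the final two nodes are evaluated as one
vectorized candidate block per partial assignment, with every topological
and relative constraint re-checked on the block. No information from the
optimizer is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chronogram import Chronogram
from .constraints import ConstraintSet

__all__ = ["GridResult", "grid_minimize"]


@dataclass
class GridResult:
    dates: np.ndarray  # full date vector (same indexing as Chronogram.dates)
    phi: float
    step: float
    n_evaluated: int


def grid_minimize(
    T: Chronogram,
    R: ConstraintSet,
    objective: str,
    step: float | None = None,
    upper: float | None = None,
    eps_len: float | None = None,
) -> GridResult:
    """Minimize an objective by exhaustive grid enumeration.

    Parameters
    ----------
    step : float, optional
        Grid spacing; default ``0.01`` x root age.
    upper : float, optional
        Upper limit for any internal date; default ``4/3`` x root age
        (dates may legitimately exceed the input root age after
        correction).
    """
    root = max(T.root_age, 1e-12)
    if step is None:
        step = 0.01 * root
    if upper is None:
        upper = (4.0 / 3.0) * root
    grid = np.arange(0.0, upper + 0.5 * step, step)
    slack = 1e-9 * root  # float guard on inequality checks

    n = T.n
    m = n - 1  # number of internal nodes
    kids = T.children
    t = T.dates

    # all inequality pairs (older/parent id, younger/child id)
    ineq = [(T.parent[i], i) for i in range(2, T.num_nodes + 1)]
    ineq += [(i, j) for _, (i, j) in R]

    older_of: dict[int, list[int]] = {i: [] for i in T.internal_ids}
    younger_of: dict[int, list[int]] = {i: [] for i in T.internal_ids}
    for _, (i, j) in R:
        if not T.is_leaf(i):
            younger_of[i].append(j)
        if not T.is_leaf(j):
            older_of[j].append(i)

    dates = t.copy()
    best = {"phi": np.inf, "dates": None, "count": 0}

    def candidates(k: int, unassigned: frozenset[int] = frozenset()) -> np.ndarray:
        """Grid values for node k bounded by *assigned* nodes only.

        Bounds involving nodes in ``unassigned`` are skipped here; the
        final block check re-validates every inequality, so skipping a
        bound can only enlarge the candidate set, never lose the optimum.
        """
        hi = upper
        if k != T.ROOT and T.parent[k] not in unassigned:
            hi = float(dates[T.parent[k]])
        lo = max((float(t[c]) for c in kids[k] if T.is_leaf(c)), default=0.0)
        for other in younger_of[k]:
            if (T.is_leaf(other) or other < k) and other not in unassigned:
                lo = max(lo, float(dates[other]))
        for other in older_of[k]:
            if (T.is_leaf(other) or other < k) and other not in unassigned:
                hi = min(hi, float(dates[other]))
        return grid[(grid >= lo - slack) & (grid <= hi + slack)]

    def eval_block(block: np.ndarray) -> None:
        keep = np.ones(block.shape[0], dtype=bool)
        for p, c in ineq:
            keep &= block[:, p] - block[:, c] >= -slack
        block = block[keep]
        if block.shape[0] == 0:
            return
        phis = _batch_objective(T, block, objective, eps_len)
        best["count"] += block.shape[0]
        idx = int(np.argmin(phis))
        if phis[idx] < best["phi"]:
            best["phi"] = float(phis[idx])
            best["dates"] = block[idx].copy()

    def final_pair() -> None:
        """Vectorize the last one or two internal nodes."""
        if m == 1:
            c = candidates(1)
            block = np.tile(dates, (c.size, 1))
            block[:, 1] = c
            eval_block(block)
            return
        a, b = m - 1, m
        free = frozenset((a, b))
        ca, cb = candidates(a, free), candidates(b, free)
        if ca.size == 0 or cb.size == 0:
            return
        A, B = np.meshgrid(ca, cb, indexing="ij")
        block = np.tile(dates, (A.size, 1))
        block[:, a] = A.ravel()
        block[:, b] = B.ravel()
        eval_block(block)

    def recurse(k: int) -> None:
        if k >= max(m - 1, 1):
            final_pair()
            return
        for v in candidates(k):
            dates[k] = v
            recurse(k + 1)

    recurse(1)
    if best["dates"] is None:
        raise RuntimeError("no feasible grid point found; refine the grid")
    return GridResult(
        dates=best["dates"], phi=best["phi"], step=step, n_evaluated=best["count"]
    )


def _batch_objective(
    T: Chronogram, batch: np.ndarray, objective: str, eps_len: float | None
) -> np.ndarray:
    """Vectorized objective over a (k, num_nodes+1) matrix of date vectors.

    Mirrors :func:`chronocorrect.correction.objective_value` exactly (a
    spot check against it is part of the test suite); evaluated here in
    matrix form because the enumeration visits millions of grid points.
    """
    if eps_len is None:
        eps_len = 1e-8 * max(T.root_age, 1e-300)
    if objective == "sdd":
        ids = np.arange(1, T.n)
        t = T.dates[ids]
        return ((t - batch[:, ids]) ** 2 / np.maximum(t, eps_len)).sum(axis=1)
    ids = np.arange(2, T.num_nodes + 1)
    par = np.array([T.parent[i] for i in ids])
    b = T.dates[par] - T.dates[ids]
    bw = np.maximum(b, eps_len)
    bp = batch[:, par] - batch[:, ids]
    if objective == "sbd":
        return ((b - bp) ** 2 / bw).sum(axis=1)
    out = np.full(batch.shape[0], np.inf)
    ok = np.all(bp > 0, axis=1)
    out[ok] = (np.sqrt(bw) * np.log(bp[ok] / bw) ** 2).sum(axis=1)
    return out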