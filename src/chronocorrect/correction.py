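"""Minimal error correction of chronograms under relative time constraints.

Given an input chronogram ``T`` with node dates ``t`` and a consistent set
``R`` of relative time constraints, find corrected dates ``t'`` that
minimize a deviation objective subject to

* topology:  ``t'_parent(i) - t'_i >= eps_topo`` for every non-root ``i``
  (a strictly positive floor stands in for the strict inequality
  ``t'_parent(i) > t'_i``),
* relative constraints:  ``t'_i >= t'_j`` for every ``(i older j)`` in R,
* fixed leaves:  ``t'_i = t_i`` for every leaf,
* optionally, absolute per-node date bounds.

Three objectives are provided. With ``b_i = t_p(i) - t_i`` and
``b'_i = t'_p(i) - t'_i``:

SBD (squared branch-length deviation)
    ``sum_i (1 / b_i) * (b_i - b'_i)^2`` over non-root nodes. Convex
    quadratic; short branches are penalized more per unit deviation.

SLRB (squared log ratio of branch lengths)
    ``sum_i sqrt(b_i) * ln(b'_i / b_i)^2`` over non-root nodes.
    Non-convex; symmetric in halving vs doubling a branch. Natural log
    (the base only rescales the objective and cannot move the argmin).

SDD (squared date deviation)
    ``sum_i (1 / t_i) * (t_i - t'_i)^2`` over internal nodes only.
    Convex quadratic; older nodes may move more cheaply.

Degenerate inputs (zero-length branches, internal nodes dated 0) are
handled by flooring the *weights'* branch lengths/dates at ``eps_len``;
the deviation terms themselves use the raw input values.

The decision variables are the ``n - 1`` internal-node dates; leaf dates
enter as constants, which is an equivalent, smaller program than carrying
all ``2n - 1`` dates with equality constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize as opt
from scipy.optimize import LinearConstraint

from .chronogram import Chronogram
from .constraints import ConstraintSet, check_consistency

__all__ = [
    "OBJECTIVES",
    "CorrectionProblem",
    "CorrectionResult",
    "InfeasibleError",
    "objective_sbd",
    "objective_slrb",
    "objective_sdd",
    "objective_value",
    "error_correct",
]

OBJECTIVES = ("sbd", "slrb", "sdd")


class InfeasibleError(RuntimeError):
    """The constraint system admits no solution (absolute bounds conflict)."""


@dataclass
class CorrectionProblem:
    """One error-correction instance.

    Parameters
    ----------
    T : Chronogram
        Input chronogram.
    R : ConstraintSet
        Relative constraints, resolved against ``T`` and consistent.
    objective : str
        One of ``"sbd"``, ``"slrb"``, ``"sdd"``.
    eps_topo : float, optional
        Minimum parent-child date separation in the corrected tree.
        Defaults to ``1e-6`` x input root age. Must be > 0 for SLRB so
        corrected branch lengths stay in the log's domain.
    eps_len : float, optional
        Floor applied to input branch lengths (SBD/SLRB weights and
        ratios) and internal dates (SDD weights). Defaults to ``1e-8`` x
        root age.
    absolute_bounds : dict[int, tuple[float | None, float | None]]
        Optional per-node (lower, upper) date bounds; off by default.
    multistart : int
        Extra random SLRB starts beyond the warm start (default 1).
    seed : int
        Seed for the SLRB multistart jitter.
    """

    T: Chronogram
    R: ConstraintSet
    objective: str = "slrb"
    eps_topo: float | None = None
    eps_len: float | None = None
    absolute_bounds: dict[int, tuple[float | None, float | None]] | None = None
    multistart: int = 1
    seed: int = 0
    gtol: float = 1e-8
    xtol: float = 1e-10

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise ValueError(f"objective must be one of {OBJECTIVES}")
        root_age = max(self.T.root_age, 1e-300)
        if self.eps_topo is None:
            self.eps_topo = 1e-6 * root_age
        if self.eps_len is None:
            self.eps_len = 1e-8 * root_age
        if self.eps_topo <= 0:
            raise ValueError("eps_topo must be > 0")
        if self.eps_len <= 0:
            raise ValueError("eps_len must be > 0")


@dataclass
class CorrectionResult:
    """Corrected dates plus solver diagnostics."""

    dates: np.ndarray  # t'_i for all nodes, same indexing as Chronogram.dates
    objective: str
    phi: float
    status: str
    n_iter: int
    constraint_residuals: dict[str, float]  # t'_older - t'_younger per constraint
    edge_length_changes: dict[int, float]  # b'_i - b_i per non-root node
    message: str = ""
    starts_tried: int = 1

    def corrected(self, T: Chronogram) -> Chronogram:
        return T.copy(dates=self.dates)


# ---------------------------------------------------------------------------
# objective evaluation (full date assignments; used for reporting and tests)


def _branch_arrays(T: Chronogram, t_prime: np.ndarray, eps_len: float):
    ids = np.arange(2, T.num_nodes + 1)
    par = np.array([T.parent[i] for i in ids])
    b = T.dates[par] - T.dates[ids]
    bp = t_prime[par] - t_prime[ids]
    return b, bp, np.maximum(b, eps_len)


def objective_sbd(
    T: Chronogram, t_prime: np.ndarray, eps_len: float | None = None
) -> float:
    """Weighted sum of squared branch-length deviations."""
    if eps_len is None:
        eps_len = 1e-8 * max(T.root_age, 1e-300)
    b, bp, bw = _branch_arrays(T, t_prime, eps_len)
    return float(np.sum((b - bp) ** 2 / bw))


def objective_slrb(
    T: Chronogram, t_prime: np.ndarray, eps_len: float | None = None
) -> float:
    """Weighted sum of squared log branch-length ratios (natural log)."""
    if eps_len is None:
        eps_len = 1e-8 * max(T.root_age, 1e-300)
    b, bp, bw = _branch_arrays(T, t_prime, eps_len)
    if np.any(bp <= 0):
        raise ValueError("SLRB requires strictly positive corrected branch lengths")
    return float(np.sum(np.sqrt(bw) * np.log(bp / bw) ** 2))


def objective_sdd(
    T: Chronogram, t_prime: np.ndarray, eps_len: float | None = None
) -> float:
    """Weighted sum of squared internal-node date deviations."""
    if eps_len is None:
        eps_len = 1e-8 * max(T.root_age, 1e-300)
    ids = np.arange(1, T.n)
    t = T.dates[ids]
    tw = np.maximum(t, eps_len)
    return float(np.sum((t - t_prime[ids]) ** 2 / tw))


def objective_value(
    T: Chronogram, t_prime: np.ndarray, objective: str, eps_len: float | None = None
) -> float:
    fn = {"sbd": objective_sbd, "slrb": objective_slrb, "sdd": objective_sdd}[objective]
    return fn(T, t_prime, eps_len)


# ---------------------------------------------------------------------------
# the constrained program over internal-node dates


class _Program:
    """Reduced program in x = internal-node dates (ids 1..n-1 -> x[0..n-2]).

    Internally all dates are rescaled to unit root age, which conditions
    the three objectives uniformly and makes solver tolerances scale-free;
    :meth:`full_dates` maps solutions back to the input scale. The
    objective value in the original units is recomputed from the final
    dates, not taken from the scaled solve.
    """

    def __init__(self, prob: CorrectionProblem):
        T = prob.T
        self.T = T
        self.prob = prob
        self.nvar = T.n - 1
        self.scale = max(T.root_age, prob.eps_len)
        self.t = T.dates / self.scale
        self.eps_topo = prob.eps_topo / self.scale
        self.eps_len = prob.eps_len / self.scale

        # edges: rows (child id, parent id); coefficients of b' = t'_par - t'_child
        ids = np.arange(2, T.num_nodes + 1)
        par = np.array([T.parent[i] for i in ids])
        self.edge_child = ids
        self.edge_parent = par
        self.b_raw = self.t[par] - self.t[ids]
        self.b_w = np.maximum(self.b_raw, self.eps_len)

        # b'_e = A_e x + c_e  (leaf dates folded into the constant)
        ne = len(ids)
        A = np.zeros((ne, self.nvar))
        c = np.zeros(ne)
        for row, (ch, pa) in enumerate(zip(ids, par)):
            A[row, pa - 1] += 1.0  # parents are always internal
            if T.is_leaf(ch):
                c[row] -= self.t[ch]
            else:
                A[row, ch - 1] -= 1.0
        self.A_edge = A
        self.c_edge = c

        # linear inequality constraints G x >= h
        G_rows = [A]  # topology: b'_e >= eps_topo
        h_rows = [np.full(ne, self.eps_topo) - c]
        self.n_topo_rows = ne
        for _, (i, j) in prob.R:
            g = np.zeros(self.nvar)
            h = 0.0
            if T.is_leaf(i):
                h -= self.t[i]
            else:
                g[i - 1] += 1.0
            if T.is_leaf(j):
                h += self.t[j]
            else:
                g[j - 1] -= 1.0
            G_rows.append(g[None, :])
            h_rows.append(np.array([h]))
        self.G = np.vstack(G_rows)
        self.h = np.concatenate(h_rows)

        lb = np.full(self.nvar, -np.inf)
        ub = np.full(self.nvar, np.inf)
        for node, (lo, hi) in (prob.absolute_bounds or {}).items():
            if T.is_leaf(node):
                d = self.t[node]
                if (lo is not None and d < lo) or (hi is not None and d > hi):
                    raise InfeasibleError(
                        f"absolute bound on fixed leaf {node} excludes its date"
                    )
                continue
            if lo is not None:
                lb[node - 1] = lo / self.scale
            if hi is not None:
                ub[node - 1] = hi / self.scale
        self.lb, self.ub = lb, ub
        self.has_bounds = np.any(np.isfinite(lb)) or np.any(np.isfinite(ub))

        self.x0 = self.t[1 : T.n].copy()

    # -- embeddings --------------------------------------------------------

    def full_dates(self, x: np.ndarray) -> np.ndarray:
        """Embed internal dates and map back to the input time scale."""
        out = self.T.dates.copy()
        out[1 : self.T.n] = x * self.scale
        return out

    def edge_lengths(self, x: np.ndarray) -> np.ndarray:
        return self.A_edge @ x + self.c_edge

    def feasible(self, x: np.ndarray, tol: float) -> bool:
        ok = np.all(self.G @ x >= self.h - tol)
        if self.has_bounds:
            ok = ok and np.all(x >= self.lb - tol) and np.all(x <= self.ub + tol)
        return bool(ok)

    def input_satisfies_all(self) -> bool:
        """True iff the input dates satisfy every constraint *non-strictly*.

        Topological separation is only required to be >= 0 here: an input
        with zero violations is its own optimum (the objectives vanish at
        the input and are nonnegative), so it is returned unchanged rather
        than pushed apart by ``eps_topo``.
        """
        h0 = self.h.copy()
        h0[: self.n_topo_rows] -= self.eps_topo  # relax topo rows to >= 0
        ok = np.all(self.G @ self.x0 >= h0)
        if self.has_bounds:
            ok = ok and np.all(self.x0 >= self.lb) and np.all(self.x0 <= self.ub)
        return bool(ok)

    # -- SBD: 0.5 x'Px + q'x + r -----------------------------------------

    def sbd_quadratic(self):
        W = 1.0 / self.b_w
        # f = sum_e W_e (b_e - (A_e x + c_e))^2
        d = self.b_raw - self.c_edge
        P = 2.0 * (self.A_edge.T * W) @ self.A_edge
        q = -2.0 * self.A_edge.T @ (W * d)
        r = float(np.sum(W * d**2))
        return P, q, r

    def sdd_quadratic(self):
        ids = np.arange(1, self.T.n)
        t = self.t[ids]
        W = 1.0 / np.maximum(t, self.eps_len)
        P = np.diag(2.0 * W)
        q = -2.0 * W * t
        r = float(np.sum(W * t**2))
        return P, q, r

    # -- SLRB --------------------------------------------------------------

    def slrb_value_grad_hess(self, x: np.ndarray):
        # Interior-point iterates may transiently leave the s > 0 region,
        # so below s_min (< eps_topo, outside the feasible set) the log is
        # replaced by its second-order Taylor expansion around s_min: the
        # objective stays finite and its gradient keeps pushing back in.
        w = np.sqrt(self.b_w)
        s = self.edge_lengths(x)
        s_min = 0.5 * self.eps_topo
        inside = s >= s_min
        sc = np.where(inside, s, s_min)
        d = s - sc  # nonzero only outside
        l = np.log(sc / self.b_w) + d / s_min - d**2 / (2.0 * s_min**2)
        lp = np.where(inside, 1.0 / sc, 1.0 / s_min - d / s_min**2)
        lpp = np.where(inside, -1.0 / sc**2, -1.0 / s_min**2)
        f = float(np.sum(w * l**2))
        g = self.A_edge.T @ (2.0 * w * l * lp)
        hcoef = 2.0 * w * (lp**2 + l * lpp)
        H = (self.A_edge.T * hcoef) @ self.A_edge
        return f, g, H


def _solve_quadratic(pg: _Program, P, q, r, prob: CorrectionProblem):
    def fun(x):
        return 0.5 * x @ P @ x + q @ x + r

    def jac(x):
        return P @ x + q

    cons = [LinearConstraint(pg.G, pg.h, np.inf)]
    bounds = opt.Bounds(pg.lb, pg.ub) if pg.has_bounds else None
    res = opt.minimize(
        fun,
        pg.x0,
        jac=jac,
        hess=lambda x: P,
        method="trust-constr",
        constraints=cons,
        bounds=bounds,
        options={"gtol": prob.gtol, "xtol": prob.xtol, "maxiter": 2000},
    )
    return res


def _slrb_starts(pg: _Program, warm: np.ndarray, prob: CorrectionProblem):
    """Warm start plus seeded multiplicative jitters of branch durations.

    Jittered starts are rebuilt bottom-up from leaf dates so they keep
    every corrected branch length strictly positive (the log's domain);
    relative-constraint residuals at a start are left to the solver.
    """
    yield warm
    rng = np.random.default_rng(prob.seed)
    T = pg.T
    kids = T.children
    order = sorted(T.internal_ids, reverse=True)  # children before parents (BFS ids)
    warm_full = pg.t.copy()  # scaled frame, same frame as the solve
    warm_full[1 : T.n] = warm
    for _ in range(prob.multistart):
        dates = warm_full.copy()
        for i in order:
            cmax_new = max(dates[c] for c in kids[i])
            cmax_old = max(warm_full[c] for c in kids[i])
            inc = warm_full[i] - cmax_old
            dates[i] = cmax_new + max(inc, pg.eps_topo) * rng.lognormal(0.0, 0.3)
        yield dates[1 : T.n].copy()


def _solve_slrb(pg: _Program, prob: CorrectionProblem):
    # feasible warm start from the SBD solution (a convex surrogate)
    P, q, r = pg.sbd_quadratic()
    warm_res = _solve_quadratic(pg, P, q, r, prob)
    warm = np.asarray(warm_res.x, dtype=float)

    cons = [LinearConstraint(pg.G, pg.h, np.inf)]
    bounds = opt.Bounds(pg.lb, pg.ub) if pg.has_bounds else None
    tol = _feas_tol(pg)
    best, best_key = None, None
    tried = 0
    for x0 in _slrb_starts(pg, warm, prob):
        tried += 1
        res = opt.minimize(
            lambda x: pg.slrb_value_grad_hess(x)[0],
            x0,
            jac=lambda x: pg.slrb_value_grad_hess(x)[1],
            hess=lambda x: pg.slrb_value_grad_hess(x)[2],
            method="trust-constr",
            constraints=cons,
            bounds=bounds,
            options={"gtol": prob.gtol, "xtol": prob.xtol, "maxiter": 3000},
        )
        key = (not pg.feasible(res.x, tol), res.fun)  # feasible first, then value
        if best is None or key < best_key:
            best, best_key = res, key
    return best, tried


def _feas_tol(pg: _Program) -> float:
    # the program is already scaled to unit root age
    return 1e-8


def error_correct(problem: CorrectionProblem) -> CorrectionResult:
    """Solve one error-correction instance.

    SBD and SDD are convex quadratic programs solved to global optimality;
    SLRB is non-convex and the best of the (seeded) multistart local
    solves, warm-started from the SBD optimum, is returned.

    If the input already satisfies every constraint it is returned
    unchanged with objective value 0 (the objectives are nonnegative and
    vanish only at the input).

    Raises
    ------
    InfeasibleError
        No dating satisfies the system. With the default options this can
        only happen when absolute bounds are enabled; relative constraints
        alone are always satisfiable once they pass the consistency check.
    """
    prob = problem
    rep = check_consistency(prob.T, prob.R)
    if not rep:
        raise InfeasibleError(f"temporally inconsistent constraints: cycle {rep.cycle}")

    pg = _Program(prob)
    tol = _feas_tol(pg)
    starts = 1

    if pg.input_satisfies_all():
        x, phi, status, nit, msg = pg.x0, 0.0, "optimal_identity", 0, "input feasible"
    else:
        if prob.objective == "sbd":
            res = _solve_quadratic(pg, *pg.sbd_quadratic(), prob)
        elif prob.objective == "sdd":
            res = _solve_quadratic(pg, *pg.sdd_quadratic(), prob)
        else:
            res, starts = _solve_slrb(pg, prob)
        x = np.asarray(res.x, dtype=float)
        if not pg.feasible(x, tol):
            if pg.has_bounds:
                raise InfeasibleError(
                    "solver could not satisfy the constraint system; absolute "
                    f"bounds likely conflict with relative constraints "
                    f"(max residual {np.max(pg.h - pg.G @ x):.3g})"
                )
            raise RuntimeError(
                f"solver returned an infeasible point (status {res.status}): "
                f"{res.message}"
            )
        status = "optimal" if res.status in (1, 2) else f"status_{res.status}"
        nit, msg = int(res.nit), str(res.message)
        # objective value in the input units (the solve ran at unit root age)
        phi = objective_value(prob.T, pg.full_dates(x), prob.objective, prob.eps_len)

    dates = pg.full_dates(x)
    T = prob.T
    residuals = {
        cid: float(dates[i] - dates[j]) for cid, (i, j) in prob.R
    }
    changes = {
        i: float((dates[T.parent[i]] - dates[i]) - (T.dates[T.parent[i]] - T.dates[i]))
        for i in range(2, T.num_nodes + 1)
    }
    return CorrectionResult(
        dates=dates,
        objective=prob.objective,
        phi=max(phi, 0.0),
        status=status,
        n_iter=nit,
        constraint_residuals=residuals,
        edge_length_changes=changes,
        message=msg,
        starts_tried=starts,
    )
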