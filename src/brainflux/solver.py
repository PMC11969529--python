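"""Low-level LP/QP solution layer.

Linear programs (FBA, FVA, task feasibility) are solved with the HiGHS
backend of :func:`scipy.optimize.linprog`.  Quadratic programs (MOMA and the
second-stage squared-flux minimization) are solved with OSQP when it is
importable, and otherwise with an augmented-Lagrangian loop around
:func:`scipy.optimize.lsq_linear`.  Either way the returned point is
*polished*: with the active bound set fixed, the equality-constrained
least-squares KKT system is re-solved exactly, so steady-state residuals and
coupling constraints hold to near machine precision.

All solvers are configured deterministically (no randomized crossover or
time-based seeding), so repeated runs give identical results on a platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog, lsq_linear

__all__ = ["LPResult", "QPResult", "solve_lp", "solve_qp"]

try:  # OSQP ships with the cobra/optlang stack; optional here
    import osqp  # type: ignore

    _HAVE_OSQP = True
except ImportError:  # pragma: no cover - exercised only without osqp
    _HAVE_OSQP = False

#: feasibility tolerance requested from the LP solver
LP_TOL = 1e-9
#: residual targets for the QP path
QP_EQ_TOL = 1e-9


@dataclass
class LPResult:
    status: str  # optimal | infeasible | unbounded | error
    x: Optional[np.ndarray]
    objective: Optional[float]
    message: str = ""


@dataclass
class QPResult:
    status: str
    x: Optional[np.ndarray]
    objective: Optional[float]  # value of ||x - target||^2
    message: str = ""


_LP_STATUS = {0: "optimal", 1: "error", 2: "infeasible", 3: "unbounded", 4: "error"}


def solve_lp(
    c: np.ndarray,
    A_eq: sp.spmatrix,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    sense: str = "min",
) -> LPResult:
    """Solve min/max c.x s.t. A_eq x = b_eq, lb <= x <= ub."""
    sign = 1.0 if sense == "min" else -1.0
    res = linprog(
        c=sign * np.asarray(c, dtype=float),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": LP_TOL, "dual_feasibility_tolerance": LP_TOL},
    )
    status = _LP_STATUS.get(res.status, "error")
    if status != "optimal":
        return LPResult(status=status, x=None, objective=None, message=res.message)
    return LPResult(status="optimal", x=res.x, objective=float(sign * res.fun), message="")


def _polish_qp(
    A_eq: sp.spmatrix,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    target: np.ndarray,
    x: np.ndarray,
    active_tol: float = 1e-7,
) -> Optional[np.ndarray]:
    """Exact KKT re-solve of min ||x-target||^2 with the active set fixed.

    Variables within ``active_tol`` of a bound are pinned there; the
    remaining equality-constrained projection has the closed form solved via
    a least-norm linear system.  Returns None if the polished point violates
    a bound or an equality beyond tolerance (caller keeps the raw solution).
    """
    n = len(x)
    A = sp.csr_matrix(A_eq)
    at_lb = x - lb <= active_tol
    at_ub = ub - x <= active_tol
    fixed = at_lb | at_ub
    xf = np.where(at_ub, ub, lb)
    free = ~fixed
    if not free.any():
        resid = A @ xf - b_eq
        return xf if (np.abs(resid).max() if resid.size else 0.0) <= 1e-9 else None
    Af = A[:, free].toarray() if A.shape[0] else np.zeros((0, int(free.sum())))
    rhs = b_eq - (A[:, fixed] @ xf[fixed] if fixed.any() else 0.0)
    t = target[free]
    # projection of t onto {Af z = rhs}: z = t - Af^T lam, Af Af^T lam = Af t - rhs
    if Af.shape[0]:
        G = Af @ Af.T
        try:
            lam = np.linalg.lstsq(G, Af @ t - rhs, rcond=None)[0]
        except np.linalg.LinAlgError:  # pragma: no cover
            return None
        z = t - Af.T @ lam
    else:
        z = t
    out = xf.copy()
    out[free] = z
    if (out < lb - 1e-9).any() or (out > ub + 1e-9).any():
        return None
    out = np.clip(out, lb, ub)
    resid = A @ out - b_eq
    if resid.size and np.abs(resid).max() > 1e-8:
        return None
    return out


def _solve_qp_osqp(A_eq, b_eq, lb, ub, target):
    n = len(target)
    P = sp.eye(n, format="csc") * 2.0
    q = -2.0 * target
    A = sp.vstack([sp.csc_matrix(A_eq), sp.eye(n, format="csc")], format="csc")
    l = np.concatenate([b_eq, lb])
    u = np.concatenate([b_eq, ub])
    prob = osqp.OSQP()
    opts = dict(
        verbose=False,
        eps_abs=1e-10,
        eps_rel=1e-10,
        max_iter=200000,
        scaled_termination=False,
    )
    try:
        prob.setup(P, q, A, l, u, polishing=True, **opts)
    except TypeError:  # older osqp releases use "polish"
        prob.setup(P, q, A, l, u, polish=True, **opts)
    try:
        res = prob.solve(raise_error=False)
    except TypeError:  # pragma: no cover - older osqp solve() signature
        res = prob.solve()
    status = res.info.status
    if "solved" not in status:
        if "infeasible" in status:
            return QPResult(status="infeasible", x=None, objective=None, message=status)
        return QPResult(status="error", x=None, objective=None, message=status)
    x = np.asarray(res.x, dtype=float)
    return QPResult(status="optimal", x=x, objective=None, message=status)


def _solve_qp_auglag(A_eq, b_eq, lb, ub, target, max_outer=60):
    """Fallback: augmented-Lagrangian bounded least squares."""
    A = sp.csr_matrix(A_eq)
    m, n = A.shape
    if m == 0:
        x = np.clip(target, lb, ub)
        return QPResult(status="optimal", x=x, objective=None)
    rho = 1e4
    u = np.zeros(m)
    x = np.clip(target, lb, ub)
    I = sp.eye(n, format="csr")
    for _ in range(max_outer):
        M = sp.vstack([I, np.sqrt(rho) * A], format="csr")
        rhs = np.concatenate([target, np.sqrt(rho) * (b_eq - u)])
        res = lsq_linear(M, rhs, bounds=(lb, ub), method="trf", tol=1e-14, max_iter=300)
        x = res.x
        r = A @ x - b_eq
        if np.abs(r).max() <= QP_EQ_TOL:
            return QPResult(status="optimal", x=x, objective=None)
        u = u + r
        rho = min(rho * 5.0, 1e12)
    if np.abs(A @ x - b_eq).max() <= 1e-6:
        return QPResult(status="optimal", x=x, objective=None)
    return QPResult(status="error", x=None, objective=None, message="aug-lag did not converge")


def solve_qp(
    A_eq: sp.spmatrix,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    target: np.ndarray,
) -> QPResult:
    """Minimize ||x - target||^2 s.t. A_eq x = b_eq, lb <= x <= ub."""
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    target = np.asarray(target, dtype=float)
    b_eq = np.asarray(b_eq, dtype=float)
    if _HAVE_OSQP:
        res = _solve_qp_osqp(A_eq, b_eq, lb, ub, target)
        if res.status == "error":  # pragma: no cover - rare numerical fallback
            res = _solve_qp_auglag(A_eq, b_eq, lb, ub, target)
    else:  # pragma: no cover - exercised only without osqp
        res = _solve_qp_auglag(A_eq, b_eq, lb, ub, target)
    if res.status != "optimal":
        return res
    x = res.x
    polished = _polish_qp(A_eq, b_eq, lb, ub, target, x)
    if polished is not None and np.sum((polished - target) ** 2) <= np.sum((x - target) ** 2) + 1e-9:
        x = polished
    return QPResult(status="optimal", x=x, objective=float(np.sum((x - target) ** 2)))
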