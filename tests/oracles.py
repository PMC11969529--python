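"""Independent brute-force oracles used to cross-check the solvers.

These deliberately avoid the code paths they validate: the LP oracle
enumerates basic feasible solutions directly, the projection oracle uses the
closed-form least-squares projection, and the hypergeometric oracle sums
exact binomial-coefficient terms.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional, Tuple

import numpy as np


def vertex_enumeration_lp(
    c: np.ndarray,
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    sense: str = "max",
    tol: float = 1e-9,
) -> Optional[float]:
    """Optimum of max/min c.v s.t. S v = 0, lb <= v <= ub by enumerating
    basic feasible solutions (all bounds finite; None if infeasible)."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    m, n = S.shape
    r = np.linalg.matrix_rank(S) if S.size else 0
    best = None

    def consider(v: np.ndarray) -> None:
        nonlocal best
        if np.any(v < lb - 1e-8) or np.any(v > ub + 1e-8):
            return
        if S.size and np.abs(S @ v).max() > 1e-7:
            return
        obj = float(c @ v)
        if best is None or (sense == "max" and obj > best) or (sense == "min" and obj < best):
            best = obj

    free_count = r
    for free in itertools.combinations(range(n), free_count):
        nonbasic = [j for j in range(n) if j not in free]
        A_f = S[:, list(free)] if free else np.zeros((m, 0))
        for pattern in itertools.product((0, 1), repeat=len(nonbasic)):
            v = np.zeros(n)
            for j, at_ub in zip(nonbasic, pattern):
                v[j] = ub[j] if at_ub else lb[j]
            rhs = -S[:, nonbasic] @ v[nonbasic] if nonbasic else np.zeros(m)
            if free:
                sol, *_ = np.linalg.lstsq(A_f, rhs, rcond=None)
                v[list(free)] = sol
            consider(v)
    return best


def projection_qp(
    S: np.ndarray,
    target: np.ndarray,
    fixed: Optional[dict] = None,
) -> np.ndarray:
    """Closed-form min ||v - target||^2 s.t. S v = 0 (+ v_j = value rows),
    ignoring inequality bounds — valid when the true solution is interior."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    m, n = S.shape
    rows = [S]
    rhs = [np.zeros(m)]
    if fixed:
        for j, value in fixed.items():
            e = np.zeros(n)
            e[j] = 1.0
            rows.append(e[None, :])
            rhs.append(np.array([value]))
    A = np.vstack(rows)
    b = np.concatenate(rhs)
    # projection onto {A v = b}: v = t - A^T (A A^T)^+ (A t - b)
    lam = np.linalg.pinv(A @ A.T) @ (A @ target - b)
    return target - A.T @ lam


def hypergeom_upper_tail(M: int, K: int, n: int, obs: int) -> float:
    """P(X >= obs), X = |random n-subset of M intersect fixed K-set|, exact."""
    if obs <= 0:
        return 1.0
    total = math.comb(M, n)
    acc = 0
    for j in range(obs, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(M - K, n - j)
    return acc / total


def hypergeom_by_enumeration(M: int, K: int, n: int, obs: int) -> float:
    """Same tail probability by brute-force enumeration of all n-subsets of
    a universe of size M (only sensible for M <= 15)."""
    universe = list(range(M))
    special = set(range(K))
    hits = 0
    total = 0
    for subset in itertools.combinations(universe, n):
        total += 1
        if len(special.intersection(subset)) >= obs:
            hits += 1
    return hits / total if total else 1.0
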