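"""Exact discrete optimal transport (transportation simplex).

Solves min <P, C> over plans P >= 0 with row sums a and column sums b,
the linear program behind the earth mover's distance.  Distributions in
this package are small (a handful of distinct terms per organ-system
label), so an exact solver is both feasible and preferable to entropic
approximation: its optima can be checked against an independent generic
LP formulation to machine precision.

The implementation is the classic MODI / u-v method: a north-west-corner
basic feasible solution, potentials solved along the basis tree, and
cycle pivots until no reduced cost is negative.
"""

from __future__ import annotations

import numpy as np

from .errors import TransportError

_TOL = 1e-12


def _northwest_corner(a: np.ndarray, b: np.ndarray) -> tuple[dict[tuple[int, int], float], list[tuple[int, int]]]:
    """Initial basic feasible solution with exactly m+n-1 basic cells."""
    m, n = len(a), len(b)
    rem_a = a.astype(float).copy()
    rem_b = b.astype(float).copy()
    flow: dict[tuple[int, int], float] = {}
    basis: list[tuple[int, int]] = []
    i = j = 0
    while True:
        t = min(rem_a[i], rem_b[j])
        flow[(i, j)] = t
        basis.append((i, j))
        rem_a[i] -= t
        rem_b[j] -= t
        if i == m - 1 and j == n - 1:
            break
        if rem_a[i] <= _TOL and i < m - 1:
            i += 1
        else:
            j += 1
    return flow, basis


def _potentials(cost: np.ndarray, basis: list[tuple[int, int]], m: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Solve u_i + v_j = C_ij on the basis tree (u_0 = 0)."""
    adj: list[list[tuple[int, tuple[int, int]]]] = [[] for _ in range(m + n)]
    for (i, j) in basis:
        adj[i].append((m + j, (i, j)))
        adj[m + j].append((i, (i, j)))
    u = np.full(m, np.nan)
    v = np.full(n, np.nan)
    u[0] = 0.0
    stack = [0]
    seen = [False] * (m + n)
    seen[0] = True
    while stack:
        node = stack.pop()
        for nxt, (ci, cj) in adj[node]:
            if seen[nxt]:
                continue
            if nxt >= m:
                v[nxt - m] = cost[ci, cj] - u[ci]
            else:
                u[nxt] = cost[ci, cj] - v[cj]
            seen[nxt] = True
            stack.append(nxt)
    if np.any(np.isnan(u)) or np.any(np.isnan(v)):
        raise TransportError("basis does not span all rows and columns")
    return u, v


def _find_cycle(basis: list[tuple[int, int]], enter: tuple[int, int], m: int, n: int) -> list[tuple[int, int]]:
    """Cells of the unique cycle created by adding ``enter`` to the basis tree.

    Returned in cyclic order starting with the entering cell, so signs
    alternate with position (+ at even, - at odd indices).
    """
    adj: dict[int, list[tuple[int, tuple[int, int]]]] = {}
    for (i, j) in basis:
        adj.setdefault(i, []).append((m + j, (i, j)))
        adj.setdefault(m + j, []).append((i, (i, j)))
    start, goal = enter[0], m + enter[1]
    parent: dict[int, tuple[int, tuple[int, int]]] = {start: (-1, (-1, -1))}
    stack = [start]
    while stack:
        node = stack.pop()
        if node == goal:
            break
        for nxt, cell in adj.get(node, []):
            if nxt not in parent:
                parent[nxt] = (node, cell)
                stack.append(nxt)
    if goal not in parent:
        raise TransportError("basis tree disconnected")
    path_cells: list[tuple[int, int]] = []
    node = goal
    while node != start:
        prev, cell = parent[node]
        path_cells.append(cell)
        node = prev
    # enter connects row enter[0] (=start) and col goal; path runs goal -> start,
    # so reverse it to walk start -> goal and close the cycle at the entering cell.
    return [enter] + list(reversed(path_cells))


def solve_transport(
    cost: np.ndarray, a: np.ndarray, b: np.ndarray, max_iter: int | None = None
) -> tuple[float, np.ndarray]:
    """Minimize sum(P * cost) subject to row/column marginals (a, b).

    Both marginals must be non-negative and sum to the same total
    (normalized internally to 1).  Returns (optimal value, optimal plan).
    """
    cost = np.asarray(cost, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m, n = cost.shape
    if len(a) != m or len(b) != n:
        raise ValueError("marginal lengths do not match the cost matrix")
    if np.any(a < 0) or np.any(b < 0) or a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("marginals must be non-negative with positive mass")
    if abs(a.sum() - b.sum()) > 1e-6 * max(a.sum(), b.sum()):
        raise ValueError("unbalanced transport problem")
    a = a / a.sum()
    b = b / b.sum()

    if m == 1:
        plan = b[None, :].copy()
        return float(cost[0] @ b), plan
    if n == 1:
        plan = a[:, None].copy()
        return float(a @ cost[:, 0]), plan

    flow, basis = _northwest_corner(a, b)
    if max_iter is None:
        max_iter = 50 * (m + n) ** 2
    for _ in range(max_iter):
        u, v = _potentials(cost, basis, m, n)
        reduced = cost - u[:, None] - v[None, :]
        for (i, j) in basis:
            reduced[i, j] = 0.0
        enter = np.unravel_index(np.argmin(reduced), reduced.shape)
        if reduced[enter] >= -1e-11:
            break
        enter = (int(enter[0]), int(enter[1]))
        cycle = _find_cycle(basis, enter, m, n)
        minus = cycle[1::2]
        theta = min(flow[c] for c in minus)
        leave = min((c for c in minus if flow[c] <= theta + _TOL), key=lambda c: flow[c])
        for pos, cell in enumerate(cycle):
            if pos % 2 == 0:
                flow[cell] = flow.get(cell, 0.0) + theta
            else:
                flow[cell] -= theta
        flow.pop(leave, None)
        basis.remove(leave)
        basis.append(enter)
    else:
        raise TransportError("transportation simplex did not converge")

    plan = np.zeros((m, n))
    for (i, j), f in flow.items():
        plan[i, j] = max(f, 0.0)
    value = float((plan * cost).sum())
    return value, plan
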