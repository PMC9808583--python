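"""Independent reference implementations used to cross-check the package.

Kept deliberately naive and decoupled from the implementation paths they
verify: a generic linear program for optimal transport, exhaustive span
matching for the gazetteer, and an O(n^3) Lance-Williams Ward linkage.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def lp_transport_value(cost: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Optimal transport value via a generic LP (HiGHS) on the flattened plan."""
    m, n = cost.shape
    A_eq = np.zeros((m + n, m * n))
    for i in range(m):
        A_eq[i, i * n : (i + 1) * n] = 1.0
    for j in range(n):
        A_eq[m + j, j::n] = 1.0
    res = linprog(
        cost.ravel(),
        A_eq=A_eq,
        b_eq=np.concatenate([a, b]),
        bounds=(0, None),
        method="highs",
    )
    assert res.status == 0, res.message
    return float(res.fun)


def brute_force_spans(folded_text: str, folded_surfaces: dict[str, str]) -> list[tuple[int, int, str]]:
    """All word-boundary matches, reduced to the maximal non-overlapping set
    preferring longer spans (ties: leftmost)."""

    def word(c: str) -> bool:
        return c.isalnum() or c == "_"

    matches = []
    for fsurf, canonical in folded_surfaces.items():
        for start in range(len(folded_text) - len(fsurf) + 1):
            if folded_text[start : start + len(fsurf)] != fsurf:
                continue
            end = start + len(fsurf)
            if start > 0 and word(folded_text[start - 1]) and word(fsurf[0]):
                continue
            if end < len(folded_text) and word(folded_text[end - 1]) and word(folded_text[end]):
                continue
            matches.append((start, end, canonical))
    matches.sort(key=lambda t: (-(t[1] - t[0]), t[0], t[2]))
    kept: list[tuple[int, int, str]] = []
    for s, e, c in matches:
        if all(e <= s2 or s >= e2 for s2, e2, _ in kept):
            kept.append((s, e, c))
    return sorted(kept)


def naive_ward_heights(D: np.ndarray) -> np.ndarray:
    """Merge heights of Ward linkage by direct Lance-Williams recursion.

    At each step the closest active pair (lowest indices on ties) is
    merged; distances to the merged cluster follow

        d(u, v)^2 = [ (|v|+|s|) d(v,s)^2 + (|v|+|t|) d(v,t)^2
                      - |v| d(s,t)^2 ] / (|s|+|t|+|v|)
    """
    D = D.astype(float).copy()
    n = D.shape[0]
    sizes = {i: 1 for i in range(n)}
    dist = {frozenset((i, j)): D[i, j] for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    heights = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                key = frozenset((active[ai], active[aj]))
                d = dist[key]
                if best is None or d < best[0]:
                    best = (d, active[ai], active[aj])
        d, s, t = best
        heights.append(d)
        for v in active:
            if v in (s, t):
                continue
            ns, nt, nv = sizes[s], sizes[t], sizes[v]
            d2 = (
                (nv + ns) * dist[frozenset((v, s))] ** 2
                + (nv + nt) * dist[frozenset((v, t))] ** 2
                - nv * d**2
            ) / (ns + nt + nv)
            dist[frozenset((v, next_id))] = np.sqrt(max(d2, 0.0))
        sizes[next_id] = sizes[s] + sizes[t]
        active = [v for v in active if v not in (s, t)] + [next_id]
        next_id += 1
    return np.asarray(heights)
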