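"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's LP path: the FBA oracle enumerates
candidate vertices of {v : S v = 0, lb <= v <= ub} by fixing coordinate
subsets at their bounds and solving the remaining equality system by least
squares, then takes the best feasible objective. Exponential, fine at n <= 6.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_fba_objective(S, lb, ub, c, tol=1e-7):
    """Max of c·v over the flux polytope via vertex enumeration; None if no
    feasible candidate point is found."""
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S)
    free = n - rank
    candidates = []

    def try_point(v):
        if (m == 0 or np.max(np.abs(S @ v)) <= tol) and np.all(
            v >= lb - tol
        ) and np.all(v <= ub + tol):
            candidates.append(np.clip(v, lb, ub))

    if free <= 0:
        v, *_ = np.linalg.lstsq(S, np.zeros(m), rcond=None)
        try_point(v)
    for idx in itertools.combinations(range(n), max(free, 0)):
        rest = [j for j in range(n) if j not in idx]
        A = S[:, rest]
        for pattern in itertools.product((0, 1), repeat=len(idx)):
            fixed = np.array(
                [lb[j] if p == 0 else ub[j] for j, p in zip(idx, pattern)]
            )
            rhs = -S[:, list(idx)] @ fixed if idx else np.zeros(m)
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None) if rest else (np.array([]),)
            v = np.zeros(n)
            v[list(idx)] = fixed
            v[rest] = sol
            try_point(v)
    if not candidates:
        return None
    return max(float(c @ v) for v in candidates)


def random_tiny_system(seed: int):
    """Seeded random stoichiometric system with <= 6 reactions; v = 0 is
    always feasible and all bounds are finite, so an optimum exists."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(2, 4))
    n = int(rng.integers(4, 7))
    S = rng.integers(-2, 3, size=(m, n)).astype(float)
    ub = rng.integers(1, 11, size=n).astype(float)
    lb = np.where(rng.random(n) < 0.5, -rng.integers(1, 11, size=n), 0.0).astype(float)
    c = rng.random(n)
    return S, lb, ub, c


def brute_force_bbh(query: dict, reference: dict, k: int, min_score: float):
    """All-vs-all Jaccard + mutual-unique-best oracle for kmer_bbh."""

    def kmers(s):
        return {s[i : i + k] for i in range(len(s) - k + 1)}

    def jac(a, b):
        ka, kb = kmers(a), kmers(b)
        u = ka | kb
        return len(ka & kb) / len(u) if u else 0.0

    sim = {
        (q, r): jac(qs, rs)
        for q, qs in query.items()
        for r, rs in reference.items()
    }
    pairs = []
    for q in query:
        row = {r: sim[(q, r)] for r in reference}
        best = max(row.values())
        tops = [r for r, s in row.items() if s == best]
        if len(tops) != 1 or best < min_score:
            continue
        r = tops[0]
        col = {qq: sim[(qq, r)] for qq in query}
        cbest = max(col.values())
        ctops = [qq for qq, s in col.items() if s == cbest]
        if ctops == [q]:
            pairs.append((q, r, best))
    pairs.sort(key=lambda t: (-t[2], t[0]))
    return pairs
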