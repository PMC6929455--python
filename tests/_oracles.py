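"""Independent brute-force reference implementations used only by the tests.

Everything here is written directly from the mathematical definitions with
plain Python loops, deliberately sharing no code with the package, so that
agreement between the two is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import numpy as np


# --- DAG semantic similarity ------------------------------------------------

def bf_ancestors(edges: set[tuple[str, str]], term: str) -> set[str]:
    """Transitive closure of the child->parent relation, by fixpoint iteration."""
    closure = {term}
    changed = True
    while changed:
        changed = False
        for c, p in edges:
            if c in closure and p not in closure:
                closure.add(p)
                changed = True
    return closure


def bf_contribution(edges: set[tuple[str, str]], root: str, node: str,
                    delta: float) -> float:
    """Decaying contribution by naive recursion over children inside T(root)."""
    tset = bf_ancestors(edges, root)
    if node == root:
        return 1.0
    kids = [c for c, p in edges if p == node and c in tset]
    return delta * max(bf_contribution(edges, root, c, delta) for c in kids)


def bf_semantic_value(edges, root, delta) -> float:
    return sum(bf_contribution(edges, root, t, delta)
               for t in bf_ancestors(edges, root))


def bf_semantic_similarity(edges, a: str, b: str, delta: float) -> float:
    ta, tb = bf_ancestors(edges, a), bf_ancestors(edges, b)
    num = sum(bf_contribution(edges, a, t, delta)
              + bf_contribution(edges, b, t, delta)
              for t in ta & tb)
    return num / (bf_semantic_value(edges, a, delta)
                  + bf_semantic_value(edges, b, delta))


def random_dag(rng: np.random.Generator, n_nodes: int) -> set[tuple[str, str]]:
    """Random DAG: edges only from lower to higher topological index."""
    names = [f"t{i}" for i in range(n_nodes)]
    edges = set()
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < 0.3:
                edges.add((names[i], names[j]))
    return edges


# --- GIP kernel ---------------------------------------------------------------

def bf_gip(profiles: np.ndarray, scale: float = 1.0) -> np.ndarray:
    n = profiles.shape[0]
    gamma = scale / np.mean([sum(v * v for v in profiles[i]) for i in range(n)])
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d2 = sum((profiles[i, t] - profiles[j, t]) ** 2
                     for t in range(profiles.shape[1]))
            K[i, j] = np.exp(-gamma * d2)
    return K


# --- WKNKN --------------------------------------------------------------------

def bf_wknkn(Y: np.ndarray, Sm: np.ndarray, Sd: np.ndarray,
             K: int, p: float) -> np.ndarray:
    """Scalar-loop WKNKN: both sides from the original Y, max with Y."""

    def side(Ymat, S):
        n, m = Ymat.shape
        est = np.zeros((n, m))
        for i in range(n):
            elig = [j for j in range(n)
                    if j != i and any(Ymat[j, t] == 1 for t in range(m))]
            elig.sort(key=lambda j: (-S[i, j], j))
            nbrs = elig[:K]
            denom = sum(S[i, j] for j in nbrs)
            if denom <= 0:
                continue
            for t in range(m):
                est[i, t] = sum(p**r * S[i, j] * Ymat[j, t]
                                for r, j in enumerate(nbrs)) / denom
        return est

    row = side(Y, Sm)
    col = side(Y.T, Sd).T
    out = np.maximum(Y, (row + col) / 2.0)
    return np.clip(out, 0.0, 1.0)


# --- objective ----------------------------------------------------------------

def bf_objective(Y, A, B, Sm, Sd, ll, ld, lt, include_l21=True) -> float:
    n, m = Y.shape
    k = A.shape[1]
    val = sum((Y[i, j] - sum(A[i, t] * B[j, t] for t in range(k))) ** 2
              for i in range(n) for j in range(m))
    val += ll * (sum(a * a for a in A.ravel()) + sum(b * b for b in B.ravel()))
    if include_l21:
        val += ll * sum(np.sqrt(sum(B[j, t] ** 2 for t in range(k)))
                        for j in range(m))
    val += ld * sum((Sm[i, j] - sum(A[i, t] * A[j, t] for t in range(k))) ** 2
                    for i in range(n) for j in range(n))
    val += lt * sum((Sd[i, j] - sum(B[i, t] * B[j, t] for t in range(k))) ** 2
                    for i in range(m) for j in range(m))
    return val


# --- AUC ----------------------------------------------------------------------

def bf_auc(scores, labels) -> float:
    """All-pairs Mann-Whitney with ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if sp > sn else (0.5 if sp == sn else 0.0)
               for sp in pos for sn in neg)
    return wins / (len(pos) * len(neg))
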