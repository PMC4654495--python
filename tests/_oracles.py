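"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (BFS, set intersections,
exhaustive enumeration) and shares no code with the implementation
under test.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


def bfs_closure(edges: list[tuple[str, str]],
                pairs: set[tuple[str, str]]) -> set[tuple[str, str]]:
    """Transitive closure of (gene, term) pairs over child->parent edges, by BFS."""
    parents: dict[str, set[str]] = {}
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)
    closed = set()
    for gene, term in pairs:
        frontier = [term]
        seen = {term}
        while frontier:
            t = frontier.pop()
            closed.add((gene, t))
            for p in parents.get(t, ()):
                if p not in seen:
                    seen.add(p)
                    frontier.append(p)
    return closed


def brute_force_projection(B: np.ndarray) -> np.ndarray:
    """T_ij = |genes(i) & genes(j)| / (k_i k_j) by per-pair set intersection."""
    n_terms = B.shape[1]
    gene_sets = [set(np.nonzero(B[:, j])[0]) for j in range(n_terms)]
    k = [len(s) for s in gene_sets]
    T = np.zeros((n_terms, n_terms))
    for i in range(n_terms):
        for j in range(n_terms):
            if i != j and k[i] > 0 and k[j] > 0:
                shared = len(gene_sets[i] & gene_sets[j])
                T[i, j] = float(shared) / (float(k[i]) * float(k[j]))
    return T


def dense_modularity(A: np.ndarray, labels: np.ndarray, r: float) -> float:
    """Matrix-form evaluation of the resolution-generalized modularity."""
    k = A.sum(axis=1)
    two_m = k.sum()
    mean_k = k.mean()
    gamma = 1.0 + r / mean_k
    same = labels[:, None] == labels[None, :]
    null = gamma * np.outer(k, k) / two_m
    return float(np.sum((A - null) * same) / two_m)


def set_partitions(items: list):
    """All partitions of a list (recursive; fine up to ~10 items)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1:]
        yield [[first]] + smaller


def exhaustive_best_modularity(A: np.ndarray, r: float = 0.0) -> float:
    """Maximum modularity over every partition of the node set."""
    n = A.shape[0]
    best = -np.inf
    for part in set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, block in enumerate(part):
            labels[list(block)] = c
        best = max(best, dense_modularity(A, labels, r))
    return best


def hypergeom_tail_by_enumeration(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws.

    The urn has N items, K of them marked; a draw takes n items.
    """
    marked = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


def best_jaccard_all_pairs(X: dict, Y: dict) -> dict[str, tuple[str, float]]:
    """For each x, the max-Jaccard y by direct scan (ties: first by J then size, id)."""
    out = {}
    for xid, x in X.items():
        scored = []
        for yid, y in Y.items():
            j = len(x & y) / len(x | y)
            scored.append((-j, len(y), yid))
        scored.sort()
        negj, _, yid = scored[0]
        out[xid] = (yid, -negj)
    return out
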