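"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's graph machinery: closures are
computed by breadth-first search over the raw edge list, and every aggregate
is a direct transcription of its defining formula.
"""

from __future__ import annotations

import math
from collections import deque

import pytest

from intego import figure1_fixture
from intego.fixtures import random_go_benchmark


@pytest.fixture(scope="session")
def fig1():
    return figure1_fixture()


@pytest.fixture(scope="session")
def small_benchmarks():
    """A handful of small seeded benchmarks for oracle comparisons."""
    return [
        random_go_benchmark(n_terms=40, n_genes=18, n_ecs=3, noise=0.15, seed=s)
        for s in range(5)
    ]


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def bfs_closure(edges, term: str) -> set[str]:
    """Inclusive ancestor closure by BFS over raw (child, parent, rel) edges."""
    up: dict[str, set[str]] = {}
    for child, parent, _rel in edges:
        up.setdefault(child, set()).add(parent)
    seen = {term}
    queue = deque([term])
    while queue:
        node = queue.popleft()
        for parent in up.get(node, ()):
            if parent not in seen:
                seen.add(parent)
                queue.append(parent)
    return seen


def oracle_counts(edges, direct: dict[str, frozenset[str]]):
    """Per-term propagated gene counts from per-gene BFS closures."""
    closures = {
        g: set().union(*(bfs_closure(edges, t) for t in terms))
        for g, terms in direct.items()
    }
    counts: dict[str, int] = {}
    for closed in closures.values():
        for t in closed:
            counts[t] = counts.get(t, 0) + 1
    return closures, counts


def oracle_ic(count: int, total: int) -> float:
    return -math.log(count / total)


def oracle_lca_set(edges, counts, total, t1, t2):
    """Argmax-IC members of the exhaustive common-ancestor intersection."""
    common = bfs_closure(edges, t1) & bfs_closure(edges, t2)
    annotated = [t for t in common if counts.get(t, 0) > 0]
    best = max(oracle_ic(counts[t], total) for t in annotated)
    return {t for t in annotated
            if abs(oracle_ic(counts[t], total) - best) < 1e-12}


def oracle_wang_svalues(edges, term, weights):
    """S-values by explicit enumeration of all upward paths."""
    up: dict[str, list[tuple[str, str]]] = {}
    for child, parent, rel in edges:
        up.setdefault(child, []).append((parent, rel))
    best = {term: 1.0}
    stack = [(term, 1.0)]
    while stack:
        node, contrib = stack.pop()
        for parent, rel in up.get(node, ()):
            value = contrib * weights[rel]
            if value > best.get(parent, 0.0):
                best[parent] = value
                stack.append((parent, value))
    return best


def oracle_bma(term_sim, T1, T2) -> float:
    """Double-loop best-match average with the nonzero-count rule."""
    best1 = [max(term_sim(t, u) for u in T2) for t in T1]
    best2 = [max(term_sim(u, t) for t in T1) for u in T2]
    nonzero = sum(1 for v in best1 + best2 if v != 0.0)
    if nonzero == 0:
        return 0.0
    return (sum(best1) + sum(best2)) / nonzero


def oracle_diff_g(sim, g, ei_genes, ej_genes, c):
    """Eq-style transcription with explicit count multipliers."""
    others = sorted(set(ei_genes) - {g})
    inter = [1.0 - sim[tuple(sorted((g, x)))] + c for x in sorted(ej_genes)]
    intra = [1.0 - sim[tuple(sorted((g, x)))] + c for x in others]
    return math.log(
        (len(others) * sum(inter)) / (len(ej_genes) * sum(intra))
    )


def oracle_logfc(sim, groups, ei, c):
    """Triple-loop mean-of-means over disjoint partner ECs."""
    partners = [e for e in sorted(groups) if e != ei and not (groups[e] & groups[ei])]
    genes = sorted(groups[ei])
    outer = []
    for ej in partners:
        outer.append(
            sum(oracle_diff_g(sim, g, groups[ei], groups[ej], c) for g in genes)
            / len(genes)
        )
    return sum(outer) / len(outer)
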