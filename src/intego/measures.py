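"""Seed gene/term similarity measures: Yu, Resnik, Schlicker and Wang.

Yu scores gene pairs directly from the rarity of their lowest-common-ancestor
(LCA) equivalence class; Resnik, Schlicker and Wang score term pairs and are
lifted to gene pairs by the best-match average (BMA) over the genes' direct
annotation sets.  A small registry lets further measures be plugged in.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Mapping

import networkx as nx
import pandas as pd

from .ontology import (
    DEFAULT_WANG_WEIGHTS,
    AnnotationTable,
    OntologyGraph,
    TermStats,
    UnknownTermError,
    ancestors,
    gene_lca_set,
    information_content,
    lca_set,
    propagate_annotations,
)

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Order a gene (or term) pair lexicographically."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class SimilarityContext:
    """Everything the measures need: graph, propagated annotations, term stats."""

    graph: OntologyGraph
    annot: AnnotationTable
    stats: TermStats
    wang_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WANG_WEIGHTS)
    )

    @classmethod
    def build(
        cls,
        graph: OntologyGraph,
        annot: AnnotationTable,
        wang_weights: Mapping[str, float] | None = None,
    ) -> "SimilarityContext":
        if annot.propagated is None:
            annot = propagate_annotations(graph, annot)
        stats = information_content(graph, annot)
        return cls(
            graph=graph,
            annot=annot,
            stats=stats,
            wang_weights=dict(wang_weights or DEFAULT_WANG_WEIGHTS),
        )


# ---------------------------------------------------------------------------
# Yu measure (gene level)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LcaPairIndex:
    """Gene pairs grouped by their LCA set.

    ``total_pairs`` is the number of unordered pairs (no self-pairs) among the
    indexed genes; ``pair_count_by_lca_set[s]`` is how many of them have LCA
    set ``s``.  The counts partition the pairs, so they sum to ``total_pairs``.
    """

    lca_sets: Mapping[Pair, frozenset[str]]
    pair_count_by_lca_set: Mapping[frozenset[str], int]
    total_pairs: int


def build_lca_pair_index(
    stats: TermStats,
    graph: OntologyGraph,
    annot: AnnotationTable,
    genes: Iterable[str],
) -> LcaPairIndex:
    """Compute every unordered pair's gene-level LCA set and group by equality."""
    genes = sorted(set(genes))
    if len(genes) < 2:
        raise ValueError("need at least two annotated genes to index pairs")
    lca_sets: dict[Pair, frozenset[str]] = {}
    counter: Counter[frozenset[str]] = Counter()
    for g1, g2 in combinations(genes, 2):
        s = gene_lca_set(stats, graph, annot, g1, g2)
        lca_sets[(g1, g2)] = s
        counter[s] += 1
    return LcaPairIndex(
        lca_sets=lca_sets,
        pair_count_by_lca_set=dict(counter),
        total_pairs=len(lca_sets),
    )


def yu_gene_sim(index: LcaPairIndex, g1: str, g2: str) -> float:
    """Yu similarity −ln(n/N): rare LCA classes mean similar genes.

    ``n`` counts the gene pairs sharing this pair's LCA set (the pair counts
    itself, so n ≥ 1 and the score is finite and non-negative).
    """
    pair = canonical_pair(g1, g2)
    try:
        s = index.lca_sets[pair]
    except KeyError:
        raise KeyError(f"gene pair {pair} not present in the index") from None
    n = index.pair_count_by_lca_set[s]
    return -math.log(n / index.total_pairs)


# ---------------------------------------------------------------------------
# Resnik and Schlicker measures (term level)
# ---------------------------------------------------------------------------

def resnik_term_sim(
    stats: TermStats, graph: OntologyGraph, t1: str, t2: str
) -> float:
    """IC of the lowest common ancestor (all maximal-IC members tie by construction)."""
    lcas = lca_set(stats, graph, t1, t2)
    if not lcas:
        raise UnknownTermError(f"no annotated common ancestor for ({t1}, {t2})")
    return stats.ic_of(next(iter(lcas)))


def schlicker_term_sim(
    stats: TermStats, graph: OntologyGraph, t1: str, t2: str
) -> float:
    """Relevance similarity: Lin-style ratio damped by LCA commonness.

    2·IC(LCA) / (IC(t1)+IC(t2)) × (1 − |G_LCA|/|G_root|).  The second factor
    pushes pairs whose LCA is near the root toward zero.  When both terms are
    the root the denominator vanishes and the similarity is defined as 0.
    """
    denom = stats.ic_of(t1) + stats.ic_of(t2)
    if denom == 0.0:
        return 0.0
    lcas = lca_set(stats, graph, t1, t2)
    ic_lca = stats.ic_of(next(iter(lcas)))
    # Tied LCAs share one IC, hence one count; min() is a no-op kept for clarity.
    count_lca = min(stats.count[t] for t in lcas)
    return (2.0 * ic_lca / denom) * (1.0 - count_lca / stats.total)


# ---------------------------------------------------------------------------
# Wang measure (term level)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WangSValueMap:
    """Semantic contributions of a term's ancestors to the term itself."""

    term: str
    svalue: Mapping[str, float]
    weights: Mapping[str, float]

    @property
    def total(self) -> float:
        return sum(self.svalue.values())


def wang_svalues(
    graph: OntologyGraph,
    term: str,
    weights: Mapping[str, float] | None = None,
) -> WangSValueMap:
    """S-values by dynamic programming over the term's ancestor subgraph.

    S(term) = 1 and S(p) = max over edges (c→p) inside the subgraph of
    weight(relation)·S(c): the maximal semantic contribution over all paths.
    """
    weights = dict(weights or DEFAULT_WANG_WEIGHTS)
    for rel, w in weights.items():
        if not 0.0 < w < 1.0:
            raise ValueError(f"weight for {rel!r} must lie in (0, 1), got {w}")
    anc = ancestors(graph, term, inclusive=True)
    sub = graph.graph.subgraph(anc)
    svalue: dict[str, float] = {}
    # Children precede parents in a topological order of the child→parent DAG.
    for node in nx.topological_sort(sub):
        if node == graph.resolve(term):
            svalue[node] = 1.0
            continue
        svalue[node] = max(
            weights[sub.edges[c, node]["relation"]] * svalue[c]
            for c in sub.predecessors(node)
        )
    return WangSValueMap(term=term, svalue=svalue, weights=weights)


def wang_term_sim(
    graph: OntologyGraph,
    t1: str,
    t2: str,
    weights: Mapping[str, float] | None = None,
) -> float:
    """Wang similarity: shared S-value mass over total S-value mass.

    Σ_{p ∈ P1∩P2} (S_{t1,p} + S_{t2,p}) / (Σ_{p∈P1} S_{t1,p} + Σ_{p∈P2} S_{t2,p}),
    with P1, P2 the self-inclusive ancestor sets.  Always in (0, 1] because
    the root is a shared ancestor with positive S-value.
    """
    s1 = wang_svalues(graph, t1, weights)
    s2 = wang_svalues(graph, t2, weights)
    common = set(s1.svalue) & set(s2.svalue)
    numerator = sum(s1.svalue[p] + s2.svalue[p] for p in common)
    return numerator / (s1.total + s2.total)


# ---------------------------------------------------------------------------
# Best-match average (term → gene lift)
# ---------------------------------------------------------------------------

def bma_gene_sim(
    term_sim: Callable[[str, str], float],
    terms1: Iterable[str],
    terms2: Iterable[str],
) -> float:
    """Best-match average of a term similarity over two annotation sets.

    Each term is matched to its best counterpart in the other set; the sum of
    best matches is divided by the number of terms whose best match is
    nonzero.  If every best match is zero the similarity is 0.
    """
    T1, T2 = sorted(set(terms1)), sorted(set(terms2))
    if not T1 or not T2:
        raise ValueError("best-match average requires nonempty term sets")
    cache: dict[Pair, float] = {}

    def sim(a: str, b: str) -> float:
        key = canonical_pair(a, b)
        if key not in cache:
            cache[key] = term_sim(*key)
        return cache[key]

    best1 = [max(sim(t, u) for u in T2) for t in T1]
    best2 = [max(sim(t, u) for u in T1) for t in T2]
    denom = sum(1 for v in best1 + best2 if v != 0.0)
    if denom == 0:
        return 0.0
    return (sum(best1) + sum(best2)) / denom


# ---------------------------------------------------------------------------
# Measure registry and batch driver
# ---------------------------------------------------------------------------

PairScorer = Callable[[str, str], float]
MeasureFactory = Callable[[SimilarityContext, list[str]], PairScorer]


def _yu_factory(ctx: SimilarityContext, genes: list[str]) -> PairScorer:
    index = build_lca_pair_index(ctx.stats, ctx.graph, ctx.annot, genes)
    return lambda g1, g2: yu_gene_sim(index, g1, g2)


def _bma_factory(term_sim: Callable[..., float], needs_stats: bool) -> MeasureFactory:
    def factory(ctx: SimilarityContext, genes: list[str]) -> PairScorer:
        if needs_stats:
            base = lambda a, b: term_sim(ctx.stats, ctx.graph, a, b)
        else:
            base = lambda a, b: term_sim(ctx.graph, a, b, ctx.wang_weights)
        cache: dict[Pair, float] = {}

        def cached(a: str, b: str) -> float:
            key = canonical_pair(a, b)
            if key not in cache:
                cache[key] = base(*key)
            return cache[key]

        def score(g1: str, g2: str) -> float:
            return bma_gene_sim(
                cached,
                ctx.annot.terms_of(g1, propagated=False),
                ctx.annot.terms_of(g2, propagated=False),
            )

        return score

    return factory


MEASURES: dict[str, MeasureFactory] = {
    "yu": _yu_factory,
    "resnik": _bma_factory(resnik_term_sim, needs_stats=True),
    "schlicker": _bma_factory(schlicker_term_sim, needs_stats=True),
    "wang": _bma_factory(wang_term_sim, needs_stats=False),
}


def register_measure(name: str, factory: MeasureFactory) -> None:
    """Add a gene-pair measure to the registry (overwrites an existing name)."""
    MEASURES[name] = factory


def compute_measure_column(
    measure: str,
    genes: Iterable[str],
    ctx: SimilarityContext,
) -> pd.Series:
    """Score every unordered gene pair with one measure.

    Returns a Series indexed by canonical ``(gene1, gene2)`` tuples in
    lexicographic order — deterministic regardless of input gene order.
    """
    if measure not in MEASURES:
        raise KeyError(
            f"unknown measure {measure!r}; registered: {sorted(MEASURES)}"
        )
    genes = sorted(set(genes))
    scorer = MEASURES[measure](ctx, genes)
    pairs = list(combinations(genes, 2))
    values = [scorer(g1, g2) for g1, g2 in pairs]
    return pd.Series(
        values,
        index=pd.MultiIndex.from_tuples(pairs, names=["gene1", "gene2"]),
        name=measure,
    )


def write_column_tsv(column: pd.Series, path) -> None:
    """Write a similarity column as ``gene1<TAB>gene2<TAB>measure<TAB>score``."""
    with open(path, "w") as fh:
        for (g1, g2), score in column.items():
            fh.write(f"{g1}\t{g2}\t{column.name}\t{score:.10g}\n")
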