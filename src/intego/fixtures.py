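"""Built-in test inputs: the worked-example toy ontology, the illustrative
rank-integration score matrix, and seeded synthetic benchmarks.

The toy ontology (9 terms, 10 genes) reproduces the worked numbers used
throughout: Yu(g1, g2) = −ln(9/45) ≈ 1.61, Resnik(t2, t7) = IC(t1) ≈ 0.51,
Schlicker(t2, t7) ≈ 0.15 and Schlicker(t3, t8) ≈ 0.09.  The synthetic
benchmarks plant EC-coherent functional groups inside disjoint subtrees of a
layered random DAG so that the adaptive-selection machinery can be exercised
without any downloaded GO/GAF/EC data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import AnnotationTable, OntologyGraph, TermStats, propagate_annotations
from .evaluation import ECMap, EvalConfig, evaluate, select_best_method
from .integration import (
    BackgroundSet,
    GeneSimDB,
    IntegrationConfig,
    build_genesimdb,
    integrate_all,
)
from .measures import Pair, SimilarityContext

# ---------------------------------------------------------------------------
# Toy ontology (worked example)
# ---------------------------------------------------------------------------

#: Child→parent edges of the toy DAG (all is_a).
FIGURE1_EDGES: tuple[tuple[str, str, str], ...] = (
    ("t1", "t5", "is_a"),
    ("t5", "root", "is_a"),
    ("t2", "t1", "is_a"),
    ("t4", "t1", "is_a"),
    ("t6", "t1", "is_a"),
    ("t3", "t2", "is_a"),
    ("t3", "t4", "is_a"),
    ("t7", "t6", "is_a"),
    ("t8", "t7", "is_a"),
)

#: Direct gene annotations of the toy example.
FIGURE1_ANNOTATIONS: Mapping[str, str] = {
    "g01": "t2",
    "g03": "t2",
    "g04": "t3",
    "g02": "t7",
    "g05": "t8",
    "g06": "t6",
    "g07": "t5",
    "g08": "t5",
    "g09": "t5",
    "g10": "t5",
}

#: Worked values the toy fixture must reproduce (unrounded).
FIGURE1_EXPECTED: Mapping[str, float] = {
    "yu_g01_g02": 1.609438,       # −ln(9/45)
    "resnik_t2_t7": 0.510826,     # −ln(6/10)
    "schlicker_t2_t7": 0.145254,
    "schlicker_t3_t8": 0.088739,
}


@dataclass(frozen=True)
class Figure1Fixture:
    """The toy ontology with annotations, term stats and expected values."""

    graph: OntologyGraph
    annotations: AnnotationTable
    stats: TermStats
    context: SimilarityContext
    expected: Mapping[str, float]


def figure1_fixture() -> Figure1Fixture:
    """Build the 9-term, 10-gene worked example."""
    graph = OntologyGraph.from_edges(FIGURE1_EDGES, namespace="molecular_function")
    direct = AnnotationTable(
        direct={g: frozenset({t}) for g, t in FIGURE1_ANNOTATIONS.items()}
    )
    annot = propagate_annotations(graph, direct)
    ctx = SimilarityContext.build(graph, annot)
    return Figure1Fixture(
        graph=graph,
        annotations=ctx.annot,
        stats=ctx.stats,
        context=ctx,
        expected=dict(FIGURE1_EXPECTED),
    )


def write_figure1_obo(path: str | Path) -> None:
    """Write the toy ontology as a minimal OBO 1.2 file."""
    parents: dict[str, list[str]] = {}
    for child, parent, _rel in FIGURE1_EDGES:
        parents.setdefault(child, []).append(parent)
    terms = sorted({t for e in FIGURE1_EDGES for t in e[:2]})
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: intego-toy\n")
        for term in terms:
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            fh.write("namespace: molecular_function\n")
            for parent in sorted(parents.get(term, [])):
                fh.write(f"is_a: {parent} ! {parent}\n")


def write_figure1_gaf(path: str | Path) -> None:
    """Write the toy annotations as a 17-column GAF 2.1 file."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for gene, term in sorted(FIGURE1_ANNOTATIONS.items()):
            cols = [""] * 17
            cols[0] = "intego"
            cols[1] = gene
            cols[2] = gene
            cols[4] = term
            cols[5] = "PMID:0"
            cols[6] = "IEA"
            cols[8] = "F"
            cols[11] = "protein"
            cols[12] = "taxon:0"
            cols[13] = "20140101"
            cols[14] = "intego"
            fh.write("\t".join(cols) + "\n")


def write_figure1_annotations(path: str | Path) -> None:
    """Write the toy annotations as a headerless gene<TAB>term table."""
    with open(path, "w") as fh:
        for gene, term in sorted(FIGURE1_ANNOTATIONS.items()):
            fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# Illustrative rank-integration matrix
# ---------------------------------------------------------------------------

#: Raw similarity scores of ten gene pairs under three made-up measures.
TABLE1_SCORES: Mapping[str, Sequence[float]] = {
    "M_A": (2.4, 1.8, 3.0, 1.2, 0.9, 0.5, 1.0, 1.8, 0.2, 2.1),
    "M_B": (0.2, 0.6, 0.9, 0.3, 0.1, 0.5, 0.4, 0.4, 0.7, 0.8),
    "M_C": (0.04, 0.12, 0.03, 0.05, 0.06, 0.02, 0.09, 0.13, 0.01, 0.16),
}


def table1_fixture() -> pd.DataFrame:
    """The illustrative 10-pair × 3-measure score matrix.

    Rows are indexed by canonical pair tuples ``(p01, p02) … (p19, p20)`` so
    the matrix drops straight into the ranking/integration machinery.
    """
    pairs = [(f"p{2*i+1:02d}", f"p{2*i+2:02d}") for i in range(10)]
    frame = pd.DataFrame(
        dict(TABLE1_SCORES),
        index=pd.MultiIndex.from_tuples(pairs, names=["gene1", "gene2"]),
    )
    return frame


# ---------------------------------------------------------------------------
# Synthetic benchmarks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticBenchmark:
    """A seeded benchmark with EC-coherent functional groups planted in
    disjoint subtrees of a layered random DAG."""

    graph: OntologyGraph
    annotations: AnnotationTable
    ec: ECMap
    subtree_terms: Mapping[str, frozenset[str]]
    seed: int
    noise: float


def random_go_benchmark(
    n_terms: int = 200,
    n_genes: int = 120,
    n_ecs: int = 12,
    branching: int = 3,
    noise: float = 0.1,
    seed: int = 0,
) -> SyntheticBenchmark:
    """Generate a layered random DAG with one subtree per EC group.

    Each EC receives an equal share of the genes; each gene is annotated to
    1–3 terms inside its EC's subtree, and a ``noise`` fraction of those
    annotations is relocated uniformly at random anywhere in the ontology
    (modelling annotation error).  Subtrees share only the root, so inter-EC
    term overlap is minimal by construction.  Deterministic per seed.
    """
    if n_terms < n_ecs * branching:
        raise ValueError("n_terms must be at least n_ecs * branching")
    if n_genes < 2 * n_ecs:
        raise ValueError("n_genes must allow >= 2 genes per EC")
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    root = "T0000"
    ecs = [f"{i + 1}.1.1.1" for i in range(n_ecs)]
    subtree_roots = [f"T{i + 1:04d}" for i in range(n_ecs)]
    edges: list[tuple[str, str, str]] = [(t, root, "is_a") for t in subtree_roots]
    subtree_terms: dict[str, list[str]] = {
        ec: [sr] for ec, sr in zip(ecs, subtree_roots)
    }
    child_count: dict[str, int] = {t: 0 for t in subtree_roots}

    next_id = n_ecs + 1
    remaining = n_terms - 1 - n_ecs  # root and subtree roots already placed
    for i in range(remaining):
        ec = ecs[i % n_ecs]
        term = f"T{next_id:04d}"
        next_id += 1
        members = subtree_terms[ec]
        open_slots = [t for t in members if child_count[t] < branching]
        candidates = open_slots if open_slots else members
        parent = candidates[rng.integers(len(candidates))]
        relation = "is_a" if rng.random() < 0.8 else "part_of"
        edges.append((term, parent, relation))
        child_count[parent] = child_count.get(parent, 0) + 1
        child_count[term] = 0
        # occasional second parent within the same subtree keeps it a DAG
        if len(members) > 1 and rng.random() < 0.3:
            second = members[rng.integers(len(members))]
            if second != parent:
                edges.append((term, second, "is_a"))
        subtree_terms[ec].append(term)

    graph = OntologyGraph.from_edges(edges, namespace="molecular_function")

    per_ec = n_genes // n_ecs
    extra = n_genes - per_ec * n_ecs
    all_terms = sorted(t for t in graph.terms if t != root)
    direct: dict[str, frozenset[str]] = {}
    groups: dict[str, set[str]] = {ec: set() for ec in ecs}
    gene_idx = 0
    for k, ec in enumerate(ecs):
        size = per_ec + (1 if k < extra else 0)
        pool = subtree_terms[ec]
        for _ in range(size):
            gene = f"G{gene_idx:03d}"
            gene_idx += 1
            n_annot = int(rng.integers(1, 4))
            terms = set()
            for _ in range(n_annot):
                if rng.random() < noise:
                    terms.add(all_terms[rng.integers(len(all_terms))])
                else:
                    terms.add(pool[rng.integers(len(pool))])
            direct[gene] = frozenset(terms)
            groups[ec].add(gene)

    annot = propagate_annotations(graph, AnnotationTable(direct=direct))
    ecmap = ECMap(groups={ec: frozenset(g) for ec, g in groups.items()})
    return SyntheticBenchmark(
        graph=graph,
        annotations=annot,
        ec=ecmap,
        subtree_terms={ec: frozenset(t) for ec, t in subtree_terms.items()},
        seed=seed,
        noise=noise,
    )


def corrupt_measure(
    column: pd.Series,
    fraction: float,
    seed: int,
    pairs: Sequence[Pair] | None = None,
) -> pd.Series:
    """Shuffle a measure's scores among a random fraction of its pairs.

    ``pairs`` restricts the shuffle to a designated subset (e.g. the pairs
    within some EC groups); the score multiset over the shuffled positions is
    preserved, only the pairing is permuted.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = column.copy()
    eligible = (
        [p for p in column.index if p in set(pairs)] if pairs is not None
        else list(column.index)
    )
    k = int(round(fraction * len(eligible)))
    if k < 2:
        return out
    chosen_idx = rng.choice(len(eligible), size=k, replace=False)
    chosen = [eligible[i] for i in chosen_idx]
    values = out.loc[chosen].to_numpy()
    out.loc[chosen] = rng.permutation(values)
    return out


def ec_subset_pairs(ec: ECMap, ec_subset: Sequence[str]) -> list[Pair]:
    """Canonical pairs with both endpoints among the genes of the given ECs."""
    genes = sorted(set().union(*(ec.groups[e] for e in ec_subset)))
    from itertools import combinations

    return list(combinations(genes, 2))


# ---------------------------------------------------------------------------
# Adaptive-selection experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdaptiveTrialResult:
    """Outcome of one adaptive-selection trial on a synthetic benchmark."""

    winner: str
    method_medians: Mapping[str, float]
    seed_medians: Mapping[str, float]


def adaptive_selection_trial(
    seed: int,
    n_terms: int = 200,
    n_genes: int = 120,
    n_ecs: int = 12,
    noise: float = 0.1,
    measures: Sequence[str] = ("yu", "schlicker", "wang"),
    methods: Sequence[str] = ("max", "min", "mean", "median"),
    c: float = 0.001,
) -> AdaptiveTrialResult:
    """Run the full pipeline on one benchmark with complementary measure strengths.

    The EC groups are split into as many disjoint, equal parts as there are
    seed measures; each measure keeps its own part clean (its favorable
    functional groups) and has its scores fully shuffled among the pairs
    internal to the other parts.  Every EC therefore has exactly one reliable
    measure — the regime in which measures have disjoint favorable EC groups
    and only an integration that tracks the best evidence per pair can recover
    all of them.  The corrupted columns are re-ranked jointly, the candidate
    integration methods are evaluated by LogFC, and the best method is
    selected adaptively.
    """
    bench = random_go_benchmark(
        n_terms=n_terms, n_genes=n_genes, n_ecs=n_ecs, noise=noise, seed=seed
    )
    ctx = SimilarityContext.build(bench.graph, bench.annotations)
    bg = BackgroundSet(genes=frozenset(bench.annotations.gene_universe),
                       species="synthetic")
    db = build_genesimdb(list(measures), bg, set(), ctx)

    ecs = bench.ec.ecs
    part = len(ecs) // len(measures)
    scores = db.scores.copy()
    for i, m in enumerate(measures):
        favorable = set(ecs[i * part:(i + 1) * part])
        corrupt_ecs = [e for e in ecs if e not in favorable]
        target_pairs = ec_subset_pairs(bench.ec, corrupt_ecs)
        scores[m] = corrupt_measure(
            scores[m], fraction=1.0, seed=seed * 1000 + i, pairs=target_pairs
        )
    from .integration import _rank_tables  # re-rank the corrupted columns

    ranks, rank_sims = _rank_tables(scores, db.n_genes, db.norm_mode)
    db = GeneSimDB(scores, ranks, rank_sims, db.n_genes, db.norm_mode, db.meta)

    sim_by_method: dict[str, dict[Pair, float]] = {}
    for method in methods:
        config = IntegrationConfig(method=method, measures=tuple(measures))
        sim_by_method[method] = integrate_all(db, config).to_dict()
    for m in measures:
        sim_by_method[m] = db.rank_sims[m].to_dict()

    result = evaluate(sim_by_method, bench.ec, EvalConfig(c=c))
    report = select_best_method(result, candidates=list(methods))
    medians = result.medians()
    return AdaptiveTrialResult(
        winner=report.winner,
        method_medians={m: float(medians[m]) for m in methods},
        seed_medians={m: float(medians[m]) for m in measures},
    )
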