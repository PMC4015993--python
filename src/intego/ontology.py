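"""Gene Ontology graphs, annotation tables and information content.

The DAG is held as a :class:`networkx.DiGraph` whose edges run child term →
parent term, each tagged with its relation (``is_a`` or ``part_of``).  Gene
annotations are propagated upward along this graph (the "true-path rule"), and
the information content of a term is the negative natural log of the fraction
of annotated genes falling under its propagated closure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger("intego")

#: Edge relations retained when building ontology graphs.
KEPT_RELATIONS = ("is_a", "part_of")

#: Default semantic-contribution decay per edge relation (Wang et al. values).
DEFAULT_WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


class OntologyError(Exception):
    """Base class for ontology construction and lookup failures."""


class CyclicOntologyError(OntologyError):
    """The child→parent edge relation contains a cycle."""


class NoRootError(OntologyError):
    """No unique parentless term exists in the requested namespace."""


class UnknownTermError(OntologyError, KeyError):
    """A term identifier is absent from the graph."""


class UnannotatedGeneError(OntologyError, KeyError):
    """A gene has no (propagated) annotation."""


class MalformedGafError(OntologyError):
    """A GAF row does not have the expected column layout."""


class EmptyAnnotationError(OntologyError):
    """An operation requiring annotations received an empty table."""


@dataclass(frozen=True)
class OntologyGraph:
    """A single-namespace GO DAG with typed child→parent edges.

    Parameters
    ----------
    graph
        Directed graph; an edge ``(c, p)`` means *c* is a child of *p* and
        carries a ``relation`` attribute (``is_a`` or ``part_of``).
    root
        The unique term with no parents.
    namespace
        Ontology aspect label, e.g. ``molecular_function``.
    alt_ids
        Mapping of secondary term identifiers to their canonical identifier.
    """

    graph: nx.DiGraph
    root: str
    namespace: str = "molecular_function"
    alt_ids: Mapping[str, str] = field(default_factory=dict)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str, str]]:
        return {(c, p, d["relation"]) for c, p, d in self.graph.edges(data=True)}

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def resolve(self, term: str) -> str:
        """Map an identifier (possibly an alt_id) to its canonical term."""
        if term in self.graph:
            return term
        return self.alt_ids.get(term, term)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, str]],
        namespace: str = "molecular_function",
        alt_ids: Mapping[str, str] | None = None,
    ) -> "OntologyGraph":
        """Build and validate a graph from ``(child, parent, relation)`` triples."""
        g = nx.DiGraph()
        for child, parent, relation in edges:
            if relation not in KEPT_RELATIONS:
                continue
            g.add_edge(child, parent, relation=relation)
        return cls._validated(g, namespace, alt_ids or {})

    @classmethod
    def _validated(
        cls, g: nx.DiGraph, namespace: str, alt_ids: Mapping[str, str]
    ) -> "OntologyGraph":
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise CyclicOntologyError(f"ontology contains a cycle: {cycle}")
        roots = [t for t in g.nodes if g.out_degree(t) == 0]
        if len(roots) != 1:
            raise NoRootError(
                f"expected exactly one parentless term in namespace {namespace!r}, "
                f"found {sorted(roots)!r}"
            )
        return cls(graph=g, root=roots[0], namespace=namespace, alt_ids=dict(alt_ids))


@dataclass
class AnnotationTable:
    """Gene → GO term annotations, direct and (optionally) propagated."""

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]] | None = None

    @property
    def gene_universe(self) -> set[str]:
        return set(self.direct)

    def terms_of(self, gene: str, propagated: bool = True) -> frozenset[str]:
        table = self.propagated if propagated else self.direct
        if table is None:
            raise EmptyAnnotationError("annotations have not been propagated yet")
        try:
            return table[gene]
        except KeyError:
            raise UnannotatedGeneError(gene) from None


@dataclass(frozen=True)
class TermStats:
    """Per-term annotated-gene counts and information content (nats)."""

    count: Mapping[str, int]
    total: int
    ic: Mapping[str, float]
    unannotated: frozenset[str] = frozenset()

    def ic_of(self, term: str) -> float:
        try:
            value = self.ic[term]
        except KeyError:
            raise UnknownTermError(term) from None
        if math.isnan(value):
            raise UnknownTermError(f"term {term} has no annotated genes; IC undefined")
        return value


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_obo(
    path: str | Path, namespace: str = "molecular_function"
) -> OntologyGraph:
    """Read an OBO 1.2/1.4 file and return the DAG of one namespace.

    Obsolete terms are dropped, only ``is_a`` and ``relationship: part_of``
    edges are kept, and secondary identifiers (``alt_id``) are recorded so
    annotations using them can be resolved to canonical terms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    multi = obonet.read_obo(path, ignore_obsolete=True)

    def ns(node: str) -> str | None:
        return multi.nodes[node].get("namespace")

    # If the file declares no namespaces, keep every term.
    declared = any(ns(n) is not None for n in multi.nodes)
    keep = {n for n in multi.nodes if not declared or ns(n) == namespace}

    g = nx.DiGraph()
    g.add_nodes_from(keep)
    for child, parent, relation in multi.edges(keys=True):
        if relation in KEPT_RELATIONS and child in keep and parent in keep:
            g.add_edge(child, parent, relation=relation)

    alt_ids: dict[str, str] = {}
    for node in keep:
        for alt in multi.nodes[node].get("alt_id", []):
            alt_ids[alt] = node
    return OntologyGraph._validated(g, namespace, alt_ids)


#: GAF column indices (0-based): DB object id, qualifier, GO id, evidence, aspect.
_GAF_GENE, _GAF_QUALIFIER, _GAF_TERM, _GAF_EVIDENCE, _GAF_ASPECT = 1, 3, 4, 6, 8
_GAF_NCOLS = 17


def parse_gaf(
    path: str | Path,
    aspect: str = "F",
    evidence_filter: set[str] | None = None,
) -> AnnotationTable:
    """Read a GAF 2.1/2.2 file into a direct annotation table.

    Rows whose qualifier contains ``NOT`` are dropped, only rows matching
    ``aspect`` are kept, and ``evidence_filter`` (when given) restricts rows
    to the listed evidence codes.  Propagation is left to
    :func:`propagate_annotations`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != _GAF_NCOLS:
                raise MalformedGafError(
                    f"{path}:{lineno}: expected {_GAF_NCOLS} columns, got {len(cols)}"
                )
            if "NOT" in cols[_GAF_QUALIFIER].split("|"):
                continue
            if cols[_GAF_ASPECT] != aspect:
                continue
            if evidence_filter is not None and cols[_GAF_EVIDENCE] not in evidence_filter:
                continue
            direct.setdefault(cols[_GAF_GENE], set()).add(cols[_GAF_TERM])
    return AnnotationTable(direct={g: frozenset(t) for g, t in direct.items()})


def parse_gene2go(path: str | Path) -> AnnotationTable:
    """Read a headerless two-column ``gene<TAB>GO:ID`` annotation table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            gene, term = line.rstrip("\n").split("\t")[:2]
            direct.setdefault(gene, set()).add(term)
    return AnnotationTable(direct={g: frozenset(t) for g, t in direct.items()})


def write_annotations_tsv(
    annot: AnnotationTable, path: str | Path, propagated: bool = False
) -> None:
    """Write annotations as ``gene<TAB>term`` rows (sorted, one per pair)."""
    table = annot.propagated if propagated else annot.direct
    if table is None:
        raise EmptyAnnotationError("no propagated annotations to write")
    with open(path, "w") as fh:
        for gene in sorted(table):
            for term in sorted(table[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# Closures and information content
# ---------------------------------------------------------------------------

def ancestors(ograph: OntologyGraph, term: str, inclusive: bool = True) -> set[str]:
    """Transitive parents of ``term`` (self-inclusive by default).

    The self-inclusive form is what the semantic-similarity measures use:
    every parent set P_t contains t itself.
    """
    term = ograph.resolve(term)
    if term not in ograph.graph:
        raise UnknownTermError(term)
    anc = nx.descendants(ograph.graph, term)  # edges run child→parent
    if inclusive:
        anc = anc | {term}
    return anc


def propagate_annotations(
    ograph: OntologyGraph,
    annot: AnnotationTable,
    on_unknown: str = "error",
) -> AnnotationTable:
    """Close each gene's annotation set under the parent relation.

    ``on_unknown`` controls what happens when a direct annotation names a term
    absent from the graph: ``"error"`` raises, ``"skip"`` drops it with a
    warning.  Genes left with no known terms are dropped entirely.
    """
    if on_unknown not in ("error", "skip"):
        raise ValueError(f"on_unknown must be 'error' or 'skip', got {on_unknown!r}")
    closure_cache: dict[str, set[str]] = {}
    propagated: dict[str, frozenset[str]] = {}
    direct_kept: dict[str, frozenset[str]] = {}
    for gene, terms in annot.direct.items():
        closed: set[str] = set()
        kept: set[str] = set()
        for term in terms:
            resolved = ograph.resolve(term)
            if resolved not in ograph.graph:
                if on_unknown == "error":
                    raise UnknownTermError(term)
                logger.warning("gene %s annotated to unknown term %s; skipped", gene, term)
                continue
            if resolved not in closure_cache:
                closure_cache[resolved] = ancestors(ograph, resolved, inclusive=True)
            closed |= closure_cache[resolved]
            kept.add(resolved)
        if closed:
            propagated[gene] = frozenset(closed)
            direct_kept[gene] = frozenset(kept)
    return AnnotationTable(direct=direct_kept, propagated=propagated)


def information_content(ograph: OntologyGraph, annot: AnnotationTable) -> TermStats:
    """Count propagated annotations per term and derive IC = −ln(|G_t|/|G_root|).

    Terms annotating no gene get ``nan`` IC and are reported in
    ``TermStats.unannotated``; IC-based measures refuse to score them.
    """
    if annot.propagated is None:
        annot = propagate_annotations(ograph, annot)
    if not annot.propagated:
        raise EmptyAnnotationError("no annotated genes")
    count: dict[str, int] = {t: 0 for t in ograph.graph.nodes}
    for terms in annot.propagated.values():
        for t in terms:
            count[t] += 1
    total = len(annot.propagated)
    ic: dict[str, float] = {}
    unannotated = set()
    for t, n in count.items():
        if n == 0:
            ic[t] = math.nan
            unannotated.add(t)
        else:
            ic[t] = -math.log(n / total)
    if unannotated:
        logger.warning(
            "%d of %d terms annotate no gene; their IC is undefined",
            len(unannotated), len(count),
        )
    return TermStats(count=count, total=total, ic=ic, unannotated=frozenset(unannotated))


def _argmax_ic(stats: TermStats, terms: set[str]) -> set[str]:
    """Members of ``terms`` attaining the maximal (finite) IC."""
    best = max(
        (stats.ic[t] for t in terms if not math.isnan(stats.ic.get(t, math.nan))),
        default=None,
    )
    if best is None:
        return set()
    return {t for t in terms if stats.ic.get(t) == best}


def lca_set(
    stats: TermStats, ograph: OntologyGraph, t1: str, t2: str
) -> set[str]:
    """All common (self-inclusive) ancestors of maximal information content.

    The result is a set because several common ancestors may tie on IC; it is
    never empty since the root is a common ancestor of every pair.
    """
    common = ancestors(ograph, t1) & ancestors(ograph, t2)
    return _argmax_ic(stats, common)


def gene_lca_set(
    stats: TermStats,
    ograph: OntologyGraph,
    annot: AnnotationTable,
    g1: str,
    g2: str,
) -> frozenset[str]:
    """Maximal-IC members of the intersection of two genes' propagated closures."""
    common = set(annot.terms_of(g1)) & set(annot.terms_of(g2))
    return frozenset(_argmax_ic(stats, common))
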