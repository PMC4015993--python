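"""Rank-based unification and integration of seed measures.

Raw seed-measure scores live on incommensurable scales, so every measure's
column over all gene pairs (background ∪ user genes) is converted to a
competition ranking (ascending; ties share the minimum rank) and normalized to
(0, 1].  The per-measure rank similarities are then reduced pair-wise by an
integration method: max, min, mean, median, or a user-registered reducer.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .measures import SimilarityContext, compute_measure_column

logger = logging.getLogger("intego")

RANK_NORM_MODES = ("pairs", "eq5_literal")


@dataclass(frozen=True)
class BackgroundSet:
    """The fixed per-species gene set against which user pairs are ranked."""

    genes: frozenset[str]
    species: str = ""
    note: str = ""

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass
class GeneSimDB:
    """Scores, ranks and rank similarities for all pairs over BG ∪ G.

    ``scores``, ``ranks`` and ``rank_sims`` are DataFrames sharing a
    MultiIndex of canonical (lexicographically ordered) gene pairs, one column
    per measure.
    """

    scores: pd.DataFrame
    ranks: pd.DataFrame
    rank_sims: pd.DataFrame
    n_genes: int
    norm_mode: str = "pairs"
    meta: dict = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.scores)

    @property
    def measures(self) -> list[str]:
        return list(self.scores.columns)

    def pair_rank_sims(self, g1: str, g2: str) -> dict[str, float]:
        key = (g1, g2) if g1 <= g2 else (g2, g1)
        return self.rank_sims.loc[key].to_dict()

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write the score table as TSV plus a JSON metadata sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = self.scores.reset_index()
        out.to_csv(directory / "genesimdb.tsv", sep="\t", index=False)
        meta = dict(self.meta)
        meta.update(n_genes=self.n_genes, norm_mode=self.norm_mode)
        (directory / "genesimdb.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "GeneSimDB":
        directory = Path(directory)
        meta = json.loads((directory / "genesimdb.json").read_text())
        table = pd.read_csv(directory / "genesimdb.tsv", sep="\t")
        scores = table.set_index(["gene1", "gene2"])
        n_genes = meta.pop("n_genes")
        norm_mode = meta.pop("norm_mode")
        ranks, rank_sims = _rank_tables(scores, n_genes, norm_mode)
        return cls(scores, ranks, rank_sims, n_genes, norm_mode, meta)


class MissingScoreError(KeyError):
    """A required measure value is absent for a pair."""


def competition_rank(scores: Sequence[float]) -> np.ndarray:
    """Ascending competition ("1224") ranks: rank = 1 + #strictly smaller."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty score list")
    if not np.all(np.isfinite(arr)):
        raise ValueError("scores must be finite to be ranked")
    return rankdata(arr, method="min").astype(int)


def rank_sim(rank: int, db: "GeneSimDB | None" = None, mode: str = "pairs",
             n_pairs: int | None = None, n_genes: int | None = None) -> float:
    """Normalize a rank to (0, 1].

    ``pairs`` mode divides by the number of ranked pairs (rank 9 of 10 pairs
    → 0.9); ``eq5_literal`` computes 2·rank / (number of genes)².  The sizes
    may come from a :class:`GeneSimDB` or be passed explicitly.
    """
    if db is not None:
        n_pairs = db.n_pairs
        n_genes = db.n_genes
    if mode == "pairs":
        if n_pairs is None:
            raise ValueError("pairs mode requires n_pairs")
        if not 1 <= rank <= n_pairs:
            raise ValueError(f"rank {rank} outside [1, {n_pairs}]")
        return rank / n_pairs
    if mode == "eq5_literal":
        if n_genes is None:
            raise ValueError("eq5_literal mode requires n_genes")
        return 2.0 * rank / (n_genes ** 2)
    raise ValueError(f"unknown rank normalization mode {mode!r}")


def _rank_tables(
    scores: pd.DataFrame, n_genes: int, norm_mode: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    ranks = pd.DataFrame(
        {m: competition_rank(scores[m].to_numpy()) for m in scores.columns},
        index=scores.index,
    )
    if norm_mode == "pairs":
        rank_sims = ranks / len(scores)
    elif norm_mode == "eq5_literal":
        rank_sims = 2.0 * ranks / (n_genes ** 2)
    else:
        raise ValueError(f"unknown rank normalization mode {norm_mode!r}")
    return ranks, rank_sims.astype(float)


def _context_hash(ctx: SimilarityContext) -> str:
    h = hashlib.sha256()
    for edge in sorted(ctx.graph.edges):
        h.update(repr(edge).encode())
    for gene in sorted(ctx.annot.direct):
        h.update(gene.encode())
        h.update(",".join(sorted(ctx.annot.direct[gene])).encode())
    return h.hexdigest()[:16]


def build_genesimdb(
    measures: Sequence[str],
    bg: BackgroundSet,
    user_genes: Iterable[str],
    ctx: SimilarityContext,
    norm_mode: str = "pairs",
    cache_dir: str | Path | None = None,
) -> GeneSimDB:
    """Score, rank and normalize every pair over BG ∪ G for each measure.

    Pairs within BG, within G and across are ranked jointly; if G ⊆ BG no new
    pairs appear.  Genes without annotations are excluded with a warning.
    A ``cache_dir`` enables reuse of a previously saved score table when the
    ontology, annotations and measure list are unchanged.
    """
    genes = set(bg.genes) | set(user_genes)
    annotated = {g for g in genes if g in ctx.annot.gene_universe}
    dropped = genes - annotated
    if dropped:
        logger.warning("excluding %d genes with no annotation: %s",
                       len(dropped), sorted(dropped)[:10])
    genes = sorted(annotated)
    if len(genes) < 2:
        raise ValueError("need at least two annotated genes to build a GeneSimDB")

    meta = {
        "context_hash": _context_hash(ctx),
        "measures": list(measures),
        "genes_hash": hashlib.sha256(",".join(genes).encode()).hexdigest()[:16],
    }
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        meta_path = cache_dir / "genesimdb.json"
        if meta_path.exists():
            cached_meta = json.loads(meta_path.read_text())
            if all(cached_meta.get(k) == v for k, v in meta.items()):
                logger.info("reusing cached GeneSimDB from %s", cache_dir)
                db = GeneSimDB.load(cache_dir)
                db.norm_mode = norm_mode
                db.ranks, db.rank_sims = _rank_tables(db.scores, db.n_genes, norm_mode)
                return db

    columns = {m: compute_measure_column(m, genes, ctx) for m in measures}
    scores = pd.DataFrame(columns)
    scores.index.names = ["gene1", "gene2"]
    ranks, rank_sims = _rank_tables(scores, len(genes), norm_mode)
    db = GeneSimDB(scores, ranks, rank_sims, len(genes), norm_mode, meta)
    if cache_dir is not None:
        db.save(cache_dir)
    return db


# ---------------------------------------------------------------------------
# Integration methods
# ---------------------------------------------------------------------------

Reducer = Callable[[Mapping[str, float]], float]

INTEGRATORS: dict[str, Reducer] = {
    "max": lambda v: max(v.values()),
    "min": lambda v: min(v.values()),
    "mean": lambda v: float(np.mean(list(v.values()))),
    "median": lambda v: float(np.median(list(v.values()))),
}


def register_integration(name: str, reducer: Reducer) -> None:
    """Register a custom integration reducer; it receives {measure: rank_sim}."""
    INTEGRATORS[name] = reducer


@dataclass(frozen=True)
class IntegrationConfig:
    """Which measures to integrate and how."""

    method: str = "max"
    measures: tuple[str, ...] = ("yu", "schlicker", "wang")
    norm_mode: str = "pairs"

    def __post_init__(self):
        if not self.measures:
            raise ValueError("integration requires at least one measure")
        if self.method not in INTEGRATORS:
            raise ValueError(
                f"unknown integration method {self.method!r}; "
                f"registered: {sorted(INTEGRATORS)}"
            )
        if self.norm_mode not in RANK_NORM_MODES:
            raise ValueError(f"unknown rank normalization mode {self.norm_mode!r}")


def integrate(rank_sims: Mapping[str, float], config: IntegrationConfig) -> float:
    """Reduce one pair's per-measure rank similarities to a single score."""
    try:
        values = {m: rank_sims[m] for m in config.measures}
    except KeyError as exc:
        raise MissingScoreError(f"measure {exc.args[0]!r} missing for this pair") from None
    return INTEGRATORS[config.method](values)


def integrate_all(
    db: GeneSimDB,
    config: IntegrationConfig,
    restrict_to: Iterable[str] | None = None,
) -> pd.Series:
    """Apply the configured reducer to every pair in the database.

    ``restrict_to`` limits the output to pairs within the given user gene set
    (the database is still ranked over all pairs).
    """
    table = db.rank_sims[list(config.measures)]
    method = config.method
    if method == "max":
        out = table.max(axis=1)
    elif method == "min":
        out = table.min(axis=1)
    elif method == "mean":
        out = table.mean(axis=1)
    elif method == "median":
        out = table.median(axis=1)
    else:
        reducer = INTEGRATORS[method]
        out = pd.Series(
            [reducer(row._asdict() if hasattr(row, "_asdict") else dict(row))
             for row in table.to_dict("records")],
            index=table.index,
        )
    out.name = method
    if restrict_to is not None:
        wanted = set()
        for g1, g2 in combinations(sorted(set(restrict_to)), 2):
            wanted.add((g1, g2))
        out = out.loc[[p for p in out.index if p in wanted]]
    return out
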