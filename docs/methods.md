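# Methods

## Model and assumptions

The package treats the Gene Ontology's Molecular Function branch as a DAG
whose edges run child term → parent term and are typed `is_a` or `part_of`;
all other relations (`regulates`, …) are dropped at parse time. Annotations
obey the true-path rule: a gene annotated to a term is implicitly annotated
to every ancestor, so all counting happens on the propagated (ancestor-closed)
annotation sets. Information content is the negative *natural* log of the
annotated-gene fraction, `IC(t) = −ln(|G_t|/|G_root|)`; the natural log is
what makes the toy ontology's worked values come out right (−ln(6/10) = 0.51).

Parent sets are self-inclusive throughout (`P_t` contains `t`), and the
lowest common ancestor of a pair is defined as the *set* of common ancestors
attaining maximal IC — several ancestors can tie exactly (equal propagated
counts imply equal IC), and measures that need a single IC or count use the
shared tied value. For gene-level common ancestry (the Yu measure), the
common-ancestor pool is the intersection of the two genes' propagated
closures; for single-term genes this reduces exactly to term-level LCA.

## Seed measures

- **Yu** scores a gene pair by the rarity of its LCA-set equivalence class,
  `−ln(n/N)` over unordered pairs without self-pairs (N = C(k,2)); a pair
  always counts itself, so the score is finite and ≥ 0.
- **Resnik** is IC of the LCA; **Schlicker** rescales it by the pair's own
  ICs and damps LCAs close to the root by `1 − |G_LCA|/|G_root|`. When both
  terms are the root (zero denominator) the similarity is defined as 0.
- **Wang** S-values are computed by a dynamic program over the term's
  inclusive ancestor subgraph in topological order — equivalent to maximizing
  the product of edge weights over all upward paths. Edge weights default to
  0.8 (`is_a`) and 0.6 (`part_of`), the conventional values for this measure
  family; they are configurable and validated to lie in (0, 1).
- Term measures lift to genes by the best-match average over *direct*
  annotation sets (the sets the genes were actually annotated with); the
  nonzero-count rule applies to the denominator only. Terms annotating no
  gene have undefined IC and are refused by the IC-based measures rather than
  silently scored.

## Rank unification and integration

Each measure's column over all unordered pairs of BG ∪ G is ranked ascending
with competition ("1224") ranking — tied scores share the minimal rank — and
normalized by the number of ranked pairs, so rank similarity lies in (0, 1]
and the best pair(s) score 1 when the top score is unique. This is the
normalization that reproduces the worked integration table (rank 9 of 10
pairs → 0.9) and is the default; the literal alternative `2r/(n_genes)²` is
kept as mode `eq5_literal` for comparison but is not bounded by 1 and is not
used anywhere else. Ranking all BG×BG pairs jointly with the user pairs keeps
a user pair's rank meaningful against the species background.

Integration reduces the per-pair mapping {measure → rank similarity} with
max, min, mean or median; custom reducers can be registered and receive the
full mapping. Ranks are invariant under strictly monotone transformations of
a measure's raw scores, which is the formal content of the scale-unification
claim and is property-tested.

## EC-based evaluation and adaptive selection

Genes sharing a four-field EC number form a gold-standard functional group;
groups with fewer than two genes are dropped (default `min_group_size = 2`)
and the background set is the union of the retained groups. For gene g in
group e_i and a disjoint group e_j, the per-gene contrast is

    diff_g(e_i, e_j) = ln( mean_{g'∈e_j} d(g,g') / mean_{g*∈e_i∖{g}} d(g,g*) )

with distance `d = 1 − sim + c`. The printed form of this statistic carries
group-size multipliers; because the intra set excludes the focal gene they
cancel exactly into the two means, and the implementation asserts this
identity numerically in tests. LogFC(e_i) averages diff_g over e_i's genes
and then over all disjoint partner groups (a mean of means; the partner count
is the averaging denominator, since any larger universe would only shrink all
scores by a constant). ECs without a disjoint partner have undefined LogFC
and are excluded, never imputed.

Similarities fed to the evaluation are always rank-normalized — for seed
measures and integrated methods alike — so distances stay positive (raw Yu
scores exceed 1 and would make `1 − sim` negative). The smoothing constant
defaults to `c = 0.001`; it only matters when intra-group distances approach
zero, where it caps the attainable LogFC at `ln((1+c)/c) ≈ 6.9`. A reporting
clip (e.g. [−0.05, 5]) can be applied on export only; selection and testing
always use unclipped scores.

Selection ranks candidate methods by their median per-EC LogFC (no method
can dominate literally every EC), breaking ties by mean and then name.
Tukey's HSD over the per-EC LogFC vectors (one-way layout, studentized range
distribution, via statsmodels) quantifies whether the winner's advantage is
family-wise significant; R's `TukeyHSD` and `scipy.stats.tukey_hsd` serve as
independent cross-checks in the test suite. Covariance against external
per-pair scores (e.g. log BLAST bit scores, supplied precomputed) is a plain
sample covariance over the shared pairs.

## Synthetic benchmarks

`random_go_benchmark` emulates the structure the evaluation depends on, not
real GO statistics: a layered random DAG in which each EC group owns a
disjoint subtree hanging off the root (80% `is_a`, occasional second parent
inside the same subtree, at most `branching` children per term where
possible). Genes are annotated to 1–3 terms of their group's subtree, and a
`noise` fraction of annotations is relocated uniformly at random anywhere in
the ontology, modelling annotation error. Defaults (200 terms, 120 genes, 12
EC groups, noise 0.1) give ten genes per group — comfortably above the
min-size-2 rule — and a background of 7,140 pairs, a size chosen so the whole
adaptive experiment runs in seconds per seed. Generators are pure functions
of their seed (bit-identical regeneration).

The adaptive-selection experiment (`adaptive_selection_trial`) plants the
regime in which integration pays off: measures with *complementary
strengths*. The EC groups are split into as many disjoint parts as there are
seed measures; each measure keeps its own part clean and has its scores
shuffled among the pairs internal to the other parts, so every EC group has
exactly one reliable measure. Under max integration the reliable measure's
high intra-group rank similarities survive the reduction for every group,
while min and mean are dragged down by the shuffled columns and median tracks
the majority (two of three unreliable) — max is therefore the structurally
correct winner, and the experiment verifies the selector recovers it, with
max's median LogFC above every individual seed measure's.

What passing these benchmarks does *not* show: behaviour under real GO
term-count distributions, shallow or incomplete annotation, multi-EC genes at
realistic rates, or background sets orders of magnitude larger — the
benchmarks validate the machinery and its selection logic, not species-level
effect sizes.

## Numerical choices and degenerate inputs

- Ranking requires finite scores; NaN/inf raise immediately.
- Competition ranking uses `scipy.stats.rankdata(method="min")`.
- Gene pairs and term pairs are always keyed in lexicographic (canonical)
  order; measure columns are deterministic under input permutation.
- Obsolete terms are dropped at OBO parse; secondary identifiers (`alt_id`)
  resolve to canonical terms. Annotation rows with a `NOT` qualifier are
  dropped; evidence codes are kept unless a filter is given.
- Unknown annotation terms either raise or skip-with-warning
  (`on_unknown="skip"`); genes left termless are dropped.
- A cyclic ontology, a missing unique root, malformed GAF rows (with line
  number), unannotated genes, overlapping EC groups in `diff_g`, and
  zero-variance Tukey layouts each raise a distinct, named error.
- The GeneSimDB cache is keyed by hashes of the edge set, the direct
  annotations and the measure list; a warm load re-ranks from the cached raw
  scores, so changing the normalization mode never requires recomputation.

## Known limitations

- Cross-namespace similarity is out of scope; one namespace per graph.
- No incremental re-ranking: adding genes triggers a full re-rank (the pair
  count changes anyway).
- The Yu measure's LCA-set equality test is exact set equality; in very large
  ontologies near-identical LCA sets form distinct classes, which is the
  measure's own definition but makes it granular on sparse backgrounds.
- Sequence similarity is consumed only as precomputed per-pair tables; the
  package never runs alignments.
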