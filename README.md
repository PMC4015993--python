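# intego

Rank-based integrative gene functional similarity over the Gene Ontology.

## What problem this solves

Comparing two genes by their Molecular Function annotations is a standard step
in function prediction, network inference and annotation quality control, but
no single semantic similarity measure uses all of the information in the GO:
the Yu measure uses annotation statistics around lowest common ancestors
(LCAs), the Resnik and Schlicker measures use information content, and the
Wang measure uses the aggregated semantic contributions of all common parents.
Each is better than the others on some functional groups and worse on others.

`intego` integrates these *seed measures* instead of choosing one. Because
their raw scores live on incommensurable scales, each measure's scores over
all gene pairs of a background set BG (plus the user's genes G) are converted
to a competition ranking and normalized, and the per-pair rank similarities
are then reduced by an integration method (max, min, mean, median, or a
user-registered reducer). Which reducer is best is decided *adaptively*, by
scoring every candidate against Enzyme Commission (EC) groups: genes sharing
a four-field EC number should be more similar to each other than to genes of
disjoint EC groups.

## The statistics

For genes g₁, g₂ with direct annotation sets T₁, T₂:

- **Yu**: `GeneSim(g₁,g₂) = −ln(n/N)` where n counts gene pairs sharing the
  pair's LCA set and N is the total number of unordered pairs.
- **Resnik**: `TermSim(t₁,t₂) = IC(LCA₁₂)` with `IC(t) = −ln(|G_t|/|G_root|)`
  over propagated annotations.
- **Schlicker**: `2·IC(LCA₁₂)/(IC(t₁)+IC(t₂)) · (1 − |G_LCA₁₂|/|G_root|)`.
- **Wang**: `Σ_{p∈P₁∩P₂}(S₁ₚ+S₂ₚ) / (Σ S₁ₚ + Σ S₂ₚ)` with S-values decaying by
  0.8 (is_a) / 0.6 (part_of) per edge along the best path.
- Term-level measures are lifted to genes by the best-match average
  `(Σ_{t∈T₁} max_{u∈T₂} sim(t,u) + Σ_{t∈T₂} max_{u∈T₁} sim(t,u)) / (|T₁|+|T₂|)`,
  counting only terms with a nonzero best match in the denominator.
- **Rank similarity**: `RankSim(g₁,g₂,m) = rank / n_pairs` (ascending
  competition ranking over all pairs of BG ∪ G).
- **LogFC** of EC group e: the log ratio of mean inter-EC to mean intra-EC
  gene distance, `distance = 1 − RankSim + c` (c = 0.001), averaged over
  genes of e and over all ECs disjoint from e. The integration method with
  the highest median LogFC across ECs is selected; candidates are also
  compared by Tukey's HSD over their per-EC LogFC vectors.

## Worked example

The package ships the classic 9-term / 10-gene teaching ontology:

```python
import intego as ig

fx = ig.figure1_fixture()
idx = ig.build_lca_pair_index(fx.stats, fx.graph, fx.annotations,
                              fx.annotations.gene_universe)
print(round(ig.yu_gene_sim(idx, "g01", "g02"), 2))                      # 1.61
print(round(ig.resnik_term_sim(fx.stats, fx.graph, "t2", "t7"), 2))     # 0.51
print(round(ig.schlicker_term_sim(fx.stats, fx.graph, "t2", "t7"), 2))  # 0.15
print(round(ig.schlicker_term_sim(fx.stats, fx.graph, "t3", "t8"), 2))  # 0.09
```

`1.61 = −ln(9/45)`: nine of the 45 gene pairs share the (g01, g02) LCA set
{t1}, so the pair is moderately specific. Resnik gives (t2, t7) and (t3, t8)
the same 0.51 because both share the LCA t1; Schlicker separates them (0.15
vs 0.09) because t3 and t8 sit farther below that ancestor.

From the shell, the same toy data plus an integrated similarity:

```sh
intego fixture figure1 --out toy/
intego sim --obo toy/toy.obo --gaf toy/toy.gaf \
      --genes g01,g02,g05 --integration max --out sim.tsv
```

which prints pair similarities such as `g01 g02 0.8` — the maximum over the
Yu/Schlicker/Wang rank similarities of that pair against the 45-pair
background ranking.

Evaluation and adaptive selection run on any annotation + EC table, e.g. a
generated benchmark:

```sh
intego fixture random --seed 3 --out bench/
intego evaluate --obo bench/benchmark.obo ... --ec bench/benchmark.ec.tsv --out eval/
intego select   --obo ... --ec ...   # prints e.g. "max"
```

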