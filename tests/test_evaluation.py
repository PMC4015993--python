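"""EC-grouped LogFC evaluation, adaptive selection, Tukey HSD, covariance."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import tukey_hsd as scipy_tukey

import intego as ig
from intego.evaluation import DegenerateDataError, DisjointnessError, ECFormatError

from conftest import oracle_diff_g, oracle_logfc

# Reference three-group dataset; adjusted p-values computed independently with
# R's TukeyHSD (aov + TukeyHSD, R 4.3) and frozen here.
TUKEY_GROUPS = {
    "A": [24.5, 23.5, 26.4, 27.1, 29.9],
    "B": [28.4, 34.2, 29.5, 32.2, 30.1],
    "C": [26.1, 28.3, 24.3, 26.2, 27.8],
}
TUKEY_R_PADJ = {("A", "B"): 0.0144483267, ("A", "C"): 0.9803107241,
                ("B", "C"): 0.0203311367}


def constant_sim(genes, value):
    from itertools import combinations
    return {pair: value for pair in combinations(sorted(genes), 2)}


def two_group_sim(gi, gj, intra, inter):
    """Similarity table with uniform intra-group and inter-group values."""
    from itertools import combinations
    sim = {}
    for a, b in combinations(sorted(set(gi) | set(gj)), 2):
        same = (a in gi) == (b in gi)
        sim[(a, b)] = intra if same else inter
    return sim


class TestECMap:
    def test_incomplete_ec_rejected(self):
        with pytest.raises(ECFormatError):
            ig.ECMap(groups={"1.1.1.-": frozenset({"a", "b"})})

    def test_load_drops_small_groups(self, tmp_path):
        path = tmp_path / "ec.tsv"
        path.write_text("g1\t1.1.1.1\ng2\t1.1.1.1\ng3\t2.2.2.2\n")
        ecmap = ig.load_ec_table(path)
        assert ecmap.ecs == ["1.1.1.1"]

    def test_background_is_group_union(self):
        ecmap = ig.ECMap(groups={
            "1.1.1.1": frozenset({"g1", "g2"}),
            "2.2.2.2": frozenset({"g2", "g3"}),
        })
        assert ig.build_background(ecmap).genes == {"g1", "g2", "g3"}

    def test_empty_background_rejected(self, tmp_path):
        path = tmp_path / "ec.tsv"
        path.write_text("g1\t1.1.1.1\n")  # single-gene group is dropped
        with pytest.raises(ValueError):
            ig.build_background(ig.load_ec_table(path))

    def test_disjoint_partners_respect_overlap(self):
        ecmap = ig.ECMap(groups={
            "1.1.1.1": frozenset({"g1", "g2"}),
            "2.2.2.2": frozenset({"g2", "g3"}),
            "3.3.3.3": frozenset({"g4", "g5"}),
        })
        assert ecmap.disjoint_partners("1.1.1.1") == ["3.3.3.3"]


class TestDiffG:
    def test_constant_similarity_scores_zero(self):
        gi, gj = {"a", "b", "c"}, {"x", "y"}
        sim = constant_sim(gi | gj, 0.4)
        assert ig.diff_g(sim, "a", gi, gj, c=0.001) == pytest.approx(0.0)

    def test_perfect_separation_closed_form(self):
        gi, gj = {"a", "b"}, {"x", "y"}
        sim = two_group_sim(gi, gj, intra=1.0, inter=0.0)
        expected = math.log(1.001 / 0.001)
        assert ig.diff_g(sim, "a", gi, gj, c=0.001) == pytest.approx(expected)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        gi, gj = ["a", "b", "c"], ["x", "y"]
        from itertools import combinations
        sim = {p: float(rng.uniform(0, 1))
               for p in combinations(sorted(gi + gj), 2)}
        for g in gi:
            assert ig.diff_g(sim, g, gi, gj, c=0.01) == pytest.approx(
                oracle_diff_g(sim, g, set(gi), set(gj), 0.01), abs=1e-12
            )

    def test_count_multipliers_cancel_into_means(self):
        """The printed formula's |G(ei)| x / |G(ej)| x multipliers are exactly
        a ratio of means once the intra set excludes the focal gene."""
        rng = np.random.default_rng(17)
        from itertools import combinations
        gi, gj = ["a", "b", "c", "d"], ["x", "y", "z"]
        sim = {p: float(rng.uniform(0, 1))
               for p in combinations(sorted(gi + gj), 2)}
        for g in gi:
            mean_form = ig.diff_g(sim, g, gi, gj, c=0.001)
            count_form = oracle_diff_g(sim, g, set(gi), set(gj), 0.001)
            assert mean_form == pytest.approx(count_form, abs=1e-12)

    def test_overlapping_groups_rejected(self):
        sim = constant_sim({"a", "b", "x"}, 0.5)
        with pytest.raises(DisjointnessError):
            ig.diff_g(sim, "a", {"a", "b"}, {"b", "x"}, c=0.001)

    def test_gene_must_belong_to_group(self):
        sim = constant_sim({"a", "b", "x"}, 0.5)
        with pytest.raises(ValueError):
            ig.diff_g(sim, "x", {"a", "b"}, {"x"}, c=0.001)

    def test_locality_third_group_irrelevant(self):
        """diff_g(e1, e2) never touches genes outside e1 ∪ e2."""
        gi, gj = {"a", "b"}, {"x", "y"}
        sim = two_group_sim(gi, gj, intra=0.9, inter=0.1)
        base = ig.diff_g(sim, "a", gi, gj, c=0.001)
        sim_more = dict(sim)
        for g in sorted(gi | gj):
            sim_more[tuple(sorted((g, "zz")))] = 0.77
        assert ig.diff_g(sim_more, "a", gi, gj, c=0.001) == pytest.approx(base)


class TestLogFC:
    def _ecmap(self):
        return ig.ECMap(groups={
            "1.1.1.1": frozenset({"a", "b"}),
            "2.2.2.2": frozenset({"x", "y"}),
        })

    def test_symmetric_structure_gives_equal_scores(self):
        ecmap = self._ecmap()
        sim = two_group_sim({"a", "b"}, {"x", "y"}, intra=0.9, inter=0.2)
        assert ig.logfc(sim, ecmap, "1.1.1.1") == pytest.approx(
            ig.logfc(sim, ecmap, "2.2.2.2")
        )

    def test_perfect_separation_value(self):
        ecmap = self._ecmap()
        sim = two_group_sim({"a", "b"}, {"x", "y"}, intra=1.0, inter=0.0)
        assert ig.logfc(sim, ecmap, "1.1.1.1") == pytest.approx(
            math.log(1.001 / 0.001), abs=1e-9
        )

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(23)
        groups = {
            "1.1.1.1": frozenset({"a", "b", "c"}),
            "2.2.2.2": frozenset({"x", "y"}),
            "3.3.3.3": frozenset({"p", "q", "r"}),
        }
        from itertools import combinations
        universe = sorted(set().union(*groups.values()))
        sim = {p: float(rng.uniform(0, 1)) for p in combinations(universe, 2)}
        ecmap = ig.ECMap(groups=groups)
        for ec in ecmap.ecs:
            assert ig.logfc(sim, ecmap, ec) == pytest.approx(
                oracle_logfc(sim, {e: set(g) for e, g in groups.items()}, ec, 0.001),
                abs=1e-12,
            )

    def test_intra_similarity_monotonicity(self):
        ecmap = self._ecmap()
        low = two_group_sim({"a", "b"}, {"x", "y"}, intra=0.5, inter=0.2)
        high = two_group_sim({"a", "b"}, {"x", "y"}, intra=0.8, inter=0.2)
        assert ig.logfc(high, ecmap, "1.1.1.1") > ig.logfc(low, ecmap, "1.1.1.1")

    def test_no_disjoint_partner_flagged(self):
        ecmap = ig.ECMap(groups={
            "1.1.1.1": frozenset({"a", "b"}),
            "2.2.2.2": frozenset({"b", "c"}),
        })
        sim = constant_sim({"a", "b", "c"}, 0.5)
        with pytest.raises(ValueError):
            ig.logfc(sim, ecmap, "1.1.1.1")

    def test_rank_normalized_distances_stay_positive(self, fig1):
        """1 − sim + c > 0 holds for every rank-normalized similarity."""
        bg = ig.BackgroundSet(genes=frozenset(fig1.annotations.gene_universe))
        db = ig.build_genesimdb(["yu", "schlicker"], bg, set(), fig1.context)
        distances = 1.0 - db.rank_sims + 0.001
        assert (distances > 0).all().all()


class TestEvaluate:
    def test_single_method_single_pair(self):
        ecmap = ig.ECMap(groups={
            "1.1.1.1": frozenset({"a", "b"}),
            "2.2.2.2": frozenset({"x", "y"}),
        })
        sim = two_group_sim({"a", "b"}, {"x", "y"}, intra=0.9, inter=0.1)
        result = ig.evaluate({"max": sim}, ecmap)
        assert result.table.shape == (1, 2)
        assert result.table.loc["max", "1.1.1.1"] == pytest.approx(
            ig.logfc(sim, ecmap, "1.1.1.1")
        )

    def test_shuffled_measure_scores_lower(self, small_benchmarks):
        bench = small_benchmarks[0]
        ctx = ig.SimilarityContext.build(bench.graph, bench.annotations)
        bg = ig.BackgroundSet(genes=frozenset(bench.annotations.gene_universe))
        db = ig.build_genesimdb(["schlicker"], bg, set(), ctx)
        clean = db.rank_sims["schlicker"]
        shuffled = ig.corrupt_measure(clean, fraction=1.0, seed=99)
        result = ig.evaluate(
            {"clean": clean.to_dict(), "shuffled": shuffled.to_dict()}, bench.ec
        )
        medians = result.medians()
        assert medians["clean"] > medians["shuffled"]

    def test_invariant_to_ec_order(self):
        groups = {
            "1.1.1.1": frozenset({"a", "b"}),
            "2.2.2.2": frozenset({"x", "y"}),
            "3.3.3.3": frozenset({"p", "q"}),
        }
        sim = constant_sim({"a", "b", "x", "y", "p", "q"}, 0.5)
        r1 = ig.evaluate({"m": sim}, ig.ECMap(groups=groups))
        r2 = ig.evaluate({"m": sim}, ig.ECMap(groups=dict(reversed(list(groups.items())))))
        pd.testing.assert_frame_equal(r1.table, r2.table)


class TestSelection:
    def _result(self, vectors):
        return ig.LogFCResult(table=pd.DataFrame.from_dict(
            vectors, orient="index", columns=["e1", "e2", "e3"]
        ))

    def test_single_candidate(self):
        result = self._result({"max": [1.0, 2.0, 3.0]})
        assert ig.select_best_method(result).winner == "max"

    def test_dominant_candidate_wins(self):
        result = self._result({"good": [5.0, 5.0, 5.0], "bad": [1.0, 1.0, 1.0]})
        report = ig.select_best_method(result)
        assert report.winner == "good"
        assert report.ranking == ("good", "bad")

    def test_median_tie_broken_by_mean_then_name(self):
        result = self._result({
            "b": [1.0, 2.0, 9.0],   # median 2, mean 4
            "a": [1.0, 2.0, 3.0],   # median 2, mean 2
            "c": [1.0, 2.0, 9.0],   # ties b on both; name breaks
        })
        assert ig.select_best_method(result).ranking == ("b", "c", "a")

    def test_all_undefined_rejected(self):
        result = ig.LogFCResult(table=pd.DataFrame(
            {"e1": [np.nan], "e2": [np.nan]}, index=["m"]
        ))
        with pytest.raises(ValueError):
            ig.select_best_method(result)


class TestBestPerEC:
    def test_total_dominance(self):
        table = pd.DataFrame({"e1": [2.0, 1.0], "e2": [2.0, 1.0]},
                             index=["A", "B"])
        counts, ties = ig.best_per_ec(ig.LogFCResult(table=table))
        assert counts == {"A": 2, "B": 0}
        assert ties == {}

    def test_identical_vectors_all_tied(self):
        table = pd.DataFrame({"e1": [1.0, 1.0], "e2": [2.0, 2.0]},
                             index=["A", "B"])
        counts, ties = ig.best_per_ec(ig.LogFCResult(table=table))
        assert counts == {"A": 2, "B": 2}
        assert set(ties) == {"e1", "e2"}

    def test_counts_match_argmax_recount(self, small_benchmarks):
        bench = small_benchmarks[1]
        ctx = ig.SimilarityContext.build(bench.graph, bench.annotations)
        bg = ig.BackgroundSet(genes=frozenset(bench.annotations.gene_universe))
        db = ig.build_genesimdb(["yu", "schlicker"], bg, set(), ctx)
        result = ig.evaluate(
            {m: db.rank_sims[m].to_dict() for m in ["yu", "schlicker"]}, bench.ec
        )
        counts, _ = ig.best_per_ec(result)
        for method in result.methods:
            expected = sum(
                1 for ec in result.ecs
                if result.table[ec].dropna().max() == result.table.loc[method, ec]
            )
            assert counts[method] == expected


class TestTukey:
    def _result_from_groups(self, groups):
        ecs = [f"e{i}" for i in range(len(next(iter(groups.values()))))]
        return ig.LogFCResult(table=pd.DataFrame(
            {e: {m: groups[m][i] for m in groups} for i, e in enumerate(ecs)}
        ))

    def test_identical_groups_not_significant(self):
        result = self._result_from_groups({
            "m1": [1.0, 2.0, 3.0, 4.0], "m2": [1.0, 2.0, 3.0, 4.0]
        })
        table = ig.tukey_compare(result)
        assert float(table["p_adj"].iloc[0]) == pytest.approx(1.0, abs=1e-6)

    def test_matches_r_reference_values(self):
        result = self._result_from_groups(TUKEY_GROUPS)
        table = ig.tukey_compare(result)
        for _, row in table.iterrows():
            key = tuple(sorted((row["group1"], row["group2"])))
            assert float(row["p_adj"]) == pytest.approx(TUKEY_R_PADJ[key], abs=1e-3)

    def test_matches_scipy_oracle(self):
        result = self._result_from_groups(TUKEY_GROUPS)
        table = ig.tukey_compare(result)
        ref = scipy_tukey(*[TUKEY_GROUPS[m] for m in ["A", "B", "C"]])
        lookup = {("A", "B"): ref.pvalue[0, 1], ("A", "C"): ref.pvalue[0, 2],
                  ("B", "C"): ref.pvalue[1, 2]}
        for _, row in table.iterrows():
            key = tuple(sorted((row["group1"], row["group2"])))
            assert float(row["p_adj"]) == pytest.approx(lookup[key], abs=1e-9)

    def test_relabelling_invariance(self):
        result = self._result_from_groups(TUKEY_GROUPS)
        relabeled = self._result_from_groups(
            {"Z": TUKEY_GROUPS["A"], "Q": TUKEY_GROUPS["B"], "W": TUKEY_GROUPS["C"]}
        )
        p1 = sorted(float(p) for p in ig.tukey_compare(result)["p_adj"])
        p2 = sorted(float(p) for p in ig.tukey_compare(relabeled)["p_adj"])
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_degenerate_variance_rejected(self):
        result = self._result_from_groups({
            "m1": [1.0, 1.0, 1.0], "m2": [2.0, 2.0, 2.0]
        })
        with pytest.raises(DegenerateDataError):
            ig.tukey_compare(result)


class TestCovariance:
    def test_self_covariance_is_variance(self):
        sim = {("a", "b"): 0.1, ("a", "c"): 0.5, ("b", "c"): 0.9}
        cov, n = ig.covariance_external(sim, dict(sim))
        assert n == 3
        assert cov == pytest.approx(np.var([0.1, 0.5, 0.9], ddof=1))

    def test_constant_external_scores_zero(self):
        sim = {("a", "b"): 0.1, ("a", "c"): 0.5, ("b", "c"): 0.9}
        external = {p: 7.0 for p in sim}
        assert ig.covariance_external(sim, external)[0] == pytest.approx(0.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        pairs = [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")]
        sim = {p: float(rng.uniform()) for p in pairs}
        external = {p: float(rng.uniform()) for p in pairs[:3]}
        cov, n = ig.covariance_external(sim, external)
        shared = pairs[:3]
        x = np.array([sim[p] for p in shared])
        y = np.array([external[p] for p in shared])
        expected = float(np.sum((x - x.mean()) * (y - y.mean())) / (len(shared) - 1))
        assert n == 3
        assert cov == pytest.approx(expected, abs=1e-12)

    def test_too_few_shared_pairs(self):
        with pytest.raises(ValueError):
            ig.covariance_external({("a", "b"): 0.1}, {("a", "b"): 0.2})


class TestBackgroundSubsample:
    def test_full_coverage_matches_direct_logfc(self):
        groups = {
            "1.1.1.1": frozenset({"a", "b"}),
            "2.2.2.2": frozenset({"x", "y"}),
        }
        ecmap = ig.ECMap(groups=groups)
        sim = two_group_sim({"a", "b"}, {"x", "y"}, intra=0.9, inter=0.1)
        table = ig.background_subsample_experiment(
            sim, ecmap, fractions=[1.0], repeats=2, seed=0
        )
        direct = np.mean([ig.logfc(sim, ecmap, e) for e in ecmap.ecs])
        assert np.allclose(table["mean_logfc"], direct)
        assert (table["n_computable_ecs"] == 2).all()
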