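import math

import numpy as np
import pandas as pd
import pytest

from icgec.downstream import (
    NEGATIVE_SCORE_RESET,
    benjamini_hochberg,
    bin_scores,
    classify_edg_ecg,
    expression_epigenetic_coupling,
    hypergeometric_enrichment,
    identify_ddsg,
    identify_ddug,
    mark_dynamics_correlation,
    permutation_overlap_test,
    relative_change,
    score_table_entropy,
    shannon_entropy,
    two_fold_dynamic_genes,
)


class TestEdgEcg:
    def test_quartile_split(self):
        scores = pd.Series(range(1, 9), index=[f"g{i}" for i in range(8)], dtype=float)
        edg, ecg = classify_edg_ecg(scores)
        assert edg == ["g0", "g1"] and ecg == ["g6", "g7"]

    def test_ties_broken_by_stable_order(self):
        scores = pd.Series([0.5] * 8, index=[f"g{i}" for i in range(8)])
        edg, ecg = classify_edg_ecg(scores)
        assert edg == ["g0", "g1"] and ecg == ["g6", "g7"]
        assert not set(edg) & set(ecg)

    def test_ceiling_rule(self):
        n = 4001
        scores = pd.Series(np.linspace(-1, 1, n), index=[f"g{i}" for i in range(n)])
        edg, ecg = classify_edg_ecg(scores)
        assert len(edg) == len(ecg) == 1001


class TestBinScores:
    def test_equal_bins(self):
        scores = pd.Series(np.arange(100.0), index=[f"g{i}" for i in range(100)])
        bins, _ = bin_scores(scores, 20)
        assert [len(b) for b in bins] == [5] * 20

    def test_query_counts_in_bottom_bin(self):
        scores = pd.Series(np.arange(100.0), index=[f"g{i}" for i in range(100)])
        bins, counts = bin_scores(scores, 20, query={f"g{i}" for i in range(5)})
        assert counts.tolist() == [5] + [0] * 19

    def test_planted_dynamic_genes_concentrate_in_low_bins(self, sim_pair_small,
                                                           sim_result_small):
        from scipy.stats import spearmanr

        _, _, truth, pair = sim_pair_small
        query = set(truth.dynamic_genes) & set(pair.gene_ids)
        _, counts = bin_scores(sim_result_small.gene_scores, 20, query=query)
        rho = spearmanr(np.arange(20), counts).statistic
        assert rho < 0


class TestPermutationTest:
    def test_full_overlap_ties_give_p_one(self):
        genes = {f"g{i}" for i in range(20)}
        cats = {"a": set(list(genes)[:8]), "b": set(list(genes)[8:])}
        targets = {"a": genes, "b": genes}  # every gene is in the target class
        res = permutation_overlap_test(cats, targets, n_perm=100, seed=0)
        assert res["a"].observed_proportion == 1.0
        assert res["a"].empirical_p == 1.0

    def test_unreachable_overlap_gives_add_one_minimum(self):
        # category "a" sits entirely inside its class; permutations draw its 5
        # members from a pool of 100, so matching all 5 has probability
        # 1/C(100,5) ~ 1e-8 and never occurs: p = 1/1001
        pool = [f"g{i}" for i in range(100)]
        cats = {"a": set(pool[:5]), "b": set(pool[5:])}
        targets = {"a": set(pool[:5]), "b": set()}
        res = permutation_overlap_test(cats, targets, n_perm=1000, seed=1)
        assert res["a"].observed_count == 5
        assert (res["a"].permuted_counts < 5).all()
        assert res["a"].empirical_p == pytest.approx(1 / 1001)

    def test_seed_changes_null_not_observation(self):
        pool = [f"g{i}" for i in range(30)]
        cats = {"a": set(pool[:10]), "b": set(pool[10:])}
        targets = {"a": set(pool[5:15]), "b": set(pool[:5])}
        r1 = permutation_overlap_test(cats, targets, n_perm=50, seed=1)
        r2 = permutation_overlap_test(cats, targets, n_perm=50, seed=2)
        assert r1["a"].observed_count == r2["a"].observed_count
        assert not np.array_equal(r1["a"].permuted_counts, r2["a"].permuted_counts)

    def test_reproducible_under_seed_and_never_zero(self):
        pool = [f"g{i}" for i in range(30)]
        cats = {"a": set(pool[:10]), "b": set(pool[10:])}
        targets = {"a": set(pool[:10]), "b": set(pool[10:])}
        r1 = permutation_overlap_test(cats, targets, n_perm=200, seed=7)
        r2 = permutation_overlap_test(cats, targets, n_perm=200, seed=7)
        assert np.array_equal(r1["a"].permuted_counts, r2["a"].permuted_counts)
        assert r1["a"].empirical_p > 0

    def test_overlapping_categories_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            permutation_overlap_test({"a": {"g1"}, "b": {"g1"}},
                                     {"a": {"g1"}, "b": {"g1"}}, 10, 0)


class TestEntropy:
    def test_uniform_profile_attains_ln_k(self):
        assert shannon_entropy([0.5, 0.5, 0.5, 0.5]) == pytest.approx(math.log(4), abs=1e-12)

    def test_near_degenerate_profile(self):
        assert shannon_entropy([1.0, 1e-6, 1e-6, 1e-6]) < 1e-4

    def test_negative_reset_rule(self):
        h_neg = shannon_entropy([-0.3, 0.5, 0.5, 0.5])
        h_reset = shannon_entropy([NEGATIVE_SCORE_RESET, 0.5, 0.5, 0.5])
        assert h_neg == pytest.approx(h_reset)
        assert h_neg == pytest.approx(math.log(3), abs=1e-4)

    def test_entropy_bounds(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.uniform(-1, 1, size=(50, 4)),
                             index=[f"g{i}" for i in range(50)],
                             columns=list("ABCD"))
        ent = score_table_entropy(table)
        assert (ent >= 0).all() and (ent <= math.log(4) + 1e-12).all()


def ddsg_bruteforce(table, entropy_quantile, fold, score_quantile):
    """Literal application of the three filters, one gene at a time."""
    reset = table.values.astype(float).copy()
    reset[reset < 0] = NEGATIVE_SCORE_RESET
    ent = np.array([shannon_entropy(row) for row in table.values])
    out = {d: [] for d in table.columns}
    for i, g in enumerate(table.index):
        if ent[i] > np.quantile(ent, entropy_quantile):
            continue
        for j, d in enumerate(table.columns):
            others = [reset[i, k] for k in range(table.shape[1]) if k != j]
            if (reset[i, j] * fold <= min(others)
                    and reset[i, j] <= np.quantile(reset, score_quantile)):
                out[d].append(g)
                break
    return out


class TestDdsgDdug:
    @pytest.fixture
    def toy_table(self):
        # g0: strong A-specific drop; g1: marginal (2x not 2.5x ratio);
        # the rest near-uniform high scores
        rows = {
            "g0": [0.01, 0.60, 0.65, 0.70],
            "g1": [0.30, 0.60, 0.62, 0.64],
            "g2": [0.80, 0.82, 0.81, 0.80],
            "g3": [0.79, 0.80, 0.83, 0.80],
            "g4": [0.81, 0.80, 0.80, 0.82],
            "g5": [0.80, 0.81, 0.79, 0.80],
            "g6": [0.78, 0.80, 0.80, 0.81],
            "g7": [0.80, 0.80, 0.82, 0.79],
            "g8": [0.82, 0.79, 0.80, 0.80],
            "g9": [0.80, 0.80, 0.80, 0.80],
        }
        return pd.DataFrame.from_dict(rows, orient="index", columns=list("ABCD")).astype(float)

    def test_singleton_recovered(self, toy_table):
        out = identify_ddsg(toy_table)
        assert out["A"] == ["g0"]
        assert all(not v for d, v in out.items() if d != "A")

    def test_matches_bruteforce(self, toy_table):
        assert identify_ddsg(toy_table) == ddsg_bruteforce(toy_table, 0.20, 2.5, 0.05)

    def test_relaxed_fold_adds_marginal_gene(self, toy_table):
        out = identify_ddsg(toy_table, fold=1.5)
        assert out["A"] == ["g0", "g1"]
        assert out == ddsg_bruteforce(toy_table, 0.20, 1.5, 0.05)

    def test_uniform_table_yields_nothing(self):
        table = pd.DataFrame(0.5, index=[f"g{i}" for i in range(10)], columns=list("ABCD"))
        out = identify_ddsg(table)
        assert all(not v for v in out.values())

    def test_ddsg_direction_sets_disjoint(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.uniform(0, 1, size=(200, 4)),
                             index=[f"g{i}" for i in range(200)], columns=list("ABCD"))
        out = identify_ddsg(table)
        all_calls = [g for v in out.values() for g in v]
        assert len(all_calls) == len(set(all_calls))

    def test_ddug_uniform_high_gene_selected(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.uniform(0.1, 0.5, size=(50, 4)),
                             index=[f"g{i}" for i in range(50)], columns=list("ABCD"))
        table.loc["g0"] = [0.99, 0.99, 0.99, 0.99]
        assert "g0" in identify_ddug(table)

    def test_ddug_minimum_rule_excludes_one_low_direction(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.uniform(0.1, 0.5, size=(50, 4)),
                             index=[f"g{i}" for i in range(50)], columns=list("ABCD"))
        table.loc["g0"] = [0.99, 0.99, 0.99, 0.05]
        assert "g0" not in identify_ddug(table)

    def test_ddug_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.uniform(-0.2, 1, size=(6, 4)),
                             index=[f"g{i}" for i in range(6)], columns=list("ABCD"))
        reset = table.values.copy()
        reset[reset < 0] = NEGATIVE_SCORE_RESET
        ent = np.array([shannon_entropy(r) for r in table.values])
        expected = [g for i, g in enumerate(table.index)
                    if ent[i] >= np.quantile(ent, 0.8)
                    and reset[i].min() > np.quantile(reset, 0.8)]
        assert identify_ddug(table) == expected


class TestEnrichment:
    def test_identical_sets_p_one(self):
        s = {f"g{i}" for i in range(10)}
        assert hypergeometric_enrichment(s, s, s) == pytest.approx(1.0)

    def test_closed_form_example(self):
        universe = {f"g{i}" for i in range(10)}
        annotated = {f"g{i}" for i in range(5)}
        query = {"g0", "g1"}
        assert hypergeometric_enrichment(query, annotated, universe) == pytest.approx(
            10 / 45, abs=1e-12
        )

    def test_zero_overlap_near_one(self):
        universe = {f"g{i}" for i in range(10)}
        assert hypergeometric_enrichment({"g0"}, {"g9"}, universe) > 0.05

    def test_bh_monotone_and_bounded(self):
        p = np.array([0.001, 0.02, 0.04, 0.5, 0.9])
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()
        assert (np.diff(q[np.argsort(p)]) >= -1e-15).all()


class TestMarkDynamics:
    @pytest.fixture
    def matrices(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(60)]
        marks = [f"m{j}" for j in range(5)]
        d1 = pd.DataFrame(rng.lognormal(1, 1, size=(60, 5)), index=genes, columns=marks)
        noise = rng.normal(0, 0.05, size=(60, 5))
        d2 = d1 * np.exp(noise)
        return d1, d2, genes

    def test_identical_matrices_all_one(self, matrices):
        d1, _, genes = matrices
        out = mark_dynamics_correlation(d1, d1.copy(), set(genes[:30]), set(genes[30:]))
        np.testing.assert_allclose(out["corr_a"], 1.0, atol=1e-12)

    def test_permuted_mark_sorts_first(self, matrices):
        d1, d2, genes = matrices
        rng = np.random.default_rng(6)
        group_a, group_b = set(genes[:30]), set(genes[30:])
        d2 = d2.copy()
        d2.loc[list(group_a), "m2"] = rng.permutation(d2.loc[list(group_a), "m2"].values)
        out = mark_dynamics_correlation(d1, d2, group_a, group_b)
        assert out.iloc[0]["mark"] == "m2"
        assert abs(out.iloc[0]["corr_a"]) < 0.5

    def test_spearman_invariant_to_monotone_distortion(self, matrices):
        d1, _, genes = matrices
        out = mark_dynamics_correlation(d1, d1**3, set(genes[:30]), set(genes[30:]),
                                        method="spearman")
        np.testing.assert_allclose(out["corr_a"], 1.0, atol=1e-12)
        np.testing.assert_allclose(out["corr_b"], 1.0, atol=1e-12)


class TestCoupling:
    def test_relative_change_arithmetic(self):
        assert relative_change(np.array([3.0]), np.array([1.0]))[0] == pytest.approx(0.5)
        assert relative_change(np.array([2.0]), np.array([2.0]))[0] == 0.0
        assert relative_change(np.array([0.0]), np.array([0.0]))[0] == 0.0

    def test_planted_coupled_mark_correlates(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(50)]
        e1 = {g: float(v) for g, v in zip(genes, rng.lognormal(1, 1, 50))}
        e2 = {g: float(v) for g, v in zip(genes, rng.lognormal(1, 1, 50))}
        expr_change = relative_change(np.array([e1[g] for g in genes]),
                                      np.array([e2[g] for g in genes]))
        # mark "coupled": its relative change equals the expression change
        base = rng.lognormal(1, 0.5, 50)
        m2_coupled = base * (1 - expr_change) / (1 + expr_change)
        d1 = pd.DataFrame({"coupled": base, "random": rng.lognormal(1, 1, 50)}, index=genes)
        d2 = pd.DataFrame({"coupled": m2_coupled, "random": rng.lognormal(1, 1, 50)}, index=genes)
        out = expression_epigenetic_coupling(e1, e2, d1, d2, set(genes))
        assert out["coupled"] == pytest.approx(1.0, abs=1e-9)
        assert abs(out["random"]) < 0.5


class TestTwoFold:
    def test_threshold_cases(self):
        e1 = {"up": 4.0, "flat": 1.9, "zero": 0.0}
        e2 = {"up": 1.0, "flat": 1.0, "zero": 0.0}
        out = two_fold_dynamic_genes(e1, e2)
        assert out == ["up"]
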