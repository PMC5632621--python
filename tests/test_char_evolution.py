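"""Mk1 likelihood, rate estimation and marginal ancestral reconstruction,
checked against exhaustive enumeration oracles on small trees."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from ecodelim import char_evolution as ce
from ecodelim.synthetic_data import simulate_mk_characters

from conftest import make_tree
from oracles import mk_brute_loglik, mk_brute_marginals, mk_transition_expm


class TestMk1Transition:
    def test_zero_time_is_identity(self):
        np.testing.assert_allclose(ce.mk1_transition(1.3, 0.0, 4), np.eye(4))

    def test_stationary_limit_is_uniform(self):
        P = ce.mk1_transition(5.0, 1e6, 3)
        np.testing.assert_allclose(P, np.full((3, 3), 1 / 3), atol=1e-12)

    def test_binary_closed_form_value(self):
        P = ce.mk1_transition(1.0, 1.0, 2)
        assert P[0, 0] == pytest.approx(0.5 * (1 + np.exp(-2)), abs=1e-12)

    @pytest.mark.parametrize("alpha,t,k", [(0.5, 0.3, 2), (2.0, 0.1, 3),
                                           (0.05, 4.0, 4), (1.0, 1.0, 7)])
    def test_matches_matrix_exponential(self, alpha, t, k):
        np.testing.assert_allclose(ce.mk1_transition(alpha, t, k),
                                   mk_transition_expm(alpha, t, k), atol=1e-12)
        assert ce.mk1_transition(alpha, t, k).sum(axis=1) == pytest.approx(np.ones(k))

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match="k"):
            ce.mk1_transition(1.0, 1.0, 1)


class TestMk1Loglik:
    def test_impossible_data_zero_time(self):
        tree = make_tree("(A:0.0,B:0.0);")
        ll = ce.mk1_loglik(tree, {"A": 0, "B": 1}, alpha=1.0, k=2)
        assert ll == -np.inf

    def test_all_missing_likelihood_one(self, five_tip_tree):
        ll = ce.mk1_loglik(five_tip_tree, {t: None for t in "ABCDE"}, 0.7, 3)
        assert ll == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k,seed", [(2, 0), (3, 1), (4, 2)])
    def test_pruning_equals_enumeration(self, five_tip_tree, k, seed):
        r = np.random.default_rng(seed)
        tips = {t: int(r.integers(0, k)) for t in "ABCDE"}
        tips["C"] = None  # one missing tip exercises the ones-vector rule
        for alpha in (0.1, 0.9, 3.0):
            ll = ce.mk1_loglik(five_tip_tree, tips, alpha, k)
            assert ll == pytest.approx(mk_brute_loglik(five_tip_tree, tips, alpha, k),
                                       abs=1e-9)

    def test_polytomy_handled_as_hard_multifurcation(self):
        tree = make_tree("(A:0.2,B:0.3,C:0.4,(D:0.1,E:0.2):0.3);")
        tips = {"A": 0, "B": 1, "C": 0, "D": 1, "E": 0}
        ll = ce.mk1_loglik(tree, tips, 0.8, 2)
        assert ll == pytest.approx(mk_brute_loglik(tree, tips, 0.8, 2), abs=1e-9)

    def test_unknown_tip_errors(self, five_tip_tree):
        with pytest.raises(KeyError, match="E"):
            ce.mk1_loglik(five_tip_tree, {t: 0 for t in "ABCD"}, 1.0, 2)

    def test_rerooting_invariance(self, five_tip_tree):
        tips = {"A": 0, "B": 1, "C": 2, "D": 0, "E": 1}
        ll0 = ce.mk1_loglik(five_tip_tree, tips, 0.6, 3)
        for label, frac in (("A", 0.5), ("D", 0.25)):
            t2 = make_tree(five_tip_tree.as_string(schema="newick"))
            node = t2.find_node_with_taxon_label(label)
            L = node.edge.length
            t2.reroot_at_edge(node.edge, length1=frac * L, length2=(1 - frac) * L,
                              update_bipartitions=False)
            assert ce.mk1_loglik(t2, tips, 0.6, 3) == pytest.approx(ll0, abs=1e-10)


class TestOptimizeRate:
    def test_invariant_character_pinned_to_lower_bound(self, five_tip_tree):
        rate, ll, at_bound = ce.optimize_rate(five_tip_tree, {t: 1 for t in "ABCDE"}, 3)
        assert at_bound and rate == pytest.approx(ce.RATE_BOUNDS[0], rel=1e-2)

    def test_optimum_beats_dense_grid_scan(self, five_tip_tree):
        tips = {"A": 0, "B": 1, "C": 0, "D": 2, "E": 2}
        rate, ll, _ = ce.optimize_rate(five_tip_tree, tips, 3)
        grid = np.logspace(-8, 3, 10_000)
        grid_best = max(ce.mk1_loglik(five_tip_tree, tips, a, 3) for a in grid)
        assert ll >= grid_best - 1e-6

    def test_deterministic(self, five_tip_tree):
        tips = {"A": 0, "B": 1, "C": 1, "D": 0, "E": 1}
        assert ce.optimize_rate(five_tip_tree, tips, 2) == \
            ce.optimize_rate(five_tip_tree, tips, 2)

    def test_needs_two_observed_tips(self, five_tip_tree):
        states = {t: None for t in "ABCDE"}
        states["A"] = 0
        with pytest.raises(ValueError, match="non-missing"):
            ce.optimize_rate(five_tip_tree, states, 2)

    def test_rate_recovery_from_simulated_characters(self, eight_tip_tree):
        # per-character ML estimates around the generating rate
        tips_df, _ = simulate_mk_characters(eight_tip_tree, alpha=0.5, k=2,
                                            n_chars=200, seed=11)
        arrays = ce._TreeArrays(eight_tip_tree)
        rates = []
        for col in tips_df.columns:
            states = {t: int(v) for t, v in tips_df[col].items()}
            if len(set(states.values())) < 2:
                continue  # invariant characters estimate 0
            rates.append(ce.optimize_rate(arrays, states, 2)[0])
        assert 0.2 <= np.median(rates) <= 1.2


class TestMarginalAsr:
    def test_two_tips_opposite_states_symmetric_root(self):
        tree = make_tree("(A:0.5,B:0.5);")
        asr = ce.marginal_asr(tree, {"A": 0, "B": 1}, alpha=0.7, k=2)
        root = asr.node_probs[asr.node_probs.index == "node0"]
        np.testing.assert_allclose(root[["0", "1"]].to_numpy(), [[0.5, 0.5]], atol=1e-12)

    def test_uniform_tips_near_certain_root(self, five_tip_tree):
        asr = ce.marginal_asr(five_tip_tree, {t: 1 for t in "ABCDE"}, alpha=0.01, k=3)
        internal = asr.node_probs[~asr.node_probs["is_tip"]]
        assert (internal["1"] > 0.99).all()

    @pytest.mark.parametrize("k,seed", [(2, 3), (3, 4), (4, 5)])
    def test_marginals_equal_bruteforce_conditionals(self, five_tip_tree, k, seed):
        r = np.random.default_rng(seed)
        tips = {t: int(r.integers(0, k)) for t in "ABCDE"}
        asr = ce.marginal_asr(five_tip_tree, tips, alpha=0.8, k=k)
        brute = mk_brute_marginals(five_tip_tree, tips, 0.8, k)
        for label, probs in brute.items():
            got = asr.node_probs.loc[label, [str(s) for s in range(k)]].to_numpy(float)
            np.testing.assert_allclose(got, probs, atol=1e-9)

    def test_observed_tips_have_indicator_marginals(self, five_tip_tree):
        tips = {"A": 0, "B": 1, "C": 2, "D": 1, "E": 0}
        asr = ce.marginal_asr(five_tip_tree, tips, alpha=0.5, k=3)
        for t, s in tips.items():
            row = asr.node_probs.loc[t, ["0", "1", "2"]].to_numpy(float)
            expect = np.zeros(3)
            expect[s] = 1.0
            np.testing.assert_allclose(row, expect, atol=1e-12)

    def test_node_vectors_normalized(self, five_tip_tree):
        asr = ce.marginal_asr(five_tip_tree, {"A": 0, "B": 1, "C": 0, "D": 1, "E": 0},
                              alpha=0.3, k=2)
        sums = asr.node_probs[["0", "1"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)


class TestAsrReport:
    @pytest.fixture
    def matrix(self):
        return pd.DataFrame({
            "hairpoint": ["absent", "erect", "reflexed", "erect", np.nan],
            "lamella_height": [1, 2, 7, 2, 1],
        }, index=pd.Index(list("ABCDE"), name="taxon"))

    def test_repeat_runs_identical(self, five_tip_tree, matrix):
        trees = {"its1": five_tip_tree}
        r1 = ce.asr_report(trees, matrix)
        r2 = ce.asr_report(trees, matrix)
        pd.testing.assert_frame_equal(r1, r2)

    def test_dropping_character_removes_it(self, five_tip_tree, matrix):
        rep = ce.asr_report({"t": five_tip_tree}, matrix, characters=["hairpoint"])
        assert set(rep["character"]) == {"hairpoint"}

    def test_row_count_is_nodes_times_characters(self, five_tip_tree, matrix):
        rep = ce.asr_report({"t": five_tip_tree}, matrix)
        n_nodes = 9  # 5 tips + 4 internal
        assert len(rep) == n_nodes * 2

    def test_label_mismatch_lists_offenders(self, five_tip_tree, matrix):
        with pytest.raises(ValueError, match="E"):
            ce.asr_report({"t": five_tip_tree}, matrix.drop(index="E"))

    def test_state_mapping_bins_lamellae(self, five_tip_tree, matrix):
        smap = {i: ("low" if i <= 2 else "high") for i in range(1, 8)}
        rep = ce.asr_report({"t": five_tip_tree}, matrix,
                            characters=["lamella_height"],
                            state_maps={"lamella_height": smap})
        state_cols = [c for c in rep.columns
                      if c not in {"tree", "character", "node", "is_tip",
                                   "ml_rate", "log_likelihood", "rate_at_bound"}]
        assert sorted(state_cols) == ["high", "low"]

    def test_clade_fixed_states_recovered(self):
        # two 5-tip clades, state fixed per clade, long stem between them
        nwk = ("((A1:0.05,(A2:0.05,(A3:0.05,(A4:0.05,A5:0.05):0.05):0.05):0.05):1.0,"
               "(B1:0.05,(B2:0.05,(B3:0.05,(B4:0.05,B5:0.05):0.05):0.05):0.05):1.0);")
        tree = make_tree(nwk)
        states = {f"A{i}": 0 for i in range(1, 6)} | {f"B{i}": 1 for i in range(1, 6)}
        rate, _, _ = ce.optimize_rate(tree, states, 2)
        asr = ce.marginal_asr(tree, states, rate, 2)
        internal = asr.node_probs[~asr.node_probs["is_tip"]]
        # every within-clade ancestor should be reconstructed confidently;
        # only the root (between the clades) may stay ambiguous
        confident = (internal[["0", "1"]].max(axis=1) > 0.95).sum()
        assert confident >= len(internal) - 1


def test_read_tree_fills_missing_lengths(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((A,B),C);\n")
    tree = ce.read_tree(p)
    lengths = [e.length for e in tree.preorder_edge_iter()
               if e.head_node.parent_node is not None]
    assert lengths == [1.0] * len(lengths)


def test_nexus_morph_export(tmp_path, five_tip_tree):
    matrix = pd.DataFrame({"hairpoint": ["absent", "erect", "erect", "reflexed", None]},
                          index=pd.Index(list("ABCDE"), name="taxon"))
    out = tmp_path / "m.nex"
    ce.write_nexus_morph(matrix, out)
    text = out.read_text()
    assert text.startswith("#NEXUS") and "NTAX=5" in text and "?" in text
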