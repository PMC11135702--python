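import math

import numpy as np
import pandas as pd
import pytest

from conftest import enum_loglik_posteriors, random_rooted_tree
from orgatlas import asr
from orgatlas.phylotree import label_internal_nodes, parse_newick


def make_tree(newick):
    t = parse_newick(newick)
    t.is_rooted = True
    label_internal_nodes(t)
    return t


class TestLoglik:
    def test_cherry_closed_form(self):
        # 2 tips, branches t each, states (1,1):
        # L = 1/2 [P11(t)^2 + P01(t)^2]
        t_len, q = 0.7, 0.4
        tree = make_tree(f"(A:{t_len},B:{t_len});")
        char = asr.BinaryCharacter("x", {"A": 1, "B": 1})
        e = math.exp(-2 * q * t_len)
        stay, flip = 0.5 * (1 + e), 0.5 * (1 - e)
        expected = 0.5 * (stay**2 + flip**2)
        assert abs(asr.loglik(tree, char, q) - math.log(expected)) < 1e-12

    def test_constant_character_limit_half(self):
        tree = make_tree("((A:1,B:1):1,C:2);")
        char = asr.BinaryCharacter("x", {"A": 1, "B": 1, "C": 1})
        assert abs(asr.loglik(tree, char, 1e-9) - math.log(0.5)) < 1e-6

    def test_nonpositive_rate_errors(self):
        tree = make_tree("(A:1,B:1);")
        char = asr.BinaryCharacter("x", {"A": 1, "B": 0})
        with pytest.raises(ValueError):
            asr.loglik(tree, char, 0.0)

    def test_child_order_invariance(self, rng):
        t1 = make_tree("((A:1,B:2):0.5,C:1.5);")
        t2 = make_tree("(C:1.5,(B:2,A:1):0.5);")
        char = asr.BinaryCharacter("x", {"A": 1, "B": 0, "C": 1})
        assert abs(asr.loglik(t1, char, 0.3) - asr.loglik(t2, char, 0.3)) < 1e-12

    def test_matches_enumeration_5_tips(self, rng):
        tree, labels = random_rooted_tree(rng, 5)
        states = {l: int(rng.integers(2)) for l in labels}
        char = asr.BinaryCharacter("x", states)
        ll_oracle, _ = enum_loglik_posteriors(tree, states, 0.3)
        assert abs(asr.loglik(tree, char, 0.3) - ll_oracle) < 1e-12


class TestMarginalPosteriors:
    def test_all_present_small_q(self):
        tree = make_tree("((A:1,B:1):1,C:2);")
        char = asr.BinaryCharacter("x", {"A": 1, "B": 1, "C": 1})
        post = asr.marginal_posteriors(tree, char, 1e-8)
        for lab in ("N0", "N1"):
            assert post[lab] > 1 - 1e-6

    def test_symmetric_cherry_is_half(self):
        tree = make_tree("(A:1,B:1);")
        char = asr.BinaryCharacter("x", {"A": 1, "B": 0})
        post = asr.marginal_posteriors(tree, char, 0.8)
        assert post["N0"] == pytest.approx(0.5, abs=1e-12)

    def test_matches_enumeration_4_tips(self, rng):
        tree, labels = random_rooted_tree(rng, 4)
        states = {l: int(rng.integers(2)) for l in labels}
        char = asr.BinaryCharacter("x", states)
        _, oracle = enum_loglik_posteriors(tree, states, 0.5)
        post = asr.marginal_posteriors(tree, char, 0.5)
        for lab, v in oracle.items():
            assert abs(post[lab] - v) < 1e-10

    def test_tip_posteriors_equal_observations(self, rng):
        tree, labels = random_rooted_tree(rng, 5)
        states = {l: int(rng.integers(2)) for l in labels}
        post = asr.marginal_posteriors(
            tree, asr.BinaryCharacter("x", states), 0.4
        )
        for l in labels:
            assert post[l] == states[l]

    def test_er_flip_symmetry(self, rng):
        tree, labels = random_rooted_tree(rng, 6)
        states = {l: int(rng.integers(2)) for l in labels}
        char = asr.BinaryCharacter("x", states)
        p = asr.marginal_posteriors(tree, char, 0.37)
        pf = asr.marginal_posteriors(tree, char.flipped(), 0.37)
        for lab in p:
            assert abs(p[lab] - (1.0 - pf[lab])) < 1e-14

    def test_normalization_property(self, rng):
        # P(present) in [0,1] everywhere over fuzzed cases
        for _ in range(20):
            n = int(rng.integers(2, 7))
            tree, labels = random_rooted_tree(rng, n)
            states = {l: int(rng.integers(2)) for l in labels}
            q = float(rng.uniform(0.01, 3.0))
            post = asr.marginal_posteriors(
                tree, asr.BinaryCharacter("x", states), q
            )
            assert all(0.0 <= v <= 1.0 for v in post.values())


class TestFitRate:
    def test_constant_character_errors(self):
        tree = make_tree("(A:1,B:1);")
        with pytest.raises(asr.ConstantCharacterError):
            asr.fit_rate(tree, asr.BinaryCharacter("x", {"A": 1, "B": 1}))

    def test_beats_100_point_grid(self, rng):
        tree, labels = random_rooted_tree(rng, 6)
        states = {l: int(rng.integers(2)) for l in labels}
        states[labels[0]] = 1 - states[labels[1]]  # ensure non-constant
        char = asr.BinaryCharacter("x", states)
        bounds = (1e-6, 100.0)
        q_hat, ll_hat = asr.fit_rate(tree, char, bounds)
        assert bounds[0] <= q_hat <= bounds[1]
        for q in np.geomspace(*bounds, 100):
            assert ll_hat >= asr.loglik(tree, char, float(q)) - 1e-6

    def test_flip_symmetry_of_rate(self, rng):
        tree, labels = random_rooted_tree(rng, 6)
        states = {l: int(rng.integers(2)) for l in labels}
        states[labels[0]] = 1 - states[labels[1]]
        char = asr.BinaryCharacter("x", states)
        q1, _ = asr.fit_rate(tree, char)
        q2, _ = asr.fit_rate(tree, char.flipped())
        assert q1 == pytest.approx(q2, rel=1e-6)


class TestAsrAll:
    def _presence(self):
        return pd.DataFrame(
            [[1, 1, 1], [1, 0, 0], [0, 0, 0]],
            index=["OGc1", "OGv", "OGc0"],
            columns=["A", "B", "C"],
        )

    def test_constant_rows_get_degenerate_posteriors(self):
        tree = make_tree("((A:1,B:1):1,C:2);")
        post, rates = asr.asr_all(self._presence(), tree)
        wide = post.pivot(index="og_id", columns="node", values="p_present")
        assert (wide.loc["OGc1"] == 1.0).all()
        assert (wide.loc["OGc0"] == 0.0).all()
        r = rates.set_index("og_id")
        assert r.at["OGc1", "constant"] and r.at["OGc1", "q_hat"] == 0.0
        assert not r.at["OGv", "constant"]

    def test_row_permutation_same_table(self):
        tree = make_tree("((A:1,B:1):1,C:2);")
        p = self._presence()
        post1, _ = asr.asr_all(p, tree)
        post2, _ = asr.asr_all(p.iloc[::-1], tree)
        pd.testing.assert_frame_equal(post1, post2)

    def test_missing_tree_tip_scored_absent(self):
        tree = make_tree("((A:1,B:1):1,C:2);")
        p = pd.DataFrame([[1, 1]], index=["OG1"], columns=["A", "B"])
        post, _ = asr.asr_all(p, tree)
        assert not post.empty  # C imputed absent: character non-constant


class TestCallGains:
    def _table(self, pa, pp):
        return pd.DataFrame(
            {"og_id": ["OG1", "OG1"], "node": ["N1", "N0"],
             "p_present": [pa, pp]}
        )

    def _tree(self):
        return make_tree("((A:1,B:1):1,C:2);")  # N0 root, N1 = (A,B)

    def _anc(self, tree):
        node = next(
            nd for nd in tree.preorder_node_iter()
            if not nd.is_leaf() and nd.label == "N1"
        )
        return {"anc": node}

    def test_gained(self):
        tree = self._tree()
        t = asr.call_gains(self._table(0.9, 0.1), tree, self._anc(tree), 0.75)
        assert t["anc"] == {"OG1"}

    def test_ambiguous_parent_depends_on_reading(self):
        tree = self._tree()
        default = asr.call_gains(
            self._table(0.9, 0.5), tree, self._anc(tree), 0.75
        )
        lax = asr.call_gains(
            self._table(0.9, 0.5), tree, self._anc(tree), 0.75,
            parent_reading="lax",
        )
        assert not default["anc"]
        assert lax["anc"] == {"OG1"}

    def test_exact_threshold_not_gained(self):
        tree = self._tree()
        t = asr.call_gains(self._table(0.75, 0.1), tree, self._anc(tree), 0.75)
        assert not t["anc"]

    def test_root_ancestor_errors(self):
        tree = self._tree()
        with pytest.raises(ValueError, match="root"):
            asr.call_gains(
                self._table(0.9, 0.1), tree, {"r": tree.seed_node}, 0.75
            )

    def test_sweep_monotonicity(self, rng):
        tree, labels = random_rooted_tree(rng, 8)
        p = pd.DataFrame(
            rng.integers(0, 2, size=(30, 8)),
            index=[f"OG{i}" for i in range(30)],
            columns=labels,
        )
        post, _ = asr.asr_all(p, tree)
        anc = {
            nd.label: nd
            for nd in tree.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        }
        tables = {
            tau: asr.call_gains(post, tree, anc, tau)
            for tau in (0.65, 0.75, 0.85)
        }
        for name in anc:
            assert tables[0.85][name] <= tables[0.75][name] <= tables[0.65][name]

    def test_root_presence_reported_separately(self):
        tree = self._tree()
        got = asr.root_presence(self._table(0.9, 0.9), tree, 0.75)
        assert got == {"OG1"}


class TestSingleCharacterReport:
    def test_constant_trace_all_ones(self):
        tree = make_tree("((A:1,B:1):1,C:2);")
        p = pd.DataFrame(
            [[1, 1, 1]], index=["OG1"], columns=["A", "B", "C"]
        )
        post, _ = asr.asr_all(p, tree)
        newick, table = asr.single_character_report("OG1", post, tree)
        assert (table["p_present"] == 1.0).all()
        assert "_p1.000000" in newick

    def test_output_newick_isomorphic(self):
        tree = make_tree("((A:1,B:1):1,C:2);")
        p = pd.DataFrame([[1, 0, 1]], index=["OG1"], columns=["A", "B", "C"])
        post, _ = asr.asr_all(p, tree)
        newick, _ = asr.single_character_report("OG1", post, tree)
        back = parse_newick(newick)
        assert sorted(lf.taxon.label for lf in back.leaf_node_iter()) == [
            "A", "B", "C",
        ]

    def test_unknown_og_errors(self):
        tree = make_tree("(A:1,B:1);")
        post = pd.DataFrame(columns=["og_id", "node", "p_present"])
        with pytest.raises(KeyError):
            asr.single_character_report("nope", post, tree)

    def test_rbcs_like_control(self):
        # present in all green tips, absent elsewhere: posterior high at the
        # green MRCA, low at deeper ancestors
        from orgatlas.simulate import SimConfig, simulate_tree

        tree = simulate_tree(SimConfig(seed=3))
        green = [
            l for l in (lf.taxon.label for lf in tree.leaf_node_iter())
            if l.startswith(("chlorophyte", "zygnematophyceae", "embryophyte"))
        ]
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        p = pd.DataFrame(
            [[1 if t in green else 0 for t in tips]],
            index=["rbcS"], columns=tips,
        )
        post, rates = asr.asr_all(p, tree)
        wide = post.pivot(index="og_id", columns="node", values="p_present")
        mrca = tree.mrca(taxon_labels=green)
        root_lab = tree.seed_node.label
        assert wide.at["rbcS", mrca.label] > 0.75
        assert wide.at["rbcS", root_lab] < 0.25
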