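"""Fitch/Sankoff parsimony against a brute-force enumeration oracle."""

import itertools
import random

import pytest

from karyevo.parsimony import (
    RootedTree,
    TreeNode,
    character_column,
    fitch,
    map_synapomorphies,
    reconstruct_root_karyotype,
)


# --- independent oracle: enumerate every internal-node assignment -----------

def brute_force_length(tree, tips, states):
    """Minimal number of state changes over all internal labelings."""
    internals = [n for n in tree.root.postorder() if not n.is_leaf]
    best = None
    for assign in itertools.product(states, repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        cost = 0
        for node in tree.root.preorder():
            for child in node.children:
                ps = amap[id(node)]
                if child.is_leaf:
                    cs = tips[child.label]
                    if cs is None:
                        continue  # missing tip can always copy the parent
                else:
                    cs = amap[id(child)]
                cost += ps != cs
        if best is None or cost < best:
            best = cost
    return best


def random_tree(rng, n_tips):
    """Random rooted topology, with occasional polytomies."""
    nodes = [TreeNode(label=f"t{i}") for i in range(n_tips)]
    while len(nodes) > 1:
        k = min(len(nodes), rng.choice([2, 2, 2, 3]))
        group = [nodes.pop(rng.randrange(len(nodes))) for _ in range(k)]
        parent = TreeNode(children=group)
        for g in group:
            g.parent = parent
        nodes.append(parent)
    return RootedTree(nodes[0])


class TestFitch:
    def test_new_world_derived_state(self, trees, matrices):
        # diploid-number character: only one tip derived -> root {0}, one change
        tips = character_column(matrices["ricinulei"], 1)
        res = fitch(trees["ricinulei"], tips)
        assert res.root_set == frozenset({"0"})
        assert res.length == 1

    def test_constant_character(self):
        tree = RootedTree.from_newick("(a,(b,(c,d)));")
        res = fitch(tree, {t: "0" for t in "abcd"})
        assert res.length == 0
        assert res.root_set == frozenset({"0"})

    def test_missing_tip_is_full_ambiguity(self):
        tree = RootedTree.from_newick("(a,(b,(c,d)));")
        res = fitch(tree, {"a": "0", "b": None, "c": "1", "d": "1"},
                    state_space=("0", "1"))
        assert res.length == 1

    def test_all_missing_rejected(self):
        tree = RootedTree.from_newick("(a,(b,c));")
        with pytest.raises(ValueError):
            fitch(tree, {"a": None, "b": None, "c": None})

    def test_matches_brute_force_on_random_instances(self):
        rng = random.Random(20250930)
        for case in range(50):
            n_tips = rng.randint(3, 8)
            n_states = rng.randint(2, 4)
            states = tuple(str(s) for s in range(n_states))
            tree = random_tree(rng, n_tips)
            tips = {
                label: (None if rng.random() < 0.15 else rng.choice(states))
                for label in tree.tip_labels
            }
            if all(s is None for s in tips.values()):
                tips[tree.tip_labels[0]] = states[0]
            res = fitch(tree, tips, state_space=states)
            assert res.length == brute_force_length(tree, tips, states), (
                f"case {case}: {tree.to_newick()} {tips}"
            )

    def test_mpr_sets_are_feasible(self):
        # every state in a node's MPR set is used by some optimal labeling:
        # fixing the root to each member must keep the optimal length
        tree = RootedTree.from_newick("((a,b),(c,(d,e)));")
        tips = {"a": "0", "b": "1", "c": "1", "d": "0", "e": "2"}
        res = fitch(tree, tips, state_space=("0", "1", "2"))
        root_costs = res.costs[id(tree.root)]
        for s in res.root_set:
            assert root_costs[s] == res.length

    def test_outgroup_invariance(self):
        """Adding an outgroup carrying the reconstructed root state leaves
        the parsimony length unchanged."""
        rng = random.Random(7)
        for _ in range(20):
            tree = random_tree(rng, rng.randint(3, 7))
            states = ("0", "1", "2")
            tips = {t: rng.choice(states) for t in tree.tip_labels}
            res = fitch(tree, tips, state_space=states)
            root_state = sorted(res.root_set)[0]
            out = TreeNode(label="outgroup")
            new_root = TreeNode(children=[out, tree.root])
            out.parent = new_root
            tree.root.parent = new_root
            bigger = RootedTree(new_root)
            tips2 = dict(tips, outgroup=root_state)
            assert fitch(bigger, tips2, state_space=states).length == res.length


class TestSynapomorphyMapping:
    def test_single_origin_is_unique(self, trees, matrices):
        # monoarmed predominance arises once, on the New World clade stem
        tips = character_column(matrices["ricinulei"], 2)
        cmap = map_synapomorphies(trees["ricinulei"], tips, state_space=("0", "1"))
        assert len(cmap.changes) == 1
        change = cmap.changes[0]
        assert change.unique
        assert set(change.branch.split("+")) == {
            "Cryptocellus_narino", "Pseudocellus_gertschi"
        }

    def test_two_origins_flagged_non_unique(self):
        tree = RootedTree.from_newick("((a,b),(c,d));")
        tips = {"a": "1", "b": "0", "c": "1", "d": "0"}
        cmap = map_synapomorphies(tree, tips, state_space=("0", "1"))
        origins = [c for c in cmap.changes if c.to_state == "1"]
        assert len(origins) == 2
        assert all(not c.unique for c in origins)

    @pytest.mark.parametrize("resolution", ["ACCTRAN", "DELTRAN"])
    def test_change_count_equals_parsimony_length(self, resolution):
        rng = random.Random(99)
        for _ in range(25):
            tree = random_tree(rng, rng.randint(3, 8))
            states = ("0", "1", "2")
            tips = {t: rng.choice(states) for t in tree.tip_labels}
            res = fitch(tree, tips, state_space=states)
            cmap = map_synapomorphies(
                tree, tips, resolution=resolution, state_space=states
            )
            assert cmap.n_changes == res.length

    def test_unknown_resolution_rejected(self):
        tree = RootedTree.from_newick("(a,(b,c));")
        with pytest.raises(ValueError):
            map_synapomorphies(tree, {"a": "0", "b": "0", "c": "1"},
                               resolution="MIDDLING")


class TestRootKaryotypes:
    def test_ricinuleid_ancestor(self, trees, matrices):
        recon = reconstruct_root_karyotype(trees["ricinulei"], matrices["ricinulei"])
        assert recon[1]["meanings"] == [40]       # ancestral 2n
        assert recon[2]["meanings"] == ["biarmed_predominant"]

    def test_schizomid_ancestor(self, trees, matrices):
        recon = reconstruct_root_karyotype(trees["schizomida"], matrices["schizomida"])
        assert recon[1]["meanings"] == [22]

    def test_schizomid_ancestor_robust_to_alternative_topology(self, matrices):
        from karyevo.io import load_fixture
        tree = load_fixture("schizomida.tree.alt_stenochrus")
        recon = reconstruct_root_karyotype(tree, matrices["schizomida"])
        assert recon[1]["meanings"] == [22]

    def test_solifuge_ancestor_reported_as_full_set(self, trees, matrices):
        recon = reconstruct_root_karyotype(trees["solifugae"], matrices["solifugae"])
        assert "0" in recon[1]["root_states"]  # 24 chromosomes among optima
        assert 24 in recon[1]["meanings"]
        # ambiguity is reported, never silently resolved
        assert len(recon[1]["meanings"]) == len(recon[1]["root_states"])

    def test_amblypygid_ancestor(self, trees, matrices):
        recon = reconstruct_root_karyotype(trees["amblypygi"], matrices["amblypygi"])
        assert recon[1]["meanings"] == [(74, 78)]
        assert recon[2]["meanings"] == ["monoarmed_predominant"]
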