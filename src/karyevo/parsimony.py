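"""Parsimony mapping of discrete characters on rooted topologies.

Characters are unordered multistate with unit change cost, reconstructed
by the Fitch/Sankoff dynamic programme: an upward pass computes, per node
and state, the minimal number of changes in the subtree; the minimum over
root states is the parsimony length, and a downward pass yields every
node's set of states attainable in some most-parsimonious reconstruction
(the MPR sets). Missing tips ('?') carry the universal state set.
Polytomies are handled natively by the Sankoff recursion.

A single most-parsimonious labeling is obtained by resolving ties either
ACCTRAN (changes placed as close to the root as possible) or DELTRAN
(delayed toward the tips). On that labeling each branch where the state
changes is a hypothesized synapomorphy of the clade below it; a derived
state arising on exactly one branch is a unique synapomorphy, otherwise
non-unique (homoplasy).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Any, Hashable, Iterable, Mapping, Sequence

import dendropy

from .characters import CharacterMatrix, CharacterScheme, MISSING, decode_state

__all__ = [
    "RootedTree",
    "TreeNode",
    "FitchResult",
    "Change",
    "ChangeMap",
    "fitch",
    "map_synapomorphies",
    "reconstruct_root_karyotype",
]

INF = float("inf")


@dataclass
class TreeNode:
    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterable["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterable["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()


class RootedTree:
    """Rooted, tip-labeled topology; polytomies allowed, no branch lengths."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._index_nodes()

    def _index_nodes(self) -> None:
        labels = [n.label for n in self.root.postorder() if n.is_leaf]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        if any(l is None for l in labels):
            raise ValueError("every tip must be labeled")
        self.tip_labels: tuple[str, ...] = tuple(labels)

    @classmethod
    def from_newick(cls, newick: str) -> "RootedTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        def convert(dnode) -> TreeNode:
            node = TreeNode(
                label=dnode.taxon.label if dnode.taxon else dnode.label
            )
            for dchild in dnode.child_nodes():
                child = convert(dchild)
                child.parent = node
                node.children.append(child)
            return node
        return cls(convert(dtree.seed_node))

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label or ""
            return "(" + ",".join(fmt(c) for c in node.children) + ")"
        return fmt(self.root) + ";"

    def n_tips(self) -> int:
        return len(self.tip_labels)


@dataclass
class FitchResult:
    length: int
    root_set: frozenset[Hashable]
    mpr_sets: dict[int, frozenset[Hashable]]      # id(node) -> MPR state set
    costs: dict[int, dict[Hashable, float]]       # id(node) -> state -> subtree cost
    states: tuple[Hashable, ...]

    def node_set(self, node: TreeNode) -> frozenset[Hashable]:
        return self.mpr_sets[id(node)]


def _tip_states(
    tree: RootedTree,
    tip_to_state: Mapping[str, Hashable],
    state_space: Sequence[Hashable],
) -> dict[int, set[Hashable]]:
    out: dict[int, set[Hashable]] = {}
    universe = set(state_space)
    for node in tree.root.postorder():
        if not node.is_leaf:
            continue
        if node.label not in tip_to_state:
            raise KeyError(f"tip {node.label!r} missing from character data")
        s = tip_to_state[node.label]
        out[id(node)] = set(universe) if s is None else {s}
    return out


def fitch(
    tree: RootedTree,
    tip_to_state: Mapping[str, Hashable],
    state_space: Sequence[Hashable] | None = None,
) -> FitchResult:
    """Unit-cost parsimony over a rooted tree, polytomies included.

    ``tip_to_state`` maps every tip label to its state or None for
    missing. Returns the parsimony length, the root's optimal set and
    every node's MPR set.
    """
    if state_space is None:
        observed = sorted(
            {s for s in tip_to_state.values() if s is not None}, key=repr
        )
        state_space = tuple(observed)
    if not state_space:
        raise ValueError("character has no non-missing tip: reconstruction undefined")
    states = tuple(state_space)
    tips = _tip_states(tree, tip_to_state, states)

    # upward (Sankoff) pass: cost[node][s] = min changes in subtree given node=s
    costs: dict[int, dict[Hashable, float]] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            allowed = tips[id(node)]
            costs[id(node)] = {s: (0.0 if s in allowed else INF) for s in states}
        else:
            row: dict[Hashable, float] = {}
            for s in states:
                total = 0.0
                for child in node.children:
                    crow = costs[id(child)]
                    total += min(
                        crow[t] + (0.0 if t == s else 1.0) for t in states
                    )
                row[s] = total
            costs[id(node)] = row

    root_costs = costs[id(tree.root)]
    best = min(root_costs.values())
    if best == INF:
        raise ValueError("no feasible reconstruction (conflicting fixed tips?)")
    root_set = frozenset(s for s in states if root_costs[s] == best)

    # downward pass: g[node][s] = min changes over the whole tree given node=s
    g: dict[int, dict[Hashable, float]] = {id(tree.root): dict(root_costs)}
    for node in tree.root.preorder():
        grow = g[id(node)]
        for child in node.children:
            crow = costs[id(child)]
            # cost of the rest of the tree, seen from `child`, given parent state p:
            # rest(p) = g[node](p) - min_t(crow[t] + [t != p])
            rest: dict[Hashable, float] = {}
            for p in states:
                sub = min(crow[t] + (0.0 if t == p else 1.0) for t in states)
                rest[p] = grow[p] - sub
            g[id(child)] = {
                s: crow[s] + min(rest[p] + (0.0 if p == s else 1.0) for p in states)
                for s in states
            }

    mpr = {
        nid: frozenset(s for s in states if row[s] == best)
        for nid, row in g.items()
    }
    return FitchResult(
        length=int(best), root_set=root_set, mpr_sets=mpr, costs=costs, states=states
    )


@dataclass(frozen=True)
class Change:
    branch: str        # label of the child clade (tip label or clade tip list)
    character_id: int | None
    from_state: Hashable
    to_state: Hashable
    unique: bool


@dataclass
class ChangeMap:
    resolution: str
    assignment: dict[int, Hashable]  # id(node) -> resolved state
    changes: list[Change]

    @property
    def n_changes(self) -> int:
        return len(self.changes)


def _clade_name(node: TreeNode) -> str:
    tips = [n.label for n in node.postorder() if n.is_leaf]
    return tips[0] if len(tips) == 1 else "+".join(tips)


def map_synapomorphies(
    tree: RootedTree,
    tip_to_state: Mapping[str, Hashable],
    resolution: str = "ACCTRAN",
    state_space: Sequence[Hashable] | None = None,
    character_id: int | None = None,
    result: FitchResult | None = None,
) -> ChangeMap:
    """Resolve one most-parsimonious labeling and flag state origins.

    ACCTRAN breaks ties toward changing on the branch entering a node
    (changes accelerate rootward); DELTRAN toward keeping the parent's
    state (changes delayed tipward). Either way the number of changes
    equals the parsimony length. A derived state with exactly one origin
    branch is a unique synapomorphy.
    """
    if resolution not in ("ACCTRAN", "DELTRAN"):
        raise ValueError("resolution must be ACCTRAN or DELTRAN")
    res = result or fitch(tree, tip_to_state, state_space)
    states = res.states

    assignment: dict[int, Hashable] = {}
    root_costs = res.costs[id(tree.root)]
    best = min(root_costs.values())
    # root: any optimal state; prefer the one kept by most children (DELTRAN)
    # or simply the first optimal state (stable, deterministic)
    root_state = sorted((s for s in states if root_costs[s] == best), key=repr)[0]
    assignment[id(tree.root)] = root_state

    for node in tree.root.preorder():
        p = assignment[id(node)]
        for child in node.children:
            crow = res.costs[id(child)]
            total = lambda s: crow[s] + (0.0 if s == p else 1.0)  # noqa: E731
            opt = min(total(s) for s in states)
            candidates = sorted((s for s in states if total(s) == opt), key=repr)
            if p in candidates:
                if resolution == "DELTRAN":
                    choice = p
                else:  # ACCTRAN: change now if any optimal alternative exists
                    alts = [s for s in candidates if s != p]
                    choice = alts[0] if alts else p
            else:
                choice = candidates[0]
            assignment[id(child)] = choice

    # collect changes and count origins per derived state
    raw: list[tuple[TreeNode, Hashable, Hashable]] = []
    for node in tree.root.preorder():
        for child in node.children:
            a, b = assignment[id(node)], assignment[id(child)]
            if a != b:
                raw.append((child, a, b))
    origins: dict[Hashable, int] = {}
    for _, _, b in raw:
        origins[b] = origins.get(b, 0) + 1
    changes = [
        Change(
            branch=_clade_name(child),
            character_id=character_id,
            from_state=a,
            to_state=b,
            unique=origins[b] == 1,
        )
        for child, a, b in raw
    ]
    return ChangeMap(resolution=resolution, assignment=assignment, changes=changes)


def character_column(matrix: CharacterMatrix, char_id: int) -> dict[str, str | None]:
    """Per-taxon state symbols of one character; None where missing."""
    idx = [c.id for c in matrix.scheme.characters].index(char_id)
    return {
        taxon: (None if row[idx] == MISSING else row[idx])
        for taxon, row in matrix.rows.items()
    }


def reconstruct_root_karyotype(
    tree: RootedTree,
    matrix: CharacterMatrix,
    scheme: CharacterScheme | None = None,
) -> dict[int, dict[str, Any]]:
    """Fitch every character and decode the root's optimal states.

    Returns per character id a dict with the root state-code set, the
    decoded meanings of each optimal code, and the parsimony length.
    Ambiguous roots keep the full set; nothing is silently resolved.
    """
    scheme = scheme or matrix.scheme
    out: dict[int, dict[str, Any]] = {}
    for character in scheme.characters:
        column = character_column(matrix, character.id)
        present = {t: s for t, s in column.items() if t in tree.tip_labels}
        if all(s is None for s in present.values()):
            out[character.id] = {
                "root_states": frozenset(),
                "meanings": [],
                "length": None,
                "note": "all tips missing",
            }
            continue
        res = fitch(tree, present, state_space=tuple(character.states))
        out[character.id] = {
            "root_states": res.root_set,
            "meanings": [
                decode_state(scheme, character.id, code)
                for code in sorted(res.root_set)
            ],
            "length": res.length,
        }
    return out
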