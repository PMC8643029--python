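"""Positions, exposure bookkeeping, and the maximal good decomposition.

A *position* records, per input tree, the root label of the subtree still
under consideration (or nothing, if the tree no longer contributes).  A
position is *valid* when each nonempty entry is exactly the LCA of its
tree's surviving taxa.  ``decompose`` computes the unique maximal nice
exposed subset S of a valid position together with the blocks of the
induced child partition and the successor positions — the engine of the
top-down agreement-tree construction.

Bad-label elimination never reinserts anything into the display graph:
removing a bad label from S only merges block records through a per-call
union-find over component ids ("virtual" reconnection).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .display import DisplayGraph
from .errors import ContractError
from .trees import Profile, SemiLabeledTree

__all__ = [
    "Position",
    "ProfileTables",
    "ExposureState",
    "Block",
    "Decomposition",
    "initial_position",
    "position_label_set",
    "is_valid_position",
    "decompose",
]


# A position is a tuple with one entry per input tree: the single label of
# the subtree root under consideration, or None.
Position = Tuple[Optional[str], ...]


class ProfileTables:
    """Per-tree label-indexed lookup tables for a normalized profile.

    Under full singular labeling there is a bijection labels <-> nodes per
    tree, so children, parents, and clusters can all be indexed by label.
    """

    def __init__(self, profile: Profile):
        if not profile.is_normalized:
            raise ContractError("profile must be fully and singularly labeled")
        self.profile = profile
        self.k = profile.k
        # children_by_label[i][label] -> list of child labels in T_i
        self.children_by_label: List[Dict[str, List[str]]] = []
        self.root_label: List[str] = []
        self.membership: Dict[str, Set[int]] = {}  # J(l) = {i : l in X_i}
        for i, tree in enumerate(profile):
            table: Dict[str, List[str]] = {}
            for v in tree.preorder():
                (lv,) = tree.taxa_of(v)
                table[lv] = [next(iter(tree.taxa_of(c))) for c in tree.children(v)]
                self.membership.setdefault(lv, set()).add(i)
            self.children_by_label.append(table)
            (rl,) = tree.taxa_of(tree.root)
            self.root_label.append(rl)

    def children(self, i: int, label: str) -> List[str]:
        return self.children_by_label[i][label]

    def J(self, label: str) -> Set[int]:
        return self.membership[label]

    def subtree_labels(self, i: int, label: str) -> Set[str]:
        """X_i(label): all labels in the subtree of T_i rooted at ``label``."""
        out = set()
        stack = [label]
        table = self.children_by_label[i]
        while stack:
            v = stack.pop()
            out.add(v)
            stack.extend(table[v])
        return out


class ExposureState:
    """Per-taxon 'unseen' lists: the tree indices in J(l) not yet reached.

    A label is exposed once its unseen list is empty; it stays exposed
    until deleted from the display graph.
    """

    def __init__(self, tables: ProfileTables):
        self.unseen: Dict[str, Set[int]] = {
            lab: set(js) for lab, js in tables.membership.items()
        }

    def observe(self, position: Position) -> None:
        """Record that each label in the position has been reached in its tree."""
        for i, lab in enumerate(position):
            if lab is not None:
                self.unseen[lab].discard(i)

    def is_exposed(self, label: str) -> bool:
        return not self.unseen[label]


@dataclass
class Block:
    """One block of the child partition: a sparse per-tree child array."""

    children: Dict[int, List[str]] = field(default_factory=dict)

    def add(self, i: int, label: str) -> None:
        self.children.setdefault(i, []).append(label)

    def absorb(self, other: "Block") -> None:
        for i, labs in other.children.items():
            self.children.setdefault(i, []).extend(labs)

    def label_set(self) -> Set[str]:
        out: Set[str] = set()
        for labs in self.children.values():
            out.update(labs)
        return out


@dataclass
class Decomposition:
    """The maximal good decomposition (S, Pi) of a valid position."""

    S: Set[str]
    blocks: List[Block]
    positions: List[Position]
    bad_order: List[str]
    n_iterations: int
    new_exposed: Set[str]
    # per elimination: (bad label, child-label set of the merged block)
    merge_log: List[Tuple[str, Set[str]]] = field(default_factory=list)

    @property
    def trace(self) -> Dict[str, object]:
        """JSON-serializable debug record of this call."""
        return {
            "S": sorted(self.S),
            "bad_labels": list(self.bad_order),
            "block_sizes": sorted(len(b.label_set()) for b in self.blocks),
            "n_successors": len(self.positions),
        }


def initial_position(profile: Profile) -> Position:
    """pi^init: the root label of every input tree."""
    out = []
    for tree in profile:
        taxa = tree.taxa_of(tree.root)
        if len(taxa) != 1:
            raise ContractError("profile must be fully and singularly labeled")
        out.append(next(iter(taxa)))
    return tuple(out)


def position_label_set(tables: ProfileTables, position: Position) -> Set[str]:
    """X_P(pi): union over trees of the subtree label sets at the position roots."""
    out: Set[str] = set()
    for i, lab in enumerate(position):
        if lab is not None:
            out.update(tables.subtree_labels(i, lab))
    return out


def is_valid_position(tables: ProfileTables, position: Position) -> bool:
    """Direct check of the validity equation: each nonempty entry must be the
    LCA in its tree of that tree's share of X_P(pi)."""
    xp = position_label_set(tables, position)
    for i, lab in enumerate(position):
        tree = tables.profile[i]
        share = tree.label_set & xp
        if not share:
            if lab is not None:
                return False
            continue
        if lab is None:
            return False
        lca_node = tree.lca_taxa(share)
        if tree.taxa_of(lca_node) != {lab}:
            return False
    return True


class _UnionFind:
    def __init__(self) -> None:
        self.parent: Dict[int, int] = {}

    def add(self, x: int) -> None:
        self.parent.setdefault(x, x)

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union_into(self, winner: int, loser: int) -> None:
        self.parent[self.find(loser)] = self.find(winner)


def decompose(
    position: Position,
    tables: ProfileTables,
    graph: DisplayGraph,
    state: ExposureState,
    *,
    rng: Optional[random.Random] = None,
) -> Decomposition:
    """Compute the maximal good decomposition of a valid position.

    The display graph and exposure state are mutated: indices are removed
    from unseen lists and newly exposed labels are deleted from the graph.
    ``rng``, if given, randomizes the bad-label elimination order (the final
    S and partition are invariant under that order; tests rely on this).
    """
    k = tables.k

    # -- exposure update and S initialization ------------------------------
    state.observe(position)
    pos_labels = [lab for lab in position if lab is not None]
    S: Set[str] = {lab for lab in pos_labels if state.is_exposed(lab)}
    new_exposed = {lab for lab in S if graph.is_alive(lab)}

    # -- delete newly exposed labels from the display graph ----------------
    graph.delete_exposed(sorted(new_exposed))

    # -- sparse child arrays and the block partition ------------------------
    # Ch_P(pi), per tree; blocks keyed by display-graph component id.
    uf = _UnionFind()
    blocks: Dict[int, Block] = {}
    for i, lab in enumerate(position):
        if lab is None:
            continue
        for c in tables.children(i, lab):
            cid = graph.component_of(c)
            uf.add(cid)
            blocks.setdefault(cid, Block()).add(i, c)

    # Alive non-S position labels also pin a component: a component with no
    # children of pi (an already-complete subtree) still yields a successor.
    for i, lab in enumerate(position):
        if lab is None or lab in S:
            continue
        if not graph.is_alive(lab):  # pragma: no cover - defensive
            raise ContractError(
                f"non-exposed position label {lab!r} is missing from the graph"
            )
        cid = graph.component_of(lab)
        uf.add(cid)
        blocks.setdefault(cid, Block())

    K: Set[int] = {i for i, lab in enumerate(position) if lab is not None and lab in S}

    # -- bad-label elimination ---------------------------------------------
    def bad_candidates() -> List[str]:
        found: List[str] = []
        for i in sorted(K):
            lab = position[i]
            if lab in found:
                continue
            counts: Dict[int, int] = {}
            for c in tables.children(i, lab):
                b = uf.find(graph.component_of(c))
                counts[b] = counts.get(b, 0) + 1
                if counts[b] >= 2:
                    found.append(lab)
                    break
        return found

    bad_order: List[str] = []
    merge_log: List[Tuple[str, Set[str]]] = []
    n_iterations = 0
    merged_home: Dict[str, int] = {}  # bad label -> block id of its merged block
    while True:
        cands = bad_candidates()
        if not cands:
            break
        n_iterations += 1
        bad = rng.choice(cands) if rng is not None else cands[0]
        bad_order.append(bad)
        K_prime = {i for i, lab in enumerate(position) if lab == bad}
        # merge every block holding a child of the bad label
        target: Optional[int] = None
        for i in sorted(K_prime):
            for c in tables.children(i, bad):
                b = uf.find(graph.component_of(c))
                if target is None:
                    target = b
                elif b != target:
                    blocks[target].absorb(blocks.pop(b))
                    uf.union_into(target, b)
                    target = uf.find(target)
        if target is None:
            # bad label cannot be childless; bad_candidates guarantees it
            raise ContractError("bad label without children")  # pragma: no cover
        merged_home[bad] = target
        merge_log.append((bad, blocks[target].label_set()))
        S.discard(bad)
        K -= K_prime

    # -- successor positions (Eq. 3, per block) -----------------------------
    # absorbed blocks were popped, so ``blocks`` holds exactly the survivors
    final_blocks = list(blocks.items())

    positions_out: List[Position] = []
    blocks_out: List[Block] = []
    for bid, block in final_blocks:
        entry: List[Optional[str]] = []
        for i, lab in enumerate(position):
            if lab is None:
                entry.append(None)
                continue
            if lab in S:
                cs = [
                    c
                    for c in tables.children(i, lab)
                    if uf.find(graph.component_of(c)) == uf.find(bid)
                ]
                if len(cs) > 1:  # pragma: no cover - guarded by elimination loop
                    raise ContractError("niceness violated: two children in one block")
                entry.append(cs[0] if cs else None)
            else:
                if graph.is_alive(lab):
                    lab_bid = graph.component_of(lab)
                else:
                    lab_bid = merged_home[lab]
                entry.append(lab if uf.find(lab_bid) == uf.find(bid) else None)
        positions_out.append(tuple(entry))
        blocks_out.append(block)

    return Decomposition(
        S=S,
        blocks=blocks_out,
        positions=positions_out,
        bad_order=bad_order,
        n_iterations=n_iterations,
        new_exposed=new_exposed,
        merge_log=merge_log,
    )
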