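"""Semi-labeled rooted trees (X-trees) and profiles.

A semi-labeled tree is a rooted tree together with a map from a taxon set
onto its nodes such that every leaf — and more generally every node with at
most one child — carries at least one taxon.  Internal taxa represent
higher-order groups (as in taxonomies).  The module provides Newick I/O
(internal-node labels supported), cluster computation, restriction to a
taxon subset, the agreement predicate between a supertree and an input
tree, and the normalization step that assigns fresh taxa to unlabeled
nodes of a profile.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

from .errors import ContractError, DuplicateLabelError, NewickParseError, XTreeError

logger = logging.getLogger(__name__)

ANON_PREFIX = "__anon"

__all__ = [
    "SemiLabeledTree",
    "Profile",
    "parse_newick",
    "parse_profile",
    "to_newick",
    "clusters",
    "restrict",
    "restrict_with_origin",
    "fully_label",
    "agrees_with",
    "ANON_PREFIX",
]


class SemiLabeledTree:
    """A rooted semi-labeled tree.

    Nodes are opaque integer identifiers.  ``children`` maps each node to an
    ordered list of child nodes; ``node_taxa`` maps each node to the
    (possibly empty) set of taxa labeling it.  The inverse map taxon->node
    is derived and cached.
    """

    __slots__ = ("_root", "_children", "_parent", "_node_taxa", "_taxon_node")

    def __init__(
        self,
        root: int,
        children: Dict[int, List[int]],
        node_taxa: Dict[int, Set[str]],
        *,
        validate: bool = True,
    ):
        self._root = root
        self._children = {v: list(cs) for v, cs in children.items()}
        for v in node_taxa:
            self._children.setdefault(v, [])
        self._node_taxa = {v: set(ts) for v, ts in node_taxa.items()}
        for v in self._children:
            self._node_taxa.setdefault(v, set())
        self._parent: Dict[int, int] = {}
        for v, cs in self._children.items():
            for c in cs:
                self._parent[c] = v
        self._taxon_node: Dict[str, int] = {}
        for v, ts in self._node_taxa.items():
            for t in ts:
                if t in self._taxon_node:
                    raise DuplicateLabelError(
                        f"taxon {t!r} labels two nodes of the same tree"
                    )
                self._taxon_node[t] = v
        if validate:
            self._validate()

    def _validate(self) -> None:
        if self._root not in self._children:
            raise ContractError("root is not a node of the tree")
        if self._root in self._parent:
            raise ContractError("root has a parent")
        seen = set()
        for v in self.preorder():
            if v in seen:
                raise ContractError("cycle or repeated node id in tree")
            seen.add(v)
        if len(seen) != len(self._children):
            raise ContractError("tree is not connected (unreachable nodes)")
        for v in seen:
            if len(self._children[v]) <= 1 and not self._node_taxa[v]:
                kind = "leaf" if not self._children[v] else "unary node"
                raise XTreeError(f"unlabeled {kind} (node {v}) violates the X-tree definition")

    # -- basic accessors ---------------------------------------------------

    @property
    def root(self) -> int:
        return self._root

    def children(self, v: int) -> List[int]:
        return self._children[v]

    def parent(self, v: int) -> Optional[int]:
        return self._parent.get(v)

    def taxa_of(self, v: int) -> Set[str]:
        """The set phi^{-1}(v) of taxa labeling node ``v``."""
        return self._node_taxa[v]

    def node_of(self, taxon: str) -> int:
        """The node phi(taxon)."""
        return self._taxon_node[taxon]

    @property
    def label_set(self) -> Set[str]:
        return set(self._taxon_node)

    @property
    def n_nodes(self) -> int:
        return len(self._children)

    @property
    def n_edges(self) -> int:
        return len(self._children) - 1

    @property
    def is_fully_labeled(self) -> bool:
        return all(self._node_taxa[v] for v in self._children)

    @property
    def is_singularly_labeled(self) -> bool:
        return all(len(self._node_taxa[v]) <= 1 for v in self._children)

    def max_out_degree(self) -> int:
        return max(len(cs) for cs in self._children.values())

    # -- traversals --------------------------------------------------------

    def preorder(self) -> Iterator[int]:
        stack = [self._root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(self._children[v]))

    def postorder(self) -> Iterator[int]:
        order = list(self.preorder())
        return reversed(order)

    # -- clusters and LCA --------------------------------------------------

    def cluster_map(self) -> Dict[int, FrozenSet[str]]:
        """Map each node u to its cluster X(u) (taxa of u and descendants)."""
        out: Dict[int, FrozenSet[str]] = {}
        for v in self.postorder():
            acc: Set[str] = set(self._node_taxa[v])
            for c in self._children[v]:
                acc.update(out[c])
            out[v] = frozenset(acc)
        return out

    def depths(self) -> Dict[int, int]:
        d = {self._root: 0}
        for v in self.preorder():
            for c in self._children[v]:
                d[c] = d[v] + 1
        return d

    def lca_nodes(self, nodes: Iterable[int]) -> int:
        """Lowest common ancestor by naive upward walks."""
        it = iter(nodes)
        try:
            cur = next(it)
        except StopIteration:
            raise ContractError("LCA of an empty node set")
        depth = self.depths()
        for v in it:
            a, b = cur, v
            while depth[a] > depth[b]:
                a = self._parent[a]
            while depth[b] > depth[a]:
                b = self._parent[b]
            while a != b:
                a = self._parent[a]
                b = self._parent[b]
            cur = a
        return cur

    def lca_taxa(self, taxa: Iterable[str]) -> int:
        return self.lca_nodes(self._taxon_node[t] for t in taxa)

    # -- serialization -----------------------------------------------------

    def to_newick(self, multi_label_delimiter: str = "+") -> str:
        return to_newick(self, multi_label_delimiter)

    def canonical_newick(self, multi_label_delimiter: str = "+") -> str:
        """Newick with children sorted by smallest contained taxon.

        Two trees have equal cluster sets iff their canonical Newick strings
        are identical (labels sorted within nodes, subtrees sorted by their
        lexicographically smallest taxon).
        """
        cmap = self.cluster_map()

        def render(v: int) -> str:
            name = multi_label_delimiter.join(sorted(self._node_taxa[v]))
            kids = sorted(self._children[v], key=lambda c: min(cmap[c]))
            if not kids:
                return _quote_if_needed(name)
            inner = ",".join(render(c) for c in kids)
            return f"({inner}){_quote_if_needed(name)}"

        return render(self._root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SemiLabeledTree({self.to_newick()!r})"


@dataclass(frozen=True)
class Profile:
    """An ordered collection of semi-labeled input trees T_1..T_k."""

    trees: Tuple[SemiLabeledTree, ...]

    def __init__(self, trees: Sequence[SemiLabeledTree]):
        object.__setattr__(self, "trees", tuple(trees))

    @property
    def k(self) -> int:
        return len(self.trees)

    @property
    def label_set(self) -> Set[str]:
        """X_P, the union of the label sets of the input trees."""
        out: Set[str] = set()
        for t in self.trees:
            out.update(t.label_set)
        return out

    @property
    def n(self) -> int:
        return len(self.label_set)

    @property
    def total_size(self) -> int:
        """M_P: total number of nodes plus edges over all input trees."""
        return sum(t.n_nodes + t.n_edges for t in self.trees)

    @property
    def is_normalized(self) -> bool:
        return all(t.is_fully_labeled and t.is_singularly_labeled for t in self.trees)

    def __iter__(self) -> Iterator[SemiLabeledTree]:
        return iter(self.trees)

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i: int) -> SemiLabeledTree:
        return self.trees[i]


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_SPECIALS = set("(),;:'[]\t\n\r ")


def _quote_if_needed(name: str) -> str:
    if name and not (set(name) & _SPECIALS):
        return name
    return "'" + name.replace("'", "''") + "'"


class _NewickScanner:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos] in " \t\n\r":
            self.pos += 1

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def error(self, msg: str) -> NewickParseError:
        return NewickParseError(msg, self.pos)

    def read_label(self) -> str:
        self.skip_ws()
        if self.peek() == "'":
            start = self.pos
            self.pos += 1
            out = []
            while True:
                if self.pos >= len(self.text):
                    self.pos = start
                    raise self.error("unterminated quoted label")
                ch = self.text[self.pos]
                if ch == "'":
                    if self.pos + 1 < len(self.text) and self.text[self.pos + 1] == "'":
                        out.append("'")
                        self.pos += 2
                        continue
                    self.pos += 1
                    return "".join(out)
                out.append(ch)
                self.pos += 1
        out = []
        while self.pos < len(self.text) and self.text[self.pos] not in _SPECIALS:
            out.append(self.text[self.pos])
            self.pos += 1
        return "".join(out)

    def skip_branch_length(self) -> bool:
        self.skip_ws()
        if self.peek() != ":":
            return False
        self.pos += 1
        start = self.pos
        while self.pos < len(self.text) and (
            self.text[self.pos].isdigit() or self.text[self.pos] in ".+-eE"
        ):
            self.pos += 1
        if self.pos == start:
            raise self.error("expected a branch length after ':'")
        return True


def parse_newick(
    text: str, multi_label_delimiter: Optional[str] = None
) -> SemiLabeledTree:
    """Parse a single rooted Newick expression into a SemiLabeledTree.

    Internal-node labels (after ``)``) are kept as taxa of internal nodes.
    Branch lengths are parsed and discarded with a log warning.  If
    ``multi_label_delimiter`` is given, node labels are split on it, so that
    multiply-labeled agreement trees written by :func:`to_newick` round-trip.
    """
    sc = _NewickScanner(text)
    counter = itertools.count()
    children: Dict[int, List[int]] = {}
    node_taxa: Dict[int, Set[str]] = {}
    saw_branch_length = False

    def new_node() -> int:
        v = next(counter)
        children[v] = []
        node_taxa[v] = set()
        return v

    def parse_clade() -> int:
        nonlocal saw_branch_length
        sc.skip_ws()
        v = new_node()
        if sc.peek() == "(":
            sc.pos += 1
            while True:
                c = parse_clade()
                children[v].append(c)
                sc.skip_ws()
                if sc.peek() == ",":
                    sc.pos += 1
                    continue
                if sc.peek() == ")":
                    sc.pos += 1
                    break
                raise sc.error("expected ',' or ')'")
        label = sc.read_label()
        if label:
            if multi_label_delimiter:
                node_taxa[v].update(label.split(multi_label_delimiter))
            else:
                node_taxa[v].add(label)
        if sc.skip_branch_length():
            saw_branch_length = True
        return v

    sc.skip_ws()
    if not sc.peek():
        raise sc.error("empty Newick input")
    root = parse_clade()
    sc.skip_ws()
    if sc.peek() != ";":
        raise sc.error("expected ';' at end of tree")
    sc.pos += 1
    sc.skip_ws()
    if sc.pos < len(sc.text):
        raise sc.error("trailing characters after ';'")
    if saw_branch_length:
        logger.warning("branch lengths present in Newick input were discarded")
    return SemiLabeledTree(root, children, node_taxa)


def parse_profile(
    text: str, multi_label_delimiter: Optional[str] = None
) -> Profile:
    """Parse a multi-tree Newick document (one tree per line) into a Profile."""
    trees = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        trees.append(parse_newick(line, multi_label_delimiter))
    if not trees:
        raise NewickParseError("no trees found in input", 0)
    return Profile(trees)


def to_newick(tree: SemiLabeledTree, multi_label_delimiter: str = "+") -> str:
    """Serialize a tree; multi-taxon nodes join their taxa, sorted, by the delimiter."""

    def render(v: int) -> str:
        name = multi_label_delimiter.join(sorted(tree.taxa_of(v)))
        kids = tree.children(v)
        if not kids:
            return _quote_if_needed(name)
        inner = ",".join(render(c) for c in kids)
        return f"({inner}){_quote_if_needed(name)}"

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# Clusters, restriction, agreement
# ---------------------------------------------------------------------------


def clusters(tree: SemiLabeledTree) -> Set[FrozenSet[str]]:
    """The cluster set Cl(T) = { X(u) : u in V(T) } (distinct clusters only)."""
    return set(tree.cluster_map().values())


def restrict(tree: SemiLabeledTree, Y: Iterable[str]) -> SemiLabeledTree:
    """Restriction T|Y: the semi-labeled tree whose clusters are
    the nonempty intersections of Cl(T) with Y."""
    return restrict_with_origin(tree, Y)[0]


def restrict_with_origin(
    tree: SemiLabeledTree, Y: Iterable[str]
) -> Tuple[SemiLabeledTree, Dict[int, int]]:
    """Restriction plus a map from each new node to the source node it came from.

    The origin map is what lets a caller that later assigns fresh taxa to
    unlabeled nodes of the restriction know which original node each fresh
    taxon stands for.
    """
    Yset = set(Y)
    if not Yset:
        raise ContractError("cannot restrict to an empty taxon set")
    missing = Yset - tree.label_set
    if missing:
        raise ContractError(f"taxa not in tree: {sorted(missing)!r}")

    # keep[v]: does T(v) contain a Y-taxon?
    keep: Dict[int, bool] = {}
    for v in tree.postorder():
        flag = bool(tree.taxa_of(v) & Yset)
        for c in tree.children(v):
            flag = flag or keep[c]
        keep[v] = flag

    counter = itertools.count()
    children: Dict[int, List[int]] = {}
    node_taxa: Dict[int, Set[str]] = {}
    origin: Dict[int, int] = {}

    def build(v: int) -> Optional[int]:
        """Return the root of the restricted subtree below v, or None."""
        if not keep[v]:
            return None
        built = [build(c) for c in tree.children(v)]
        built = [b for b in built if b is not None]
        own = tree.taxa_of(v) & Yset
        if not own and len(built) == 1:
            return built[0]  # suppress out-of-Y unary node
        w = next(counter)
        children[w] = built
        node_taxa[w] = set(own)
        origin[w] = v
        return w

    # iterative variant of build() to avoid recursion limits on deep chains
    def build_iter(start: int) -> Optional[int]:
        result: Dict[int, Optional[int]] = {}
        stack: List[Tuple[int, bool]] = [(start, False)]
        while stack:
            v, expanded = stack.pop()
            if not keep[v]:
                result[v] = None
                continue
            if not expanded:
                stack.append((v, True))
                for c in tree.children(v):
                    stack.append((c, False))
                continue
            built = [result[c] for c in tree.children(v)]
            built = [b for b in built if b is not None]
            own = tree.taxa_of(v) & Yset
            if not own and len(built) == 1:
                result[v] = built[0]
                continue
            w = next(counter)
            children[w] = built
            node_taxa[w] = set(own)
            origin[w] = v
            result[v] = w
        return result[start]

    del build  # the recursive version documents the logic; use the iterative one
    new_root = build_iter(tree.root)
    assert new_root is not None
    sub = SemiLabeledTree(new_root, children, node_taxa)
    return sub, origin


def fully_label(
    profile: Profile, prefix: str = ANON_PREFIX
) -> Tuple[Profile, Set[str]]:
    """Assign a fresh taxon to every unlabeled node of every tree.

    Returns the normalized profile and the set of synthetic taxa added.
    Fresh taxa are drawn from a reserved namespace ``<prefix><counter>``
    disjoint from the input taxa; an agreement tree of the result is an
    agreement tree of the original profile.
    """
    def check_collision() -> None:
        # only relevant when fresh labels are actually minted: a fully
        # labeled profile may legitimately carry reserved-prefix taxa
        # (e.g. re-reading a previously generated profile)
        for t in profile.label_set:
            if t.startswith(prefix):
                raise ContractError(
                    f"input taxon {t!r} collides with the reserved prefix "
                    f"{prefix!r}; choose a different prefix"
                )

    counter = itertools.count(1)
    added: Set[str] = set()
    new_trees = []
    for tree in profile:
        if not tree.is_singularly_labeled:
            raise ContractError("input trees must be singularly labeled")
        if tree.is_fully_labeled:
            new_trees.append(tree)
            continue
        check_collision()
        node_taxa = {}
        for v in tree.preorder():
            ts = set(tree.taxa_of(v))
            if not ts:
                fresh = f"{prefix}{next(counter)}"
                added.add(fresh)
                ts = {fresh}
            node_taxa[v] = ts
        new_trees.append(
            SemiLabeledTree(
                tree.root,
                {v: list(tree.children(v)) for v in tree.preorder()},
                node_taxa,
            )
        )
    return Profile(new_trees), added


def strip_labels(tree: SemiLabeledTree, taxa: Set[str]) -> SemiLabeledTree:
    """Drop the given taxa from the tree (used to remove synthetic labels).

    Nodes left unlabeled are kept when they still satisfy the X-tree
    invariants (>= 2 children) and suppressed otherwise.
    """
    keep = tree.label_set - taxa
    if not keep:
        raise ContractError("stripping would remove every taxon")
    return restrict(tree, keep)


def agrees_with(supertree: SemiLabeledTree, input_tree: SemiLabeledTree) -> bool:
    """True iff the restriction of ``supertree`` to the input tree's taxa
    has exactly the input tree's cluster set."""
    X_in = input_tree.label_set
    if not X_in <= supertree.label_set:
        raise ContractError("input tree labels are not contained in the supertree")
    return clusters(input_tree) == clusters(restrict(supertree, X_in))
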