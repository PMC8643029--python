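"""Independent correctness oracles.

``verify_agreement`` checks a candidate supertree against a profile using
the local LCA/ancestry characterization of agreement (three conditions per
input-tree label), entirely independently of the construction algorithm.

``brute_force_agreement`` decides agreement for tiny instances by
exhaustive enumeration of every fully-labeled candidate tree on the
profile's taxa: all set partitions of the taxon set crossed with all
rooted tree shapes on the partition blocks.  It exists purely as a test
oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, FrozenSet, Iterator, List, Optional, Sequence, Set, Tuple

from .builder import BuildResult, BuildStats, Status
from .errors import ContractError
from .trees import Profile, SemiLabeledTree

__all__ = ["VerifierReport", "verify_agreement", "brute_force_agreement"]


@dataclass
class VerifierReport:
    ok: bool
    violations: List[Tuple[int, str, Tuple[str, ...]]] = field(default_factory=list)


def verify_agreement(supertree: SemiLabeledTree, profile: Profile) -> VerifierReport:
    """Check the three agreement conditions for every input-tree label.

    For each tree T_i and each taxon a in X_i:

    E1  the supertree node carrying a is the LCA of T_i's cluster at a;
    E2  that node is a proper ancestor of the node of each child-label of a;
    E3  distinct child-labels of a descend from distinct children of a's node.

    All three hold for every i and a iff the supertree agrees with every
    input tree.
    """
    if supertree.label_set != profile.label_set:
        raise ContractError("supertree label set must equal the profile label set")

    depth = supertree.depths()
    violations: List[Tuple[int, str, Tuple[str, ...]]] = []

    def ancestor_at_child(u: int, v: int) -> Optional[int]:
        """The child of u on the path from u down to v, or None if u is not
        a proper ancestor of v."""
        prev = None
        while depth[v] > depth[u]:
            prev = v
            v = supertree.parent(v)
        return prev if v == u else None

    for i, tree in enumerate(profile):
        cmap = tree.cluster_map()
        for v in tree.preorder():
            for a in tree.taxa_of(v):
                pa = supertree.node_of(a)
                # E1
                lca = supertree.lca_nodes(supertree.node_of(x) for x in cmap[v])
                if lca != pa:
                    violations.append((i, "E1", (a,)))
                # E2 / E3
                seen_children: Dict[int, str] = {}
                for c in tree.children(v):
                    for b in tree.taxa_of(c):
                        pb = supertree.node_of(b)
                        arm = ancestor_at_child(pa, pb)
                        if arm is None:
                            violations.append((i, "E2", (a, b)))
                            continue
                        if arm in seen_children:
                            violations.append((i, "E3", (a, seen_children[arm], b)))
                        else:
                            seen_children[arm] = b
    return VerifierReport(ok=not violations, violations=violations)


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle
# ---------------------------------------------------------------------------


def _set_partitions(items: Sequence[str]) -> Iterator[List[List[str]]]:
    """All set partitions, by recursive block assignment."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


@lru_cache(maxsize=None)
def _rooted_shapes(b: int) -> Tuple[Tuple[int, Tuple[int, ...]], ...]:
    """All rooted labeled trees on nodes 0..b-1 as (root, parent-vector).

    Enumerated via Pruefer sequences (b^(b-2) unrooted labeled trees, each
    rooted at every node), b^(b-1) trees total.
    """
    if b == 1:
        return ((0, (-1,)),)
    shapes: List[Tuple[int, Tuple[int, ...]]] = []
    for seq in itertools.product(range(b), repeat=b - 2):
        edges = _pruefer_decode(seq, b)
        adj: Dict[int, List[int]] = {i: [] for i in range(b)}
        for u, v in edges:
            adj[u].append(v)
            adj[v].append(u)
        for root in range(b):
            parent = [-1] * b
            stack = [root]
            seen = {root}
            while stack:
                u = stack.pop()
                for w in adj[u]:
                    if w not in seen:
                        seen.add(w)
                        parent[w] = u
                        stack.append(w)
            shapes.append((root, tuple(parent)))
    return tuple(shapes)


def _pruefer_decode(seq: Sequence[int], b: int) -> List[Tuple[int, int]]:
    degree = [1] * b
    for x in seq:
        degree[x] += 1
    edges = []
    import heapq

    leaves = [i for i in range(b) if degree[i] == 1]
    heapq.heapify(leaves)
    for x in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, x))
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(leaves, x)
    u = heapq.heappop(leaves)
    v = heapq.heappop(leaves)
    edges.append((u, v))
    return edges


def _candidate_trees(taxa: Sequence[str]) -> Iterator[SemiLabeledTree]:
    """Every fully-labeled semi-labeled tree on the given taxa."""
    for part in _set_partitions(tuple(sorted(taxa))):
        blocks = [sorted(blk) for blk in part]
        b = len(blocks)
        for root, parent in _rooted_shapes(b):
            children: Dict[int, List[int]] = {i: [] for i in range(b)}
            for w, p in enumerate(parent):
                if p >= 0:
                    children[p].append(w)
            node_taxa = {i: set(blocks[i]) for i in range(b)}
            yield SemiLabeledTree(root, children, node_taxa, validate=False)


def brute_force_agreement(profile: Profile, max_labels: int = 6) -> BuildResult:
    """Decide agreement by exhaustive search over all fully-labeled trees
    on X_P.  Refuses instances with more than ``max_labels`` taxa.

    Enumerating only fully-labeled candidates is sufficient: an agreeing
    profile always has an agreement tree in which every node carries a
    taxon.  For normalized profiles each candidate is screened with the
    local E1-E3 conditions (cheap); otherwise the restriction-based
    cluster comparison is used, since the local characterization assumes
    fully labeled inputs.
    """
    if not profile.is_normalized:
        # Completeness of the fully-labeled enumeration requires fully
        # labeled inputs (a raw profile can agree only through a tree with
        # an unlabeled node); adding distinct fresh labels preserves the
        # agree/disagree decision exactly.
        from .trees import fully_label

        profile, _ = fully_label(profile)
    taxa = sorted(profile.label_set)
    if len(taxa) > max_labels:
        raise ContractError(
            f"brute force refuses {len(taxa)} labels after normalization "
            f"(max {max_labels}): combinatorial explosion guard"
        )
    stats = BuildStats()
    n = len(taxa)
    if n <= _INDEXED_CUTOFF:
        idx = {t: i for i, t in enumerate(taxa)}
        rows_idx = [
            (idx[a], tuple(idx[x] for x in cluster), tuple(idx[b] for b in kids))
            for a, cluster, kids in _constraint_rows(profile)
        ]
        for part, root, parent, depth, node_of in _indexed_candidates(n):
            if _check_indexed(parent, depth, node_of, rows_idx):
                tree = _tree_from_indexed(taxa, part, root, parent)
                return BuildResult(status=Status.AGREES, tree=tree, stats=stats)
        return BuildResult(status=Status.DISAGREES, tree=None, stats=stats)
    rows = _constraint_rows(profile)
    for cand in _candidate_trees(taxa):
        if _satisfies_rows(cand, rows):
            return BuildResult(status=Status.AGREES, tree=cand, stats=stats)
    return BuildResult(status=Status.DISAGREES, tree=None, stats=stats)


_INDEXED_CUTOFF = 7


@lru_cache(maxsize=8)
def _indexed_candidates(
    n: int,
) -> Tuple[Tuple[Tuple[Tuple[int, ...], ...], int, Tuple[int, ...], Tuple[int, ...], Tuple[int, ...]], ...]:
    """All fully-labeled candidate trees on taxa 0..n-1 in flat-array form:
    (partition, root, parent-vector, depth-vector, taxon->node vector)."""
    out = []
    for part in _set_partitions(tuple(range(n))):
        blocks = tuple(tuple(sorted(blk)) for blk in part)
        b = len(blocks)
        node_of = [0] * n
        for bi, blk in enumerate(blocks):
            for t in blk:
                node_of[t] = bi
        for root, parent in _rooted_shapes(b):
            depth = [0] * b
            for v in range(b):
                d, u = 0, v
                while parent[u] >= 0:
                    u = parent[u]
                    d += 1
                depth[v] = d
            out.append((blocks, root, parent, tuple(depth), tuple(node_of)))
    return tuple(out)


def _check_indexed(
    parent: Tuple[int, ...],
    depth: Tuple[int, ...],
    node_of: Tuple[int, ...],
    rows: List[Tuple[int, Tuple[int, ...], Tuple[int, ...]]],
) -> bool:
    for a, cluster, kids in rows:
        pa = node_of[a]
        lca = pa
        for x in cluster:
            v = node_of[x]
            u = lca
            while depth[u] > depth[v]:
                u = parent[u]
            while depth[v] > depth[u]:
                v = parent[v]
            while u != v:
                u = parent[u]
                v = parent[v]
            lca = u
        if lca != pa:
            return False
        seen = 0
        for bx in kids:
            v = node_of[bx]
            prev = -1
            while depth[v] > depth[pa]:
                prev = v
                v = parent[v]
            if v != pa or prev < 0:
                return False
            bit = 1 << prev
            if seen & bit:
                return False
            seen |= bit
    return True


def _tree_from_indexed(
    taxa: Sequence[str],
    part: Tuple[Tuple[int, ...], ...],
    root: int,
    parent: Tuple[int, ...],
) -> SemiLabeledTree:
    b = len(part)
    children: Dict[int, List[int]] = {i: [] for i in range(b)}
    for w, p in enumerate(parent):
        if p >= 0:
            children[p].append(w)
    node_taxa = {i: {taxa[t] for t in part[i]} for i in range(b)}
    return SemiLabeledTree(root, children, node_taxa, validate=False)


def _constraint_rows(
    profile: Profile,
) -> List[Tuple[str, Tuple[str, ...], Tuple[str, ...]]]:
    """Per input-tree label: (label, its cluster's taxa, its child labels)."""
    rows = []
    for tree in profile:
        cmap = tree.cluster_map()
        for v in tree.preorder():
            for a in tree.taxa_of(v):
                kids = tuple(b for c in tree.children(v) for b in tree.taxa_of(c))
                rows.append((a, tuple(cmap[v]), kids))
    return rows


def _satisfies_rows(
    cand: SemiLabeledTree,
    rows: List[Tuple[str, Tuple[str, ...], Tuple[str, ...]]],
) -> bool:
    """E1-E3 screening of a candidate, with early exit."""
    depth = cand.depths()
    parent = cand.parent
    node_of = cand.node_of

    def arm(u: int, v: int) -> Optional[int]:
        prev = None
        while depth[v] > depth[u]:
            prev = v
            v = parent(v)
        return prev if v == u else None

    for a, cluster, kids in rows:
        pa = node_of(a)
        # E1: pa must be the LCA of the cluster's nodes
        lca = pa
        for x in cluster:
            v = node_of(x)
            u = lca
            while depth[u] > depth[v]:
                u = parent(u)
            while depth[v] > depth[u]:
                v = parent(v)
            while u != v:
                u = parent(u)
                v = parent(v)
            lca = u
        if lca != pa:
            return False
        seen: Set[int] = set()
        for b in kids:
            c_arm = arm(pa, node_of(b))
            if c_arm is None or c_arm in seen:
                return False
            seen.add(c_arm)
    return True
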