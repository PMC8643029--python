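"""The display graph of a profile, with decremental connectivity.

The display graph has one vertex per distinct taxon and one (deduplicated)
undirected edge per parent-child label pair occurring in any input tree.
The agreement algorithm only ever *deletes* vertices and edges, each at
most once over a whole run, and needs to know, after each batch of
deletions, which component each surviving taxon belongs to.

Two interchangeable backends maintain the component index:

``"bfs"`` (default)
    On every single edge deletion, an alternating bidirectional BFS runs
    from both endpoints over the surviving adjacency.  If the frontiers
    meet, the component did not split.  If one side exhausts first, that
    side is the smaller piece (up to a constant factor) and only it is
    relabeled with a fresh component id — the classic
    "scan the smaller component" technique.

``"naive"``
    After deleting a vertex, recompute the components of the affected
    region from scratch by BFS.  Slower, but trivially correct; used as a
    cross-check in the test suite.

Correctness is backend-independent; both are validated against a
from-scratch BFS partition oracle in the tests.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .errors import ContractError
from .trees import Profile

__all__ = ["DisplayGraph", "SplitRecord", "build_display_graph"]


@dataclass
class SplitRecord:
    """One component split produced while deleting a batch of taxa.

    ``scanned`` is the side that was relabeled (the exhausted/smaller side);
    ``marked_moved`` is its intersection with the marked taxon set.
    """

    old_component: int
    new_component: int
    scanned: Set[str]
    marked_moved: Set[str]


class DisplayGraph:
    """Undirected graph on taxa supporting vertex deletion with a
    maintained component partition."""

    def __init__(self, adjacency: Dict[str, Set[str]], backend: str = "bfs"):
        if backend not in ("bfs", "naive"):
            raise ContractError(f"unknown connectivity backend {backend!r}")
        self.backend = backend
        self._adj: Dict[str, Set[str]] = {v: set(ns) for v, ns in adjacency.items()}
        self._alive: Set[str] = set(self._adj)
        self._comp: Dict[str, int] = {}
        self._comp_ids = itertools.count()
        self._marks: Set[str] = set()
        # instrumentation: how many times each taxon was moved to a smaller side
        self.move_counts: Dict[str, int] = {}
        self._init_components()

    # -- construction ------------------------------------------------------

    def _init_components(self) -> None:
        for v in self._adj:
            if v not in self._comp:
                cid = next(self._comp_ids)
                for u in self._bfs_from(v):
                    self._comp[u] = cid

    def _bfs_from(self, start: str, limit: Optional[Set[str]] = None) -> Set[str]:
        seen = {start}
        q = deque([start])
        while q:
            v = q.popleft()
            for u in self._adj[v]:
                if u not in seen and (limit is None or u in limit):
                    seen.add(u)
                    q.append(u)
        return seen

    # -- queries -----------------------------------------------------------

    @property
    def vertices(self) -> Set[str]:
        return set(self._adj)

    @property
    def alive(self) -> Set[str]:
        return set(self._alive)

    def is_alive(self, taxon: str) -> bool:
        return taxon in self._alive

    def neighbors(self, taxon: str) -> Set[str]:
        return set(self._adj[taxon])

    def n_edges(self) -> int:
        return sum(len(ns) for ns in self._adj.values()) // 2

    def component_of(self, taxon: str) -> int:
        """Component handle; equal handles <=> same component. O(1)."""
        if taxon not in self._alive:
            raise ContractError(f"taxon {taxon!r} has been deleted")
        return self._comp[taxon]

    def components(self) -> Dict[int, Set[str]]:
        """Full partition of the alive vertices (linear scan; for tests/debug)."""
        out: Dict[int, Set[str]] = {}
        for v in self._alive:
            out.setdefault(self._comp[v], set()).add(v)
        return out

    def set_marks(self, taxa: Iterable[str]) -> None:
        self._marks = set(taxa)

    # -- deletion ----------------------------------------------------------

    def delete_exposed(self, new_labels: Iterable[str]) -> List[SplitRecord]:
        """Delete each taxon in ``new_labels`` (edges one at a time, then the
        vertex), maintaining the component index.  Returns the split log.

        Every taxon passed must be alive: old exposed labels — deleted in an
        ancestor call — must be skipped by the caller.
        """
        log: List[SplitRecord] = []
        for ell in new_labels:
            if ell not in self._alive:
                raise ContractError(
                    f"taxon {ell!r} was already deleted (old labels must be skipped)"
                )
            for u in list(self._adj[ell]):
                self._delete_edge(ell, u, log)
            self._alive.discard(ell)
            del self._comp[ell]
        return log

    def _delete_edge(self, a: str, b: str, log: List[SplitRecord]) -> None:
        self._adj[a].discard(b)
        self._adj[b].discard(a)
        if self.backend == "naive":
            self._recheck_naive(a, b, log)
        else:
            self._recheck_bidirectional(a, b, log)

    def _recheck_naive(self, a: str, b: str, log: List[SplitRecord]) -> None:
        side_a = self._bfs_from(a, limit=self._alive)
        if b in side_a:
            return
        side_b = self._bfs_from(b, limit=self._alive)
        smaller = side_a if len(side_a) <= len(side_b) else side_b
        self._relabel(smaller, self._comp[a], log)

    def _recheck_bidirectional(self, a: str, b: str, log: List[SplitRecord]) -> None:
        """Alternate one BFS step from each endpoint; the side whose frontier
        exhausts first is the split-off piece and is the only side scanned."""
        seen_a: Set[str] = {a}
        seen_b: Set[str] = {b}
        qa = deque([a])
        qb = deque([b])
        while True:
            if not qa:
                self._relabel(seen_a, self._comp[a], log)
                return
            v = qa.popleft()
            for u in self._adj[v]:
                if u in seen_b:
                    return  # frontiers met: still connected
                if u not in seen_a:
                    seen_a.add(u)
                    qa.append(u)
            if not qb:
                self._relabel(seen_b, self._comp[b], log)
                return
            v = qb.popleft()
            for u in self._adj[v]:
                if u in seen_a:
                    return
                if u not in seen_b:
                    seen_b.add(u)
                    qb.append(u)

    def _relabel(self, side: Set[str], old_cid: int, log: List[SplitRecord]) -> None:
        new_cid = next(self._comp_ids)
        for v in side:
            self._comp[v] = new_cid
            self.move_counts[v] = self.move_counts.get(v, 0) + 1
        log.append(
            SplitRecord(
                old_component=old_cid,
                new_component=new_cid,
                scanned=set(side),
                marked_moved=side & self._marks,
            )
        )

    # -- debug output ------------------------------------------------------

    def edge_list_tsv(self) -> str:
        lines = []
        for v in sorted(self._adj):
            for u in sorted(self._adj[v]):
                if v < u:
                    lines.append(f"{v}\t{u}")
        return "\n".join(lines) + "\n"

    def to_dot(self) -> str:
        lines = ["graph display {"]
        for v in sorted(self._adj):
            lines.append(f'  "{v}";')
        for v in sorted(self._adj):
            for u in sorted(self._adj[v]):
                if v < u:
                    lines.append(f'  "{v}" -- "{u}";')
        lines.append("}")
        return "\n".join(lines) + "\n"


def build_display_graph(profile: Profile, backend: str = "bfs") -> DisplayGraph:
    """Build H_P: one vertex per taxon, one edge per distinct unordered
    parent-child label pair over all trees (parallel edges deduplicated)."""
    if not profile.is_normalized:
        raise ContractError("profile must be fully and singularly labeled")
    adj: Dict[str, Set[str]] = {}
    for tree in profile:
        for v in tree.preorder():
            (tv,) = tree.taxa_of(v)
            adj.setdefault(tv, set())
            for c in tree.children(v):
                (tc,) = tree.taxa_of(c)
                adj.setdefault(tc, set())
                adj[tv].add(tc)
                adj[tc].add(tv)
    return DisplayGraph(adj, backend=backend)
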