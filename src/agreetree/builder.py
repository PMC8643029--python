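"""Breadth-first assembly of an agreement tree, or certified disagreement.

The build starts at the initial position (all input-tree roots), repeatedly
computes the maximal good decomposition of the dequeued position, creates a
tree node for its S, and enqueues the successor positions.  If any
processed position has an empty maximal nice exposed subset, no agreement
tree exists and the build stops immediately, reporting the offending
position.
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Set, Tuple

from .decomposition import (
    Decomposition,
    ExposureState,
    Position,
    ProfileTables,
    decompose,
    initial_position,
    is_valid_position,
    position_label_set,
)
from .display import build_display_graph
from .errors import ContractError
from .trees import Profile, SemiLabeledTree

__all__ = ["Status", "BuildStats", "BuildResult", "build_agreement_tree", "verify_and_build"]


class Status(Enum):
    AGREES = "AGREES"
    DISAGREES = "DISAGREES"


@dataclass
class BuildStats:
    positions_processed: int = 0
    decompose_calls: int = 0
    bad_labels_eliminated: int = 0
    max_while_iterations: int = 0


@dataclass
class BuildResult:
    status: Status
    tree: Optional[SemiLabeledTree]
    stats: BuildStats
    conflict_position: Optional[Position] = None

    @property
    def agrees(self) -> bool:
        return self.status is Status.AGREES


def build_agreement_tree(
    profile: Profile,
    *,
    backend: str = "bfs",
    check: bool = False,
    bad_label_rng: Optional[random.Random] = None,
    queue_discipline: str = "fifo",
    trace: Optional[List[Dict[str, object]]] = None,
    graph=None,
) -> BuildResult:
    """Run the top-down agreement construction on a normalized profile.

    Parameters
    ----------
    profile:
        Fully and singularly labeled profile (see :func:`agreetree.trees.fully_label`).
    backend:
        Display-graph connectivity backend, ``"bfs"`` or ``"naive"``.
    check:
        Enable expensive self-checks: validity of every enqueued position,
        the disjoint-cover property of every decomposition, the child
        partition audit, and the component index against a fresh BFS.
    bad_label_rng:
        Randomize the bad-label elimination order (result is invariant).
    queue_discipline:
        ``"fifo"`` (breadth-first, default) or ``"lifo"``; the output tree is
        the same either way.
    trace:
        If a list is supplied, a JSON-friendly record of every decompose
        call is appended to it.
    """
    if not profile.is_normalized:
        raise ContractError(
            "profile must be fully and singularly labeled; call fully_label() first"
        )
    if queue_discipline not in ("fifo", "lifo"):
        raise ContractError(f"unknown queue discipline {queue_discipline!r}")

    tables = ProfileTables(profile)
    if graph is None:
        graph = build_display_graph(profile, backend=backend)
    state = ExposureState(tables)
    stats = BuildStats()
    n = profile.n

    # output tree under construction
    node_ids = iter(range(2 * n + 1))
    children: Dict[int, List[int]] = {}
    node_taxa: Dict[int, Set[str]] = {}
    root_node: Optional[int] = None

    queue: deque = deque([(initial_position(profile), None)])
    while queue:
        if queue_discipline == "fifo":
            position, pred = queue.popleft()
        else:
            position, pred = queue.pop()
        stats.positions_processed += 1
        if stats.positions_processed > 2 * n:  # pragma: no cover - safety net
            raise ContractError("position count exceeded the 2n bound")

        if check:
            if not is_valid_position(tables, position):
                raise ContractError(f"invalid position dequeued: {position!r}")
            xp_before = position_label_set(tables, position)

        dec = decompose(position, tables, graph, state, rng=bad_label_rng)
        stats.decompose_calls += 1
        stats.bad_labels_eliminated += len(dec.bad_order)
        stats.max_while_iterations = max(stats.max_while_iterations, dec.n_iterations)
        if trace is not None:
            trace.append(dec.trace)
        if dec.n_iterations > tables.k:  # pragma: no cover - safety net
            raise ContractError("bad-label loop exceeded k iterations")

        if not dec.S:
            return BuildResult(
                status=Status.DISAGREES,
                tree=None,
                stats=stats,
                conflict_position=position,
            )

        if check:
            _audit_decomposition(tables, position, dec, xp_before)

        node = next(node_ids)
        children[node] = []
        node_taxa[node] = set(dec.S)
        if pred is None:
            root_node = node
        else:
            children[pred].append(node)
        for succ in dec.positions:
            queue.append((succ, node))

    assert root_node is not None
    tree = SemiLabeledTree(root_node, children, node_taxa)
    return BuildResult(status=Status.AGREES, tree=tree, stats=stats)


def _audit_decomposition(
    tables: ProfileTables,
    position: Position,
    dec: Decomposition,
    xp_before: Set[str],
) -> None:
    """Instrumented-mode checks: disjoint cover, progress, and the child
    partition conditions (every position label has at most one child per
    block if in S, and all its children in one block otherwise)."""
    succ_sets = [position_label_set(tables, p) for p in dec.positions]
    union: Set[str] = set()
    total = 0
    for s in succ_sets:
        union.update(s)
        total += len(s)
    if total != len(union):
        raise ContractError("successor label sets are not pairwise disjoint")
    if union | dec.S != xp_before or union & dec.S:
        raise ContractError("X_P(pi) is not the disjoint union of S and successors")
    if dec.positions and not union < xp_before:
        raise ContractError("no strict progress in decomposition")

    block_sets = [b.label_set() for b in dec.blocks]
    for i, lab in enumerate(position):
        if lab is None:
            continue
        ch = set(tables.children(i, lab))
        if not ch:
            continue
        hits = [bs & ch for bs in block_sets if bs & ch]
        if lab in dec.S:
            if any(len(h) > 1 for h in hits):
                raise ContractError("partition audit: S-label with two children in a block")
        else:
            if len(hits) > 1 or (hits and hits[0] != ch):
                raise ContractError("partition audit: non-S label with split children")
    for p in dec.positions:
        if not is_valid_position(tables, p):
            raise ContractError(f"invalid successor position {p!r}")


def verify_and_build(profile: Profile, **kwargs) -> BuildResult:
    """Build, then re-check the result with the independent E1-E3 verifier.

    Raises :class:`ContractError` if the verifier rejects a produced tree
    (self-check mode for CI); disagreement results pass through untouched.
    """
    from .verify import verify_agreement  # local import to avoid a cycle

    result = build_agreement_tree(profile, **kwargs)
    if result.status is Status.AGREES:
        report = verify_agreement(result.tree, profile)
        if not report.ok:
            raise ContractError(
                f"internal error: built tree fails verification: {report.violations!r}"
            )
    return result
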