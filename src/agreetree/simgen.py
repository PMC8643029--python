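"""Synthetic profiles that are guaranteed to agree.

A complete D-ary seed tree with m labeled nodes is restricted to k random,
partially overlapping taxon subsets.  Restriction can create unlabeled
internal nodes (LCAs that fell outside the subset); those receive fresh
taxa, which does not affect agreement.  The seed tree — carrying all fresh
taxa on the seed nodes they stand for, restricted to the profile's taxon
set — is an agreement tree for the generated profile by construction.
"""

from __future__ import annotations

import math
import random
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .builder import build_agreement_tree
from .errors import ContractError
from .trees import (
    ANON_PREFIX,
    Profile,
    SemiLabeledTree,
    fully_label,
    restrict,
    restrict_with_origin,
)

__all__ = [
    "GeneratorConfig",
    "GeneratedProfile",
    "make_seed_tree",
    "generate_profile",
    "benchmark_sweep",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the seed-tree profile generator.

    ``p_used`` is the probability that each subset element is drawn from the
    pool of labels already used by earlier draws (keeping the trees'
    taxon sets overlapping); ``min_frac`` sets the lower bound of the
    uniform subset-size distribution at ``max(2, ceil(min_frac * m))``.
    """

    D: int
    m: int
    k: int
    rng_seed: int = 0
    p_used: float = 0.5
    min_frac: float = 0.1

    def __post_init__(self):
        if self.D < 2:
            raise ContractError("D must be >= 2")
        if self.m < 1:
            raise ContractError("m must be >= 1")
        if self.k < 1:
            raise ContractError("k must be >= 1")


@dataclass
class GeneratedProfile:
    """A generated profile plus the structures needed to certify it.

    ``reference_tree`` is the relabeled seed tree restricted to the
    profile's taxon set: an agreement tree for ``profile`` by construction.
    """

    profile: Profile
    seed_tree: SemiLabeledTree
    reference_tree: SemiLabeledTree
    subsets: List[Set[str]]
    added_labels: Set[str]


def make_seed_tree(D: int, m: int) -> SemiLabeledTree:
    """Complete D-ary tree with exactly m nodes, filled level by level,
    left to right; node i (breadth-first order) is labeled ``"t<i>"``."""
    if D < 2 or m < 1:
        raise ContractError("require D >= 2 and m >= 1")
    children: Dict[int, List[int]] = {i: [] for i in range(m)}
    for i in range(1, m):
        children[(i - 1) // D].append(i)
    node_taxa = {i: {f"t{i}"} for i in range(m)}
    return SemiLabeledTree(0, children, node_taxa)


def generate_profile(config: GeneratorConfig) -> GeneratedProfile:
    """Draw k overlapping label subsets of the seed tree and restrict.

    Deterministic for a fixed config: one seeded RNG, draws consumed in a
    fixed order (subset size first, then elements one at a time).
    """
    rng = random.Random(config.rng_seed)
    seed = make_seed_tree(config.D, config.m)
    seed_labels = sorted(seed.label_set, key=lambda t: int(t[1:]))

    lo = min(config.m, max(2, math.ceil(config.min_frac * config.m)))
    used: List[str] = []
    used_set: Set[str] = set()
    unused: List[str] = list(seed_labels)

    subsets: List[Set[str]] = []
    for _ in range(config.k):
        size = rng.randint(lo, config.m)
        # split the draw between the used and unused pools: each element
        # comes from the used pool with probability p_used, capped by pool
        # sizes (shortfalls spill into the other pool)
        want_used = sum(1 for _ in range(size) if rng.random() < config.p_used)
        n_used = min(want_used, len(used))
        n_new = min(size - n_used, len(unused))
        n_used = min(size - n_new, len(used))
        chosen = set(rng.sample(used, n_used)) | set(rng.sample(unused, n_new))
        newly = [t for t in unused if t in chosen]
        if newly:
            used.extend(newly)
            used_set.update(newly)
            unused = [t for t in unused if t not in chosen]
        subsets.append(chosen)

    # Restrict the seed to each subset; assign fresh taxa to unlabeled
    # nodes (distinct across the whole profile), remembering which seed
    # node each fresh taxon stands for.
    counter = 0
    fresh_on_seed_node: Dict[int, Set[str]] = {}
    added: Set[str] = set()
    trees: List[SemiLabeledTree] = []
    for Y in subsets:
        sub, origin = restrict_with_origin(seed, Y)
        node_taxa: Dict[int, Set[str]] = {}
        for v in sub.preorder():
            ts = set(sub.taxa_of(v))
            if not ts:
                counter += 1
                fresh = f"{ANON_PREFIX}{counter}"
                added.add(fresh)
                ts = {fresh}
                fresh_on_seed_node.setdefault(origin[v], set()).add(fresh)
            node_taxa[v] = ts
        trees.append(
            SemiLabeledTree(
                sub.root, {v: list(sub.children(v)) for v in sub.preorder()}, node_taxa
            )
        )
    profile = Profile(trees)

    # Reference agreement tree: seed tree with the fresh taxa attached to
    # their seed nodes, restricted to the profile's taxon set.
    ref_taxa: Dict[int, Set[str]] = {
        v: set(seed.taxa_of(v)) for v in seed.preorder()
    }
    for v, fresh_set in fresh_on_seed_node.items():
        ref_taxa[v].update(fresh_set)
    decorated = SemiLabeledTree(
        seed.root, {v: list(seed.children(v)) for v in seed.preorder()}, ref_taxa
    )
    reference = restrict(decorated, profile.label_set)
    return GeneratedProfile(
        profile=profile,
        seed_tree=seed,
        reference_tree=reference,
        subsets=subsets,
        added_labels=added,
    )


def benchmark_sweep(
    grid: Sequence[Tuple[int, int, int]],
    trials: int = 3,
    rng_seed: int = 0,
    backend: str = "bfs",
) -> List[Dict[str, float]]:
    """Run the builder over a (D, m, k) grid, averaging wall time per cell.

    Returns one row per cell: D, m, k, n, M_P = n * k, mean/stdev time in
    seconds, positions processed, and bad labels eliminated (last trial).
    """
    rows: List[Dict[str, float]] = []
    for D, m, k in grid:
        times: List[float] = []
        n = mp = positions = eliminated = 0
        for t in range(trials):
            cfg = GeneratorConfig(D=D, m=m, k=k, rng_seed=rng_seed + 7919 * t)
            gen = generate_profile(cfg)
            n = gen.profile.n
            mp = n * k
            start = time.perf_counter()
            result = build_agreement_tree(gen.profile, backend=backend)
            times.append(time.perf_counter() - start)
            if not result.agrees:  # pragma: no cover - generator soundness
                raise ContractError("generated profile unexpectedly disagrees")
            positions = result.stats.positions_processed
            eliminated = result.stats.bad_labels_eliminated
        mean = sum(times) / len(times)
        var = sum((x - mean) ** 2 for x in times) / len(times)
        rows.append(
            {
                "D": D,
                "m": m,
                "k": k,
                "n": n,
                "M_P": mp,
                "mean_time_s": mean,
                "stdev_time_s": var**0.5,
                "positions": positions,
                "bad_labels": eliminated,
            }
        )
    return rows
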