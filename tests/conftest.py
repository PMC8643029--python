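"""Shared fixtures: the worked-example profile and random-profile helpers.

The worked-example profile is a four-tree profile over 12 original taxa
(a-l) plus 6 synthetic taxa (1-6) on the originally unlabeled nodes.  It
is wired so that the decomposition of its initial position exercises every
interesting branch: exposure, block formation, two bad labels, virtual
merges, and a multiply-labeled output node.
"""

import random

import pytest

from agreetree.trees import (
    Profile,
    SemiLabeledTree,
    fully_label,
    parse_newick,
    parse_profile,
    restrict,
)

# fully labeled form (synthetic taxa 1-6 written explicitly)
EXAMPLE_NEWICKS = [
    "(((a,c,e)3,b)2,d)1;",
    "(b,c,g)4;",
    "((h)k,(i,j)5,f)g;",
    "(i,j,l)6;",
]

# the same trees with the synthetic taxa absent (unlabeled internal nodes)
EXAMPLE_NEWICKS_RAW = [
    "(((a,c,e),b),d);",
    "(b,c,g);",
    "((h)k,(i,j),f)g;",
    "(i,j,l);",
]


@pytest.fixture
def example_profile() -> Profile:
    return Profile([parse_newick(nw) for nw in EXAMPLE_NEWICKS])


@pytest.fixture
def example_profile_raw() -> Profile:
    return Profile([parse_newick(nw) for nw in EXAMPLE_NEWICKS_RAW])


@pytest.fixture
def example_variant_profile() -> Profile:
    """The worked example with taxon c removed from the second tree."""
    newicks = list(EXAMPLE_NEWICKS)
    newicks[1] = "(b,g)4;"
    return Profile([parse_newick(nw) for nw in newicks])


def random_labeled_tree(rng: random.Random, taxa) -> SemiLabeledTree:
    """A uniform-ish random rooted tree with one taxon per node."""
    taxa = list(taxa)
    rng.shuffle(taxa)
    n = len(taxa)
    children = {0: []}
    for v in range(1, n):
        p = rng.randrange(v)
        children[p].append(v)
        children[v] = []
    node_taxa = {v: {taxa[v]} for v in range(n)}
    return SemiLabeledTree(0, children, node_taxa)


def random_small_profile(rng: random.Random, max_taxa: int = 5, max_trees: int = 3):
    """A random profile of restrictions of one random seed tree (agreeing
    unless ``conflict`` perturbs it): returns the *normalized* profile.

    Used by the oracle-equivalence suite; the result's label universe is
    kept small enough for the exhaustive oracle.
    """
    while True:
        n = rng.randint(2, max_taxa)
        taxa = [chr(97 + i) for i in range(n)]
        k = rng.randint(1, max_trees)
        conflict = rng.random() < 0.5
        seeds = [random_labeled_tree(rng, taxa)]
        if conflict:
            seeds.append(random_labeled_tree(rng, taxa))
        trees = []
        for _ in range(k):
            seed = seeds[rng.randrange(len(seeds))]
            size = rng.randint(2, n)
            sub = rng.sample(taxa, size)
            trees.append(restrict(seed, sub))
        profile = Profile(trees)
        normalized, _ = fully_label(profile)
        if normalized.n <= 6:
            return normalized
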