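"""Unit and property tests for the tree data model and Newick I/O."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agreetree.errors import (
    ContractError,
    DuplicateLabelError,
    NewickParseError,
    XTreeError,
)
from agreetree.trees import (
    Profile,
    SemiLabeledTree,
    agrees_with,
    clusters,
    fully_label,
    parse_newick,
    parse_profile,
    restrict,
    strip_labels,
    to_newick,
)
from conftest import random_labeled_tree


def C(*groups):
    """Shorthand: cluster set from iterables of single-char taxa."""
    return {frozenset(g) for g in groups}


class TestParseNewick:
    def test_internal_labels(self):
        t = parse_newick("((a,b)f,c)g;")
        assert t.n_nodes == 5
        assert t.label_set == {"a", "b", "c", "f", "g"}
        f_node = t.node_of("f")
        assert t.children(f_node) != []  # f labels an internal node

    def test_unlabeled_root_fan(self):
        t = parse_newick("(a,b,c);")
        assert t.label_set == {"a", "b", "c"}
        assert not t.taxa_of(t.root)
        assert not t.is_fully_labeled

    def test_duplicate_label_rejected(self):
        with pytest.raises(DuplicateLabelError):
            parse_newick("((a,b),(a,c));")

    def test_unlabeled_unary_rejected(self):
        with pytest.raises(XTreeError):
            parse_newick("((a));")

    def test_unlabeled_leaf_rejected(self):
        with pytest.raises(XTreeError):
            parse_newick("(a,);")

    def test_labeled_unary_root_accepted(self):
        t = parse_newick("(a)g;")
        assert t.label_set == {"a", "g"}
        assert len(t.children(t.root)) == 1

    def test_malformed_reports_offset(self):
        with pytest.raises(NewickParseError) as exc:
            parse_newick("((a,b)")
        assert exc.value.offset == 6

    def test_missing_semicolon(self):
        with pytest.raises(NewickParseError):
            parse_newick("(a,b)")

    def test_branch_lengths_discarded(self):
        t = parse_newick("((a:0.1,b:0.2)f:0.3,c)g;")
        assert t.label_set == {"a", "b", "c", "f", "g"}

    def test_quoted_labels(self):
        t = parse_newick("('sp one','sp''two')r;")
        assert "sp one" in t.label_set
        assert "sp'two" in t.label_set

    def test_empty_input(self):
        with pytest.raises(NewickParseError):
            parse_newick("   ")

    def test_multi_label_delimiter(self):
        t = parse_newick("((a,b)f+g,c)h;", multi_label_delimiter="+")
        assert t.taxa_of(t.node_of("f")) == {"f", "g"}

    def test_parse_profile_multiline(self):
        p = parse_profile("(a,b)r;\n(c,d)s;\n")
        assert p.k == 2
        assert p.label_set == {"a", "b", "c", "d", "r", "s"}


class TestToNewick:
    def test_single_node(self):
        t = SemiLabeledTree(0, {0: []}, {0: {"x"}})
        assert to_newick(t) == "x;"

    def test_multi_taxon_sorted_join(self):
        t = SemiLabeledTree(0, {0: [1, 2]}, {0: {"g", "4"}, 1: {"a"}, 2: {"b"}})
        assert to_newick(t, "+") == "(a,b)4+g;"

    def test_round_trip_preserves_clusters(self):
        t = parse_newick("((a,b)f,c)g;")
        t2 = parse_newick(to_newick(t))
        assert clusters(t) == clusters(t2)

    def test_canonical_sorts_children(self):
        t1 = parse_newick("((b,a)f,c)g;")
        t2 = parse_newick("(c,(a,b)f)g;")
        assert t1.canonical_newick() == t2.canonical_newick()


class TestClusters:
    def test_example(self):
        t = parse_newick("((a,b)f,c)g;")
        assert clusters(t) == C("a", "b", "c", "abf", "abcfg")

    def test_single_node(self):
        t = parse_newick("x;")
        assert clusters(t) == C("x")

    def test_labeled_chain(self):
        t = parse_newick("(a)g;")
        assert clusters(t) == C("a", "ag")


class TestRestrict:
    def test_drop_internal_labels(self):
        t = parse_newick("((a,b)f,c)g;")
        r = restrict(t, {"a", "b", "c"})
        assert clusters(r) == C("a", "b", "c", "ab", "abc")
        assert r.label_set == {"a", "b", "c"}

    def test_identity(self):
        t = parse_newick("((a,b)f,c)g;")
        assert clusters(restrict(t, t.label_set)) == clusters(t)

    def test_empty_rejected(self):
        t = parse_newick("(a,b)r;")
        with pytest.raises(ContractError):
            restrict(t, set())

    def test_no_unlabeled_unary_nodes(self):
        t = parse_newick("(((a,b)x,c)y,d)z;")
        r = restrict(t, {"a", "b", "d"})
        for v in r.preorder():
            assert len(r.children(v)) >= 2 or r.taxa_of(v)

    def test_restriction_cluster_definition(self):
        """Structural restriction equals the cluster-set definition."""
        rng = random.Random(7)
        for _ in range(100):
            n = rng.randint(2, 8)
            taxa = [chr(97 + i) for i in range(n)]
            t = random_labeled_tree(rng, taxa)
            y = set(rng.sample(taxa, rng.randint(1, n)))
            expected = {
                frozenset(w & y) for w in clusters(t) if w & y
            }
            assert clusters(restrict(t, y)) == expected

    def test_composition(self):
        """restrict(restrict(T,Y),Z) ~ restrict(T, Y&Z) by cluster equality."""
        rng = random.Random(11)
        for _ in range(100):
            n = rng.randint(3, 8)
            taxa = [chr(97 + i) for i in range(n)]
            t = random_labeled_tree(rng, taxa)
            y = set(rng.sample(taxa, rng.randint(2, n)))
            z = set(rng.sample(sorted(y), rng.randint(1, len(y))))
            assert clusters(restrict(restrict(t, y), z)) == clusters(restrict(t, z))


class TestFullyLabel:
    def test_counts_and_placement(self, example_profile_raw):
        normalized, added = fully_label(example_profile_raw)
        assert len(added) == 6
        # placement: one fresh taxon per originally-unlabeled node, per tree
        per_tree = [3, 1, 1, 1]
        for tree, raw, expect in zip(normalized, example_profile_raw, per_tree):
            assert len(tree.label_set - raw.label_set) == expect
            assert tree.is_fully_labeled and tree.is_singularly_labeled

    def test_already_labeled_unchanged(self, example_profile):
        normalized, added = fully_label(example_profile)
        assert added == set()
        assert [to_newick(t) for t in normalized] == [
            to_newick(t) for t in example_profile
        ]

    def test_cherry_gets_one_label(self):
        p = Profile([parse_newick("(a,b);")])
        normalized, added = fully_label(p)
        assert len(added) == 1
        assert normalized[0].taxa_of(normalized[0].root) == added

    def test_prefix_collision(self):
        p = Profile([parse_newick("(__anon1,b);")])
        with pytest.raises(ContractError):
            fully_label(p)

    def test_preserves_original_clusters(self, example_profile_raw):
        normalized, added = fully_label(example_profile_raw)
        for tree, raw in zip(normalized, example_profile_raw):
            kept = {
                frozenset(w - added) for w in clusters(tree) if w - added
            }
            assert kept == clusters(raw)


class TestAgreesWith:
    def test_self(self):
        t = parse_newick("((a,b)f,c)g;")
        assert agrees_with(t, t)

    def test_mismatched_cherry(self):
        supertree = parse_newick("((a,b)x,c)y;")
        inp = parse_newick("((a,c)x,b)y;")
        with pytest.raises(ContractError):
            agrees_with(supertree, parse_newick("((a,c)x,b)z;"))
        assert not agrees_with(supertree, inp)

    def test_containment_required(self):
        supertree = parse_newick("(a,b)r;")
        inp = parse_newick("(a,q)r;")
        with pytest.raises(ContractError):
            agrees_with(supertree, inp)


class TestStripLabels:
    def test_strip_synthetic(self):
        t = parse_newick("((a,b)__anon1,c)r;")
        s = strip_labels(t, {"__anon1"})
        assert s.label_set == {"a", "b", "c", "r"}
        assert clusters(s) == C("a", "b", "c", "ab", "abcr")


@st.composite
def random_tree_strategy(draw):
    n = draw(st.integers(min_value=1, max_value=8))
    seed = draw(st.integers(min_value=0, max_value=2**30))
    rng = random.Random(seed)
    taxa = [chr(97 + i) for i in range(n)]
    return random_labeled_tree(rng, taxa)


class TestProperties:
    @given(random_tree_strategy())
    @settings(max_examples=100, deadline=None)
    def test_newick_round_trip_is_cluster_identity(self, t):
        assert clusters(parse_newick(to_newick(t))) == clusters(t)

    @given(random_tree_strategy(), random_tree_strategy())
    @settings(max_examples=100, deadline=None)
    def test_canonical_newick_iff_equal_clusters(self, t1, t2):
        same_clusters = clusters(t1) == clusters(t2)
        same_canon = t1.canonical_newick() == t2.canonical_newick()
        if t1.label_set == t2.label_set:
            assert same_clusters == same_canon

    @given(random_tree_strategy())
    @settings(max_examples=60, deadline=None)
    def test_restrict_output_is_valid_xtree(self, t):
        rng = random.Random(5)
        taxa = sorted(t.label_set)
        y = set(rng.sample(taxa, rng.randint(1, len(taxa))))
        r = restrict(t, y)
        assert r.label_set == y
        for v in r.preorder():
            if len(r.children(v)) <= 1:
                assert r.taxa_of(v)


class TestProfile:
    def test_derived_fields(self, example_profile):
        assert example_profile.k == 4
        assert example_profile.n == 18
        assert example_profile.is_normalized

    def test_total_size(self):
        p = parse_profile("(a,b)r;\n(c,d)s;")
        # each tree: 3 nodes + 2 edges
        assert p.total_size == 10
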