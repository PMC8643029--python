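# agreetree

Agreement supertrees for rooted **semi-labeled trees** — trees whose
leaves are always labeled and whose internal nodes may also carry taxa,
as in taxonomies.

Given a profile of `k` rooted input trees over partially overlapping
taxon sets, `agreetree` either constructs an **agreement tree** — a
supertree on the union of all taxa whose restriction to each input
tree's taxon set is isomorphic to that input tree — or certifies that no
such tree exists.  Unlike compatibility testing, agreement treats
multifurcations as *hard*: children of a polytomy must remain in
distinct subtrees.

The construction works top-down.  All input trees are first made fully
labeled by assigning fresh taxa to unlabeled nodes (this never changes
the answer).  The *display graph* — one vertex per taxon, one edge per
parent–child label pair over all trees — is then decomposed
position-by-position: at each step the unique maximal set of "exposed"
root labels is computed, bad labels (forced multifurcations whose
children fall into one component) are eliminated by virtually merging
component blocks, and the surviving blocks become independent
subproblems.  Vertices and edges of the display graph are deleted at
most once over a whole run; component splits are tracked by scanning the
smaller side.

## Library

```python
import agreetree as ag

profile = ag.parse_profile("((a,b)f,c)g;\n(b,(c,d))h;\n")
normalized, added = ag.fully_label(profile)
result = ag.build_agreement_tree(normalized)
if result.agrees:
    print(ag.to_newick(result.tree))     # multi-taxon nodes joined by '+'
else:
    print("disagreement at", result.conflict_position)
```

Other entry points: `ag.restrict`, `ag.clusters`, `ag.agrees_with`,
`ag.verify_agreement` (independent local-conditions checker),
`ag.brute_force_agreement` (exhaustive oracle for ≤ 6–7 taxa), and
`ag.generate_profile` (seeded generator of profiles guaranteed to
agree, derived from a complete D-ary seed tree).

## Command line

```sh
# build an agreement tree (exit 0) or report disagreement (exit 1)
agreetree agree profile.nwk [more.nwk ...] [-o out.nwk] [--strip-synthetic]

# check a candidate supertree against a profile (exit 0 ok / 1 fail)
agreetree verify supertree.nwk profile.nwk

# deterministic synthetic profiles and benchmarks
agreetree generate -D 3 -m 500 -k 50 --seed 17 -o profile.nwk --manifest meta.json
agreetree bench --grid "2,100,10;3,500,50" --trials 3 -o bench.csv
```

Newick conventions: internal-node labels appear after `)`, quoted labels
follow the standard, branch lengths are parsed and discarded (the
algorithm is purely topological), one tree per line in multi-tree files.
Multiply-labeled nodes of an output agreement tree are written with
their taxa sorted and joined by `+` (configurable with `--delimiter`).
Exit codes: 0 agree/ok, 1 disagree/verification failure, 2 usage or
parse error.

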