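"""Tree searches: oracle equivalence, constraints, collapse, consensus."""

import numpy as np
import pytest

from conftest import all_rooted_trees, oracle_tree_length

from maxpars.matrix import CharacterMatrix
from maxpars.parsimony import min_steps, tree_length
from maxpars.search import (
    TopologyConstraint,
    branch_and_bound,
    collapse_zero,
    constrain,
    exhaustive_search,
    heuristic_search,
    strict_consensus,
)
from maxpars.simulate import simulate_matrix, simulate_tree
from maxpars.tree import parse_newick


def _random_instance(n_taxa, seed, n_char=10):
    tree = simulate_tree(n_taxa, seed=seed)
    m = simulate_matrix(
        tree, n_char=n_char, n_states=3, change_prob=0.25,
        ordered_fraction=0.2, missing_profile=0.1, seed=seed + 1000,
    )
    return tree, m


def test_three_taxa_single_topology():
    _, m = _random_instance(3, seed=1)
    result = exhaustive_search(m)
    assert result.nodes_visited == 1  # one unrooted shape on 3 tips
    _, m4 = _random_instance(4, seed=1)
    assert exhaustive_search(m4).nodes_visited == 3  # (2n-5)!! at n=4


def test_exhaustive_recovers_generating_tree_without_homoplasy():
    tree = simulate_tree(6, seed=2)
    m = simulate_matrix(tree, n_char=40, change_prob=0.06, seed=3)
    # only meaningful when the simulation happens to be homoplasy-free
    if tree_length(tree, m) == sum(min_steps(m, c) for c in range(m.n_char)):
        result = exhaustive_search(m)
        assert result.best_length == tree_length(tree, m)
        assert any(t.same_topology(tree, rooted=False) for t in result.trees)


def test_exhaustive_matches_oracle_enumeration():
    """Best length agrees with scoring every rooted shape by brute force."""
    tree, m = _random_instance(6, seed=4, n_char=8)
    result = exhaustive_search(m)
    labels = m.taxa
    oracle_best = min(
        oracle_tree_length(t, m) for t in all_rooted_trees(labels)
    )
    assert result.best_length == oracle_best


def test_exhaustive_cap():
    _, m = _random_instance(10, seed=5)
    with pytest.raises(ValueError, match="capped"):
        exhaustive_search(m)


@pytest.mark.parametrize("seed", range(12))
def test_branch_and_bound_equals_exhaustive(seed):
    n = 6 + seed % 3  # 6..8 taxa
    _, m = _random_instance(n, seed=seed + 10)
    ex = exhaustive_search(m)
    bb = branch_and_bound(m, seed=seed)
    assert bb.best_length == ex.best_length
    ex_keys = {frozenset(t.bipartitions()) for t in ex.trees}
    bb_keys = {frozenset(t.bipartitions()) for t in bb.trees}
    assert ex_keys == bb_keys


@pytest.mark.parametrize("seed", range(6))
def test_heuristic_never_beaten_by_its_own_bound(seed):
    _, m = _random_instance(8, seed=seed + 40)
    heur = heuristic_search(m, n_replicates=8, seed=seed)
    bb = branch_and_bound(m, seed=seed)
    assert bb.best_length <= heur.best_length
    # with several replicates SPR usually reaches the optimum at this size
    assert heur.best_length - bb.best_length <= 1


def test_heuristic_on_identical_taxa_scores_zero():
    m = CharacterMatrix(list("ABCDE"), [[frozenset([1])] * 6 for _ in "ABCDE"])
    heur = heuristic_search(m, n_replicates=2, seed=0)
    assert heur.best_length == 0


def test_search_results_reproducible_given_seed():
    _, m = _random_instance(8, seed=77)
    a = heuristic_search(m, n_replicates=5, seed=11)
    b = heuristic_search(m, n_replicates=5, seed=11)
    assert a.best_length == b.best_length
    assert [t.to_newick() for t in a.trees] == [t.to_newick() for t in b.trees]
    c = branch_and_bound(m, seed=3)
    d = branch_and_bound(m, seed=3)
    assert [t.to_newick() for t in c.trees] == [t.to_newick() for t in d.trees]


def _soft_length(tree, matrix):
    """Minimum length over binary resolutions of a (possibly polytomous)
    tree — enumeration oracle, small n only."""
    from conftest import all_rooted_trees

    want = tree.bipartitions()
    return min(
        tree_length(t, matrix)
        for t in all_rooted_trees(sorted(tree.leaf_labels()))
        if want <= t.bipartitions()
    )


def test_stored_trees_all_have_best_length():
    _, m = _random_instance(7, seed=13)
    result = branch_and_bound(m)
    for t in result.trees:
        # collapsed trees summarise binary resolutions at the optimum
        assert _soft_length(t, m) == result.best_length
    keys = [frozenset(t.bipartitions()) for t in result.trees]
    assert len(keys) == len(set(keys))  # pairwise distinct after collapse


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------


def test_constrain_validation():
    _, m = _random_instance(6, seed=20)
    con = constrain(m, m.taxa[1:3], "enforce")
    assert con.mode == "enforce"
    with pytest.raises(ValueError):
        constrain(m, m.taxa[1:] + ["nope"], "enforce")
    with pytest.raises(ValueError):  # full ingroup is improper
        constrain(m, m.taxa[1:], "prohibit")
    with pytest.raises(ValueError):
        constrain(m, m.taxa[:2], "sideways")


def test_enforce_cherry_on_four_taxa():
    # two characters favour (A,B)(C,D); one supports the enforced (A,C)
    m = CharacterMatrix(
        list("ABCD"),
        [
            [frozenset([0]), frozenset([0]), frozenset([1])],
            [frozenset([0]), frozenset([0]), frozenset([0])],
            [frozenset([1]), frozenset([1]), frozenset([1])],
            [frozenset([1]), frozenset([1]), frozenset([0])],
        ],
    )
    free = exhaustive_search(m, outgroup="B")
    assert free.best_length == 4
    con = constrain(m, ["A", "C"], "enforce")
    result = exhaustive_search(m, [con], outgroup="B")
    assert result.best_length == 5  # two characters each gain a step
    for t in result.trees:
        assert t.find_clade({"A", "C"}) is not None


def test_constrained_optimum_never_below_unconstrained():
    for seed in range(5):
        _, m = _random_instance(7, seed=seed + 60)
        free = branch_and_bound(m)
        clade = set(m.taxa[2:5])
        enforced = branch_and_bound(m, [constrain(m, clade, "enforce")])
        prohibited = branch_and_bound(m, [constrain(m, clade, "prohibit")])
        assert enforced.best_length >= free.best_length
        assert prohibited.best_length >= free.best_length
        assert min(enforced.best_length, prohibited.best_length) == free.best_length


def test_contradictory_constraints_rejected():
    _, m = _random_instance(6, seed=30)
    clade = set(m.taxa[1:3])
    with pytest.raises(ValueError, match="contradictory"):
        branch_and_bound(
            m,
            [constrain(m, clade, "enforce"), constrain(m, clade, "prohibit")],
        )


def test_constrained_bb_matches_filtered_exhaustive():
    for seed in range(4):
        _, m = _random_instance(6, seed=seed + 90)
        clade = set(m.taxa[2:4])
        for mode in ("enforce", "prohibit"):
            con = constrain(m, clade, mode)
            ex = exhaustive_search(m, [con])
            bb = branch_and_bound(m, [con], seed=seed)
            assert bb.best_length == ex.best_length
            assert {frozenset(t.bipartitions()) for t in bb.trees} == {
                frozenset(t.bipartitions()) for t in ex.trees
            }


# ---------------------------------------------------------------------------
# collapse rule
# ---------------------------------------------------------------------------


def test_edge_with_unambiguous_change_retained():
    m = CharacterMatrix(
        list("ABCD"),
        [[frozenset([0])], [frozenset([0])], [frozenset([1])], [frozenset([1])]],
    )
    tree = parse_newick("((A,B),(C,D));")
    collapsed = collapse_zero(tree, m)
    assert collapsed.same_topology(tree)


def test_all_missing_matrix_collapses_to_star():
    m = CharacterMatrix(list("ABCDE"), [[frozenset()] for _ in "ABCDE"])
    tree = parse_newick("((A,B),((C,D),E));")
    collapsed = collapse_zero(tree, m)
    assert collapsed.clades() == set()  # star


def test_collapse_preserves_length_and_matches_assignment_oracle():
    """Internal branches retained are exactly those carrying a change in
    every most-parsimonious assignment (checked by enumerating assignments
    on the unrooted shape)."""
    for seed in range(5):
        tree, m = _random_instance(6, seed=seed + 200, n_char=6)
        base = tree_length(tree, m)
        collapsed = collapse_zero(tree, m)
        # the input tree remains a resolution of the collapsed summary, so
        # the best resolution is at least as short as the input
        assert collapsed.bipartitions() <= tree.bipartitions()
        assert _soft_length(collapsed, m) <= base
        retained = collapsed.clades()
        root = tree.root
        for node in tree.internal_nodes(include_root=False):
            clade = frozenset(leaf.label for leaf in _leaves(node))
            if node.parent is root and len(root.children) == 2:
                sibling = next(c for c in root.children if c is not node)
                if sibling.is_leaf:
                    # pendant edge of that leaf: never collapsible
                    assert clade in retained
                    continue
                partner = sibling  # unrooted edge spans the fake root
            else:
                partner = node.parent
            if _min_edge_changes(tree, m, node, partner) > 0:
                assert clade in retained
            else:
                assert clade not in retained


def _leaves(node):
    if node.is_leaf:
        yield node
    else:
        for c in node.children:
            yield from _leaves(c)


def _min_edge_changes(tree, matrix, target, partner):
    """Oracle: summed minimum change between ``target`` and ``partner``
    states across all optimal assignments (brute force per character)."""
    from itertools import product

    total = 0
    internals = tree.internal_nodes()
    nodes = list(tree.postorder())
    root = tree.root
    for c in range(matrix.n_char):
        ordered = matrix.ordering(c) == "ordered"
        observed = sorted({s for row in matrix.cells for s in row[c]}) or [0]
        domain = (
            list(range(min(observed), max(observed) + 1)) if ordered else observed
        )

        def step(a, b):
            return abs(a - b) if ordered else (0 if a == b else 1)

        best_cost, best_edge = None, None
        for assign in product(domain, repeat=len(internals)):
            amap = dict(zip((id(n) for n in internals), assign))
            cost = 0
            for node in nodes:
                if node is root:
                    continue
                p = amap[id(node.parent)]
                if node.is_leaf:
                    cell = matrix.cell(node.label, c)
                    if cell:
                        cost += min(step(s, p) for s in cell)
                else:
                    cost += step(amap[id(node)], p)
            edge = step(amap[id(target)], amap[id(partner)])
            if best_cost is None or cost < best_cost:
                best_cost, best_edge = cost, edge
            elif cost == best_cost:
                best_edge = min(best_edge, edge)
        total += best_edge
    return total


# ---------------------------------------------------------------------------
# strict consensus
# ---------------------------------------------------------------------------


def test_consensus_idempotent_on_identical_trees():
    tree = parse_newick("((A,B),((C,D),E));")
    cons = strict_consensus([tree, tree.copy()])
    assert cons.same_topology(tree)


def test_consensus_of_conflicting_trees_is_star():
    a = parse_newick("((A,B),(C,D));")
    b = parse_newick("((A,C),(B,D));")
    assert strict_consensus([a, b]).clades() == set()


def test_consensus_keeps_exactly_shared_clades():
    a = parse_newick("((A,B),((C,D),(E,F)));")
    b = parse_newick("((A,B),((C,E),(D,F)));")
    cons = strict_consensus([a, b])
    assert cons.clades() == {
        frozenset({"A", "B"}),
        frozenset({"C", "D", "E", "F"}),  # shared by both resolutions
    }


def test_consensus_matches_dendropy():
    import dendropy

    trees = [
        parse_newick("((A,B),((C,D),(E,F)));"),
        parse_newick("(((A,B),C),(D,(E,F)));"),
        parse_newick("((A,(B,C)),((D,E),F));"),
    ]
    ours = strict_consensus(trees)
    tns = dendropy.TaxonNamespace()
    dlist = dendropy.TreeList(
        [
            dendropy.Tree.get(
                data=t.to_newick(), schema="newick", taxon_namespace=tns,
                rooting="force-rooted",
            )
            for t in trees
        ],
        taxon_namespace=tns,
    )
    dcons = dlist.consensus(min_freq=1.0)
    theirs = parse_newick(dcons.as_string(schema="newick").replace("[&R] ", ""))
    assert ours.clades() == theirs.clades()


def test_consensus_leaf_set_mismatch():
    with pytest.raises(ValueError, match="leaf set"):
        strict_consensus([parse_newick("(A,(B,C));"), parse_newick("(A,(B,D));")])
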