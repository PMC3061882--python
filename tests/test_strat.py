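"""Stratigraphic congruence metrics against enumeration oracles."""

import itertools
import math

import numpy as np
import pytest

from conftest import all_rooted_trees

from maxpars.ages import AgeTable
from maxpars.simulate import simulate_ages, simulate_tree
from maxpars.strat import (
    g_max,
    g_min,
    gap_excess,
    ger,
    metric_range,
    mig,
    msm_star,
    permutation_pvalue,
    prune,
    sci,
    strat_report,
)
from maxpars.tree import parse_newick


def _random_ages(labels, seed, lo=60.0, hi=170.0):
    rng = np.random.default_rng(seed)
    return {t: float(v) for t, v in zip(labels, rng.uniform(lo, hi, len(labels)))}


# ---------------------------------------------------------------------------
# prune
# ---------------------------------------------------------------------------


def test_prune_to_all_leaves_is_identity():
    tree = parse_newick("((A,B),((C,D),E));")
    assert prune(tree, tree.leaf_labels()).same_topology(tree)


def test_prune_caterpillar_to_alternating_leaves():
    tree = parse_newick("(A,(B,(C,(D,(E,F)))));")
    pruned = prune(tree, ["A", "C", "E"])
    assert pruned.same_topology(parse_newick("(A,(C,E));"))


def test_prune_rejects_foreign_taxa():
    tree = parse_newick("(A,(B,C));")
    with pytest.raises(ValueError):
        prune(tree, ["A", "Z"])


# ---------------------------------------------------------------------------
# MIG
# ---------------------------------------------------------------------------


def test_mig_hand_computed_caterpillar():
    # ages 40 > 30 > 20 > 10 on the matching ladder: each join implies a
    # ghost down to the younger member, total = 10+10+10 = the FAD range
    tree = parse_newick("(A,(B,(C,D)));")
    ages = {"A": 40.0, "B": 30.0, "C": 20.0, "D": 10.0}
    assert mig(tree, ages) == pytest.approx(30.0)
    assert gap_excess(tree, ages) == pytest.approx(0.0)


def test_mig_zero_iff_all_equal():
    tree = parse_newick("((A,B),(C,D));")
    assert mig(tree, {t: 50.0 for t in "ABCD"}) == 0.0


def test_mig_symmetric_under_equal_aged_sister_swap():
    tree = parse_newick("((A,B),(C,D));")
    ages = {"A": 50.0, "B": 30.0, "C": 30.0, "D": 20.0}
    swapped = {"A": 50.0, "C": 30.0, "B": 30.0, "D": 20.0}
    assert mig(tree, ages) == mig(tree, swapped)


def test_mig_missing_age_raises():
    tree = parse_newick("(A,(B,C));")
    with pytest.raises(ValueError, match="missing ages"):
        mig(tree, {"A": 10.0, "B": 9.0})


# ---------------------------------------------------------------------------
# SCI
# ---------------------------------------------------------------------------


def test_sci_perfectly_ordered_caterpillar():
    tree = parse_newick("(A,(B,(C,D)));")
    assert sci(tree, {"A": 40.0, "B": 30.0, "C": 20.0, "D": 10.0}) == 1.0


def test_sci_reversed_caterpillar_hand_audit():
    # oldest nested deepest: every scored node's subtree contains the oldest
    # FAD while its sister (a younger leaf) is younger => all inconsistent
    tree = parse_newick("(A,(B,(C,D)));")
    ages = {"A": 10.0, "B": 20.0, "C": 30.0, "D": 40.0}
    assert sci(tree, ages) == 0.0


def test_sci_ties_count_as_consistent():
    tree = parse_newick("((A,B),(C,D));")
    assert sci(tree, {t: 5.0 for t in "ABCD"}) == 1.0


def test_sci_needs_scored_nodes():
    with pytest.raises(ValueError):
        sci(parse_newick("(A,B,C);"), {"A": 3.0, "B": 2.0, "C": 1.0})


# ---------------------------------------------------------------------------
# GER and closed-form extremes
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(4))
def test_g_extremes_match_exhaustive_enumeration_n5(seed):
    labels = list("ABCDE")
    ages = _random_ages(labels, seed)
    migs = [mig(t, ages) for t in all_rooted_trees(labels)]
    assert min(migs) == pytest.approx(g_min(ages))
    assert max(migs) == pytest.approx(g_max(ages))


def test_ger_matches_formula_on_enumerated_extremes():
    labels = list("ABCDE")
    ages = _random_ages(labels, 11)
    trees = all_rooted_trees(labels)
    migs = [mig(t, ages) for t in trees]
    lo, hi = min(migs), max(migs)
    probe = trees[37]
    expected = 1.0 - (mig(probe, ages) - lo) / (hi - lo)
    assert ger(probe, ages) == pytest.approx(expected)


def test_ger_is_one_for_minimal_mig_topology():
    tree = parse_newick("(A,(B,(C,(D,E))));")
    ages = {"A": 50.0, "B": 40.0, "C": 30.0, "D": 20.0, "E": 10.0}
    assert ger(tree, ages) == pytest.approx(1.0)


def test_ger_degenerate_equal_ages():
    tree = parse_newick("((A,B),C);")
    assert ger(tree, {t: 9.0 for t in "ABC"}) == 1.0


# ---------------------------------------------------------------------------
# MSM* and the closed-form identity
# ---------------------------------------------------------------------------


def test_msm_star_congruent_comb_is_one():
    tree = parse_newick("(A,(B,(C,(D,E))));")
    ages = {"A": 50.0, "B": 40.0, "C": 30.0, "D": 20.0, "E": 10.0}
    assert msm_star(tree, ages) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(8))
def test_msm_star_identity_with_mig(seed):
    """The irreversible-DP length equals the summed implied gap, so
    MSM* = L_min/(L_min + excess) = L_min/MIG identically."""
    tree = simulate_tree(6, seed=seed)
    ages = _random_ages(tree.leaf_labels(), seed + 500)
    l_min = max(ages.values()) - min(ages.values())
    value = msm_star(tree, ages)
    assert value == pytest.approx(l_min / (l_min + gap_excess(tree, ages)))
    assert value == pytest.approx(l_min / mig(tree, ages))


def test_msm_star_all_equal_fads_is_one_by_convention():
    tree = parse_newick("((A,B),C);")
    assert msm_star(tree, {t: 7.0 for t in "ABC"}) == 1.0


@pytest.mark.parametrize("seed", range(6))
def test_metric_bounds_and_invariances(seed):
    tree = simulate_tree(7, seed=seed + 30)
    ages = _random_ages(tree.leaf_labels(), seed + 60)
    s, gr, ms = sci(tree, ages), ger(tree, ages), msm_star(tree, ages)
    assert 0.0 <= s <= 1.0 and 0.0 <= gr <= 1.0 and 0.0 < ms <= 1.0
    # GER and MSM* invariant to adding a constant; MSM* to rescaling; MIG linear
    shifted = {t: v + 37.0 for t, v in ages.items()}
    scaled = {t: v * 2.5 for t, v in ages.items()}
    assert ger(tree, shifted) == pytest.approx(gr)
    assert msm_star(tree, shifted) == pytest.approx(ms)
    assert msm_star(tree, scaled) == pytest.approx(ms)
    assert mig(tree, scaled) == pytest.approx(2.5 * mig(tree, ages))


def test_congruent_ages_make_all_metrics_one():
    for seed in range(5):
        tree = simulate_tree(8, seed=seed + 70)
        table = simulate_ages(tree, mode="congruent", seed=seed)
        ages = table.points
        assert gap_excess(tree, ages) == pytest.approx(0.0, abs=1e-9)
        assert sci(tree, ages) == 1.0
        assert ger(tree, ages) == pytest.approx(1.0)
        assert msm_star(tree, ages) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# interval ranges
# ---------------------------------------------------------------------------


def test_metric_range_degenerate_intervals():
    tree = parse_newick("(A,(B,(C,D)));")
    table = AgeTable({"A": (40, 40), "B": (30, 30), "C": (20, 20), "D": (10, 10)})
    lo, hi = metric_range(tree, table, "ger")
    point = ger(tree, {"A": 40.0, "B": 30.0, "C": 20.0, "D": 10.0})
    assert lo == hi == pytest.approx(point)


def test_metric_range_widening_never_narrows():
    tree = parse_newick("((A,B),(C,D));")
    narrow = AgeTable({"A": (45, 44), "B": (30, 29), "C": (22, 21), "D": (12, 11)})
    wide = AgeTable({"A": (48, 41), "B": (30, 29), "C": (22, 21), "D": (12, 11)})
    lo_n, hi_n = metric_range(tree, narrow, "msm")
    lo_w, hi_w = metric_range(tree, wide, "msm")
    assert lo_w <= lo_n and hi_w >= hi_n


def test_metric_range_matches_full_enumeration_9_taxa():
    tree = simulate_tree(9, seed=5)
    table = simulate_ages(tree, mode="shuffled", seed=6)
    lo, hi = metric_range(tree, table, "ger")
    taxa = tree.leaf_labels()
    values = []
    for combo in itertools.product(*(table.interval(t) for t in taxa)):
        values.append(ger(tree, dict(zip(taxa, combo))))
    assert lo == pytest.approx(min(values))
    assert hi == pytest.approx(max(values))


def test_metric_range_cap_and_fallback():
    tree = simulate_tree(17, seed=8)
    table = simulate_ages(tree, mode="shuffled", seed=9)
    with pytest.raises(ValueError, match="cap"):
        metric_range(tree, table, "ger")
    lo, hi = metric_range(tree, table, "ger", approximate=True)
    assert lo <= hi


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


def test_permutation_pvalue_small_for_congruent_comb():
    tree = parse_newick("(A,(B,(C,(D,(E,(F,(G,(H,(I,J)))))))));")
    ages = {t: 100.0 - 8 * i for i, t in enumerate("ABCDEFGHIJ")}
    p1 = permutation_pvalue(tree, ages, "msm", n_perm=99, seed=1, exact=False)
    p2 = permutation_pvalue(tree, ages, "msm", n_perm=999, seed=1, exact=False)
    assert p1 <= 0.05
    assert p2 <= p1


def test_permutation_pvalue_equal_ages_is_one():
    tree = parse_newick("((A,B),(C,D));")
    assert permutation_pvalue(tree, {t: 5.0 for t in "ABCD"}, "msm", 200) == 1.0


def test_permutation_sampler_matches_exact_enumeration_n6():
    tree = simulate_tree(6, seed=3)
    ages = _random_ages(tree.leaf_labels(), 44)
    exact = permutation_pvalue(tree, ages, "msm", n_perm=720, exact=True)
    # direct independent enumeration
    taxa = tree.leaf_labels()
    values = list(ages.values())
    obs = msm_star(tree, ages)
    hits = sum(
        1
        for perm in itertools.permutations(values)
        if msm_star(tree, dict(zip(taxa, perm))) >= obs - 1e-9
    )
    assert exact == pytest.approx(hits / math.factorial(6))
    sampled = permutation_pvalue(tree, ages, "msm", n_perm=4000, seed=0, exact=False)
    assert sampled == pytest.approx(exact, abs=0.05)


# ---------------------------------------------------------------------------
# report plumbing
# ---------------------------------------------------------------------------


def test_strat_report_bundles_consistent_values():
    tree = simulate_tree(7, seed=21)
    table = simulate_ages(tree, mode="shuffled", seed=22)
    report = strat_report(tree, table, n_perm=200, seed=1)
    ages = table.point_ages("max")
    assert report.sci == pytest.approx(sci(tree, ages))
    assert report.ger == pytest.approx(ger(tree, ages))
    assert report.msm_star == pytest.approx(msm_star(tree, ages))
    assert report.ger_range[0] <= report.ger <= report.ger_range[1]
    assert report.msm_range[0] <= report.msm_star <= report.msm_range[1]
    assert 0.0 < report.p_value <= 1.0
    summary = report.summary()
    assert set(summary) >= {"MIG", "SCI", "GER", "MSM*", "p_MSM*"}
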