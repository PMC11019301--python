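"""Ancestral reconstruction: parsimony, Mk ML, and gain-event counting."""

import numpy as np
import pytest

from oracles import brute_force_parsimony, brute_force_posteriors, random_tree_newick
from uvopsin.ancestral import (
    AncestralError,
    count_gain_events,
    fitch_states,
    joint_site_label,
    mask_tips,
    ml_marginal_states,
    read_tree,
)


def test_constant_character_is_changeless():
    tree = read_tree("((t1,t2),(t3,t4));")
    count, assignment = fitch_states(tree, {t: "A" for t in ["t1", "t2", "t3", "t4"]})
    assert count == 0
    assert all(s == "A" for s in assignment.states.values())


def test_two_clade_split_costs_one_change():
    tree = read_tree("((t1,t2),(t3,t4));")
    count, assignment = fitch_states(tree, {"t1": "A", "t2": "A", "t3": "S", "t4": "S"})
    assert count == 1
    assert assignment.state_sets[assignment.root_label] == frozenset({"A", "S"})


@pytest.mark.parametrize("seed", range(1, 41))
def test_fitch_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 7))
    tree = read_tree(random_tree_newick(rng, n))
    alphabet = ["A", "S", "T"]
    tips = {f"t{i}": alphabet[rng.integers(3)] for i in range(1, n + 1)}
    count, _ = fitch_states(tree, tips, extra_states=alphabet)
    expected = brute_force_parsimony(
        tree, tips, alphabet, cost=lambda a, b: float(a != b)
    )
    assert count == expected


@pytest.mark.parametrize("seed", range(1, 41))
def test_fitch_labelling_achieves_its_own_count(seed):
    """The deterministic top-down labelling is itself a minimum-change history."""
    rng = np.random.default_rng(1000 + seed)
    n = int(rng.integers(4, 8))
    tree = read_tree(random_tree_newick(rng, n))
    tips = {f"t{i}": "AS"[rng.integers(2)] for i in range(1, n + 1)}
    count, assignment = fitch_states(tree, tips)
    realized = sum(
        assignment.states[node.parent_node.label] != assignment.states[node.label]
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
    )
    assert realized == count


def test_ml_constant_character_high_root_posterior():
    tree = read_tree("((t1:0.05,t2:0.05):0.05,(t3:0.05,t4:0.05):0.05);")
    ml = ml_marginal_states(tree, {t: "A" for t in ["t1", "t2", "t3", "t4"]},
                            extra_states=["S"])
    assert ml.posteriors[ml.root_label]["A"] >= 0.99


def test_ml_symmetric_tree_gives_half_half():
    tree = read_tree("((t1:1,t2:1):1,(t3:1,t4:1):1);")
    ml = ml_marginal_states(tree, {"t1": "A", "t2": "S", "t3": "A", "t4": "S"})
    post = ml.posteriors[ml.root_label]
    assert post["A"] == pytest.approx(0.5, abs=1e-12)
    assert post["S"] == pytest.approx(0.5, abs=1e-12)


def test_ml_single_tip_rejected():
    with pytest.raises(AncestralError):
        ml_marginal_states(read_tree("(t1);"), {"t1": "A"})


@pytest.mark.parametrize("seed", range(1, 16))
def test_ml_matches_brute_force_summation(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 6))
    tree = read_tree(random_tree_newick(rng, n))
    alphabet = ["A", "G", "S"]
    tips = {f"t{i}": alphabet[rng.integers(3)] for i in range(1, n + 1)}
    ml = ml_marginal_states(tree, tips, extra_states=alphabet, rate=0.7)
    expected = brute_force_posteriors(tree, tips, alphabet, rate=0.7)
    for label, probs in expected.items():
        for state, p in probs.items():
            assert ml.posteriors[label][state] == pytest.approx(p, abs=1e-8)


def test_ml_invariant_to_tip_order():
    tips = {"t1": "A", "t2": "S", "t3": "A", "t4": "S", "t5": "A"}
    tree_a = read_tree("((t1:0.2,(t2:0.1,t3:0.3):0.2):0.1,(t4:0.4,t5:0.2):0.3);")
    tree_b = read_tree("(((t3:0.3,t2:0.1):0.2,t1:0.2):0.1,(t5:0.2,t4:0.4):0.3);")
    ml_a = ml_marginal_states(tree_a, tips)
    ml_b = ml_marginal_states(tree_b, tips)
    assert ml_a.posteriors[ml_a.root_label] == pytest.approx(
        ml_b.posteriors[ml_b.root_label]
    )


def test_masking_reference_tips_marginalizes_them():
    tree = read_tree("((t1:0.1,t2:0.1):0.1,(t3:0.1,t4:0.1):0.1);")
    tips = {"t1": "A", "t2": "A", "t3": "A", "t4": "S"}
    masked = mask_tips(tips, ["t4"])
    with pytest.warns(UserWarning, match="missing"):
        ml = ml_marginal_states(tree, masked, extra_states=["S"])
    assert ml.posteriors[ml.root_label]["A"] > 0.9


def test_joint_site_label_combines_sites():
    tree = read_tree("((t1,t2),(t3,t4));")
    tips114 = {"t1": "A", "t2": "A", "t3": "A", "t4": "A"}
    tips118 = {"t1": "S", "t2": "S", "t3": "S", "t4": "S"}
    _, a114 = fitch_states(tree, tips114)
    _, a118 = fitch_states(tree, tips118)
    assert joint_site_label(a114, a118, a114.root_label) == "AS"
    assert joint_site_label(a114, a118, "t1") == "AS"
    with pytest.raises(AncestralError):
        joint_site_label(a114, a118, "no_such_node")


def test_joint_site_label_rejects_mismatched_trees():
    tree_a = read_tree("((t1,t2),(t3,t4));")
    tree_b = read_tree("((u1,u2),(u3,u4));")
    _, a = fitch_states(tree_a, {t: "A" for t in ["t1", "t2", "t3", "t4"]})
    _, b = fitch_states(tree_b, {t: "S" for t in ["u1", "u2", "u3", "u4"]})
    with pytest.raises(AncestralError, match="same tree"):
        joint_site_label(a, b, "N0")


def test_single_monophyletic_origin():
    tree = read_tree("(((t1,t2),t3),(t4,t5));")
    report = count_gain_events(tree, {"t1": 1, "t2": 1, "t3": 0, "t4": 0, "t5": 0})
    assert report.n_gains == 1 and report.n_losses == 0


def test_gain_loss_budget_equals_cost():
    tree = read_tree("((((t1,t2),t3),t4),t5);")
    presence = {"t1": 1, "t2": 0, "t3": 1, "t4": 0, "t5": 0}
    report = count_gain_events(tree, presence)
    assert report.n_gains + report.n_losses == report.total_cost


@pytest.mark.parametrize("seed", range(1, 41))
def test_sankoff_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 8))
    tree = read_tree(random_tree_newick(rng, n))
    presence = {f"t{i}": int(rng.integers(2)) for i in range(1, n + 1)}
    if not any(presence.values()):
        presence["t1"] = 1
    gain_cost, loss_cost = float(rng.choice([1.0, 2.0])), 1.0
    report = count_gain_events(tree, presence, gain_cost=gain_cost, loss_cost=loss_cost)

    def cost(a, b):
        if a == b:
            return 0.0
        return gain_cost if (a, b) == (0, 1) else loss_cost

    expected = brute_force_parsimony(tree, presence, [0, 1], cost)
    assert report.total_cost == expected
    assert report.n_gains * gain_cost + report.n_losses * loss_cost == report.total_cost


@pytest.mark.parametrize("seed", range(1, 41))
def test_fitch_equals_unit_cost_sankoff(seed):
    """Unit-cost weighted parsimony and Fitch agree on the change count."""
    rng = np.random.default_rng(2000 + seed)
    n = int(rng.integers(4, 8))
    tree = read_tree(random_tree_newick(rng, n))
    presence = {f"t{i}": int(rng.integers(2)) for i in range(1, n + 1)}
    if not any(presence.values()):
        presence["t2"] = 1
    count, _ = fitch_states(tree, {k: str(v) for k, v in presence.items()},
                            extra_states=["0", "1"])
    report = count_gain_events(tree, presence, gain_cost=1.0, loss_cost=1.0)
    assert float(count) == report.total_cost


def test_missing_tips_marginalized_with_warning():
    tree = read_tree("((t1,t2),(t3,t4));")
    with pytest.warns(UserWarning, match="missing"):
        report = count_gain_events(tree, {"t1": 1, "t2": 1, "t3": None, "t4": 0})
    assert report.n_gains == 1


def test_all_missing_rejected():
    tree = read_tree("((t1,t2),(t3,t4));")
    with pytest.raises(AncestralError):
        count_gain_events(tree, {"t1": None, "t2": None, "t3": None, "t4": None})
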