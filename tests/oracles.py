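"""Independent brute-force oracles for the tree reconstructions.

These enumerate every internal-node state assignment, so they are exact for
small trees and share no code with the dynamic-programming implementations
they check.
"""

from __future__ import annotations

import itertools

import numpy as np

from uvopsin.ancestral import _mk_transition, label_nodes


def brute_force_parsimony(tree, tip_states, alphabet, cost):
    """Minimum total change cost over all internal assignments.

    ``cost(parent_state, child_state)`` is charged on every edge.
    """
    label_nodes(tree)
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = float("inf")
    for combo in itertools.product(alphabet, repeat=len(internal)):
        assigned = {node.label: state for node, state in zip(internal, combo)}
        for leaf in tree.leaf_node_iter():
            assigned[leaf.taxon.label] = tip_states[leaf.taxon.label]
        total = 0.0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            total += cost(assigned[node.parent_node.label], assigned[node.label])
        best = min(best, total)
    return best


def brute_force_posteriors(tree, tip_states, alphabet, rate=1.0, default_bl=1.0):
    """Marginal posteriors by full summation over internal assignments."""
    label_nodes(tree)
    alphabet = sorted(alphabet)
    k = len(alphabet)
    idx = {s: i for i, s in enumerate(alphabet)}
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    weights = {
        node.label: np.zeros(k) for node in tree.preorder_node_iter()
    }
    total = 0.0
    for combo in itertools.product(alphabet, repeat=len(internal)):
        assigned = {node.label: state for node, state in zip(internal, combo)}
        for leaf in tree.leaf_node_iter():
            assigned[leaf.taxon.label] = tip_states[leaf.taxon.label]
        prob = 1.0 / k  # uniform root prior
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            t = node.edge.length if node.edge.length is not None else default_bl
            P = _mk_transition(k, rate, t)
            prob *= P[idx[assigned[node.parent_node.label]], idx[assigned[node.label]]]
        total += prob
        for node in tree.preorder_node_iter():
            weights[node.label][idx[assigned[node.label]]] += prob
    return {
        label: {s: w[idx[s]] / total for s in alphabet} for label, w in weights.items()
    }


def random_tree_newick(rng, n_tips, max_bl=1.0):
    """Random binary topology with rng-drawn branch lengths."""
    nodes = [f"t{i}" for i in range(1, n_tips + 1)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        bl1, bl2 = rng.uniform(0.05, max_bl, size=2)
        merged = f"({a}:{bl1:.3f},{b}:{bl2:.3f})"
        nodes = [x for kk, x in enumerate(nodes) if kk not in (i, j)] + [merged]
    return nodes[0] + ";"
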