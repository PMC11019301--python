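"""Ancestral reconstruction of discrete characters on rooted trees.

Two reconstruction routes are provided for tuning-site residues so claims
about ancestral pigments can be probed under both:

* Fitch/Hartigan parsimony (:func:`fitch_states`) — minimum-change count,
  per-node candidate sets, and one deterministic minimum-change labelling.
* Marginal maximum likelihood under an equal-rates Mk model
  (:func:`ml_marginal_states`) — per-node posterior probabilities via the
  pruning algorithm with an outside (up) pass.

Gene-copy presence/absence is handled by weighted small parsimony
(:func:`count_gain_events`, Sankoff) with configurable gain/loss costs;
a gain (absent -> present) is the observable trace of a duplication
becoming detectable in a lineage.

Trees are consumed as rooted dendropy trees; this package never infers
topologies (upstream ML searches are out of scope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import dendropy
import numpy as np


class AncestralError(ValueError):
    pass


def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a rooted newick tree from a path or a newick string."""
    text = str(source)
    if ";" not in text and "(" not in text:  # a path, not a newick string
        text = Path(text).read_text()
    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    label_nodes(tree)
    return tree


def label_nodes(tree: dendropy.Tree) -> dendropy.Tree:
    """Give every node a stable label: taxon label for tips, N<i> preorder otherwise."""
    counter = 0
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            node.label = node.taxon.label
        elif not node.label:
            node.label = f"N{counter}"
        counter += 1
    return tree


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


@dataclass
class StateAssignment:
    """Per-node reconstructed states on one tree.

    ``states`` maps node label -> reported state. ``state_sets`` carries the
    parsimony candidate sets (Fitch route); ``posteriors`` the per-state
    marginal probabilities (ML route).
    """

    tree: dendropy.Tree
    states: dict[str, str]
    method: str
    state_sets: dict[str, frozenset] | None = None
    posteriors: dict[str, dict[str, float]] | None = None

    @property
    def root_label(self) -> str:
        return self.tree.seed_node.label


@dataclass(frozen=True)
class GainEventReport:
    n_gains: int
    gain_branches: tuple[str, ...]
    n_losses: int
    loss_branches: tuple[str, ...]
    total_cost: float
    states: Mapping[str, int]


def _resolve_tips(
    tree: dendropy.Tree, tip_states: Mapping[str, Hashable], strict: bool
) -> dict[str, Hashable]:
    resolved: dict[str, Hashable] = {}
    missing = []
    for label in _leaf_labels(tree):
        state = tip_states.get(label)
        if state is None:
            missing.append(label)
        else:
            resolved[label] = state
    if missing:
        if strict:
            raise AncestralError(f"tips without a state: {missing}")
        warnings.warn(f"tips without a state treated as missing data: {missing}")
    if not resolved:
        raise AncestralError("no tip has an observed state")
    return resolved


def fitch_states(
    tree: dendropy.Tree,
    tip_states: Mapping[str, str],
    extra_states: Iterable[str] = (),
    strict: bool = False,
) -> tuple[int, StateAssignment]:
    """Hartigan (multifurcation-safe Fitch) parsimony reconstruction.

    Returns the minimum change count and an assignment whose ``state_sets``
    are the per-node most-parsimonious candidate sets. The concrete labelling
    keeps the parent state wherever admissible and otherwise takes the
    lexicographic minimum, so output is reproducible.
    """
    label_nodes(tree)
    resolved = _resolve_tips(tree, tip_states, strict)
    alphabet = frozenset(resolved.values()) | frozenset(extra_states)

    upper: dict[str, frozenset] = {}
    changes = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = resolved.get(node.taxon.label)
            upper[node.label] = frozenset([state]) if state is not None else alphabet
            continue
        counts: dict[Hashable, int] = {}
        children = node.child_nodes()
        for child in children:
            for s in upper[child.label]:
                counts[s] = counts.get(s, 0) + 1
        best = max(counts.values())
        upper[node.label] = frozenset(s for s, c in counts.items() if c == best)
        changes += len(children) - best

    states: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        candidates = upper[node.label]
        if node.parent_node is not None and states[node.parent_node.label] in candidates:
            states[node.label] = states[node.parent_node.label]
        else:
            states[node.label] = min(candidates)

    return changes, StateAssignment(tree=tree, states=states, method="fitch", state_sets=upper)


# ------------------------------------------------------------------- Mk / ML

def _mk_transition(k: int, rate: float, t: float) -> np.ndarray:
    """Equal-rates Mk transition matrix; branch length in expected substitutions."""
    if k == 1:
        return np.ones((1, 1))
    decay = np.exp(-k * rate * t / (k - 1))
    same = 1.0 / k + (k - 1) / k * decay
    diff = 1.0 / k - 1.0 / k * decay
    matrix = np.full((k, k), diff)
    np.fill_diagonal(matrix, same)
    return matrix


def ml_marginal_states(
    tree: dendropy.Tree,
    tip_states: Mapping[str, str],
    extra_states: Iterable[str] = (),
    rate: float = 1.0,
    default_branch_length: float = 1.0,
    strict: bool = False,
) -> StateAssignment:
    """Marginal ML ancestral states under an equal-rates Mk model.

    Posteriors come from the pruning algorithm (inside pass) combined with an
    outside pass, a uniform root prior, and branch lengths as given (absent
    lengths default to ``default_branch_length``). The reported state is the
    posterior argmax with lexicographic tie-break.
    """
    label_nodes(tree)
    leaves = _leaf_labels(tree)
    if len(leaves) < 2:
        raise AncestralError("tree must have at least two tips")
    resolved = _resolve_tips(tree, tip_states, strict)
    alphabet = sorted(set(resolved.values()) | set(extra_states))
    k = len(alphabet)
    index = {s: i for i, s in enumerate(alphabet)}

    def branch_p(node: dendropy.Node) -> np.ndarray:
        t = node.edge.length if node.edge.length is not None else default_branch_length
        return _mk_transition(k, rate, t)

    inside: dict[str, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = resolved.get(node.taxon.label)
            vec = np.ones(k) if state is None else np.eye(k)[index[state]]
            inside[node.label] = vec
            continue
        vec = np.ones(k)
        for child in node.child_nodes():
            vec = vec * (branch_p(child) @ inside[child.label])
        inside[node.label] = vec

    pi = np.full(k, 1.0 / k)
    outside: dict[str, np.ndarray] = {tree.seed_node.label: pi.copy()}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        messages = {c.label: branch_p(c) @ inside[c.label] for c in children}
        for child in children:
            excl = outside[node.label].copy()
            for other in children:
                if other is not child:
                    excl = excl * messages[other.label]
            outside[child.label] = excl @ branch_p(child)

    posteriors: dict[str, dict[str, float]] = {}
    states: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        joint = outside[node.label] * inside[node.label]
        total = joint.sum()
        if total <= 0:
            raise AncestralError(f"zero likelihood at node {node.label}")
        post = joint / total
        posteriors[node.label] = {s: float(post[index[s]]) for s in alphabet}
        best = post.max()
        states[node.label] = min(s for s in alphabet if post[index[s]] >= best - 1e-12)

    return StateAssignment(
        tree=tree, states=states, method="ml-mk", posteriors=posteriors
    )


def joint_site_label(
    assignment_114: StateAssignment, assignment_118: StateAssignment, node_label: str
) -> str:
    """Two-letter pigment label, order (site 114, site 118), e.g. "AS"."""
    if set(assignment_114.states) != set(assignment_118.states):
        raise AncestralError("assignments are not on the same tree")
    try:
        return assignment_114.states[node_label] + assignment_118.states[node_label]
    except KeyError as exc:
        raise AncestralError(f"node {node_label!r} absent from assignment") from exc


def count_gain_events(
    tree: dendropy.Tree,
    presence: Mapping[str, int | None],
    gain_cost: float = 1.0,
    loss_cost: float = 1.0,
) -> GainEventReport:
    """Minimum-cost gain/loss history of a gene copy (Sankoff small parsimony).

    ``presence`` maps tip label -> 1 (copy present), 0 (absent) or None
    (unknown, e.g. transcriptome with no call — marginalized over). Ties
    prefer the absent state, which places gains as tipward as possible.
    """
    label_nodes(tree)
    resolved = _resolve_tips(tree, {k: v for k, v in presence.items() if v is not None}, False)
    if any(v not in (0, 1) for v in resolved.values()):
        raise AncestralError("presence states must be 0/1 (or None for missing)")

    big = float("inf")
    trans = np.array([[0.0, gain_cost], [loss_cost, 0.0]])  # [from, to]

    cost: dict[str, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = resolved.get(node.taxon.label)
            if state is None:
                cost[node.label] = np.zeros(2)
            else:
                vec = np.full(2, big)
                vec[state] = 0.0
                cost[node.label] = vec
            continue
        vec = np.zeros(2)
        for child in node.child_nodes():
            child_cost = cost[child.label]
            vec += np.array(
                [min(child_cost[s] + trans[p, s] for s in (0, 1)) for p in (0, 1)]
            )
        cost[node.label] = vec

    states: dict[str, int] = {}
    root = tree.seed_node
    root_cost = cost[root.label]
    states[root.label] = 0 if root_cost[0] <= root_cost[1] else 1
    gains: list[str] = []
    losses: list[str] = []
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = states[node.parent_node.label]
        options = [cost[node.label][s] + trans[parent_state, s] for s in (0, 1)]
        state = 0 if options[0] <= options[1] else 1
        states[node.label] = state
        if parent_state == 0 and state == 1:
            gains.append(node.label)
        elif parent_state == 1 and state == 0:
            losses.append(node.label)

    return GainEventReport(
        n_gains=len(gains),
        gain_branches=tuple(gains),
        n_losses=len(losses),
        loss_branches=tuple(losses),
        total_cost=float(min(root_cost)),
        states=states,
    )


def mask_tips(tip_states: Mapping[str, str], masked: Iterable[str]) -> dict[str, str | None]:
    """Set selected tips' states to missing (the reference-species control)."""
    masked = set(masked)
    return {label: (None if label in masked else state) for label, state in tip_states.items()}


def annotate_tree(tree: dendropy.Tree, assignment: StateAssignment) -> str:
    """Newick with reconstructed states (and posteriors, if any) as node comments."""
    label_nodes(tree)
    for node in tree.preorder_node_iter():
        state = assignment.states.get(node.label)
        if state is None:
            continue
        comment = f"state={state}"
        if assignment.posteriors is not None:
            probs = assignment.posteriors[node.label]
            comment += "," + ",".join(f"p_{s}={p:.4f}" for s, p in sorted(probs.items()))
        node.annotations.add_new("reconstruction", comment)
    return tree.as_string(schema="newick", suppress_annotations=False, unquoted_underscores=True)
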