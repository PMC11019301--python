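"""Synthetic inputs with known ground truth for every analysis stage.

The generators emulate the study system — SWS1-like proteins diverging at
canonical tuning sites on a species tree, gene-copy presence matrices with
planted duplication (gain) events, multinomial read counts from known
expression proportions, and sigmoidal long-pass lens spectra — so that each
stage of the package can be tested for exact recovery without downloads.
Every generator records its planted truth alongside its output; recovery
tests read truth only from those sidecars.

A single seed fans out to fixed per-generator streams, so adding a
generator never perturbs existing fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .ancestral import label_nodes, read_tree
from .numbering import ALL_SITES, OpsinSequence, load_anchor, write_fasta

#: package SWS1 consensus residues at the canonical sites; 114/118 carry the
#: ancestral "AS" intermediate pigment
SWS1_CONSENSUS: dict[int, str] = {
    46: "F", 49: "L", 52: "F", 86: "F", 90: "S", 91: "V", 93: "T", 97: "A",
    109: "A", 113: "E", 114: "A", 116: "S", 118: "S", 265: "W", 125: "S",
}

_STREAMS = {"tree": 11, "tips": 13, "counts": 17, "presence": 19, "spectrum": 23}

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


class SimulationError(ValueError):
    pass


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


# CladeSpec: tuple of tip labels -> planted value; resolved to the MRCA
CladeSpec = Mapping[tuple[str, ...], object]


@dataclass
class SimulationConfig:
    """The stated world of the synthetic study system.

    Defaults emulate the study-scale setup: a balanced 8-tip tree whose left
    half carries the short (AA) pigment and right half the long (SS) pigment
    over an AS ancestor, two disjoint planted copy-number gains, realistic
    opsin CDS lengths (~1 kb) with one million single-cone reads, and a
    UV-transmitting lens with its logistic midpoint at 380 nm.
    """

    seed: int = 0
    tree_shape: str = "balanced"  # balanced | pectinate | random
    n_tips: int = 8
    branch_length: float = 0.1
    rate: float = 0.005  # background substitution probability / site / branch
    root_state: tuple[str, str] = ("A", "S")
    clade_states: CladeSpec | None = None
    gain_clades: Sequence[tuple[str, ...]] | None = None
    loss_clades: Sequence[tuple[str, ...]] = ()
    true_proportions: Mapping[str, Mapping[str, float]] | None = None
    cds_lengths: Mapping[str, int] | None = None
    total_reads: int = 1_000_000
    spectrum_midpoint: float = 380.0
    spectrum_width: float = 10.0
    spectrum_noise_sd: float = 0.5
    mutate_tuning_sites: bool = False

    def __post_init__(self) -> None:
        if self.clade_states is None:
            half = self.n_tips // 2
            self.clade_states = {
                tuple(f"t{i}" for i in range(1, half + 1)): ("A", "A"),
                tuple(f"t{i}" for i in range(half + 1, self.n_tips + 1)): ("S", "S"),
            }
        if self.gain_clades is None:
            # study-shaped default: one single-species gain and one clade-level gain
            half = self.n_tips // 2
            self.gain_clades = [
                ("t1",),
                tuple(f"t{i}" for i in range(half + 1, self.n_tips + 1)),
            ]
        if self.true_proportions is None:
            self.true_proportions = {
                "single-cone": {"SWS1A": 0.45, "SWS1B": 0.25, "SWS2B": 0.30},
                "double-cone": {"RH2A": 0.50, "RH2B": 0.30, "LWS": 0.20},
            }
        if self.cds_lengths is None:
            self.cds_lengths = {
                "SWS1A": 1044, "SWS1B": 1044, "SWS2B": 1062,
                "RH2A": 1056, "RH2B": 1056, "LWS": 1074,
            }


# -------------------------------------------------------------------- trees

def make_tree(config: SimulationConfig) -> dendropy.Tree:
    """Tree of the configured shape with tips t1..tn and uniform branch lengths."""
    n, bl = config.n_tips, config.branch_length
    if n < 2:
        raise SimulationError("need at least two tips")
    labels = [f"t{i}" for i in range(1, n + 1)]

    def join(a: str, b: str) -> str:
        return f"({a}:{bl},{b}:{bl})"

    if config.tree_shape == "balanced":
        nodes = labels[:]
        while len(nodes) > 1:
            nodes = [
                join(nodes[i], nodes[i + 1]) if i + 1 < len(nodes) else nodes[i]
                for i in range(0, len(nodes), 2)
            ]
        newick = nodes[0]
    elif config.tree_shape == "pectinate":
        newick = labels[0]
        for label in labels[1:]:
            newick = join(newick, label)
    elif config.tree_shape == "random":
        rng = _rng(config.seed, "tree")
        nodes = labels[:]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            merged = join(nodes[i], nodes[j])
            nodes = [x for idx, x in enumerate(nodes) if idx not in (i, j)] + [merged]
        newick = nodes[0]
    else:
        raise SimulationError(f"unknown tree shape {config.tree_shape!r}")
    return read_tree(newick + ";")


def _resolve_clades(tree: dendropy.Tree, spec: CladeSpec) -> dict[str, object]:
    """Map MRCA node label -> planted value for each tip-set clade spec."""
    resolved = {}
    for tips, value in spec.items():
        mrca = tree.mrca(taxon_labels=list(tips))
        if mrca is None:
            raise SimulationError(f"no MRCA for tips {tips}")
        resolved[mrca.label] = value
    return resolved


def _descend(tree: dendropy.Tree, root_value, overrides: dict[str, object]) -> dict[str, object]:
    """Inherit a value root-to-tip, overriding at planted nodes."""
    values: dict[str, object] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            inherited = root_value
        else:
            inherited = values[node.parent_node.label]
        values[node.label] = overrides.get(node.label, inherited)
    return values


# ----------------------------------------------------------- opsin sequences

@dataclass
class OpsinSimulation:
    sequences: list[OpsinSequence]
    tree: dendropy.Tree
    true_states: dict[str, tuple[str, str]]  # node label -> (res114, res118)
    config: SimulationConfig


def simulate_opsin_tips(config: SimulationConfig) -> OpsinSimulation:
    """Evolve SWS1-like proteins on a tree with planted 114/118 states.

    The root is the bovine anchor with the package SWS1 consensus planted at
    the canonical sites. Substitution-only evolution (no indels) keeps the
    bovine numbering of every tip an identity map, so planted tuning states
    are recovered exactly by alignment-based extraction. Background
    substitutions avoid the tuning sites unless ``mutate_tuning_sites``.
    """
    if config.rate < 0:
        raise SimulationError("substitution rate must be non-negative")
    tree = make_tree(config)
    overrides = _resolve_clades(tree, config.clade_states)
    states = _descend(tree, tuple(config.root_state), overrides)

    anchor = load_anchor()
    root_seq = list(anchor.residues)
    for site, residue in SWS1_CONSENSUS.items():
        root_seq[site - 1] = residue

    protected = set() if config.mutate_tuning_sites else {s - 1 for s in ALL_SITES}
    rng = _rng(config.seed, "tips")
    sequences_at: dict[str, list[str]] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seq = root_seq[:]
        else:
            seq = sequences_at[node.parent_node.label][:]
            if config.rate > 0:
                hits = np.nonzero(rng.random(len(seq)) < config.rate)[0]
                for pos in hits:
                    if pos in protected:
                        continue
                    choices = [aa for aa in _AA20 if aa != seq[pos]]
                    seq[pos] = choices[rng.integers(len(choices))]
        s114, s118 = states[node.label]
        seq[113], seq[117] = s114, s118
        sequences_at[node.label] = seq

    sequences = [
        OpsinSequence(
            id=leaf.taxon.label,
            species=leaf.taxon.label,
            gene="SWS1",
            residues="".join(sequences_at[leaf.taxon.label]),
        )
        for leaf in tree.leaf_node_iter()
    ]
    return OpsinSimulation(sequences, tree, {k: tuple(v) for k, v in states.items()}, config)


# ------------------------------------------------------------------- counts

def simulate_counts(config: SimulationConfig, sample: str = "sim1") -> tuple[pd.DataFrame, dict]:
    """Multinomial read counts from the configured true proportions.

    Reads are drawn with probability proportional to proportion x CDS length,
    so the reads/length estimator is unbiased for the planted proportions.
    """
    if config.total_reads <= 0:
        raise SimulationError("total_reads must be positive")
    rng = _rng(config.seed, "counts")
    rows = []
    truth: dict[str, dict[str, float]] = {}
    for group, proportions in config.true_proportions.items():
        genes = list(proportions)
        p = np.array([proportions[g] for g in genes], dtype=float)
        if not np.isclose(p.sum(), 1.0):
            raise SimulationError(f"{group}: true proportions must sum to 1")
        lengths = np.array([config.cds_lengths[g] for g in genes], dtype=float)
        weights = p * lengths
        counts = rng.multinomial(config.total_reads, weights / weights.sum())
        for gene, reads, length in zip(genes, counts, lengths):
            rows.append(
                {"sample": sample, "gene": gene, "mapped_reads": int(reads), "cds_length": int(length)}
            )
        truth[group] = dict(proportions)
    return pd.DataFrame(rows), truth


# ----------------------------------------------------------------- presence

@dataclass
class PresenceSimulation:
    tree: dendropy.Tree
    presence: dict[str, int]  # tip label -> 0/1
    n_planted_gains: int
    gain_nodes: tuple[str, ...]
    loss_nodes: tuple[str, ...]


def simulate_presence(config: SimulationConfig) -> PresenceSimulation:
    """Plant copy-number gains (and optional nested losses) on a tree."""
    tree = make_tree(config)
    gain_nodes = _resolve_clades(tree, {tips: 1 for tips in config.gain_clades})
    loss_nodes = _resolve_clades(tree, {tips: 0 for tips in config.loss_clades})

    gain_tipsets = [frozenset(t.taxon.label for t in tree.mrca(taxon_labels=list(tips)).leaf_iter())
                    for tips in config.gain_clades]
    for i, a in enumerate(gain_tipsets):
        for b in gain_tipsets[i + 1 :]:
            if (a <= b or b <= a) and not config.loss_clades:
                raise SimulationError("nested planted gains require planted losses")
    for tips in config.loss_clades:
        tipset = frozenset(t.taxon.label for t in tree.mrca(taxon_labels=list(tips)).leaf_iter())
        if not any(tipset < g for g in gain_tipsets):
            raise SimulationError(f"planted loss {tips} is not nested inside a planted gain")

    overrides = {**gain_nodes, **loss_nodes}
    values = _descend(tree, 0, overrides)
    presence = {leaf.taxon.label: int(values[leaf.taxon.label]) for leaf in tree.leaf_node_iter()}
    return PresenceSimulation(
        tree=tree,
        presence=presence,
        n_planted_gains=len(gain_nodes),
        gain_nodes=tuple(sorted(gain_nodes)),
        loss_nodes=tuple(sorted(loss_nodes)),
    )


# ------------------------------------------------------------------ spectra

def simulate_spectrum(config: SimulationConfig):
    """Logistic long-pass transmission curve plus Gaussian noise (300-800 nm).

    Returns (Spectrum, truth dict with the analytic midpoint).
    """
    from .spectra import Spectrum

    if config.spectrum_noise_sd < 0:
        raise SimulationError("noise must be non-negative")
    grid = np.arange(300.0, 801.0)
    if not grid[0] <= config.spectrum_midpoint <= grid[-1]:
        raise SimulationError("spectrum midpoint outside the 300-800 nm grid")
    values = 100.0 / (1.0 + np.exp(-(grid - config.spectrum_midpoint) / config.spectrum_width))
    if config.spectrum_noise_sd > 0:
        rng = _rng(config.seed, "spectrum")
        values = values + rng.normal(0.0, config.spectrum_noise_sd, size=grid.size)
    values = np.clip(values, 0.0, None)
    truth = {"midpoint_nm": config.spectrum_midpoint, "width_nm": config.spectrum_width}
    return Spectrum(grid, values, kind="transmission"), truth


# ------------------------------------------------------------------- bundle

def simulate_bundle(outdir: str | Path, config: SimulationConfig | None = None) -> dict[str, Path]:
    """Write a full fixture bundle (inputs + ground-truth sidecars) to ``outdir``."""
    config = SimulationConfig() if config is None else config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    sim = simulate_opsin_tips(config)
    paths["fasta"] = outdir / "tips.fasta"
    write_fasta(sim.sequences, paths["fasta"])
    paths["tree"] = outdir / "tree.nwk"
    paths["tree"].write_text(sim.tree.as_string(schema="newick", unquoted_underscores=True))
    paths["states_truth"] = outdir / "truth_states.json"
    paths["states_truth"].write_text(
        json.dumps({k: list(v) for k, v in sim.true_states.items()}, indent=1)
    )

    counts, counts_truth = simulate_counts(config)
    paths["counts"] = outdir / "counts.tsv"
    counts.to_csv(paths["counts"], sep="\t", index=False)
    paths["counts_truth"] = outdir / "truth_proportions.json"
    paths["counts_truth"].write_text(json.dumps(counts_truth, indent=1))

    presence = simulate_presence(config)
    paths["presence"] = outdir / "presence.tsv"
    pd.DataFrame(
        [{"tip": tip, "present": val} for tip, val in presence.presence.items()]
    ).to_csv(paths["presence"], sep="\t", index=False)
    paths["presence_truth"] = outdir / "truth_gains.json"
    paths["presence_truth"].write_text(
        json.dumps(
            {
                "n_planted_gains": presence.n_planted_gains,
                "gain_nodes": list(presence.gain_nodes),
                "loss_nodes": list(presence.loss_nodes),
            },
            indent=1,
        )
    )

    spectrum, spectrum_truth = simulate_spectrum(config)
    paths["spectrum"] = outdir / "lens.csv"
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "transmission": spectrum.values}
    ).to_csv(paths["spectrum"], index=False)
    paths["spectrum_truth"] = outdir / "truth_spectrum.json"
    paths["spectrum_truth"].write_text(json.dumps(spectrum_truth, indent=1))

    return paths
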