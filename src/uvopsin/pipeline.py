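"""End-to-end driver joining the analysis stages into one report bundle.

Each stage is runnable on its own inputs; ``run_pipeline`` chains whichever
inputs are supplied (sequences, tree, counts, spectra) and writes per-stage
TSVs plus a per-species summary. Every output file starts with comment-line
metadata: package version, a hash of the configuration, input checksums and
the thresholds in force, so results are auditable and reruns comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .ancestral import count_gain_events, fitch_states, joint_site_label, ml_marginal_states, read_tree
from .expression import classify_sws1_usage, proportional_expression
from .numbering import ALL_SITES, align_to_anchor, extract_site_profile, load_anchor, profiles_to_rows, read_fasta
from .spectra import classify_uv_reflectance, compute_t50, read_spectrum
from .tuning import estimate_lambda_max, load_reference_panel, load_site_effects

log = logging.getLogger("uvopsin")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    panel_path: str | None = None
    effects_path: str | None = None
    anchor_path: str | None = None
    homology_threshold: int = 0
    detection_threshold: float = 0.01
    reflectance_criterion: float = 0.2
    gain_cost: float = 1.0
    loss_cost: float = 1.0
    seed: int = 0
    outdir: str = "results"

    def config_hash(self) -> str:
        # output location is not part of the analysis fingerprint
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, inputs: dict[str, str]) -> None:
    header = [
        f"# uvopsin {__version__}",
        f"# config_hash {config.config_hash()}",
        f"# thresholds homology={config.homology_threshold} "
        f"detection={config.detection_threshold} reflectance={config.reflectance_criterion}",
    ]
    header += [f"# input {name} sha256:{digest}" for name, digest in inputs.items()]
    with open(path, "w") as handle:
        handle.write("\n".join(header) + "\n")
        df.to_csv(handle, sep="\t", index=False)


def run_pipeline(
    fasta: str | Path | None = None,
    tree: str | Path | None = None,
    counts: str | Path | None = None,
    spectra: str | Path | None = None,
    presence: str | Path | None = None,
    config: RunConfig | None = None,
) -> dict[str, Path]:
    """Run every stage for which an input is supplied; returns output paths."""
    config = RunConfig() if config is None else config
    if not any([fasta, tree, counts, spectra, presence]):
        raise StageError("input: no inputs supplied")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {
        name: _checksum(path)
        for name, path in [("fasta", fasta), ("tree", tree), ("counts", counts),
                           ("spectra", spectra), ("presence", presence)]
        if path is not None
    }
    outputs: dict[str, Path] = {}
    summary: dict[str, dict] = {}

    profiles: dict[str, dict] = {}
    species_of: dict[str, str] = {}
    if fasta is not None:
        try:
            anchor = load_anchor() if config.anchor_path is None else read_fasta(config.anchor_path)[0]
            panel = load_reference_panel(config.panel_path)
            effects = load_site_effects(config.effects_path)
            estimates = []
            for seq in read_fasta(fasta):
                pmap = align_to_anchor(seq, anchor)
                profile = extract_site_profile(seq, pmap, ALL_SITES)
                profiles[seq.id] = profile
                species_of[seq.id] = seq.species or seq.id
                est = estimate_lambda_max(
                    profile, panel, effects, homology_threshold=config.homology_threshold
                )
                estimates.append(
                    {
                        "id": seq.id,
                        "species": seq.species,
                        "gene": seq.gene,
                        "lambda_max_nm": est.lambda_max_nm,
                        "variant_class": est.variant_class,
                        "reference_used": est.reference_used,
                        "applied_effects": ";".join(
                            f"{e.from_residue}{e.site}{e.to_residue}:{e.delta_nm:+g}"
                            for e in est.applied_effects
                        ),
                        "n_unmatched_sites": est.n_unmatched_sites,
                        "reason": est.reason,
                    }
                )
                summary.setdefault(species_of[seq.id], {})[f"lambda_{seq.gene or seq.id}"] = (
                    est.lambda_max_nm if est.determined else "undetermined"
                )
            outputs["sites"] = outdir / "site_profiles.tsv"
            _write_tsv(pd.DataFrame(profiles_to_rows(profiles)), outputs["sites"], config, inputs)
            outputs["lambda"] = outdir / "lambda_estimates.tsv"
            _write_tsv(pd.DataFrame(estimates), outputs["lambda"], config, inputs)
        except StageError:
            raise
        except Exception as exc:
            (outdir / "FAILED").write_text(f"sites/lambda: {exc}\n")
            raise StageError(f"sites/lambda: {exc}") from exc

    if tree is not None and profiles:
        try:
            phylo = read_tree(tree)
            tips114 = {i: p[114] for i, p in profiles.items() if p.get(114, "-") not in "-X"}
            tips118 = {i: p[118] for i, p in profiles.items() if p.get(118, "-") not in "-X"}
            _, fitch114 = fitch_states(phylo, tips114)
            _, fitch118 = fitch_states(phylo, tips118)
            ml114 = ml_marginal_states(phylo, tips114)
            ml118 = ml_marginal_states(phylo, tips118)
            rows = []
            for node in phylo.preorder_node_iter():
                rows.append(
                    {
                        "node": node.label,
                        "is_tip": node.is_leaf(),
                        "fitch_label": joint_site_label(fitch114, fitch118, node.label),
                        "ml_label": joint_site_label(ml114, ml118, node.label),
                        "ml_p114": ml114.posteriors[node.label][ml114.states[node.label]],
                        "ml_p118": ml118.posteriors[node.label][ml118.states[node.label]],
                    }
                )
            outputs["ancestral"] = outdir / "ancestral_states.tsv"
            _write_tsv(pd.DataFrame(rows), outputs["ancestral"], config, inputs)
        except Exception as exc:
            (outdir / "FAILED").write_text(f"ancestral: {exc}\n")
            raise StageError(f"ancestral: {exc}") from exc

    if presence is not None and tree is not None:
        try:
            phylo = read_tree(tree)
            table = pd.read_csv(presence, sep="\t", comment="#")
            tip_presence = dict(zip(table["tip"], table["present"]))
            report = count_gain_events(
                phylo, tip_presence, gain_cost=config.gain_cost, loss_cost=config.loss_cost
            )
            outputs["duplications"] = outdir / "duplication_events.tsv"
            _write_tsv(
                pd.DataFrame(
                    [
                        {
                            "n_gains": report.n_gains,
                            "gain_branches": ";".join(report.gain_branches),
                            "n_losses": report.n_losses,
                            "total_cost": report.total_cost,
                        }
                    ]
                ),
                outputs["duplications"],
                config,
                inputs,
            )
        except Exception as exc:
            (outdir / "FAILED").write_text(f"duplications: {exc}\n")
            raise StageError(f"duplications: {exc}") from exc

    if counts is not None:
        try:
            table = pd.read_csv(counts, sep="\t", comment="#")
            props = proportional_expression(table)
            usage = classify_sws1_usage(props, detection_threshold=config.detection_threshold)
            outputs["express"] = outdir / "expression_proportions.tsv"
            _write_tsv(props, outputs["express"], config, inputs)
            outputs["sws1_usage"] = outdir / "sws1_usage.tsv"
            _write_tsv(usage, outputs["sws1_usage"], config, inputs)
            for _, row in usage.iterrows():
                summary.setdefault(str(row["sample"]), {})["sws1_usage"] = row["usage"]
        except Exception as exc:
            (outdir / "FAILED").write_text(f"express: {exc}\n")
            raise StageError(f"express: {exc}") from exc

    if spectra is not None:
        try:
            rows = []
            for spec in read_spectrum(spectra, kind="transmission"):
                result = compute_t50(spec)
                rows.append(
                    {
                        "t50_nm": round(result.t50_nm, 2),
                        "classification": result.classification,
                        "note": result.note,
                    }
                )
            outputs["spectra"] = outdir / "spectra_classification.tsv"
            _write_tsv(pd.DataFrame(rows), outputs["spectra"], config, inputs)
        except Exception as exc:
            (outdir / "FAILED").write_text(f"spectra: {exc}\n")
            raise StageError(f"spectra: {exc}") from exc

    if summary:
        summary_rows = [{"species": sp, **vals} for sp, vals in sorted(summary.items())]
        outputs["summary"] = outdir / "summary.tsv"
        _write_tsv(pd.DataFrame(summary_rows), outputs["summary"], config, inputs)
    return outputs
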