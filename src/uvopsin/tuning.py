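"""Estimate SWS1 pigment lambda_max from tuning-site profiles.

The estimator is the comparative convention used throughout the opsin
literature: find the reference pigment (known lambda_max from in-vitro
expression or microspectrophotometry) whose tuning-site profile is closest
to the query, then add the known spectral effect of every substitution
separating query from reference. Because single-site effects in SWS1 are
generally not additive, estimation refuses to chain across substitutions
whose effect is unknown (the homology threshold, default 0) rather than
extrapolate. Predicted pigments are binned into the empirically observed
damselfish classes: short (356-362 nm, A114/A118), long (368-370 nm,
S114/S118), or intermediate between the two.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .numbering import AMBIGUOUS, MISSING, SITE_125, TUNING_SITES, SiteProfile

# side-chain polarity classes over the 20 canonical residues
POLAR = frozenset("STCYNQDEKRH")
NONPOLAR = frozenset("GAVLIPFMW")
DEFAULT_POLARITY: dict[str, str] = {
    **{aa: "polar" for aa in POLAR},
    **{aa: "nonpolar" for aa in NONPOLAR},
}

#: classify_variant boundaries (nm), inclusive at the printed endpoints
SHORT_RANGE = (356.0, 362.0)
LONG_RANGE = (368.0, 370.0)

UNDETERMINED = "undetermined"


class TuningError(ValueError):
    pass


@dataclass(frozen=True)
class SiteEffect:
    """Signed lambda_max shift (nm) of one substitution at one tuning site."""

    site: int
    from_residue: str
    to_residue: str
    delta_nm: float
    provenance: str = ""

    def reversed(self) -> "SiteEffect":
        return SiteEffect(self.site, self.to_residue, self.from_residue, -self.delta_nm, self.provenance)


@dataclass(frozen=True)
class ReferenceEntry:
    """A pigment with measured lambda_max and its tuning-site profile."""

    species: str
    gene: str
    profile: Mapping[int, str]
    lambda_max_nm: float
    method: str  # "in-vitro" | "MSP"
    is_damselfish: bool = False

    def __post_init__(self) -> None:
        if not 330.0 <= self.lambda_max_nm <= 420.0:
            raise TuningError(
                f"{self.species}/{self.gene}: lambda_max {self.lambda_max_nm} nm outside "
                "the plausible SWS1-class window [330, 420]"
            )
        if self.method not in ("in-vitro", "MSP"):
            raise TuningError(f"{self.species}/{self.gene}: unknown method {self.method!r}")

    @property
    def id(self) -> str:
        return f"{self.species}|{self.gene}"


@dataclass(frozen=True)
class LambdaEstimate:
    lambda_max_nm: float | None
    reference_used: str | None
    applied_effects: tuple[SiteEffect, ...]
    n_unmatched_sites: int
    variant_class: str
    reason: str = ""

    @property
    def determined(self) -> bool:
        return self.lambda_max_nm is not None


def polarity_change(
    site: int, residue_a: str, residue_b: str, table: Mapping[str, str] | None = None
) -> bool | None:
    """True iff the two residues fall in different polarity classes.

    Returns ``None`` (undefined) when either residue is MISSING/AMBIGUOUS.
    """
    table = DEFAULT_POLARITY if table is None else table
    if residue_a not in table or residue_b not in table:
        return None
    return table[residue_a] != table[residue_b]


def _comparable_sites(profile: SiteProfile, reference: ReferenceEntry) -> list[int]:
    # site 125 is flagged for polarity only, never used for matching or arithmetic
    sites = []
    for site in TUNING_SITES:
        q = profile.get(site, MISSING)
        r = reference.profile.get(site, MISSING)
        if q in (MISSING, AMBIGUOUS) or r in (MISSING, AMBIGUOUS):
            continue
        sites.append(site)
    return sites


def match_reference(
    profile: SiteProfile, panel: Sequence[ReferenceEntry]
) -> list[tuple[ReferenceEntry, list[int]]]:
    """Rank the panel by tuning-site mismatch count against ``profile``.

    Ties break in favour of damselfish references, then in-vitro over MSP,
    then lexicographic id, giving a total order so estimation never depends
    on panel file order.
    """
    if not panel:
        raise TuningError("reference panel is empty")
    ranked = []
    for entry in panel:
        shared = _comparable_sites(profile, entry)
        if not shared:
            continue
        mismatches = [s for s in shared if profile[s] != entry.profile[s]]
        ranked.append((entry, mismatches))
    ranked.sort(
        key=lambda item: (
            len(item[1]),
            not item[0].is_damselfish,
            item[0].method != "in-vitro",
            item[0].id,
        )
    )
    return ranked


def _effect_index(effects: Iterable[SiteEffect]) -> dict[tuple[int, str, str], SiteEffect]:
    index: dict[tuple[int, str, str], SiteEffect] = {}
    for eff in effects:
        index[(eff.site, eff.from_residue, eff.to_residue)] = eff
        index.setdefault((eff.site, eff.to_residue, eff.from_residue), eff.reversed())
    return index


def estimate_lambda_max(
    profile: SiteProfile,
    panel: Sequence[ReferenceEntry] | None = None,
    effects: Sequence[SiteEffect] | None = None,
    homology_threshold: int = 0,
) -> LambdaEstimate:
    """Predict lambda_max for a site profile against a reference panel.

    ``homology_threshold`` is the number of mismatched sites *without* a known
    spectral effect that is tolerated before the estimate is refused as
    UNDETERMINED (single-site effects are not additive, so chaining unknown
    substitutions would be guesswork).
    """
    panel = load_reference_panel() if panel is None else panel
    effects = load_site_effects() if effects is None else effects

    ambiguous = [s for s in TUNING_SITES if profile.get(s) == AMBIGUOUS]
    if ambiguous:
        return LambdaEstimate(
            None, None, (), 0, "unclassified",
            reason=f"ambiguous residue at site(s) {ambiguous}",
        )
    ranked = match_reference(profile, panel)
    if not ranked:
        return LambdaEstimate(None, None, (), 0, "unclassified", reason="no admissible reference")

    reference, mismatches = ranked[0]
    index = _effect_index(effects)
    applied: list[SiteEffect] = []
    unmatched = 0
    for site in mismatches:
        eff = index.get((site, reference.profile[site], profile[site]))
        if eff is None:
            unmatched += 1
        else:
            applied.append(eff)
    if unmatched > homology_threshold:
        return LambdaEstimate(
            None, reference.id, tuple(applied), unmatched, "unclassified",
            reason=f"{unmatched} mismatched site(s) without a known spectral effect "
            f"exceeds homology threshold {homology_threshold}",
        )
    value = reference.lambda_max_nm + sum(e.delta_nm for e in applied)
    return LambdaEstimate(
        value, reference.id, tuple(applied), unmatched, classify_variant(value)
    )


def classify_variant(lambda_max_nm: float | None) -> str:
    """Bin a predicted lambda_max into the damselfish short/long dichotomy."""
    if lambda_max_nm is None:
        return "unclassified"
    if SHORT_RANGE[0] <= lambda_max_nm <= SHORT_RANGE[1]:
        return "short"
    if LONG_RANGE[0] <= lambda_max_nm <= LONG_RANGE[1]:
        return "long"
    if SHORT_RANGE[1] < lambda_max_nm < LONG_RANGE[0]:
        return "intermediate"
    return "unclassified"


# ---------------------------------------------------------------- packaged IO

def _open_packaged(name: str):
    return resources.as_file(resources.files("uvopsin.data") / name)


def load_reference_panel(path: str | Path | None = None) -> list[ReferenceEntry]:
    """Load a reference panel TSV (packaged default if no path given)."""
    if path is None:
        with _open_packaged("reference_panel.tsv") as p:
            return load_reference_panel(p)
    entries = []
    with open(path) as handle:
        rows = csv.DictReader(
            (line for line in handle if not line.startswith("#")), delimiter="\t"
        )
        for row in rows:
            profile = {
                int(key[1:]): value
                for key, value in row.items()
                if key.startswith("s") and key[1:].isdigit() and value
            }
            entries.append(
                ReferenceEntry(
                    species=row["species"],
                    gene=row["gene"],
                    profile=profile,
                    lambda_max_nm=float(row["lambda_max_nm"]),
                    method=row["method"],
                    is_damselfish=row["is_damselfish"].strip() in ("1", "true", "True"),
                )
            )
    if not entries:
        raise TuningError(f"no reference entries in {path}")
    return entries


def load_site_effects(path: str | Path | None = None) -> list[SiteEffect]:
    """Load a site-effect TSV (packaged default if no path given)."""
    if path is None:
        with _open_packaged("site_effects.tsv") as p:
            return load_site_effects(p)
    effects = []
    with open(path) as handle:
        rows = csv.DictReader(
            (line for line in handle if not line.startswith("#")), delimiter="\t"
        )
        for row in rows:
            effects.append(
                SiteEffect(
                    site=int(row["site"]),
                    from_residue=row["from"],
                    to_residue=row["to"],
                    delta_nm=float(row["delta_nm"]),
                    provenance=row.get("provenance", ""),
                )
            )
    return effects
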