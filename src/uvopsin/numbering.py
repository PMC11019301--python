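"""Bovine-rhodopsin-anchored numbering of opsin protein sequences.

The spectral-tuning literature reports opsin residue positions in the
coordinate frame of bovine rhodopsin (348 aa, PDB 1U19), so that e.g.
"site 118" names the same structural position in every opsin class.
This module aligns a query opsin to the packaged bovine anchor with a
global (Needleman-Wunsch) alignment and extracts the residues occupying
the canonical short-wavelength-sensitive (SWS1) tuning sites:
transmembrane helix I (46, 49, 52), II (86, 90, 91, 93, 97),
III (109, 113, 114, 116, 118) and VI (265), plus the putative
retinal-binding-pocket site 125.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

#: canonical SWS1 tuning sites, bovine rhodopsin numbering (1-based)
TUNING_SITES: tuple[int, ...] = (46, 49, 52, 86, 90, 91, 93, 97, 109, 113, 114, 116, 118, 265)
#: putative tuning site, extracted and polarity-flagged but excluded from lambda_max arithmetic
SITE_125: int = 125
ALL_SITES: tuple[int, ...] = TUNING_SITES + (SITE_125,)

#: sentinel residues in a SiteProfile
MISSING = "-"
AMBIGUOUS = "X"

_CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")
_AMBIGUITY_AA = set("XBZJ")
_ALLOWED_AA = _CANONICAL_AA | _AMBIGUITY_AA

_MIN_QUERY_LENGTH = 50


class NumberingError(ValueError):
    """Raised when a sequence cannot be placed in bovine coordinates."""


@dataclass(frozen=True)
class OpsinSequence:
    """One opsin protein sequence with free-text identity metadata."""

    id: str
    residues: str
    species: str = ""
    gene: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise NumberingError(f"{self.id}: empty sequence")
        bad = set(self.residues.upper()) - _ALLOWED_AA
        if bad:
            raise NumberingError(
                f"{self.id}: non-amino-acid characters {sorted(bad)} "
                "(only the 20 canonical residues plus X/B/Z/J are accepted)"
            )
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PositionMap:
    """Monotone mapping anchor position -> query position (both 1-based)."""

    mapping: Mapping[int, int]
    score: float
    anchor_coverage: float

    def __post_init__(self) -> None:
        keys = sorted(self.mapping)
        vals = [self.mapping[k] for k in keys]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise NumberingError("position map is not strictly increasing")

    def __getitem__(self, anchor_pos: int) -> int:
        return self.mapping[anchor_pos]

    def __contains__(self, anchor_pos: int) -> bool:
        return anchor_pos in self.mapping


# SiteProfile: plain dict {site -> residue | MISSING | AMBIGUOUS}
SiteProfile = dict[int, str]


def load_anchor() -> OpsinSequence:
    """Packaged bovine rhodopsin anchor (348 aa, coordinates of PDB 1U19)."""
    ref = resources.files("uvopsin.data") / "bovine_rhodopsin_1u19.fasta"
    with resources.as_file(ref) as path:
        record = next(SeqIO.parse(str(path), "fasta"))
    ident, species, gene = record.id.split("|")
    return OpsinSequence(id=ident, species=species, gene=gene, residues=str(record.seq))


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_to_anchor(query: OpsinSequence, anchor: OpsinSequence | None = None) -> PositionMap:
    """Globally align ``query`` to the bovine anchor and return the position map.

    Anchor positions aligned to gaps in the query are absent from the map.
    The alignment uses BLOSUM62 with affine gaps (open 10, extend 1); among
    co-optimal alignments the aligner's deterministic first traceback is used,
    so extraction is reproducible.
    """
    if anchor is None:
        anchor = load_anchor()
    if len(query) < _MIN_QUERY_LENGTH:
        raise NumberingError(
            f"{query.id}: {len(query)} residues is too short to establish "
            f"homologous numbering (minimum {_MIN_QUERY_LENGTH})"
        )
    # BLOSUM62 has no column for J; score it as fully ambiguous
    q_seq = query.residues.replace("J", "X")
    a_seq = anchor.residues.replace("J", "X")
    aligner = _make_aligner()
    alignment = aligner.align(a_seq, q_seq)[0]
    mapping: dict[int, int] = {}
    for (a_start, a_end), (q_start, q_end) in zip(*alignment.aligned):
        for offset in range(a_end - a_start):
            mapping[a_start + offset + 1] = q_start + offset + 1
    return PositionMap(
        mapping=mapping,
        score=float(alignment.score),
        anchor_coverage=len(mapping) / len(anchor),
    )


def extract_site_profile(
    query: OpsinSequence,
    position_map: PositionMap,
    sites: Iterable[int] = ALL_SITES,
    anchor_length: int = 348,
) -> SiteProfile:
    """Residues of ``query`` at the requested anchor sites.

    Sites aligned to a gap are reported as :data:`MISSING`; residues X (or the
    ambiguity codes B/Z/J) are normalized to :data:`AMBIGUOUS`.
    """
    profile: SiteProfile = {}
    for site in sites:
        if not 1 <= site <= anchor_length:
            raise NumberingError(f"site {site} outside anchor length {anchor_length}")
        if site not in position_map:
            profile[site] = MISSING
            continue
        residue = query.residues[position_map[site] - 1]
        profile[site] = AMBIGUOUS if residue in _AMBIGUITY_AA else residue
    return profile


def read_fasta(path: str | Path) -> list[OpsinSequence]:
    """Read opsins from FASTA; headers ``id|species|gene`` or plain id."""
    sequences = []
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.id.split("|")
        if len(parts) >= 3:
            ident, species, gene = parts[0], parts[1], parts[2]
        else:
            ident, species, gene = record.id, "", ""
        residues = str(record.seq).replace("-", "")
        sequences.append(OpsinSequence(id=ident, species=species, gene=gene, residues=residues))
    if not sequences:
        warnings.warn(f"no sequences read from {path}")
    return sequences


def write_fasta(sequences: Iterable[OpsinSequence], path: str | Path) -> None:
    with open(path, "w") as handle:
        for seq in sequences:
            header = seq.id if not (seq.species or seq.gene) else f"{seq.id}|{seq.species}|{seq.gene}"
            handle.write(f">{header}\n")
            for start in range(0, len(seq.residues), 60):
                handle.write(seq.residues[start : start + 60] + "\n")


def profiles_to_rows(profiles: Mapping[str, SiteProfile], sites: Iterable[int] = ALL_SITES) -> list[dict]:
    """Flatten ``{sequence id -> profile}`` to TSV-ready rows (one column per site)."""
    sites = list(sites)
    return [
        {"id": ident, **{f"s{site}": profile.get(site, MISSING) for site in sites}}
        for ident, profile in profiles.items()
    ]
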