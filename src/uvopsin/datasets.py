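"""Curated study-system inputs used by the analysis scripts and checks.

``sws1_copy_number`` transcribes the published genome-survey result for
damselfishes: which of the 15 whole-genome species (plus the two
transcriptome-confirmed Pomacentrus species) carry one versus two SWS1
copies, on the subfamily clade topology (Stegastinae, (Chrominae,
Pomacentrinae)) with Amphiprionini nested inside Pomacentrinae.

``damselfish_protein_tree`` is a synthetic stand-in topology (the published
protein tree is not redistributed here) that captures the reported clade
structure and tip states at tuning sites 114/118: short (AA) Stegastinae and
Abudefdufinae, long (SS) Chrominae, a mixed Pomacentrinae with both
duplicate copies, and outgroups carrying the A114/S118 intermediate.
"""

from __future__ import annotations

ANEMONEFISH_TWO_COPY = (
    "Amphiprion_akallopisos",
    "Amphiprion_biaculeatus",
    "Amphiprion_bicinctus",
    "Amphiprion_frenatus",
    "Amphiprion_melanopus",
    "Amphiprion_nigripes",
    "Amphiprion_ocellaris",
    "Amphiprion_percula",
    "Amphiprion_perideraion",
    "Amphiprion_polymnus",
    "Amphiprion_sebae",
)


def sws1_copy_number() -> tuple[str, dict[str, int]]:
    """(rooted newick, tip -> duplicate-copy presence) for the SWS1 survey.

    Presence 1 marks species with two SWS1 copies (i.e. the duplicate copy is
    present); 0 marks single-copy species.
    """
    anemonefish = "(" * (len(ANEMONEFISH_TWO_COPY) - 1) + ANEMONEFISH_TWO_COPY[0]
    for name in ANEMONEFISH_TWO_COPY[1:]:
        anemonefish += f",{name})"
    newick = (
        "(Stegastes_partitus,"
        "((Dascyllus_trimaculatus,Chromis_chromis),"
        "(Acanthochromis_polyacanthus,"
        f"((Pomacentrus_amboinensis,Pomacentrus_australis),{anemonefish}))));"
    )
    presence = {
        "Stegastes_partitus": 0,
        "Dascyllus_trimaculatus": 0,
        "Acanthochromis_polyacanthus": 0,
        "Chromis_chromis": 1,
        "Pomacentrus_amboinensis": 1,
        "Pomacentrus_australis": 1,
        **{name: 1 for name in ANEMONEFISH_TWO_COPY},
    }
    return newick, presence


def damselfish_protein_tree() -> tuple[str, dict[str, str], dict[str, str]]:
    """(rooted newick, tip states at 114, tip states at 118).

    synthetic: a minimal stand-in for the published SWS1 protein tree. The
    Pomacentrinae duplicates appear as separate short (alpha, AA) and long
    (beta, SS) tips; three outgroups carry the intermediate A114/S118.
    """
    bl = 0.1
    newick = (
        f"(Outgroup1:{bl},(Outgroup2:{bl},(Outgroup3:{bl},"
        f"((Stegastes1:{bl},Stegastes2:{bl}):{bl},"
        f"((Chromis1:{bl},Chromis2:{bl}):{bl},"
        f"((Abudefduf1:{bl},Abudefduf2:{bl}):{bl},"
        f"((Pomacentrinae_alpha1:{bl},Pomacentrinae_alpha2:{bl}):{bl},"
        f"(Pomacentrinae_beta1:{bl},Pomacentrinae_beta2:{bl}):{bl})"
        f":{bl}):{bl}):{bl}):{bl}):{bl}):{bl});"
    )
    short_tips = ("Stegastes1", "Stegastes2", "Abudefduf1", "Abudefduf2",
                  "Pomacentrinae_alpha1", "Pomacentrinae_alpha2")
    long_tips = ("Chromis1", "Chromis2", "Pomacentrinae_beta1", "Pomacentrinae_beta2")
    outgroups = ("Outgroup1", "Outgroup2", "Outgroup3")
    tips114 = {**{t: "A" for t in short_tips}, **{t: "S" for t in long_tips},
               **{t: "A" for t in outgroups}}
    tips118 = {**{t: "A" for t in short_tips}, **{t: "S" for t in long_tips},
               **{t: "S" for t in outgroups}}
    return newick, tips114, tips118
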