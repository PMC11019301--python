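import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from uvopsin.numbering import TUNING_SITES, load_anchor
from uvopsin.tuning import load_reference_panel, load_site_effects


@pytest.fixture(scope="session")
def anchor():
    return load_anchor()


@pytest.fixture(scope="session")
def panel():
    return load_reference_panel()


@pytest.fixture(scope="session")
def effects():
    return load_site_effects()


@pytest.fixture(scope="session")
def short_profile(panel):
    """A114/A118 profile over the canonical sites (damselfish short variant)."""
    entry = next(e for e in panel if e.species == "Pomacentrus_amboinensis")
    return {s: entry.profile[s] for s in TUNING_SITES}


@pytest.fixture(scope="session")
def long_profile(short_profile):
    """S114/S118 profile (damselfish long variant)."""
    return {**short_profile, 114: "S", 118: "S"}
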