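import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from adamtsmap.library import Peptide, ProteinRecord, TilingRegion

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_protein():
    from adamtsmap.reference import proximal_protein

    return proximal_protein()


@pytest.fixture(scope="session")
def reference_library():
    from adamtsmap.reference import proximal_library

    return proximal_library()


@pytest.fixture
def rng():
    return np.random.default_rng(20240918)


def make_protein(start: int, end: int, letter: str = "A") -> ProteinRecord:
    """A synthetic homopolymer protein covering [start, end]."""
    return ProteinRecord(id="synthetic", residues=letter * (end - start + 1),
                         numbering_offset=start)


def make_peptides(starts, length=20, name_prefix="pep"):
    """Coordinate-only peptides at the given starts (synthetic, no sequence)."""
    return [
        Peptide(name=f"{name_prefix}{i + 1}", start=s, end=s + length - 1)
        for i, s in enumerate(starts)
    ]


def simple_region(start, end, domains=()):
    return TilingRegion(name="R", start=start, end=end, domains=tuple(domains))
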