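"""Shared fixtures: deterministic toy proteins, proteomes and feature sets."""

import pytest

from pepdesign.fixtures import FixtureSpec, make_protein, make_proteome
from pepdesign.sequence_io import Proteome, ProteinRecord, SequenceFeature


@pytest.fixture
def toy_record():
    return ProteinRecord(id="p1", sequence="MKNPDGSQRW", description="toy")


@pytest.fixture
def uniq_toy():
    """The two-protein uniqueness toy: target MKNPDGSQRW and an off-target
    sharing only the DGSQ 4-mer."""
    target = ProteinRecord(id="T1", sequence="MKNPDGSQRW")
    off = ProteinRecord(id="OFF1", sequence="AAADGSQAAA")
    return target, Proteome(records=[target, off])


@pytest.fixture
def random_proteome():
    """50 random proteins up to 300 aa, deterministic."""
    spec = FixtureSpec(seed=42, n_proteins=50, length_range=(60, 300))
    return make_proteome(spec)


@pytest.fixture
def small_protein():
    spec = FixtureSpec(seed=7, n_proteins=1, length_range=(120, 120))
    return make_protein(spec, 0)


@pytest.fixture
def random_features():
    """20 deterministic features of assorted kinds on a 120-aa protein."""
    import random
    rng = random.Random(123)
    kinds = ["MOD_RES", "CARBOHYD", "LIPID", "DISULFID", "TRANSMEM",
             "TOPO_DOM", "SIGNAL", "DOMAIN", "VARIANT", "VAR_SEQ",
             "CONFLICT", "WEIRD_KIND"]
    feats = []
    for i in range(20):
        start = rng.randint(1, 110)
        end = min(120, start + rng.randint(0, 15))
        feats.append(SequenceFeature(kind=rng.choice(kinds), start=start,
                                     end=end, note=f"f{i}"))
    return feats
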