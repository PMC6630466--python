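import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from mirvar import MatureMiRNA, SimConfig, UTRSequence, emit_fixtures, simulate


@pytest.fixture(scope="session")
def let7():
    return MatureMiRNA(name="let-7a-5p", mature_seq="UGAGGUAGUAGGUUGUAUAGUU")


@pytest.fixture
def let7_utr():
    # carries one planted let-7 8mer site (CTACCTCA) at offsets 3..11
    return UTRSequence(utr_id="u1", gene="G1", seq="AAACTACCTCAAAA")


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded cohort shared by read-only tests."""
    return simulate(
        SimConfig(
            rng_seed=11,
            n_utrs=15,
            utr_length=350,
            n_mirnas=6,
            n_pops=10,
            samples_per_pop=20,
            n_disrupting=8,
            n_creating=4,
            n_neutral=8,
            n_latitude_snps=2,
        )
    )


@pytest.fixture(scope="session")
def small_fixture_dir(small_sim, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    paths = emit_fixtures(small_sim, out)
    return paths


def random_utr(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def random_seed_rna(rng: np.random.Generator) -> str:
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=7))
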