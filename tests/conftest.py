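"""Shared fixtures: one deterministic simulated subject per session."""

import pytest
from Bio.Seq import Seq

from cryptomap.database_build import build_allframes_db, build_control_db
from cryptomap.pipeline import run_core
from cryptomap.synthetic_fixtures import (SUBJECT_ALLELES, SimConfig,
                                          simulate_psms, simulate_reads,
                                          simulate_reference)


def bio_translate(nt: str) -> str:
    """Independent translation oracle (Biopython)."""
    return str(Seq(nt[:len(nt) - len(nt) % 3]).translate())


@pytest.fixture(scope="session")
def sim():
    return simulate_reference(SimConfig(seed=1))


@pytest.fixture(scope="session")
def reads(sim):
    return simulate_reads(sim)


@pytest.fixture(scope="session")
def control_db(sim):
    return build_control_db(sim.personalized, sim.models)


@pytest.fixture(scope="session")
def allframes_db(reads):
    return build_allframes_db(reads)


@pytest.fixture(scope="session")
def psm_bundle(sim, control_db, allframes_db):
    return simulate_psms(sim, control_db, allframes_db)


@pytest.fixture(scope="session")
def pipeline_result(sim, reads, psm_bundle):
    psms, affinities, _ = psm_bundle
    return run_core(sim.reference, sim.variants, sim.models, sim.expression,
                    reads, psms, affinities, set(SUBJECT_ALLELES))
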