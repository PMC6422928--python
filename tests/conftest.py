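"""Shared fixtures: a seeded synthetic universe, written to disk once."""

import pytest
from pyfaidx import Fasta

from csikit import simulate


@pytest.fixture(scope="session")
def sim_ref():
    """Deterministic reference: 6 genes, both strands, 3 sites each."""
    return simulate.simulate_reference(simulate.SimConfig(), seed=11)


@pytest.fixture(scope="session")
def genome_path(sim_ref, tmp_path_factory):
    path = tmp_path_factory.mktemp("genome") / "genome.fa"
    sim_ref.write_fasta(str(path))
    return str(path)


@pytest.fixture(scope="session")
def genome(genome_path):
    return Fasta(genome_path)
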