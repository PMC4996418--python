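import pytest

from twistmotif.synthetic_data import SimulationConfig, simulate_family


@pytest.fixture(scope="session")
def family():
    """Default simulated two-paralog family, fixed seed."""
    return simulate_family(SimulationConfig(seed=42))


@pytest.fixture
def family_fasta(tmp_path, family):
    from twistmotif.seq_io import write_fasta

    path = tmp_path / "family.fasta"
    write_fasta(family.records, path)
    return path
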