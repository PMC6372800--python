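import pytest

from kinscope import SyntheticParams, generate_family


@pytest.fixture(scope="session")
def default_family():
    """One synthetic family under default conditions, shared across tests."""
    return generate_family(SyntheticParams(seed=2024))


@pytest.fixture(scope="session")
def three_group_family():
    return generate_family(
        SyntheticParams(n_groups=3, alleles_per_group=3, seed=7)
    )


@pytest.fixture
def write_fasta(tmp_path):
    def _write(entries, name="seqs.faa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in entries:
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write
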