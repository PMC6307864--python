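import pytest

from glur.reference_map import load_scheme


@pytest.fixture(scope="session")
def iglur_scheme():
    return load_scheme("iglur")


@pytest.fixture(scope="session")
def mglur_scheme():
    return load_scheme("mglur")


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write raw FASTA text to a temp file and return its path."""

    def _write(text, name="test.fa"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
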