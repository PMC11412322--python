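import pytest

from detoxrep.synthetic import default_spec, generate_dataset


@pytest.fixture(scope="session")
def demo():
    """One synthetic world shared by read-only tests."""
    return generate_dataset(default_spec(1))


@pytest.fixture()
def tmp_fasta(tmp_path):
    def _write(text: str, name: str = "test.faa"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
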