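import pytest

from phyin import demo_alignment
from phyin.alignment import Alignment


@pytest.fixture
def demo():
    """8-taxon, 10-site walk-through alignment (3 neighbour conflicts)."""
    return demo_alignment()


@pytest.fixture
def write_fasta_text(tmp_path):
    """Write raw FASTA text to a temp file and return its path."""

    def _write(text, name="in.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def make_alignment(*rows):
    """Alignment from bare sequence strings, labelled t1..tn."""
    return Alignment.from_sequences(
        (f"t{i + 1}", row) for i, row in enumerate(rows)
    )
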