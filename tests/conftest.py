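import pytest

from xselex import motif_from_counts, paper_fixture_motifs


@pytest.fixture(scope="session")
def fixtures():
    return paper_fixture_motifs()


@pytest.fixture
def toy_motif():
    """3 essential naturals + 1 stem bp, spanning 5 nt (space 4^5 = 1024)."""
    return motif_from_counts(3, 0, 1, name="toy")
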