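import numpy as np
import pytest

from cladekin import Alignment, ProteinSequence


@pytest.fixture
def toy_alignment():
    """Six sequences in three clades with one clean discriminating column.

    Column 3 separates clade A (K) from B (E) and C (E); column 5 is
    unique to the reference s1 (W vs I everywhere else).
    """
    seqs = [
        ProteinSequence("s1", "MKKAWE"),
        ProteinSequence("s2", "MKKAIE"),
        ProteinSequence("s3", "MKEAIE"),
        ProteinSequence("s4", "MKEAIE"),
        ProteinSequence("s5", "MKEAIE"),
        ProteinSequence("s6", "MKEAIE"),
    ]
    clade_map = {"s1": "A", "s2": "A", "s3": "B", "s4": "B", "s5": "C", "s6": "C"}
    return Alignment(sequences=seqs, clade_map=clade_map)


@pytest.fixture
def gapped_alignment():
    seqs = [
        ProteinSequence("a", "MK-E"),
        ProteinSequence("b", "MKLE"),
        ProteinSequence("c", "M-KT"),
    ]
    return Alignment(sequences=seqs)


def random_gapped_alignment(rng, n_seqs=None, n_cols=None):
    """Random alignment with gaps, guaranteed no all-gap column."""
    from cladekin.seq_core import AMINO_ACIDS

    n_seqs = n_seqs or rng.integers(2, 6)
    n_cols = n_cols or rng.integers(3, 30)
    aa = np.array(list(AMINO_ACIDS + "-" * 5))
    while True:
        mat = aa[rng.integers(len(aa), size=(n_seqs, n_cols))]
        if not any((mat[:, j] == "-").all() for j in range(n_cols)):
            # every sequence must keep >= 1 residue
            if all((row != "-").any() for row in mat):
                break
    seqs = [
        ProteinSequence(f"t{i}", "".join(row)) for i, row in enumerate(mat)
    ]
    return Alignment(sequences=seqs)
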