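import numpy as np
import pytest

from protshift import AlignedSequence, Alignment, SpeciesPartition
from protshift.alphabet import AMINO_ACIDS


def make_alignment(rows, group_id="g1"):
    """Build an alignment from (species, seq_id, residues) triples."""
    return Alignment(
        group_id=group_id,
        members=[AlignedSequence(seq_id=s, species=sp, residues=res) for sp, s, res in rows],
    )


def random_alignment(rng, species, n_columns, p_gap=0.05, p_x=0.02, group_id="rand"):
    """A random alignment with one sequence per species, incl. gaps and X."""
    alphabet = list(AMINO_ACIDS)
    rows = []
    for sp in species:
        chars = []
        for _ in range(n_columns):
            u = rng.random()
            if u < p_gap:
                chars.append("-")
            elif u < p_gap + p_x:
                chars.append("X")
            else:
                chars.append(alphabet[rng.integers(0, 20)])
        rows.append((sp, f"{sp}_t1", "".join(chars)))
    return make_alignment(rows, group_id=group_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def partition():
    return SpeciesPartition(["fg1", "fg2", "fg3", "fg4"], ["ref1", "ref2"])


@pytest.fixture
def small_partition():
    return SpeciesPartition(["fg1", "fg2"], ["ref1", "ref2"])
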