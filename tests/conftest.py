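import numpy as np
import pytest

from entfkit import peptides


@pytest.fixture(scope="session")
def entf_star():
    return peptides.ENTF_STAR


@pytest.fixture(scope="session")
def reference_aligner():
    """Independent local aligner (Biopython) matching the package's
    gap convention: a gap of length L costs 10 + 0.5 * L."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.5
    aligner.extend_gap_score = -0.5
    return aligner


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(peptides.RESIDUE_MONO_MASS), size=length))


from hypothesis import settings as _hsettings

_hsettings.register_profile("deterministic", derandomize=True, deadline=None)
_hsettings.load_profile("deterministic")
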