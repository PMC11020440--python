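import numpy as np
import pytest

from varfit.alignment_features import MSA
from varfit.alphabet import AMINO_ACIDS, GAP_INDEX, N_STATES, encode_sequence


def msa_from_strings(rows, ids=None):
    """Build an MSA directly from aligned row strings (row 0 = query)."""
    ids = tuple(ids or [f"seq{i}" for i in range(len(rows))])
    codes = np.vstack([encode_sequence(r) for r in rows])
    return MSA(ids=ids, codes=codes)


def random_msa(rng, m, N, gap_fraction=0.1):
    """Random MSA with a gap-free query row, arbitrary composition."""
    codes = rng.integers(0, 20, size=(m, N)).astype(np.int8)
    if m > 1 and gap_fraction > 0:
        gaps = rng.random(size=(m - 1, N)) < gap_fraction
        codes[1:][gaps] = GAP_INDEX
    return MSA(ids=tuple(f"s{i}" for i in range(m)), codes=codes)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_msa():
    return msa_from_strings([
        "ACDEF",
        "ACDEF",
        "AVDE-",
        "GCD-F",
        "ACNEF",
        "-CDEF",
    ])
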