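import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from sf3bcons.alignment import AMINO_ACIDS, MultipleAlignment


def random_alignment(rng: np.random.Generator, max_seqs=10, max_cols=20,
                     gap_rate=0.15, x_rate=0.02) -> MultipleAlignment:
    """Small random gapped alignment for fuzz/oracle tests."""
    n = int(rng.integers(2, max_seqs + 1))
    L = int(rng.integers(1, max_cols + 1))
    alphabet = np.array(list(AMINO_ACIDS))
    while True:
        rows = []
        for i in range(n):
            chars = rng.choice(alphabet, size=L).astype(object)
            gaps = rng.random(L) < gap_rate
            xs = rng.random(L) < x_rate
            chars[gaps] = "-"
            chars[xs & ~gaps] = "X"
            rows.append("".join(chars))
        cols_ok = all(
            any(row[c] != "X" for row in rows) for c in range(L)
        )
        if cols_ok:
            return MultipleAlignment([(f"s{i}", row) for i, row in enumerate(rows)])


@pytest.fixture
def toy_alignment() -> MultipleAlignment:
    return MultipleAlignment(
        [
            ("human", "MKV-LA"),
            ("yeast", "MKVQLA"),
            ("plant", "MRV-LG"),
        ]
    )
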