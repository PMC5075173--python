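"""Shared fixtures and independent oracles.

The grid-scan oracle below recomputes net charge directly from the
sequence letters and locates the sign change exhaustively; it shares no
code with the bisection solver it is used to check.
"""

import numpy as np
import pytest

from ipcalc import pka

ALL_AA = "ACDEFGHIKLMNPQRSTVWY"


def grid_scan_pi(sequence: str, pka_set, step: float = 1e-4) -> float:
    """Exhaustive 0.0001-step scan of [0, 14] for the charge sign change."""
    seq = "".join(sequence.split()).upper()
    ph = np.arange(0.0, 14.0 + step, step)
    charge = np.zeros_like(ph)
    groups = (
        (1, pka_set.pk_nterm, +1),
        (seq.count("H"), pka_set.pk_H, +1),
        (seq.count("K"), pka_set.pk_K, +1),
        (seq.count("R"), pka_set.pk_R, +1),
        (1, pka_set.pk_cterm, -1),
        (seq.count("C"), pka_set.pk_C, -1),
        (seq.count("D"), pka_set.pk_D, -1),
        (seq.count("E"), pka_set.pk_E, -1),
        (seq.count("Y"), pka_set.pk_Y, -1),
    )
    for n, pk, sign in groups:
        if n == 0 or pk is None:
            continue
        if sign > 0:
            charge += n / (1.0 + 10.0 ** (ph - pk))
        else:
            charge -= n / (1.0 + 10.0 ** (pk - ph))
    below = np.nonzero(charge < 0.0)[0]
    assert below.size and below[0] > 0, "no sign change found on the grid"
    idx = below[0]
    return 0.5 * (ph[idx - 1] + ph[idx])


def random_sequence(rng: np.random.Generator, min_len=5, max_len=200) -> str:
    length = int(rng.integers(min_len, max_len + 1))
    return "".join(ALL_AA[i] for i in rng.integers(len(ALL_AA), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20160159)


@pytest.fixture(scope="session")
def all_builtin_sets():
    return [pka.get_pka_set(name) for name in pka.list_pka_sets()]
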