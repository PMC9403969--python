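import numpy as np
import pytest

from rnascan.fold import BuiltinBackend
from rnascan.scan import ScanParams
from rnascan.shuffle import ShuffleConfig


@pytest.fixture(scope="session")
def backend():
    """Session-wide builtin folding backend (numba kernels compile once)."""
    return BuiltinBackend()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_params(window=60, n_rand=20, seed=0, step=1):
    return ScanParams(
        window=window,
        step=step,
        shuffle=ShuffleConfig(mode="mononucleotide", n_randomizations=n_rand, seed=seed),
    )


@pytest.fixture
def scan_params():
    return small_params()


def enumerate_nested_structures(n, pairable, min_loop=3):
    """All nested pairings (as frozensets of 0-based (i, j)) on n positions.

    Brute-force oracle used by fold and consensus tests; independent of
    the DP implementation.
    """

    def rec(positions):
        positions = tuple(positions)
        if not positions:
            yield frozenset()
            return
        first, rest = positions[0], positions[1:]
        # first unpaired
        for s in rec(rest):
            yield s
        # first paired with a later position (nested split)
        for idx, j in enumerate(rest):
            if j - first - 1 < min_loop or not pairable(first, j):
                continue
            inside = rest[:idx]
            outside = rest[idx + 1 :]
            for s_in in rec(inside):
                for s_out in rec(outside):
                    yield s_in | s_out | {(first, j)}

    return list(rec(range(n)))
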