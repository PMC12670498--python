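import numpy as np
import pytest

from lassokit.massmodel import RESIDUE_MASSES, LassoTopology

LETTERS = sorted(RESIDUE_MASSES)


def random_topology(rng, n_min=6, n_max=12, with_window=True) -> LassoTopology:
    """A random valid lasso topology (D/E acceptor planted at the ring end)."""
    n = int(rng.integers(n_min, n_max + 1))
    r = int(rng.integers(2, n - 1))
    core = list(rng.choice(LETTERS, size=n))
    core[r - 1] = rng.choice(["D", "E"])
    window = None
    if with_window and r + 1 <= n:
        lo = int(rng.integers(r + 1, n + 1))
        hi = int(rng.integers(lo, n + 1))
        window = (lo, hi)
    return LassoTopology(core="".join(core), ring_size=r, loop_window=window)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_top():
    """Ring NAD (r=3) + tail GG: every mass is checkable by hand."""
    return LassoTopology(core="NADGG", ring_size=3, loop_window=(4, 5))


@pytest.fixture
def lasso20_top():
    """A 20-residue core with a 10-residue Asn-initiated ring and the
    10-residue tail used throughout the MS validation examples."""
    return LassoTopology(
        core="NALVFHKPWD" + "NIQGDHGLNI", ring_size=10, loop_window=(15, 19)
    )
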