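import numpy as np
import pytest

from chromofold import (ChainParams, ConformationEnsemble, Conformation,
                        LocusSpec, generate_null_ensemble)


@pytest.fixture(scope="session")
def locus20():
    return LocusSpec("chr1", 0, 20 * 5000, 5000)


@pytest.fixture(scope="session")
def locus100():
    return LocusSpec("chr2", 230805000, 230805000 + 100 * 5000, 5000)


@pytest.fixture(scope="session")
def null_small():
    """300 chains x 30 beads: quick shared null for unit tests."""
    return generate_null_ensemble(300, 30, seed=11)


@pytest.fixture(scope="session")
def null_medium():
    """800 chains x 50 beads."""
    return generate_null_ensemble(800, 50, seed=12)


def ensemble_from_coords(coords, log_weights=None, **kw):
    """Build an ensemble directly from a (N, n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    if log_weights is None:
        log_weights = np.zeros(len(coords))
    return ConformationEnsemble.from_arrays(coords, np.asarray(log_weights,
                                                               dtype=float),
                                            **kw)
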