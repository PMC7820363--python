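import numpy as np
import pytest

from balscan import (
    BackgroundSFS,
    expected_neutral_background,
    fold_background,
    normalize_background,
)

VARIANTS = ("2", "2MAF", "1", "0", "0MAF")


@pytest.fixture(scope="session")
def bg50():
    """Deterministic neutral derived-polarity background for n = 50."""
    return expected_neutral_background(50)


@pytest.fixture(scope="session")
def g2(bg50):
    return normalize_background(bg50, "2")


@pytest.fixture(scope="session")
def spectra(bg50):
    """Normalized background spectrum for every model variant (n = 50)."""
    minor = fold_background(bg50)
    return {
        "2": normalize_background(bg50, "2"),
        "1": normalize_background(bg50, "1"),
        "0": normalize_background(bg50, "0"),
        "2MAF": normalize_background(minor, "2MAF"),
        "0MAF": normalize_background(minor, "0MAF"),
    }


@pytest.fixture
def tiny_bg():
    """Hand-checkable background: n=2, counts {(2,1): 8, (2,2): 2}."""
    return BackgroundSFS(polarity="derived", counts={(2, 1): 8, (2, 2): 2})


def random_background(n, seed, polarity="derived"):
    """Random strictly-positive background for property tests."""
    rng = np.random.default_rng(seed)
    if polarity == "derived":
        ks = range(1, n + 1)
    else:
        ks = range(0, n // 2 + 1)
    counts = {(n, k): int(rng.integers(1, 1000)) for k in ks}
    return BackgroundSFS(polarity=polarity, counts=counts)
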