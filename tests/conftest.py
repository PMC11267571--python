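import numpy as np
import pytest

from compraman import CellFixtureConfig, RamanSpectrumSet, generate_cell_fixture


@pytest.fixture
def toy_set() -> RamanSpectrumSet:
    """5 spectra x 4 wavenumbers with full metadata, one all-zero row."""
    intens = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [0.0, 0.0, 0.0, 0.0],
            [2.0, 1.0, 0.0, 1.0],
            [5.0, 5.0, 5.0, 5.0],
            [1.0, 0.0, 2.0, 0.0],
        ]
    )
    return RamanSpectrumSet(
        intensities=intens,
        wavenumbers=np.array([400.0, 800.0, 1200.0, 1600.0]),
        labels=np.array(["a", "b", "a", "b", "a"]),
        cell_line=np.array(["L1", "L1", "L2", "L2", "L1"]),
        replicate=np.array(["R1", "R2", "R1", "R2", "R1"]),
        cell_id=np.array(["c1", "c2", "c3", "c4", "c5"]),
    )


@pytest.fixture(scope="session")
def cell_fixture() -> RamanSpectrumSet:
    """Default moderate-overlap synthetic cell data set (324 spectra)."""
    return generate_cell_fixture(CellFixtureConfig(seed=7))


@pytest.fixture(scope="session")
def easy_two_class() -> RamanSpectrumSet:
    """Two classes with disjoint strong peaks: linearly separable."""
    rng = np.random.default_rng(0)
    n, k = 120, 60
    wn = np.linspace(320, 1800, k)
    base = rng.uniform(50, 60, size=(n, k))
    labels = np.repeat(["neg", "pos"], n // 2)
    base[: n // 2, 10:14] += 400.0
    base[n // 2 :, 40:44] += 400.0
    return RamanSpectrumSet(
        intensities=rng.poisson(base).astype(float), wavenumbers=wn, labels=labels
    )
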