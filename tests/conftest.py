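import numpy as np
import pytest

from letfilm.materials import get_material
from letfilm.spectra import FluenceSpectrum
from letfilm.stopping_power import build_table


@pytest.fixture(scope="session")
def water():
    return get_material("water")


@pytest.fixture(scope="session")
def ebt3_active():
    return get_material("EBT3_active")


@pytest.fixture(scope="session")
def water_table(water):
    grid = np.geomspace(1.0, 2000.0, 250)
    return build_table(water, grid, delta=1.0)


@pytest.fixture(scope="session")
def film_table(ebt3_active):
    grid = np.geomspace(1.0, 1200.0, 200)
    return build_table(ebt3_active, grid, delta=1.0)


def random_spectrum(rng, medium="water", beam="testbeam", kind="TEF", n_bins=50,
                    e_lo=1.0, e_hi=500.0):
    """A random positive histogram spectrum for property tests."""
    edges = np.geomspace(e_lo, e_hi, n_bins + 1)
    phi = rng.lognormal(mean=0.0, sigma=1.0, size=n_bins)
    return FluenceSpectrum(
        bin_edges=edges,
        phi=phi,
        sigma_phi=0.01 * phi,
        kind=kind,
        medium=medium,
        beam=beam,
    )


@pytest.fixture(scope="session")
def study_fixture(tmp_path_factory):
    """A small synthetic study (both films, default noise), generated once."""
    from letfilm.synthetic_data import make_study_fixture

    out = tmp_path_factory.mktemp("study")
    make_study_fixture(seed=1, out_dir=out)
    return out
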