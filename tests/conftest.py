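import numpy as np
import pytest

from myoseg.image_io import AnalysisParams
from myoseg.synthetic import SectionSpec, generate_section


@pytest.fixture(scope="session")
def default_params():
    return AnalysisParams()


@pytest.fixture(scope="session")
def clean_section():
    """Small noise-free synthetic section with ground truth (type stain)."""
    spec = SectionSpec(size=320, n_fibers=30, seed=7)
    return generate_section(spec) + (spec,)


@pytest.fixture(scope="session")
def clean_object_section():
    """Same geometry as ``clean_section`` but with the object stain in green."""
    spec = SectionSpec(size=320, n_fibers=30, seed=7, stain="object")
    return generate_section(spec) + (spec,)


@pytest.fixture(scope="session")
def noisy_section():
    """Noisy synthetic section for smoothing-sensitivity tests."""
    spec = SectionSpec(size=256, n_fibers=12, seed=3, noise_sd=2.0, streak_amplitude=2.0)
    return generate_section(spec) + (spec,)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def raster_from_rows(rows_cols, shape):
    """Boolean raster from (rows, cols) index arrays."""
    out = np.zeros(shape, dtype=bool)
    out[rows_cols] = True
    return out
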