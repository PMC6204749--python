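import numpy as np
import pytest
from hypothesis import settings
from PIL import Image

from uripad import TruthBundle, fit_calibration, gen_spot_image, gen_standards

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

STANDARD_CONCS = np.arange(0.0, 1001.0, 50.0)


@pytest.fixture(scope="session")
def truth() -> TruthBundle:
    return TruthBundle()


@pytest.fixture(scope="session")
def noiseless_truth(truth) -> TruthBundle:
    return truth.noiseless()


@pytest.fixture(scope="session")
def fitted_curve(truth):
    """Calibration curve fitted to one default synthetic standards set."""
    return fit_calibration(gen_standards(STANDARD_CONCS, truth, seed=11))


@pytest.fixture(scope="session")
def exact_curve(noiseless_truth):
    """Curve fitted to noiseless standards: parameters equal the truth."""
    return fit_calibration(gen_standards(STANDARD_CONCS, noiseless_truth, seed=0))


@pytest.fixture
def spot_file(tmp_path):
    """Factory writing a synthetic spot PNG and returning its path."""

    def _write(concentration, truth, seed=0, name="spot.png", **kwargs):
        image = gen_spot_image(concentration, truth, seed=seed, **kwargs)
        path = tmp_path / name
        Image.fromarray(image).save(path)
        return path

    return _write
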