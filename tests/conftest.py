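import numpy as np
import pytest

from boldstitch import BvZLaw, ExperimentDesign, NeuralCRF, generate_amplitudes
from boldstitch.synthetic import noiseless


@pytest.fixture
def crf():
    """A saturating neural contrast response function."""
    return NeuralCRF(r_max=1.0, c50=0.25, exponent_n=2.0, r0=0.0)


@pytest.fixture
def design():
    """The 6-s block design on the five-level log-spaced contrast grid."""
    return ExperimentDesign(seed=7)


@pytest.fixture
def sqrt_law():
    """Compressive power law B = 2 Z^0.5."""
    return BvZLaw(k_scale=2.0, gamma=0.5)


@pytest.fixture
def clean_dataset(design, crf, sqrt_law):
    """Noiseless summation dataset under the square-root law."""
    return generate_amplitudes(noiseless(design), crf, sqrt_law)


def true_relative_levels(design, crf):
    from boldstitch import naka_rushton_response

    z = naka_rushton_response(design.contrast_array, crf)
    return z / z[0]
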