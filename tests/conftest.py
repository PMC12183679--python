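import numpy as np
import pytest

from flowopt.reactor import ConditionBounds, KineticParameters, ReactorModel


@pytest.fixture(scope="session")
def kin() -> KineticParameters:
    return KineticParameters()


@pytest.fixture(scope="session")
def model() -> ReactorModel:
    return ReactorModel()


@pytest.fixture(scope="session")
def iso_model(model) -> ReactorModel:
    return model.isothermal()


class TwoPeakSurface:
    """Synthetic multimodal test surface on the decision box: two Gaussian
    peaks, the global one at ``p_hi`` and a lower local one at ``p_lo``."""

    def __init__(self):
        self.bounds = ConditionBounds()
        self.p_hi = np.array([6.5, 0.6, 320.0])
        self.p_lo = np.array([2.0, 1.6, 290.0])
        self.h_hi, self.h_lo = 2.0, 1.5
        self.width = 0.18  # in units of the box span

    def __call__(self, x) -> float:
        u = (np.asarray(x, dtype=float) - self.bounds.lower) / self.bounds.span
        uh = (self.p_hi - self.bounds.lower) / self.bounds.span
        ul = (self.p_lo - self.bounds.lower) / self.bounds.span
        g = lambda c, h: h * np.exp(-np.sum((u - c) ** 2) / (2 * self.width**2))
        return float(g(uh, self.h_hi) + g(ul, self.h_lo))


@pytest.fixture
def two_peak() -> TwoPeakSurface:
    return TwoPeakSurface()
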