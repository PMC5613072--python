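import numpy as np
import pytest

from monothermo import Isotherm


def make_isotherm(area, pressure, temperature=20.0, components=(("LIPID", 1.0),)):
    return Isotherm(
        area=np.asarray(area, dtype=float),
        pressure=np.asarray(pressure, dtype=float),
        temperature=temperature,
        components=components,
    )


@pytest.fixture
def linear_isotherm():
    """Exact line pi = 4*(42 - A), clipped at zero, 300 points."""
    area = np.linspace(52.0, 32.0, 300)
    pressure = np.clip(4.0 * (42.0 - area), 0.0, None)
    return make_isotherm(area, pressure)


@pytest.fixture
def volmer_isotherm():
    """Noise-free Volmer film, omega=38 A^2, 20 C, 800 points."""
    from monothermo import EOSModel, simulate_pure_isotherm

    model = EOSModel(kind="volmer", omega=38.0, pi_coh=10.0)
    return simulate_pure_isotherm(
        model, temperature=20.0, n_points=800, area_range=(42.0, 100.0)
    )
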