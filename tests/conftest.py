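import numpy as np
import pytest

from relkin import (
    CATEGORY_EXEMPLARS,
    ReleaseCurve,
    SyntheticConfig,
    ThermoParameters,
    generate_release_curve,
)


@pytest.fixture
def exemplar_iv() -> ThermoParameters:
    """Category IV: low burst followed by steady-state release (days)."""
    return CATEGORY_EXEMPLARS["IV"]


def exemplar_schedule(params: ThermoParameters, n_points: int = 30) -> np.ndarray:
    """Log-spaced schedule resolving both the burst rise and the slow tail."""
    return np.geomspace(0.1 / params.k_s, 3.0 / params.k_off, n_points)


@pytest.fixture
def noisy_iv_curve(exemplar_iv) -> ReleaseCurve:
    """A reproducible noisy curve from the category-IV exemplar."""
    return generate_release_curve(
        SyntheticConfig(
            params=exemplar_iv,
            times=exemplar_schedule(exemplar_iv, 20),
            noise_sd=0.02,
            seed=20240,
        )
    )


@pytest.fixture
def noiseless_iv_curve(exemplar_iv) -> ReleaseCurve:
    return generate_release_curve(
        SyntheticConfig(
            params=exemplar_iv,
            times=exemplar_schedule(exemplar_iv, 20),
            noise_model="none",
        )
    )
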