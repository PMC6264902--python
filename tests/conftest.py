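import numpy as np
import pytest

from retinamosaic import ModelParams, Mode, ParameterGrid


@pytest.fixture
def doli_params() -> ModelParams:
    """Worked ordered-retina constants: beta=8, gamma=10, X0=5, P0=1e-4."""
    return ModelParams.doli()


@pytest.fixture
def deterministic_doli() -> ModelParams:
    """Perfectly deterministic alternating retina (P0 = 0)."""
    return ModelParams.doli(P0_structured=0.0)


@pytest.fixture
def simulated_grid() -> ParameterGrid:
    return ParameterGrid.simulated()


@pytest.fixture
def small_grid() -> ParameterGrid:
    """Coarse grid keeping exhaustive cross-checks fast."""
    return ParameterGrid(
        modes=(Mode.fr, Mode.fg, Mode.ar, Mode.ag),
        alphas=(0.0, 0.3, 0.7, 1.0),
        epsilons=(0.0, 0.3),
        P0s=(0.0, 0.1),
        ks=(1.0, 4.0),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
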