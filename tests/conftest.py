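import numpy as np
import pytest

from patchcoex import IslandRecipe, PatchOutline, generate_island


@pytest.fixture(scope="session")
def unit_square() -> PatchOutline:
    return PatchOutline(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float), label="square")


@pytest.fixture(scope="session")
def triangle() -> PatchOutline:
    return PatchOutline(np.array([[0, 0], [1, 0], [0, 1]], float), label="tri")


@pytest.fixture(scope="session")
def circle_512() -> PatchOutline:
    """Regular 512-gon inscribed in the unit circle."""
    theta = np.linspace(0, 2 * np.pi, 512, endpoint=False)
    return PatchOutline(np.column_stack([np.cos(theta), np.sin(theta)]), label="circle")


@pytest.fixture(scope="session")
def smooth_island() -> PatchOutline:
    """Macro-lobed island with no micro-scale jaggedness."""
    return generate_island(IslandRecipe(macro_amp=0.35, micro_amp=0.0, seed=5))


@pytest.fixture(scope="session")
def noisy_island() -> PatchOutline:
    """Same macro realization as smooth_island plus micro-scale noise."""
    return generate_island(IslandRecipe(macro_amp=0.35, micro_amp=0.02, seed=5))
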