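import numpy as np
import pytest

from habitatrf.raster import EnvironmentalStack, GridGeometry, RasterGrid
from habitatrf.synthetic import LandscapeConfig, LayerSpec


@pytest.fixture
def unit_geom():
    """10x10 grid of 1-unit cells with top-left corner at (0, 10)."""
    return GridGeometry(x0=0.0, y0=10.0, dx=1.0, dy=1.0, nrows=10, ncols=10)


@pytest.fixture
def small_stack(unit_geom):
    """Three-layer harmonized stack with deterministic values."""
    rng = np.random.default_rng(42)
    stack = EnvironmentalStack()
    for name in ("temp", "precip", "veg"):
        stack.add(name, RasterGrid(rng.uniform(0, 1, unit_geom.shape), unit_geom))
    return stack


@pytest.fixture
def tiny_landscape():
    """Fast 5-layer synthetic landscape config (single-resolution)."""
    specs = {
        "temp": LayerSpec("env", 10.0, 30.0, length_scale=0.1),
        "rain": LayerSpec("env", 0.0, 200.0, length_scale=0.1),
        "veg": LayerSpec("env", 0.0, 100.0, length_scale=0.05),
        "flat": LayerSpec("env", 1.0, 1.0),
        "rough": LayerSpec("env", 0.0, 1.0, length_scale=0.0),
    }
    return LandscapeConfig(
        extent=(30.0, 26.0, 31.0, 27.0),
        resolutions={"env": 1 / 40},
        layer_specs=specs,
        suitability_coefficients={"temp": 1.0, "rain": 1.0},
        intercept=-1.0,
        n_presence=30,
        seed=11,
        derive_terrain=False,
    )
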