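import numpy as np
import pandas as pd
import pytest

from corneaquant import SynthParams, extract_green, generate_section


@pytest.fixture(scope="session")
def default_section():
    """One synthetic section with the default (curved, noisy) parameters."""
    return generate_section(SynthParams(seed=42))


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free, fissure-free parameters: tissue green is exactly
    base + layer gain."""
    return SynthParams(
        seed=7, fissure_density=0.0, noise_sd=0.0, staining_sd=0.0
    )


@pytest.fixture(scope="session")
def clean_section(clean_params):
    return generate_section(clean_params)


@pytest.fixture(scope="session")
def straight_clean_section():
    """Straight horizontal band, no stochastic components, distinct
    layer gains -- the fully analytic reference geometry."""
    return generate_section(
        SynthParams(
            seed=7, band_curvature=0.0, fissure_density=0.0, noise_sd=0.0,
            staining_sd=0.0, layer_gain=(0.0, 20.0, 20.0, 0.0),
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def make_brightness_table(rng, offsets=(0.0, 0.0), sds=(10.0, 10.0),
                          pops=("a", "b"), n_per_cell=2, layer_gain=None):
    """Small synthetic brightness table with known population structure
    (no imaging involved) for statistical unit tests."""
    rows = []
    for pop, off, sd in zip(pops, offsets, sds):
        for layer in range(1, 5):
            gain = 0.0 if layer_gain is None else layer_gain[layer - 1]
            for frame in range(1, 7):
                vals = rng.normal(150.0 + off + gain, sd, size=n_per_cell)
                for k, v in enumerate(vals):
                    rows.append(
                        {
                            "cornea_id": f"{pop}{k}",
                            "population": pop,
                            "slide_id": "S1",
                            "layer": layer,
                            "frame": frame,
                            "brightness": v,
                            "area": 100,
                        }
                    )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_green(default_section):
    return extract_green(default_section.image)
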