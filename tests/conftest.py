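import numpy as np
import pytest

from phytonox.synthetic import (
    CompoundSimDesign,
    IntensityDesign,
    TrendSpec,
    flat_trends,
    simulate_compound_dataset,
    simulate_intensity_matrix,
)


@pytest.fixture(scope="session")
def planted_fruit_matrix():
    """25-metabolite fruit matrix; first 5 metabolites decline exponentially."""
    names = [f"met_{i:02d}" for i in range(25)]
    trends = flat_trends(names)
    for name in names[:5]:
        trends[name] = TrendSpec(shape="exp_decline", baseline=100.0, rate=0.1)
    design = IntensityDesign(trends=trends, noise_sigma=0.1, seed=42)
    matrix, truth = simulate_intensity_matrix(design)
    return matrix, truth


@pytest.fixture(scope="session")
def separable_compounds():
    """Strongly separable descriptor dataset (11 informative at 5 sd)."""
    design = CompoundSimDesign(n_informative=11, effect=5.0, seed=7)
    return simulate_compound_dataset(design)


@pytest.fixture(scope="session")
def null_compounds():
    """Exchangeable-class descriptor dataset (no signal)."""
    design = CompoundSimDesign(n_informative=0, effect=0.0, seed=7)
    return simulate_compound_dataset(design)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
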