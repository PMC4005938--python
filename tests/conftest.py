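import numpy as np
import pytest

from neurolems.arraymorph import ArrayMorphology
from neurolems.nml import Point3DWithDiam
from neurolems.units import builtin_registry


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


def random_array_morphology(rng, n_segments: int, branch_probability: float = 0.2) -> ArrayMorphology:
    """Small random tree used as a property-test input (not the synth module)."""
    am = ArrayMorphology(
        vertices=np.array([[0.0, 0.0, 0.0, 10.0]]),
        connectivity=np.array([-1]),
        id="random_tree",
    )
    for k in range(n_segments):
        if k == 0:
            parent = 0
        elif rng.random() < branch_probability:
            parent = int(rng.integers(1, k + 1))
        else:
            parent = k
        point = Point3DWithDiam(
            float(rng.uniform(-500, 500)),
            float(rng.uniform(-500, 500)),
            float(rng.uniform(-500, 500)),
            float(rng.uniform(0.5, 12.0)),
        )
        am.append_child(parent, point)
    return am
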