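import numpy as np
import pytest

from chromascape.simulate import MaskSpec, gen_mask


@pytest.fixture(scope="session")
def carpet_mask():
    """Sierpinski carpet, depth 5, 243x243 (analytic D = log8/log3)."""
    return gen_mask(MaskSpec(kind="ifs_fractal", name="sierpinski_carpet",
                             depth=5, size=(243, 243)))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
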