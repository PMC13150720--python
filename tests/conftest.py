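import numpy as np
import pytest

from eipcea import make_reference_parameter_set
from eipcea.markov import ModelDraw


@pytest.fixture(scope="session")
def reference_params():
    params, _ = make_reference_parameter_set(seed=0)
    return params


@pytest.fixture(scope="session")
def reference_draw(reference_params):
    return ModelDraw.from_point_estimates(reference_params)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete generated input fixture on disk."""
    from eipcea import write_fixture

    outdir = tmp_path_factory.mktemp("fixture")
    write_fixture(outdir, seed=0)
    return outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
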