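import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from greenet.pipeline import RunConfig, run_all  # noqa: E402


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def pipeline_manifest(tmp_path_factory):
    """One full default-scale pipeline run shared by the integration tests."""
    outdir = tmp_path_factory.mktemp("pipeline")
    return run_all(RunConfig(seed=1), outdir), outdir
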