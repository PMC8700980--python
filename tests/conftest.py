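import logging

import pytest

from regcascade.config import PipelineConfig
from regcascade.pipeline import run_all
from regcascade.simulate import generate_study

logging.getLogger("regcascade").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig(seed=0)


@pytest.fixture(scope="session")
def study():
    """The default synthetic study, shared across the suite."""
    return generate_study(seed=0)


@pytest.fixture(scope="session")
def pipeline_dir(tmp_path_factory):
    """A full end-to-end pipeline run at seed 0."""
    out = tmp_path_factory.mktemp("pipeline")
    run_all(PipelineConfig(seed=0), out)
    return out
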