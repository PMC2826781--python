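import logging

import pytest

from markovcea import load_bundled_config, run_base_case

logging.getLogger("markovcea").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def base_config():
    return load_bundled_config()


@pytest.fixture(scope="session")
def base_run(base_config):
    return run_base_case(base_config)


@pytest.fixture()
def config_dict(base_config):
    return base_config.to_dict()
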