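from pathlib import Path

import numpy as np
import pytest

from worksim import PolicyLevers

SCENARIO_DIR = Path(__file__).parent / "scenarios"


@pytest.fixture
def levers():
    return PolicyLevers()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def write_yaml(tmp_path):
    def _write(text: str, name: str = "config.yaml") -> Path:
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
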