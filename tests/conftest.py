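import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tmp_fasta(tmp_path):
    def _write(content: str, name: str = "seqs.fasta"):
        path = tmp_path / name
        path.write_text(content)
        return path

    return _write
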