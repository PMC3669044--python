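import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=60)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_matrix_file(tmp_path):
    """3 clones x 4 conditions, one duplicate gene, one missing cell."""
    text = (
        "clone_id\tgene_id\tT1\tT2\tT3\tT4\n"
        "c1\tg1\t0.1\t-0.2\t0.3\t0.4\n"
        "c2\tg1\t0.1\tNA\t0.3\t0.4\n"
        "c3\tg2\t-1.0\t2.0\t0.0\t1.5\n"
    )
    path = tmp_path / "expr.tsv"
    path.write_text(text)
    return path
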