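import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def protein_fasta(tmp_path):
    path = tmp_path / "prot.fasta"
    path.write_text(">a\nMKV\n>b\nMKVLLN\n")
    return path


@pytest.fixture
def sd_ectodomain():
    from ladderlens import simulate_ectodomain

    return simulate_ectodomain("SD", 21, seed=11)
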