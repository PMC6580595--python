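import pytest

import sbscreen as sb
from sbscreen import synth


@pytest.fixture(scope="session")
def toy_bundle():
    """Default synthetic genome (2 x 200 kb, 40 genes) with TA index and
    gene models built at the toy-scale 2 kb promoter window."""
    genome, table = synth.default_reference(seed=1)
    ta_index = sb.build_ta_index(genome)
    genes = synth.annotate(genome, table, promoter_window=2_000, ta_index=ta_index)
    return genome, table, ta_index, genes


@pytest.fixture(scope="session")
def recovery_bundle():
    """Larger genome (4 x 500 kb) used for parameter-recovery studies."""
    genome, table = synth.recovery_reference(seed=2)
    ta_index = sb.build_ta_index(genome)
    genes = synth.annotate(genome, table, promoter_window=2_000, ta_index=ta_index)
    return genome, table, ta_index, genes


@pytest.fixture(scope="session")
def toy_cfg():
    return sb.toy_config()
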