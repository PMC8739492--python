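import pytest

import palcolin as pc


@pytest.fixture(scope="session")
def pal_archs():
    """The five shipped cluster fixtures, segmented."""
    return {bid: pc.load_pal_bgc(bid) for bid in pc.PAL_BGC_IDS}


@pytest.fixture(scope="session")
def bgc4(pal_archs):
    return pal_archs["pal_bgc_4"]


@pytest.fixture(scope="session")
def bgc4_structure(bgc4):
    return pc.assemble(bgc4)
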