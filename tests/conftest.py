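import numpy as np
import pytest

from hemaqc.core import DEFAULT_ANALYTES, AnalyteSpec


@pytest.fixture
def plt_spec() -> AnalyteSpec:
    """Default PLT: target 250 x 10^9/L, SD 7 (CV 2.8%), TEa +/-10 absolute."""
    return DEFAULT_ANALYTES["PLT"]


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
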