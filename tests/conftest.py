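import numpy as np
import pytest

from groupphylo import make_group

#: The group menu exercised throughout: cyclic orders 2..5 and the two
#: smallest genuine products (K3ST and Z2 x Z3 ~ Z6).
GROUP_SPECS = [[2], [3], [4], [5], [2, 2], [2, 3]]


@pytest.fixture(params=GROUP_SPECS, ids=lambda s: "Z" + "x".join(map(str, s)))
def group(request):
    return make_group(request.param)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def max_rate_error(spectrum, rates):
    """Worst absolute deviation between a recovered spectrum and the true
    RateSpec, including the total rate."""
    worst = abs(spectrum.lambda_total - rates.total_rate)
    for e, chan in rates.items():
        for sigma, a in chan.items():
            worst = max(worst, abs(spectrum.get(e, sigma) - a))
    return worst
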