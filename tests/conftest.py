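import numpy as np
import pytest

from magtk.simulate import SimulationConfig, build_community


@pytest.fixture(scope="session")
def community():
    """Default synthetic community used by several suites (seed fixed)."""
    return build_community(SimulationConfig(seed=123))


def naive_pearson(x, y):
    """Textbook product-moment correlation, coded independently of magtk."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / (sxx * syy) ** 0.5
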