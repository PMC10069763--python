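import math

import numpy as np
import pytest

from simplexcast import Hyperparameters, TimeSeries
from simplexcast.synthetic import SyntheticSpec, gen_logistic_map, gen_seasonal


def brute_force_neighbors(values, E, n, tp, current_t):
    """Independent exhaustive scan: returns [(t_i, d_i), ...] sorted by
    (distance, t_i), truncated to n.  1-based time indices."""
    values = np.asarray(values, dtype=float)
    query = values[current_t - E : current_t]
    cands = []
    for t in range(E, min(current_t - tp, len(values)) + 1):
        if t == current_t:
            continue
        d = math.sqrt(sum((a - b) ** 2 for a, b in zip(values[t - E : t], query)))
        cands.append((d, t))
    cands.sort()
    return [(t, d) for d, t in cands[:n]]


@pytest.fixture(scope="session")
def mortality_series() -> TimeSeries:
    """The seasonal mortality-like exemplar (no shock)."""
    return gen_seasonal(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def logistic_series() -> TimeSeries:
    return gen_logistic_map(400, r_param=3.9, x0=0.31)


@pytest.fixture
def periodic_series() -> TimeSeries:
    """Exactly periodic: one random 20-point pattern tiled over 5 cycles."""
    rng = np.random.default_rng(5)
    pattern = rng.uniform(0.0, 10.0, 20)
    return TimeSeries(values=np.tile(pattern, 5))


@pytest.fixture
def default_hp() -> Hyperparameters:
    return Hyperparameters()
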