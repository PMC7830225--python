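"""Shared fixtures: builtin conditions and a session-scoped trace cache."""

import numpy as np
import pytest

from grindforce import (
    GeneratorConfig,
    conditions_by_id,
    generate_force_trace,
)

#: published per-axis spike counts (x, y, z) of the six series
EXPECTED_COUNTS = {
    "1d": (23, 10, 21),
    "1w": (0, 0, 0),
    "2d": (0, 0, 5),
    "2w": (0, 1, 11),
    "3": (92, 10, 19),
    "4": (21, 25, 21),
}

SEEDS = tuple(range(1, 11))


@pytest.fixture(scope="session")
def conditions():
    return conditions_by_id()


@pytest.fixture(scope="session")
def trace_cache(conditions):
    """Memoized synthetic trial factory: (series_id, seed) -> ForceTrace."""
    cache = {}

    def get(series_id: str, seed: int):
        key = (series_id, seed)
        if key not in cache:
            cache[key] = generate_force_trace(
                conditions[series_id], GeneratorConfig(seed=seed)
            )
        return cache[key]

    return get


def make_trace(values_x, rate=100.0, values_y=None, values_z=None):
    """Small hand-built ForceTrace around explicit x-channel samples."""
    from grindforce import ForceTrace

    vx = np.asarray(values_x, dtype=float)
    n = len(vx)
    zero = np.zeros(n)
    return ForceTrace(
        sampling_rate=rate,
        t=np.arange(n) / rate,
        fx=vx,
        fy=zero if values_y is None else np.asarray(values_y, float),
        fz=zero if values_z is None else np.asarray(values_z, float),
    )
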