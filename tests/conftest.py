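import numpy as np
import pytest

from pathcv.systems import (
    ToySystemSpec,
    make_two_state_loop_spec,
    mueller_brown_minima,
    mueller_brown_saddles,
)


@pytest.fixture(scope="session")
def mb_spec():
    return ToySystemSpec("mueller-brown")


@pytest.fixture(scope="session")
def mb_minima(mb_spec):
    return mueller_brown_minima(mb_spec)


@pytest.fixture(scope="session")
def mb_saddles(mb_spec):
    return mueller_brown_saddles(mb_spec)


@pytest.fixture(scope="session")
def loop_spec():
    return make_two_state_loop_spec(n_beads=20, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def arc_position(polyline: np.ndarray, point: np.ndarray) -> float:
    """Arc-length coordinate of a point lying on a polyline (nearest segment)."""
    s = 0.0
    best = (np.inf, 0.0)
    for a, b in zip(polyline[:-1], polyline[1:]):
        ab = b - a
        seg = float(np.linalg.norm(ab))
        t = np.clip(np.dot(point - a, ab) / np.dot(ab, ab), 0.0, 1.0)
        d = float(np.linalg.norm(a + t * ab - point))
        if d < best[0]:
            best = (d, s + t * seg)
        s += seg
    return best[1]


def min_distance_to_polyline(images: np.ndarray, point: np.ndarray) -> float:
    """Distance from a point to the piecewise-linear path through images."""
    best = np.inf
    for a, b in zip(images[:-1], images[1:]):
        ab = b - a
        t = np.clip(np.dot(point - a, ab) / np.dot(ab, ab), 0.0, 1.0)
        best = min(best, float(np.linalg.norm(a + t * ab - point)))
    return best
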