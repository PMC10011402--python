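import math

import numpy as np
import pytest

from bodylines.geometry import BezierSegment, SLine

#: The classic cubic approximation constant for a 90-degree circular arc.
MAGIC_K = 0.5522847498


def quarter_circle_segment(r: float = 100.0) -> BezierSegment:
    """Magic-constant cubic approximating a quarter circle of radius r."""
    k = MAGIC_K * r
    return BezierSegment(np.array([[r, 0.0], [r, k], [k, r], [0.0, r]]))


def circular_arc_segment(r, a0, a1) -> BezierSegment:
    """Cubic arc from angle a0 to a1 with the exact (4/3)tan(theta/4) handle."""
    theta = a1 - a0
    h = 4.0 / 3.0 * math.tan(theta / 4.0) * r
    p0 = r * np.array([math.cos(a0), math.sin(a0)])
    p3 = r * np.array([math.cos(a1), math.sin(a1)])
    t0 = np.array([-math.sin(a0), math.cos(a0)])
    t3 = np.array([-math.sin(a1), math.cos(a1)])
    return BezierSegment(np.array([p0, p0 + h * t0, p3 - h * t3, p3]))


def straight_line(total: float = 300.0) -> SLine:
    """Two collinear segments along the y axis, total length ``total``."""
    half = total / 2.0
    seg = lambda y0, y1: BezierSegment(
        np.array([[0.0, y0], [0.0, y0 + (y1 - y0) / 3],
                  [0.0, y0 + 2 * (y1 - y0) / 3], [0.0, y1]])
    )
    return SLine((seg(total, half), seg(half, 0.0)), label="straight")


def random_segment(rng: np.random.Generator, scale: float = 100.0) -> BezierSegment:
    """A non-degenerate random cubic segment."""
    while True:
        pts = rng.uniform(-scale, scale, size=(4, 2))
        if np.linalg.norm(pts[1] - pts[0]) > 1e-3 * scale:
            return BezierSegment(pts)


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def quarter_circle():
    return quarter_circle_segment()


@pytest.fixture
def straight():
    return straight_line()
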