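"""Differential geometry of piecewise cubic Bézier "S-lines".

An S-line is the abstract back-profile object used throughout this package:
two concatenated cubic Bézier segments joined with positional (C0) and,
usually, tangent-direction (G1) continuity.  The module provides exact
evaluation, signed curvature, arc-length resampling into curvature profiles,
inflection location, mean absolute curvature, and plain-text I/O (JSON, CSV,
SVG export for visual inspection).

Conventions
-----------
* Coordinates are y-up canvas units (arbitrary length unit, e.g. px).
* Signed curvature is positive for a left (counter-clockwise) turn:
  ``kappa = (x'y'' - y'x'') / (x'^2 + y'^2)^(3/2)`` with derivatives taken
  with respect to the Bézier parameter t.  Mirroring a line through a
  vertical axis therefore negates kappa.
* At the junction of the two segments the curve is generally G1 but not G2,
  so kappa may jump; a profile sample landing on the junction records the
  mean of the two one-sided values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "BezierSegment",
    "SLine",
    "CurvatureProfile",
    "SingularPointError",
    "evaluate",
    "signed_curvature",
    "segment_arc_length",
    "subdivide",
    "arc_length_profile",
    "mean_absolute_curvature",
    "inflection_points",
    "is_s_shaped",
    "mirror_x",
    "transform_line",
    "sline_to_dict",
    "sline_from_dict",
    "save_slines_json",
    "load_slines_json",
    "slines_to_csv",
    "slines_from_csv",
    "slines_to_svg",
]

#: Absolute tolerance (canvas units) for C0 continuity at the junction.
C0_TOL = 1e-9
#: Angular tolerance (radians) for G1 (tangent-direction) continuity.
G1_TOL = 1e-6
#: Relative tolerance of the adaptive arc-length quadrature.
QUAD_RTOL = 1e-8
#: Default number of arc-length samples for curvature profiles.
DEFAULT_PROFILE_SAMPLES = 500


class SingularPointError(ValueError):
    """Raised when curvature is requested at a (near-)stationary point."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BezierSegment:
    """A single cubic Bézier segment defined by four 2-D control points."""

    control_points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.control_points, dtype=float)
        if pts.shape != (4, 2):
            raise ValueError(
                f"a cubic Bézier segment needs exactly 4 control points of "
                f"dimension 2, got array of shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValueError("control points must be finite")
        if np.allclose(pts, pts[0], atol=0.0, rtol=0.0, equal_nan=False) or (
            np.max(np.abs(pts - pts[0])) == 0.0
        ):
            raise ValueError("degenerate segment: all four control points coincide")
        object.__setattr__(self, "control_points", pts)

    @property
    def p0(self) -> np.ndarray:
        return self.control_points[0]

    @property
    def p3(self) -> np.ndarray:
        return self.control_points[3]

    def derivative_points(self) -> np.ndarray:
        """Control points of the derivative (quadratic) Bézier, scaled by 3."""
        return 3.0 * np.diff(self.control_points, axis=0)


@dataclass(frozen=True)
class SLine:
    """Two concatenated cubic Bézier segments sharing a junction point.

    Parameters
    ----------
    segments : pair of BezierSegment
        Traversed first-to-second; the last control point of the first must
        equal the first control point of the second within ``C0_TOL``.
    label : str
        Identifier such as ``"BL3"`` or ``"HL4"``.
    g1 : bool
        If true, tangent-direction continuity at the junction is verified:
        the handle into and the handle out of the junction must be
        anti-parallel within ``G1_TOL`` radians.
    """

    segments: tuple[BezierSegment, BezierSegment]
    label: str = ""
    g1: bool = True

    def __post_init__(self) -> None:
        if len(self.segments) != 2:
            raise ValueError("an S-line consists of exactly two segments")
        a, b = self.segments
        if not np.all(np.abs(a.p3 - b.p0) <= C0_TOL):
            raise ValueError(
                f"C0 continuity violated at junction of {self.label!r}: "
                f"{a.p3} != {b.p0}"
            )
        if self.g1:
            v_in = a.control_points[3] - a.control_points[2]
            v_out = b.control_points[1] - b.control_points[0]
            ni, no = np.linalg.norm(v_in), np.linalg.norm(v_out)
            if ni == 0.0 or no == 0.0:
                raise ValueError(f"zero-length junction handle in {self.label!r}")
            cosang = float(np.dot(v_in, v_out) / (ni * no))
            ang = float(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if ang > G1_TOL:
                raise ValueError(
                    f"G1 continuity violated at junction of {self.label!r}: "
                    f"handle directions differ by {ang:.3e} rad"
                )
        object.__setattr__(self, "segments", (a, b))

    @property
    def junction(self) -> np.ndarray:
        return self.segments[0].p3

    @property
    def start(self) -> np.ndarray:
        return self.segments[0].p0

    @property
    def end(self) -> np.ndarray:
        return self.segments[1].p3

    def control_array(self) -> np.ndarray:
        """All eight control points as a (2, 4, 2) array."""
        return np.stack([s.control_points for s in self.segments])


@dataclass(frozen=True)
class CurvatureProfile:
    """Signed curvature sampled at increasing arc-length positions."""

    s: np.ndarray
    kappa: np.ndarray
    line_label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        k = np.asarray(self.kappa, dtype=float)
        if s.ndim != 1 or k.ndim != 1 or len(s) != len(k):
            raise ValueError("s and kappa must be 1-D arrays of equal length")
        if len(s) < 2:
            raise ValueError("a curvature profile needs at least 2 samples")
        if s[0] != 0.0:
            raise ValueError("arc length must start at 0")
        if not np.all(np.diff(s) > 0):
            raise ValueError("arc-length positions must be strictly increasing")
        if not (np.all(np.isfinite(s)) and np.all(np.isfinite(k))):
            raise ValueError("profile values must be finite")
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "kappa", k)

    @property
    def length(self) -> float:
        return float(self.s[-1])


# ---------------------------------------------------------------------------
# evaluation and derivatives
# ---------------------------------------------------------------------------


def _bernstein_eval(points: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Evaluate a Bézier of any degree at parameters t (vectorised)."""
    n = len(points) - 1
    t = np.asarray(t, dtype=float)[..., None]
    out = np.zeros(t.shape[:-1] + (2,))
    from math import comb

    for i, p in enumerate(points):
        out += comb(n, i) * (1 - t) ** (n - i) * t**i * p
    return out


def evaluate(segment: BezierSegment, t: float | np.ndarray) -> np.ndarray:
    """Point on a cubic Bézier segment at parameter ``t`` in [0, 1]."""
    ta = np.asarray(t, dtype=float)
    if np.any(ta < 0.0) or np.any(ta > 1.0):
        raise ValueError(f"parameter t={t} outside the unit interval")
    return _bernstein_eval(segment.control_points, ta)


def _derivatives(segment: BezierSegment, t: float | np.ndarray):
    """First and second parametric derivatives B'(t), B''(t)."""
    d1pts = segment.derivative_points()  # degree-2 Bézier
    d2pts = 2.0 * np.diff(d1pts, axis=0)  # degree-1 Bézier
    ta = np.asarray(t, dtype=float)
    return _bernstein_eval(d1pts, ta), _bernstein_eval(d2pts, ta)


def signed_curvature(segment: BezierSegment, t: float | np.ndarray) -> float | np.ndarray:
    """Signed curvature of a segment at parameter(s) ``t``.

    Positive for counter-clockwise (left-turning) traversal in y-up
    coordinates.  Raises :class:`SingularPointError` where the first
    derivative is numerically zero (stationary point).
    """
    ta = np.asarray(t, dtype=float)
    if np.any(ta < 0.0) or np.any(ta > 1.0):
        raise ValueError(f"parameter t={t} outside the unit interval")
    d1, d2 = _derivatives(segment, ta)
    speed = np.hypot(d1[..., 0], d1[..., 1])
    if np.any(speed <= 1e-12):
        bad = np.atleast_1d(ta)[np.atleast_1d(speed) <= 1e-12]
        raise SingularPointError(
            f"stationary point: |B'(t)| <= 1e-12 at t={bad.tolist()}"
        )
    cross = d1[..., 0] * d2[..., 1] - d1[..., 1] * d2[..., 0]
    kappa = cross / speed**3
    return float(kappa) if np.isscalar(t) or ta.ndim == 0 else kappa


def subdivide(segment: BezierSegment, t0: float) -> tuple[BezierSegment, BezierSegment]:
    """Split a segment at ``t0`` by de Casteljau's algorithm.

    The two pieces trace exactly the same locus as the original, which makes
    this the canonical reparameterization used in invariance tests.
    """
    if not (0.0 < t0 < 1.0):
        raise ValueError("subdivision parameter must be strictly inside (0, 1)")
    p = segment.control_points
    a = (1 - t0) * p[:-1] + t0 * p[1:]
    b = (1 - t0) * a[:-1] + t0 * a[1:]
    c = (1 - t0) * b[:-1] + t0 * b[1:]
    left = np.array([p[0], a[0], b[0], c[0]])
    right = np.array([c[0], b[1], a[2], p[3]])
    return BezierSegment(left), BezierSegment(right)


# ---------------------------------------------------------------------------
# arc length
# ---------------------------------------------------------------------------


def _speed_func(segment: BezierSegment):
    d1pts = segment.derivative_points()

    def speed(t):
        v = _bernstein_eval(d1pts, np.asarray(t, dtype=float))
        return np.hypot(v[..., 0], v[..., 1])

    return speed


def segment_arc_length(segment: BezierSegment) -> float:
    """Arc length of a segment by adaptive quadrature (rel. tol 1e-8)."""
    speed = _speed_func(segment)
    length, _ = quad(speed, 0.0, 1.0, epsrel=QUAD_RTOL, limit=200)
    return float(length)


def _arclength_inverter(segment: BezierSegment, n_knots: int = 257):
    """Monotone interpolant t(s) for one segment, plus its total length.

    A composite Gauss–Legendre rule on a fine knot grid gives the cumulative
    arc length; the cumulative curve is rescaled so its endpoint matches the
    adaptive-quadrature total, then inverted with a monotone (PCHIP) spline.
    """
    speed = _speed_func(segment)
    knots = np.linspace(0.0, 1.0, n_knots)
    gx, gw = np.polynomial.legendre.leggauss(8)
    # map Gauss nodes into every knot interval
    mid = (knots[:-1] + knots[1:]) / 2.0
    half = np.diff(knots) / 2.0
    tgrid = mid[:, None] + half[:, None] * gx[None, :]
    sp = speed(tgrid.ravel()).reshape(tgrid.shape)
    seg_lengths = (sp * gw[None, :]).sum(axis=1) * half
    cum = np.concatenate([[0.0], np.cumsum(seg_lengths)])
    total = segment_arc_length(segment)
    if cum[-1] <= 0.0:
        raise ValueError("degenerate segment: zero arc length")
    cum *= total / cum[-1]
    t_of_s = PchipInterpolator(cum, knots)
    return t_of_s, total


def arc_length_profile(
    line: SLine, n: int = DEFAULT_PROFILE_SAMPLES
) -> CurvatureProfile:
    """Curvature profile of an S-line, sampled equally in arc length.

    ``n`` samples span the full two-segment line from s=0 to the total arc
    length.  A sample falling on the junction records the mean of the two
    one-sided curvature values, since the line is generally not G2 there.
    """
    if n < 2:
        raise ValueError("need at least 2 profile samples")
    seg_a, seg_b = line.segments
    inv_a, len_a = _arclength_inverter(seg_a)
    inv_b, len_b = _arclength_inverter(seg_b)
    total = len_a + len_b
    s = np.linspace(0.0, total, n)
    kappa = np.empty(n)
    junction_tol = 1e-9 * total
    on_junction = np.abs(s - len_a) <= junction_tol
    in_a = (s < len_a) & ~on_junction
    in_b = ~in_a & ~on_junction
    if np.any(in_a):
        kappa[in_a] = signed_curvature(seg_a, np.clip(inv_a(s[in_a]), 0.0, 1.0))
    if np.any(in_b):
        kappa[in_b] = signed_curvature(
            seg_b, np.clip(inv_b(s[in_b] - len_a), 0.0, 1.0)
        )
    if np.any(on_junction):
        kappa[on_junction] = 0.5 * (
            signed_curvature(seg_a, 1.0) + signed_curvature(seg_b, 0.0)
        )
    return CurvatureProfile(s=s, kappa=kappa, line_label=line.label)


def mean_absolute_curvature(profile: CurvatureProfile) -> float:
    """Arc-length-weighted mean of |kappa|: (1/L) * integral |kappa| ds.

    Computed by the trapezoid rule on the profile samples; an index of how
    strongly a line curves overall, independent of turn direction.
    """
    if len(profile.s) < 2:
        raise ValueError("need at least 2 samples")
    return float(np.trapezoid(np.abs(profile.kappa), profile.s) / profile.length)


def _kappa_at_s(line: SLine, inverters, s: float) -> float:
    (inv_a, len_a), (inv_b, len_b) = inverters
    if s <= len_a:
        return float(signed_curvature(line.segments[0], float(np.clip(inv_a(s), 0, 1))))
    return float(
        signed_curvature(line.segments[1], float(np.clip(inv_b(s - len_a), 0, 1)))
    )


def inflection_points(line: SLine, n_dense: int = 1024) -> list[float]:
    """Arc-length positions where the signed curvature changes sign.

    Sign changes are bracketed on a dense profile and refined by bisection to
    ``1e-6`` of the total length.  Curvature magnitudes below a noise floor
    (relative to the profile maximum) are treated as zero, so a straight line
    — whose curvature is identically zero up to round-off — yields no
    inflections.  An S-line is "S-shaped" iff exactly one position is found.
    """
    prof = arc_length_profile(line, n_dense)
    total = prof.length
    kmax = float(np.max(np.abs(prof.kappa)))
    floor = max(1e-12, 1e-9 * kmax)
    sign = np.where(prof.kappa > floor, 1, np.where(prof.kappa < -floor, -1, 0))
    inverters = (
        _arclength_inverter(line.segments[0]),
        _arclength_inverter(line.segments[1]),
    )
    out: list[float] = []
    last_nonzero = 0
    last_idx = 0
    for i in range(len(sign)):
        if sign[i] == 0:
            continue
        if last_nonzero != 0 and sign[i] != last_nonzero:
            lo, hi = prof.s[last_idx], prof.s[i]
            f_lo = _kappa_at_s(line, inverters, lo)
            try:
                root = brentq(
                    lambda s: _kappa_at_s(line, inverters, s),
                    lo,
                    hi,
                    xtol=1e-6 * total,
                )
            except ValueError:
                # discontinuous sign flip (curvature jump at the junction):
                # bisect on the sign instead of on a continuous root
                a, b = lo, hi
                while b - a > 1e-6 * total:
                    m = 0.5 * (a + b)
                    if np.sign(_kappa_at_s(line, inverters, m)) == np.sign(f_lo):
                        a = m
                    else:
                        b = m
                root = 0.5 * (a + b)
            out.append(float(root))
        last_nonzero, last_idx = sign[i], i
    return out


def is_s_shaped(line: SLine) -> bool:
    """True iff the line has exactly one curvature sign change."""
    return len(inflection_points(line)) == 1


# ---------------------------------------------------------------------------
# affine helpers
# ---------------------------------------------------------------------------


def transform_line(
    line: SLine, matrix: np.ndarray | None = None, offset: Sequence[float] = (0.0, 0.0)
) -> SLine:
    """Apply an affine map ``p -> matrix @ p + offset`` to all control points.

    The G1 flag is preserved only for orientation-preserving, angle-preserving
    maps; reflections keep G1 too (anti-parallelism is reflection-invariant).
    """
    m = np.eye(2) if matrix is None else np.asarray(matrix, dtype=float)
    off = np.asarray(offset, dtype=float)
    segs = tuple(
        BezierSegment(seg.control_points @ m.T + off) for seg in line.segments
    )
    return SLine(segments=segs, label=line.label, g1=line.g1)


def mirror_x(line: SLine, label: str | None = None) -> SLine:
    """Mirror a line through the vertical axis (x -> -x); negates curvature."""
    out = transform_line(line, np.array([[-1.0, 0.0], [0.0, 1.0]]))
    return SLine(out.segments, label=label if label is not None else line.label,
                 g1=line.g1)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def sline_to_dict(line: SLine) -> dict:
    return {
        "label": line.label,
        "segments": [seg.control_points.tolist() for seg in line.segments],
    }


def sline_from_dict(d: dict) -> SLine:
    segs = tuple(BezierSegment(np.asarray(s, dtype=float)) for s in d["segments"])
    return SLine(segments=segs, label=d.get("label", ""))


def save_slines_json(lines: Iterable[SLine], path: str | Path) -> None:
    payload = [sline_to_dict(ln) for ln in lines]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_slines_json(path: str | Path) -> list[SLine]:
    payload = json.loads(Path(path).read_text())
    if isinstance(payload, dict):
        payload = [payload]
    return [sline_from_dict(d) for d in payload]


def slines_to_csv(lines: Iterable[SLine], path: str | Path) -> None:
    """Write control points as CSV: label, segment, point_index, x, y."""
    rows = []
    for ln in lines:
        for si, seg in enumerate(ln.segments):
            for pi, (x, y) in enumerate(seg.control_points):
                rows.append(
                    {"label": ln.label, "segment": si, "point_index": pi,
                     "x": x, "y": y}
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def slines_from_csv(path: str | Path) -> list[SLine]:
    df = pd.read_csv(path)
    lines = []
    for label, grp in df.groupby("label", sort=False):
        segs = []
        for si in (0, 1):
            sub = grp[grp["segment"] == si].sort_values("point_index")
            segs.append(BezierSegment(sub[["x", "y"]].to_numpy(dtype=float)))
        lines.append(SLine(segments=tuple(segs), label=str(label)))
    return lines


_SVG_DOC = """<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}"
     viewBox="0 0 {w} {h}">
<rect width="100%" height="100%" fill="#808080"/>
{paths}
</svg>
"""


def slines_to_svg(
    lines: Sequence[SLine],
    path: str | Path,
    height: float = 300.0,
    canvas: tuple[float, float] = (500.0, 500.0),
    stroke: str = "#cc0000",
) -> None:
    """Export lines to SVG, each normalized to the given height.

    Lines are centred side by side on the canvas and flipped to SVG's
    y-down convention; each line becomes one path with two cubic ("C")
    commands.  Intended for visual inspection only.
    """
    w, h = canvas
    n = len(lines)
    paths = []
    for i, ln in enumerate(lines):
        ctrl = ln.control_array().reshape(-1, 2)
        ymin, ymax = ctrl[:, 1].min(), ctrl[:, 1].max()
        scale = height / (ymax - ymin) if ymax > ymin else 1.0
        cx = (i + 0.5) * w / n
        xmid = (ctrl[:, 0].min() + ctrl[:, 0].max()) / 2.0

        def to_canvas(p):
            x = cx + (p[0] - xmid) * scale
            y = h / 2.0 + height / 2.0 - (p[1] - ymin) * scale
            return f"{x:.3f},{y:.3f}"

        a, b = ln.segments
        pa, pb = a.control_points, b.control_points
        d = (
            f"M {to_canvas(pa[0])} "
            f"C {to_canvas(pa[1])} {to_canvas(pa[2])} {to_canvas(pa[3])} "
            f"C {to_canvas(pb[1])} {to_canvas(pb[2])} {to_canvas(pb[3])}"
        )
        paths.append(
            f'<path d="{d}" fill="none" stroke="{stroke}" stroke-width="2">'
            f"<title>{ln.label}</title></path>"
        )
    Path(path).write_text(_SVG_DOC.format(w=w, h=h, paths="\n".join(paths)))
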