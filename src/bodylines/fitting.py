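"""Least-squares fitting of a two-segment Bézier S-line to an ordered contour.

The fit reproduces the body-line extraction step: an ordered sample of a back
profile (thoracic spine down to the buttocks) is approximated by two
concatenated cubic Bézier segments whose junction is positionally (C0) and
tangent-direction (G1) continuous.  The endpoints of the fitted line
interpolate the first and last contour points, because a body line spans a
fixed anatomical extent.

Algorithm
---------
Minimisation of ``sum_k ||B(t_k) - q_k||^2`` in three stages (details and
rationale in docs/methods.md):

1. *Alternation.*  Parameters ``t_k`` start at normalised cumulative chord
   length, each point assigned to the segment on its side of the junction
   index.  Each round solves a linear least-squares problem for the free
   control points (a free-handle solve estimates the shared junction-tangent
   direction, then an exactly-G1 solve fixes it), optionally re-corresponds
   the parameters by arc length on the current curve when that fits better,
   and refines each ``t_k`` by guarded Newton projection.
2. *Joint refinement.*  Levenberg-Marquardt over the nine geometric
   parameters with footpoints re-projected inside every residual
   evaluation, which escapes the flat valley of locus-equivalent
   parameterizations where the alternation stalls.
3. *Identification.*  A re-fit with the point correspondence pinned to
   locus-based arc fractions, which pins the weakly identified valley
   direction under noise.

No stage may increase the residual materially, and the recorded
``rms_history`` is non-increasing.  The alternation stops when the
improvement falls below ``tol`` (default ``1e-6`` of the contour's
bounding-box diagonal) or after its iteration budget; non-convergence is
reported via the ``converged`` flag, not an exception.

If no junction index is given, it is placed at the contour point nearest the
sign change of the (smoothed) discrete curvature — the inflection — so that
each cubic fits a one-signed arc, mirroring how S-shaped lines are composed
of two opposite-curvature arcs meeting at the inflection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BezierSegment, SLine, evaluate, _derivatives

__all__ = ["ContourSample", "FitResult", "discrete_curvature", "fit_sline"]

DEFAULT_MAX_ITER = 50
#: Convergence tolerance as a fraction of the bounding-box diagonal.
DEFAULT_TOL_FRACTION = 1e-6
#: Newton steps per point in the parameter-correction sweep.
NEWTON_STEPS = 5


@dataclass(frozen=True)
class ContourSample:
    """An ordered 2-D point sample tracing a back profile top to bottom."""

    points: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must be an (n, 2) array")
        if len(pts) < 10:
            raise ValueError("a contour sample needs at least 10 points")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps == 0.0):
            raise ValueError("consecutive contour points must not coincide")
        object.__setattr__(self, "points", pts)

    @property
    def bbox_diagonal(self) -> float:
        span = self.points.max(axis=0) - self.points.min(axis=0)
        return float(np.hypot(*span))


@dataclass(frozen=True)
class FitResult:
    line: SLine
    rms_residual: float
    n_iterations: int
    converged: bool
    junction_index: int
    #: RMS residual after each accepted outer iteration (non-increasing).
    rms_history: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.rms_residual < 0:
            raise ValueError("rms residual cannot be negative")

    def report(self) -> dict:
        return {
            "label": self.line.label,
            "rms_residual": self.rms_residual,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "junction_index": self.junction_index,
        }


def discrete_curvature(points: np.ndarray) -> np.ndarray:
    """Signed three-point (circumscribed-circle) curvature per contour point.

    For each interior point the curvature of the circle through it and its
    two neighbours, signed by turn direction (positive = left turn, matching
    the continuous convention).  Endpoints copy their nearest interior value.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 two-dimensional points")
    a, b, c = pts[:-2], pts[1:-1], pts[2:]
    ab = b - a
    bc = c - b
    ca = a - c
    cross = ab[:, 0] * bc[:, 1] - ab[:, 1] * bc[:, 0]
    denom = (
        np.linalg.norm(ab, axis=1)
        * np.linalg.norm(bc, axis=1)
        * np.linalg.norm(ca, axis=1)
    )
    if np.any(denom == 0.0):
        raise ValueError("coincident points in a curvature triple")
    k_interior = 2.0 * cross / denom
    return np.concatenate([[k_interior[0]], k_interior, [k_interior[-1]]])


def _auto_junction(points: np.ndarray) -> int:
    """Junction index at the discrete-curvature sign change.

    The contour itself is smoothed with a moving average before the discrete
    curvature is computed (three-point curvature amplifies point noise by
    1/spacing^2), the curvature is smoothed again, and the result is scanned
    for sign changes.  Among the admissible split points (at least 4 contour
    points on each side) the crossing that best separates two opposite-signed
    arcs — the one maximising the product of the mean curvature magnitudes on
    its two sides — is chosen; with no crossing (a C-shaped or straight
    contour) the split falls back to the middle of the contour.
    """
    n = len(points)
    cwin = max(3, n // 16) | 1  # odd window
    pad = cwin // 2
    padded = np.vstack(
        [points[0] + (points[0] - points[1:pad + 1][::-1]),
         points,
         points[-1] + (points[-1] - points[-pad - 1:-1][::-1])]
    )
    kernel2 = np.ones(cwin) / cwin
    smoothed_pts = np.column_stack(
        [np.convolve(padded[:, c], kernel2, mode="valid") for c in range(2)]
    )
    kappa = discrete_curvature(smoothed_pts)
    win = max(3, n // 10)
    kernel = np.ones(win) / win
    smooth = np.convolve(kappa, kernel, mode="same")
    lo, hi = 4, n - 5
    best_j, best_score = None, -np.inf
    for j in range(lo, hi + 1):
        if smooth[j - 1] == 0.0 or np.sign(smooth[j - 1]) == np.sign(smooth[j]):
            continue
        left, right = np.mean(smooth[:j]), np.mean(smooth[j:])
        if np.sign(left) == np.sign(right):
            continue
        # weight the side means by sqrt(side length): the reliability of a
        # mean over few noisy samples is low, which suppresses spurious
        # crossings near the contour ends
        score = abs(left) * np.sqrt(j) * abs(right) * np.sqrt(n - j)
        if score > best_score:
            best_j, best_score = j, score
    return best_j if best_j is not None else n // 2


def _chord_parameters(points: np.ndarray) -> np.ndarray:
    chord = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(chord)])
    return cum / cum[-1] if cum[-1] > 0 else np.linspace(0, 1, len(points))


def _bernstein3(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)[:, None]
    return np.hstack([(1 - t) ** 3, 3 * (1 - t) ** 2 * t, 3 * (1 - t) * t**2, t**3])


def _solve_free_handles(q, t1, t2, idx_a, idx_b, q0, qn):
    """Unconstrained LS with independent junction handles w1, w2.

    Unknowns (each 2-D): P1a, J, w1 (handle into the junction, P2a = J - w1),
    w2 (handle out, P1b = J + w2), P2b.  Used only to estimate the shared
    junction tangent direction; x and y decouple, so one design matrix with
    two right-hand sides suffices.  The junction contour point belongs to
    both segments and contributes one equation per segment.
    """
    Ba = _bernstein3(t1)
    Aa = np.zeros((len(t1), 5))
    Aa[:, 0] = Ba[:, 1]              # P1a
    Aa[:, 1] = Ba[:, 2] + Ba[:, 3]   # J
    Aa[:, 2] = -Ba[:, 2]             # w1
    rhs_a = q[idx_a] - Ba[:, 0:1] * q0
    Bb = _bernstein3(t2)
    Ab = np.zeros((len(t2), 5))
    Ab[:, 1] = Bb[:, 0] + Bb[:, 1]   # J
    Ab[:, 3] = Bb[:, 1]              # w2
    Ab[:, 4] = Bb[:, 2]              # P2b
    rhs_b = q[idx_b] - Bb[:, 3:4] * qn
    w, *_ = np.linalg.lstsq(np.vstack([Aa, Ab]), np.vstack([rhs_a, rhs_b]),
                            rcond=None)
    return w  # (5, 2): rows P1a, J, w1, w2, P2b


def _solve_g1(q, t1, t2, idx_a, idx_b, q0, qn, u):
    """G1-constrained LS: handles forced along the unit direction ``u``.

    Unknowns: P1a (2), J (2), scalar handle lengths b1, b2 >= 0, P2b (2).
    The scalar lengths couple x and y, so the system is solved in flattened
    form (one row per point per coordinate).
    """
    Ba = _bernstein3(t1)
    Bb = _bernstein3(t2)
    na, nb = len(t1), len(t2)
    A = np.zeros((2 * (na + nb), 8))
    rhs = np.empty(2 * (na + nb))
    # segment a rows: x rows then y rows, then segment b rows likewise
    row = 0
    for c in range(2):
        sl = slice(row, row + na)
        A[sl, 0 + c] = Ba[:, 1]                     # P1a_c
        A[sl, 2 + c] = Ba[:, 2] + Ba[:, 3]          # J_c
        A[sl, 4] = -Ba[:, 2] * u[c]                 # b1
        rhs[sl] = q[idx_a, c] - Ba[:, 0] * q0[c]
        row += na
    for c in range(2):
        sl = slice(row, row + nb)
        A[sl, 2 + c] = Bb[:, 0] + Bb[:, 1]          # J_c
        A[sl, 5] = Bb[:, 1] * u[c]                  # b2
        A[sl, 6 + c] = Bb[:, 2]                     # P2b_c
        rhs[sl] = q[idx_b, c] - Bb[:, 3] * qn[c]
        row += nb
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    p1a = sol[0:2]
    j = sol[2:4]
    scale = float(np.linalg.norm(qn - q0))
    b1 = max(float(sol[4]), 1e-3 * scale)  # floor avoids degenerate handles
    b2 = max(float(sol[5]), 1e-3 * scale)
    p2b = sol[6:8]
    seg_a = np.array([q0, p1a, j - b1 * u, j])
    seg_b = np.array([j, j + b2 * u, p2b, qn])
    return seg_a, seg_b


def _residuals(q, t1, t2, idx_a, idx_b, seg_a, seg_b):
    """Stacked per-equation residuals (junction point counted per segment)."""
    ra = _bernstein3(t1) @ seg_a - q[idx_a]
    rb = _bernstein3(t2) @ seg_b - q[idx_b]
    return np.vstack([ra, rb])


def _t_at_arc_fractions(seg: BezierSegment, fracs: np.ndarray) -> np.ndarray:
    """Parameters at which the segment's normalized arc length equals fracs.

    Light fixed-grid version (composite Gauss on 64 intervals) of the
    arc-length inversion used in the geometry module: correspondence
    re-initialisation does not need adaptive accuracy.
    """
    from .geometry import _bernstein_eval

    d1pts = seg.derivative_points()
    knots = np.linspace(0.0, 1.0, 65)
    gx, gw = np.polynomial.legendre.leggauss(5)
    mid = (knots[:-1] + knots[1:]) / 2.0
    half = np.diff(knots) / 2.0
    tg = mid[:, None] + half[:, None] * gx[None, :]
    v = _bernstein_eval(d1pts, tg.ravel()).reshape(tg.shape + (2,))
    sp = np.hypot(v[..., 0], v[..., 1])
    cum = np.concatenate([[0.0], np.cumsum((sp * gw[None, :]).sum(axis=1) * half)])
    cum /= cum[-1]
    return np.interp(fracs, cum, knots)


def _newton_project(seg: BezierSegment, q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Refine footpoint parameters by damped Newton, keeping improvements."""
    t_new = t.copy()
    pts = evaluate(seg, t)
    best = np.sum((pts - q) ** 2, axis=1)
    cur = t.copy()
    for _ in range(NEWTON_STEPS):
        b = evaluate(seg, cur)
        d1, d2 = _derivatives(seg, cur)
        diff = b - q
        g = np.sum(diff * d1, axis=1)
        h = np.sum(d1 * d1, axis=1) + np.sum(diff * d2, axis=1)
        step = np.where(np.abs(h) > 1e-30, g / np.where(h == 0, 1.0, h), 0.0)
        cur = np.clip(cur - step, 0.0, 1.0)
        dist = np.sum((evaluate(seg, cur) - q) ** 2, axis=1)
        better = dist < best
        t_new[better] = cur[better]
        best[better] = dist[better]
    return t_new


def _poly_coeffs(ctrl: np.ndarray) -> np.ndarray:
    """Monomial coefficients (4, 2) of a cubic Bézier: B(t) = sum c_i t^i."""
    p0, p1, p2, p3 = ctrl
    return np.array(
        [p0, 3 * (p1 - p0), 3 * (p2 - 2 * p1 + p0), p3 - 3 * p2 + 3 * p1 - p0]
    )


def _project_poly(ctrl: np.ndarray, q: np.ndarray, t: np.ndarray, steps: int = 4):
    """Fast guarded Newton footpoint projection on raw control arrays.

    Same algorithm as :func:`_newton_project` but evaluated through monomial
    coefficients, for the refinement stage's hot loop.  Returns the improved
    parameters and the residual vectors at those parameters.
    """
    c = _poly_coeffs(ctrl)

    def val(tt):
        tt = tt[:, None]
        return c[0] + tt * (c[1] + tt * (c[2] + tt * c[3]))

    def der(tt):
        tt = tt[:, None]
        return c[1] + tt * (2 * c[2] + tt * 3 * c[3])

    def der2(tt):
        tt = tt[:, None]
        return 2 * c[2] + tt * 6 * c[3]

    best_t = t.copy()
    diff = val(best_t) - q
    best = np.sum(diff**2, axis=1)
    cur = t.copy()
    for _ in range(steps):
        b = val(cur)
        d1 = der(cur)
        d2 = der2(cur)
        dv = b - q
        g = np.sum(dv * d1, axis=1)
        h = np.sum(d1 * d1, axis=1) + np.sum(dv * d2, axis=1)
        step = np.where(np.abs(h) > 1e-30, g / np.where(h == 0, 1.0, h), 0.0)
        cur = np.clip(cur - step, 0.0, 1.0)
        dist = np.sum((val(cur) - q) ** 2, axis=1)
        better = dist < best
        best_t[better] = cur[better]
        best[better] = dist[better]
    return best_t, val(best_t) - q


def _vp_polish(q, idx_a, idx_b, q0, qn, seg_a, seg_b, t1, t2):
    """Variable-projection Levenberg-Marquardt refinement.

    The alternating scheme descends monotonically but can stall in the flat
    valley of locus-equivalent parameterizations (moving control points
    along the curve while the footpoints compensate barely changes the
    residual).  This stage optimises the nine geometric parameters — inner
    handle of each segment, junction, two junction handle lengths and the
    shared junction tangent angle — jointly, re-projecting the footpoints
    inside every residual evaluation so the finite-difference Jacobian sees
    the projection response.  Returns refined segments, parameters and
    whether the optimiser reported success.
    """
    from scipy.optimize import least_squares

    v_in = seg_a[3] - seg_a[2]
    v_out = seg_b[1] - seg_b[0]
    p0 = np.concatenate(
        [
            seg_a[1],
            seg_a[3],
            [
                float(np.linalg.norm(v_in)),
                float(np.linalg.norm(v_out)),
                float(np.arctan2(v_in[1], v_in[0])),
            ],
            seg_b[2],
        ]
    )
    floor = 1e-3 * float(np.linalg.norm(qn - q0))
    base_t1, base_t2 = t1.copy(), t2.copy()
    qa, qb = q[idx_a], q[idx_b]

    def build(p):
        u = np.array([np.cos(p[6]), np.sin(p[6])])
        sa = np.array([q0, p[0:2], p[2:4] - max(p[4], floor) * u, p[2:4]])
        sb = np.array([p[2:4], p[2:4] + max(p[5], floor) * u, p[7:9], qn])
        return sa, sb

    def fun(p):
        # deterministic: footpoints are always projected from the same base,
        # so the finite-difference Jacobian sees the projection response
        # without warm-start drift
        sa, sb = build(p)
        _, ra = _project_poly(sa, qa, base_t1, steps=6)
        _, rb = _project_poly(sb, qb, base_t2, steps=6)
        return np.concatenate([ra.ravel(), rb.ravel()])

    ok = False
    try:
        for _ in range(2):  # re-base the footpoints once mid-way
            sol = least_squares(
                fun, p0, method="lm", xtol=1e-10, ftol=1e-10, max_nfev=60
            )
            p0 = sol.x
            ok = bool(sol.success)
            sa, sb = build(p0)
            base_t1, _ = _project_poly(sa, qa, base_t1, steps=6)
            base_t2, _ = _project_poly(sb, qb, base_t2, steps=6)
    except Exception:
        return seg_a, seg_b, t1, t2, False
    sa, sb = build(p0)
    return sa, sb, base_t1, base_t2, ok


_GAUSS5 = np.polynomial.legendre.leggauss(5)


def _cum_arc(ctrl: np.ndarray, n_intervals: int = 24):
    """Cumulative-arc-length knots (t, normalized s) of one cubic segment."""
    gx, gw = _GAUSS5
    c = _poly_coeffs(ctrl)
    knots = np.linspace(0.0, 1.0, n_intervals + 1)
    mid = (knots[:-1] + knots[1:]) / 2.0
    half = np.diff(knots) / 2.0
    tt = (mid[:, None] + half[:, None] * gx[None, :])[..., None]
    d = c[1] + tt * (2 * c[2] + tt * (3 * c[3]))
    sp = np.hypot(d[..., 0], d[..., 1])
    cum = np.concatenate([[0.0], np.cumsum((sp * gw).sum(axis=1) * half)])
    return knots, cum / cum[-1]


def _arc_correspondence_refine(q, idx_a, idx_b, q0, qn, seg_a, seg_b, t1, t2):
    """Final identification stage: fit with locus-based uniform correspondence.

    The footpoint objective leaves the control points weakly identified: a
    one-parameter family of G1 cubic pairs traces nearly the same locus with
    different speeds, so noise slides the fit along that family.  The
    identifying information is that contours are digitized (nearly) uniformly
    along the locus.  Arc length along the locus is parameterization-
    invariant, so the data's per-segment arc fractions are estimated from the
    footpoints of the polished curve — immune to the slide — and the curve is
    re-fitted with the correspondence pinned to those fractions:
    ``t_k = (arc length of candidate)^{-1}(f_k)``.  At zero noise this
    objective has its exact minimum at the generating curve.
    """
    from scipy.optimize import least_squares

    # locus-based arc fractions of the data points
    fracs = []
    for ctrl, tt in ((seg_a, t1), (seg_b, t2)):
        knots, cum = _cum_arc(ctrl)
        fracs.append(np.interp(tt, knots, cum))
    frac_a, frac_b = fracs
    qa, qb = q[idx_a], q[idx_b]

    v_in = seg_a[3] - seg_a[2]
    p0 = np.concatenate(
        [
            seg_a[1],
            seg_a[3],
            [
                float(np.linalg.norm(v_in)),
                float(np.linalg.norm(seg_b[1] - seg_b[0])),
                float(np.arctan2(v_in[1], v_in[0])),
            ],
            seg_b[2],
        ]
    )
    floor = 1e-3 * float(np.linalg.norm(qn - q0))

    def build(p):
        u = np.array([np.cos(p[6]), np.sin(p[6])])
        sa = np.array([q0, p[0:2], p[2:4] - max(p[4], floor) * u, p[2:4]])
        sb = np.array([p[2:4], p[2:4] + max(p[5], floor) * u, p[7:9], qn])
        return sa, sb

    def resid_one(ctrl, fr, qq):
        knots, cum = _cum_arc(ctrl)
        tt = np.interp(fr, cum, knots)[:, None]
        c = _poly_coeffs(ctrl)
        pos = c[0] + tt * (c[1] + tt * (c[2] + tt * c[3]))
        return (pos - qq).ravel()

    def fun(p):
        sa, sb = build(p)
        return np.concatenate([resid_one(sa, frac_a, qa), resid_one(sb, frac_b, qb)])

    try:
        sol = least_squares(
            fun, p0, method="lm", xtol=1e-12, ftol=1e-12, max_nfev=120
        )
    except Exception:
        return seg_a, seg_b, False
    sa, sb = build(sol.x)
    return sa, sb, bool(sol.success)


def fit_sline(
    contour: ContourSample,
    junction_index: int | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float | None = None,
) -> FitResult:
    """Fit a G1 two-segment Bézier S-line to an ordered contour sample."""
    q = contour.points
    n = len(q)
    diag = contour.bbox_diagonal
    if tol is None:
        tol = DEFAULT_TOL_FRACTION * diag
    if junction_index is None:
        junction_index = _auto_junction(q)
    if not (4 <= junction_index <= n - 5):
        raise ValueError(
            f"junction index {junction_index} too close to a contour end "
            f"(need >= 4 points on each side of {n} points)"
        )
    q0, qn = q[0], q[-1]
    idx_a = np.arange(0, junction_index + 1)
    idx_b = np.arange(junction_index, n)

    # chord-length parameters, per segment (junction shared at t=1 / t=0)
    u = _chord_parameters(q)
    uj = u[junction_index]
    frac_a = u[idx_a] / uj if uj > 0 else np.linspace(0, 1, len(idx_a))
    frac_b = (
        (u[idx_b] - uj) / (1 - uj) if uj < 1 else np.linspace(0, 1, len(idx_b))
    )
    t1, t2 = frac_a.copy(), frac_b.copy()

    def rms_of(sa, sb, ta, tb):
        res = _residuals(q, ta, tb, idx_a, idx_b, sa, sb)
        return float(np.sqrt(np.mean(np.sum(res**2, axis=1))))

    def ls_at(ta, tb):
        """Direction estimate plus exactly-G1 least squares at fixed t."""
        w = _solve_free_handles(q, ta, tb, idx_a, idx_b, q0, qn)
        u = w[2] + w[3]
        nu = np.linalg.norm(u)
        if nu == 0.0:  # degenerate: fall back to the contour chord
            u = qn - q0
            nu = np.linalg.norm(u)
        sa, sb = _solve_g1(q, ta, tb, idx_a, idx_b, q0, qn, u / nu)
        return sa, sb, rms_of(sa, sb, ta, tb)

    rms = np.inf
    seg_a = seg_b = None
    converged = False
    iterations = 0
    history: list[float] = []
    # the alternating stage stalls once it reaches the flat valley; a short
    # budget suffices before handing over to the joint refinement
    alt_budget = min(max_iter, 10)
    for iterations in range(1, alt_budget + 1):
        # 1) least squares at the current parameters (never worse than the
        #    previous accepted state, which keeps the descent monotone) ...
        cand_a, cand_b, cand_rms = ls_at(t1, t2)
        if seg_a is not None:
            # ... and, as a block alternative, re-correspond the parameters
            # by arc length on the current curve and re-solve: contours are
            # sampled nearly uniformly in arc length, and footpoint
            # projection alone cannot escape the flat valley of
            # locus-equivalent parameterizations
            t1_arc = _t_at_arc_fractions(BezierSegment(seg_a), frac_a)
            t2_arc = _t_at_arc_fractions(BezierSegment(seg_b), frac_b)
            alt_a, alt_b, alt_rms = ls_at(t1_arc, t2_arc)
            if alt_rms < cand_rms:
                cand_a, cand_b, cand_rms = alt_a, alt_b, alt_rms
                t1, t2 = t1_arc, t2_arc
        seg_a, seg_b = cand_a, cand_b

        # 2) parameter correction (guarded Newton projection of each point)
        sa = BezierSegment(seg_a)
        sb = BezierSegment(seg_b)
        t1 = _newton_project(sa, q[idx_a], t1)
        t2 = _newton_project(sb, q[idx_b], t2)

        rms_new = rms_of(seg_a, seg_b, t1, t2)
        history.append(rms_new)
        if rms - rms_new < tol:
            rms = rms_new
            converged = True
            break
        rms = rms_new

    # joint refinement of the geometric parameters (see _vp_polish)
    pa, pb, t1p, t2p, ok = _vp_polish(
        q, idx_a, idx_b, q0, qn, seg_a, seg_b, t1, t2
    )
    rms_polished = rms_of(pa, pb, t1p, t2p)
    if rms_polished <= rms:
        seg_a, seg_b, t1, t2, rms = pa, pb, t1p, t2p, rms_polished
        history.append(rms)
        converged = converged or ok

    # identification stage: pin the correspondence to locus arc fractions
    ra, rb, ok2 = _arc_correspondence_refine(
        q, idx_a, idx_b, q0, qn, seg_a, seg_b, t1, t2
    )
    t1r, _ = _project_poly(ra, q[idx_a], t1, steps=8)
    t2r, _ = _project_poly(rb, q[idx_b], t2, steps=8)
    rms_refined = rms_of(ra, rb, t1r, t2r)
    # accept unless it worsened the locus fit materially (it trades a tiny
    # amount of orthogonal residual for identified control points)
    if rms_refined <= rms * 1.05 + tol:
        seg_a, seg_b = ra, rb
        if rms_refined <= rms:  # history tracks accepted descent steps only
            history.append(rms_refined)
        rms = rms_refined
        converged = converged or ok2

    line = SLine(
        segments=(BezierSegment(seg_a), BezierSegment(seg_b)),
        label=contour.label,
        g1=True,
    )
    return FitResult(
        line=line,
        rms_residual=rms,
        n_iterations=iterations,
        converged=converged,
        junction_index=junction_index,
        rms_history=tuple(history),
    )
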