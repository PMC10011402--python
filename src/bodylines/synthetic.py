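"""Synthetic study inputs: S-line families, noisy contours, rating tables.

This module generates every input the pipeline needs so all stages are
testable without the original study deposit:

* ``make_sline`` — a deterministic family of body-line stand-ins indexed by a
  lumbar-curvature angle theta (degrees).  The real body lines were extracted
  from photographs we do not possess, so the theta-to-geometry mapping here
  is the package's own: each line is two circular-arc-like Bézier segments
  joined G1 at the inflection, with the *chord deflection angle* — the angle
  between the chord of the upper arc and the chord of the lower arc at the
  junction — equal to theta.  Larger theta gives a more strongly curved line
  (the anatomical angle between thoracic spine and sacrum is defined on
  photographs and cannot be transported to an abstract line exactly; only
  order and spacing of the family matter downstream, and every consumer of
  the family is invariant to the direction of the theta-to-depth mapping).
* ``make_hogarth_family`` — a stand-in for the seven historical S-lines of
  increasing curvature (the exact 1753 geometry is not reproduced): S-lines
  whose mean absolute curvature strictly increases with the index, built on
  the body-line construction so their curvature histograms are comparable,
  and calibrated so that family member 4 is nearest the theta = 44 deg body
  line under the Histogram Difference.
* ``sample_contour`` — arc-length-equidistant samples of a line plus
  isotropic Gaussian noise, for fit-recovery experiments.  One sample is
  placed exactly on the junction so the sampled contour is representable by
  the fitting model.
* ``generate_ratings`` — long-format rating tables with the documented
  effect structure: an ordered stimulus main effect (stimuli 3 and 4 highest
  and near-equal, stimulus 1 lowest), an additive rater-gender offset (women
  rate higher), no stimulus x gender interaction, participant-level random
  intercepts, and a shared participant x stimulus latent value that makes the
  two rating contexts strongly rank-correlated.

Random streams are per participant and per component (intercepts, latents,
noise, group assignment), so enlarging the sample leaves previously generated
participants byte-identical.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fitting import ContourSample
from .geometry import (
    BezierSegment,
    SLine,
    arc_length_profile,
    evaluate,
    mean_absolute_curvature,
    _arclength_inverter,
)

__all__ = [
    "DEFAULT_THETAS",
    "OPTIMAL_LUMBAR_ANGLE",
    "MorphSpec",
    "RatingGeneratorSpec",
    "default_morphs",
    "closest_to_optimum",
    "make_sline",
    "make_body_lines",
    "make_hogarth_family",
    "make_hogarth_lines",
    "chord_angle",
    "sample_contour",
    "generate_ratings",
    "study1_spec",
    "study2_spec",
]

#: Lumbar-curvature angles (degrees) of the five study stimuli, in order.
DEFAULT_THETAS = (32.0, 39.0, 44.0, 49.0, 54.0)
#: Proposed biomechanical optimum of lumbar curvature (degrees).
OPTIMAL_LUMBAR_ANGLE = 45.5
#: Naturally occurring range of the angle (degrees): construction domain.
THETA_RANGE = (20.0, 70.0)

#: Fixed turn (degrees) of the shallow upper arc of a body-line stand-in.
_UPPER_TURN = 14.0
#: Junction height as a fraction of line height, measured from the bottom.
_JUNCTION_FRACTION = 0.35

#: Handle skew grading curvature toward the junction (see ``_arc_segment``).
_HANDLE_SKEW = 0.4

#: Chord-deflection angles (degrees) of the seven historical-line stand-ins.
#: The stand-ins share the body-line construction (so their curvature
#: histograms are commensurable with the body lines' — a precondition for
#: the Histogram Difference to grade rather than saturate) and differ only
#: in this grid, chosen once so member 1 is nearly straight, mean absolute
#: curvature increases strictly with the index, and members 4 and 5 are the
#: Histogram-Difference neighbours of the theta = 44 and theta = 49 body
#: lines respectively.
_HOGARTH_DEFLECTIONS = (8.0, 19.0, 30.0, 43.5, 50.0, 58.0, 66.0)


@dataclass(frozen=True)
class MorphSpec:
    """One study stimulus: morph id (1-5) and its lumbar angle in degrees."""

    morph_id: int
    theta: float

    def __post_init__(self) -> None:
        if not 1 <= self.morph_id <= 5:
            raise ValueError("morph_id must be 1..5")
        lo, hi = THETA_RANGE
        if not lo <= self.theta <= hi:
            raise ValueError(f"theta {self.theta} outside natural range {THETA_RANGE}")


def default_morphs() -> tuple[MorphSpec, ...]:
    return tuple(MorphSpec(i + 1, t) for i, t in enumerate(DEFAULT_THETAS))


def closest_to_optimum(
    thetas: tuple[float, ...] = DEFAULT_THETAS,
    optimum: float = OPTIMAL_LUMBAR_ANGLE,
) -> int:
    """1-based index of the angle nearest the proposed optimum."""
    diffs = [abs(t - optimum) for t in thetas]
    return int(np.argmin(diffs)) + 1


# ---------------------------------------------------------------------------
# S-line construction
# ---------------------------------------------------------------------------


def _arc_segment(
    start: np.ndarray, heading: float, turn: float, chord: float, skew: float = 0.0
):
    """Cubic Bézier arc with one-signed, smoothly varying curvature.

    ``heading`` is the start tangent angle (radians, from +x), ``turn`` the
    signed total tangent rotation, ``chord`` the chord length.  With
    ``skew = 0`` this is the standard circular-arc approximation (handle
    length (4/3)tan(turn/4) x radius at both ends); a non-zero ``skew``
    lengthens the start handle by ``(1 + skew)`` and shortens the end handle
    by ``(1 - skew)``, which keeps endpoints, tangent directions and total
    turn exact but grades the curvature from flat (long-handle end) to tight
    (short-handle end) — as fitted body lines do, where curvature
    concentrates near the lumbar inflection.  Returns the (4, 2) control
    array and the end heading.
    """
    if chord <= 0:
        raise ValueError("chord length must be positive")
    if not -0.6 <= skew <= 0.6:
        raise ValueError("handle skew outside the single-signed-curvature range")
    u0 = np.array([math.cos(heading), math.sin(heading)])
    if turn == 0.0:
        p3 = start + chord * u0
        ctrl = np.array([start, start + chord / 3 * u0, start + 2 * chord / 3 * u0, p3])
        return ctrl, heading
    h_end = heading + turn
    u1 = np.array([math.cos(h_end), math.sin(h_end)])
    cdir = heading + turn / 2.0
    p3 = start + chord * np.array([math.cos(cdir), math.sin(cdir)])
    radius = chord / (2.0 * math.sin(abs(turn) / 2.0))
    handle = (4.0 / 3.0) * math.tan(abs(turn) / 4.0) * radius
    ctrl = np.array(
        [
            start,
            start + handle * (1.0 + skew) * u0,
            p3 - handle * (1.0 - skew) * u1,
            p3,
        ]
    )
    return ctrl, h_end


def _two_arc_sline(
    upper_turn_deg: float,
    lower_turn_deg: float,
    height: float,
    junction_fraction: float,
    label: str,
    skew: float = _HANDLE_SKEW,
) -> SLine:
    """S-line from two opposite-turn circular arcs, rescaled to exact height.

    The first arc turns clockwise (negative curvature), the second counter-
    clockwise, so the junction is the single inflection.  After construction
    the whole line is uniformly scaled so its bounding-box height equals
    ``height`` (scaling preserves angles, continuity and the inflection).
    """
    if height <= 0:
        raise ValueError("height must be positive")
    phi1 = math.radians(upper_turn_deg)
    phi2 = math.radians(lower_turn_deg)
    down = -math.pi / 2.0  # start tangent: straight down
    # chord tilts from vertical fix the chord lengths from the height split
    tilt1 = phi1 / 2.0
    tilt2 = phi1 - phi2 / 2.0  # lower chord tilt (from straight down)
    drop1 = (1.0 - junction_fraction) * height
    drop2 = junction_fraction * height
    c1 = drop1 / math.cos(tilt1)
    c2 = drop2 / math.cos(tilt2)
    start = np.array([0.0, height])
    # curvature grades toward the junction on both sides: long start handle
    # above (flat thoracic end), short start handle below reversed at the
    # bottom (flattening past the buttock apex)
    ctrl1, h_mid = _arc_segment(start, down, -phi1, c1, skew=+skew)
    ctrl2, _ = _arc_segment(ctrl1[3], h_mid, phi2, c2, skew=-skew)
    seg_a, seg_b = BezierSegment(ctrl1), BezierSegment(ctrl2)
    line = SLine(segments=(seg_a, seg_b), label=label, g1=True)

    # normalize bounding-box height (arcs may bulge slightly past endpoints)
    ts = np.linspace(0.0, 1.0, 257)
    ys = np.concatenate([evaluate(seg_a, ts)[:, 1], evaluate(seg_b, ts)[:, 1]])
    xs = np.concatenate([evaluate(seg_a, ts)[:, 0], evaluate(seg_b, ts)[:, 0]])
    yspan = float(ys.max() - ys.min())
    scale = height / yspan
    shift = np.array([-xs.min() * scale, -ys.min() * scale])
    segs = tuple(
        BezierSegment(seg.control_points * scale + shift)
        for seg in (seg_a, seg_b)
    )
    return SLine(segments=segs, label=label, g1=True)


def make_sline(theta: float, height: float = 300.0, label: str | None = None) -> SLine:
    """Body-line stand-in with chord deflection angle ``theta`` (degrees).

    The upper arc turns a fixed small amount; the lower arc turns
    ``2 * theta`` more, which realises a deflection of exactly ``theta``
    between the two chords at the junction.  The result is deterministic,
    G1, has exactly one inflection, bounding-box height equal to ``height``
    and mean absolute curvature strictly increasing in theta.
    """
    lo, hi = THETA_RANGE
    if not lo <= theta <= hi:
        raise ValueError(f"theta {theta} outside the natural range {THETA_RANGE}")
    lbl = label if label is not None else f"S{theta:g}"
    return _two_arc_sline(
        _UPPER_TURN, 2.0 * theta + _UPPER_TURN, height, _JUNCTION_FRACTION, lbl
    )


def make_body_lines(
    thetas: tuple[float, ...] = DEFAULT_THETAS, height: float = 300.0
) -> list[SLine]:
    """The five body-line stand-ins, labelled BL1..BL5."""
    return [
        make_sline(t, height, label=f"BL{i + 1}") for i, t in enumerate(thetas)
    ]


def make_hogarth_family(k: int, height: float = 300.0) -> SLine:
    """Stand-in for historical S-line number ``k`` (1..7).

    S-lines of strictly increasing mean absolute curvature, member 1 nearly
    straight, built with the body-line construction on the family's own
    deflection grid.  The historical engraving is not reproduced.
    """
    if not 1 <= int(k) <= 7 or int(k) != k:
        raise ValueError("family index k must be an integer in 1..7")
    omega = _HOGARTH_DEFLECTIONS[int(k) - 1]
    return _two_arc_sline(
        _UPPER_TURN, 2.0 * omega + _UPPER_TURN, height, _JUNCTION_FRACTION,
        label=f"HL{int(k)}",
    )


def make_hogarth_lines(height: float = 300.0) -> list[SLine]:
    return [make_hogarth_family(k, height) for k in range(1, 8)]


def chord_angle(line: SLine) -> float:
    """Realized chord deflection angle at the junction, in degrees.

    The angle between the chord direction of the upper arc (start to
    junction) and that of the lower arc (junction to end).
    """
    u = line.junction - line.start
    v = line.end - line.junction
    cosang = float(
        np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    )
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# contour sampling
# ---------------------------------------------------------------------------


def sample_contour(
    line: SLine,
    n: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str | None = None,
    return_junction_index: bool = False,
):
    """Sample ``n`` points equally spaced in arc length, plus isotropic noise.

    Points are equidistant within each segment with one sample exactly at the
    junction (index returned on request), so a noise-free contour lies in the
    image of the fitting model.  Reproducible for a fixed seed.
    """
    if n < 10:
        raise ValueError("need at least 10 contour points")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    inv_a, len_a = _arclength_inverter(line.segments[0])
    inv_b, len_b = _arclength_inverter(line.segments[1])
    total = len_a + len_b
    n_a = int(np.clip(round((n - 1) * len_a / total), 5, n - 6))
    t_a = np.clip(inv_a(np.linspace(0.0, len_a, n_a + 1)), 0.0, 1.0)
    t_b = np.clip(inv_b(np.linspace(0.0, len_b, n - n_a)[1:]), 0.0, 1.0)
    pts = np.vstack(
        [evaluate(line.segments[0], t_a), evaluate(line.segments[1], t_b)]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 101)))
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    contour = ContourSample(points=pts, label=label or line.label)
    if return_junction_index:
        return contour, n_a
    return contour


# ---------------------------------------------------------------------------
# rating generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RatingGeneratorSpec:
    """Population parameters of the rating generator.

    ``rating = stimulus_mean + gender_offset * 1[woman] + participant
    intercept + participant x stimulus latent + context noise``, clipped to
    the instrument scale.  The latent term is shared between the two rating
    contexts of a stimulus, which is what makes the contexts strongly
    rank-correlated; the residual term is drawn anew per context.
    """

    stimulus_means: dict[int, float]
    gender_offset: float
    participant_sd: float
    latent_sd: float
    residual_sd: float
    n_women: int
    n_men: int
    scale: tuple[float, float]
    contexts: tuple[str, ...] = ("short_term", "long_term")
    direction_levels: tuple[str, ...] = ("none",)
    seed: int = 0

    def __post_init__(self) -> None:
        for sd in (self.participant_sd, self.latent_sd, self.residual_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        lo, hi = self.scale
        base = np.array(list(self.stimulus_means.values()))
        if np.any(base < lo) or np.any(base + max(self.gender_offset, 0.0) > hi):
            raise ValueError("population means must lie within the scale bounds")
        if self.n_women < 0 or self.n_men < 0 or self.n_women + self.n_men < 2:
            raise ValueError("need at least 2 participants")


def study1_spec(seed: int = 0, **overrides) -> RatingGeneratorSpec:
    """Default spec emulating the body-morph rating study.

    918 raters (467 men), 0-10 scale, short-/long-term contexts.  Stimulus
    means are ordered so morphs 3 and 4 are highest and near-equal and morph
    1 lowest; their grand mean (6.63) plus the gender offset (+1.29 for
    women) reproduces the reported gender means 6.63 vs 7.92.  Noise SDs are
    set so that fewer than 1% of draws hit the scale bounds and the two
    contexts correlate at rho > 0.68.
    """
    spec = RatingGeneratorSpec(
        stimulus_means={1: 5.45, 2: 6.55, 3: 7.35, 4: 7.30, 5: 6.50},
        gender_offset=1.29,
        participant_sd=0.50,
        latent_sd=0.40,
        residual_sd=0.30,
        n_women=451,
        n_men=467,
        scale=(0.0, 10.0),
        contexts=("short_term", "long_term"),
        direction_levels=("none",),
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def study2_spec(seed: int = 0, **overrides) -> RatingGeneratorSpec:
    """Default spec emulating the abstract-line rating study.

    98 raters (33 men), 1-100 visual-analogue scale, one rating per line,
    random left/right presentation with no direction effect and no gender
    effect.  Line means are ordered so lines 3 and 4 are highest and
    near-equal and lines 1 and 5 lowest and near-equal, which makes (1, 5)
    and (3, 4) the non-significant post-hoc pairs.
    """
    spec = RatingGeneratorSpec(
        stimulus_means={1: 43.0, 2: 52.0, 3: 60.0, 4: 59.8, 5: 43.5},
        gender_offset=0.0,
        participant_sd=12.0,
        latent_sd=0.0,
        residual_sd=10.0,
        n_women=65,
        n_men=33,
        scale=(1.0, 100.0),
        contexts=("single",),
        direction_levels=("left", "right"),
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


_STREAMS = {"intercept": 1, "latent": 2, "noise": 3, "direction": 4}


def _participant_rng(seed: int, stream: str, gender_code: int, index: int):
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(seed, _STREAMS[stream], gender_code, index))
    )


def generate_ratings(spec: RatingGeneratorSpec) -> pd.DataFrame:
    """Long-format rating table drawn from the generator model.

    Columns: participant, gender, stimulus, context, direction, rating.
    Deterministic for a fixed spec seed; per-participant random streams mean
    that increasing ``n_women``/``n_men`` does not perturb existing rows.
    """
    lo, hi = spec.scale
    stimuli = sorted(spec.stimulus_means)
    base = np.array([spec.stimulus_means[s] for s in stimuli])
    n_stim, n_ctx = len(stimuli), len(spec.contexts)
    rows = []
    clipped = 0
    total = 0
    roster = [("woman", i) for i in range(spec.n_women)] + [
        ("man", i) for i in range(spec.n_men)
    ]
    for gender, idx in roster:
        gcode = 0 if gender == "woman" else 1
        pid = f"{'w' if gcode == 0 else 'm'}{idx + 1:04d}"
        intercept = float(
            _participant_rng(spec.seed, "intercept", gcode, idx).normal(
                0.0, spec.participant_sd
            )
        )
        latent = _participant_rng(spec.seed, "latent", gcode, idx).normal(
            0.0, spec.latent_sd, size=n_stim
        )
        noise = _participant_rng(spec.seed, "noise", gcode, idx).normal(
            0.0, spec.residual_sd, size=(n_stim, n_ctx)
        )
        if len(spec.direction_levels) > 1:
            d_idx = int(
                _participant_rng(spec.seed, "direction", gcode, idx).integers(
                    len(spec.direction_levels)
                )
            )
            direction = spec.direction_levels[d_idx]
        else:
            direction = spec.direction_levels[0]
        offset = spec.gender_offset if gender == "woman" else 0.0
        raw = base[:, None] + offset + intercept + latent[:, None] + noise
        clip = np.clip(raw, lo, hi)
        clipped += int(np.sum(raw != clip))
        total += raw.size
        for si, stim in enumerate(stimuli):
            for ci, ctx in enumerate(spec.contexts):
                rows.append(
                    {
                        "participant": pid,
                        "gender": gender,
                        "stimulus": stim,
                        "context": ctx,
                        "direction": direction,
                        "rating": float(clip[si, ci]),
                    }
                )
    if total and clipped / total >= 0.01:
        warnings.warn(
            f"{clipped / total:.1%} of draws were clipped at the scale bounds; "
            "clipping distorts the additive effect structure",
            stacklevel=2,
        )
    return pd.DataFrame(rows)
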