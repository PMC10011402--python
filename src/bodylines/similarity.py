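"""Curvature histograms and the Histogram Difference (HD) line similarity.

Two lines are compared by binning their sampled signed curvatures on a shared
set of bin edges and summing the absolute bin-wise differences of the two
histograms.  On percent-scaled histograms HD lies in [0, 200]: 0 for
identical histograms, 200 for disjoint support (twice the total variation
distance, in percentage points).

HD is a pseudometric on histograms: it is non-negative, symmetric, satisfies
the triangle inequality, and vanishes for a line compared with itself — but
distinct lines can share a curvature histogram, so it is not a metric on
lines.

Binning is not canonical: bin count, pooled range, sampling density, and
whether mirrored (left/right-facing) lines are compared on signed or absolute
curvature all change the numbers.  Every report therefore carries its full
binning metadata so results are reproducible bit-for-bit from the report
alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import (
    DEFAULT_PROFILE_SAMPLES,
    CurvatureProfile,
    SLine,
    arc_length_profile,
)

__all__ = [
    "CurvatureHistogram",
    "SimilarityMatrix",
    "curvature_histogram",
    "histogram_difference",
    "shared_bin_edges",
    "similarity_matrix",
]

DEFAULT_BINS = 20


@dataclass(frozen=True)
class CurvatureHistogram:
    """Binned curvature frequencies of one line on explicit shared edges."""

    bin_edges: np.ndarray
    frequencies: np.ndarray
    scaled: str = "percent"  # "percent" or "count"
    line_label: str = ""
    absolute: bool = False

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        freq = np.asarray(self.frequencies, dtype=float)
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(freq) != len(edges) - 1:
            raise ValueError("need exactly one frequency per bin")
        if np.any(freq < 0):
            raise ValueError("frequencies must be non-negative")
        if self.scaled not in ("percent", "count"):
            raise ValueError("scaled must be 'percent' or 'count'")
        if self.scaled == "percent" and abs(freq.sum() - 100.0) > 1e-6:
            raise ValueError("percent-scaled frequencies must sum to 100")
        if self.scaled == "count" and np.any(freq != np.round(freq)):
            raise ValueError("count-scaled frequencies must be integers")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "frequencies", freq)


@dataclass(frozen=True)
class SimilarityMatrix:
    """HD scores for every reference x candidate pair, plus binning metadata."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match the label lists")
        if np.any(vals < 0):
            raise ValueError("HD scores are non-negative")
        object.__setattr__(self, "values", vals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_labels), columns=list(self.col_labels)
        )

    def best_matches(self) -> pd.DataFrame:
        """Per reference (row): the argmin candidate, with a tie flag.

        Ties are broken toward the lower candidate index so output is
        deterministic.
        """
        rows = []
        for i, ref in enumerate(self.row_labels):
            v = self.values[i]
            j = int(np.argmin(v))
            tie = bool(np.sum(v == v[j]) > 1)
            rows.append(
                {"reference": ref, "best_candidate": self.col_labels[j],
                 "hd": float(v[j]), "tie": tie}
            )
        return pd.DataFrame(rows)

    def save(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path)
        if json_path is not None:
            payload = {
                "row_labels": list(self.row_labels),
                "col_labels": list(self.col_labels),
                "values": self.values.tolist(),
                "metadata": {
                    k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in self.metadata.items()
                },
                "best_matches": self.best_matches().to_dict(orient="records"),
            }
            Path(json_path).write_text(json.dumps(payload, indent=2))


def curvature_histogram(
    profile: CurvatureProfile,
    bin_edges: np.ndarray,
    scaled: str = "percent",
    absolute: bool = False,
) -> CurvatureHistogram:
    """Bin a curvature profile on shared edges.

    Bins are right-open ``[e_i, e_{i+1})`` with the last bin closed; values
    outside the edge range are clipped into the end bins, so comparisons stay
    well-defined even when one profile slightly exceeds the pooled range.
    With ``absolute=True`` the magnitudes ``|kappa|`` are binned, which makes
    the histogram invariant to mirroring.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    k = np.abs(profile.kappa) if absolute else profile.kappa
    # clip into the covered range; nudge below the top edge keeps the last
    # bin closed under np.histogram's half-open convention
    k = np.clip(k, edges[0], edges[-1])
    counts, _ = np.histogram(k, bins=edges)
    n = len(k)
    if scaled == "percent":
        freq = counts * 100.0 / n
    elif scaled == "count":
        freq = counts.astype(float)
    else:
        raise ValueError("scaled must be 'percent' or 'count'")
    return CurvatureHistogram(
        bin_edges=edges,
        frequencies=freq,
        scaled=scaled,
        line_label=profile.line_label,
        absolute=absolute,
    )


def histogram_difference(ha: CurvatureHistogram, hb: CurvatureHistogram) -> float:
    """Sum of absolute bin-wise differences between two histograms."""
    if ha.scaled != hb.scaled:
        raise ValueError(
            f"scale mismatch between {ha.line_label!r} ({ha.scaled}) and "
            f"{hb.line_label!r} ({hb.scaled})"
        )
    if len(ha.bin_edges) != len(hb.bin_edges) or not np.allclose(
        ha.bin_edges, hb.bin_edges, rtol=0, atol=0
    ):
        raise ValueError(
            f"bin edges mismatch between {ha.line_label!r} and {hb.line_label!r}; "
            "histograms must share identical edges"
        )
    return float(np.sum(np.abs(ha.frequencies - hb.frequencies)))


def shared_bin_edges(
    profiles: Sequence[CurvatureProfile], bins: int = DEFAULT_BINS,
    absolute: bool = False,
) -> np.ndarray:
    """Equal-width edges spanning the pooled curvature range of all profiles."""
    pooled = np.concatenate([p.kappa for p in profiles])
    if absolute:
        pooled = np.abs(pooled)
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:  # all-constant curvature: widen to a tiny symmetric band
        pad = max(1e-12, abs(lo) * 1e-9)
        lo, hi = lo - pad, hi + pad
    return np.linspace(lo, hi, bins + 1)


def similarity_matrix(
    candidates: Sequence[SLine],
    references: Sequence[SLine],
    n_samples: int = DEFAULT_PROFILE_SAMPLES,
    bins: int = DEFAULT_BINS,
    scaled: str = "percent",
    absolute: bool = False,
) -> SimilarityMatrix:
    """All-pairs Histogram Difference between references (rows) and candidates.

    All lines are profiled with the same sampling density and binned on
    shared equal-width edges spanning the pooled curvature range, so every
    entry is comparable.  The binning metadata travels with the matrix.
    """
    if len(candidates) == 0 or len(references) == 0:
        raise ValueError("candidate and reference line lists must be non-empty")
    cand_profiles = [arc_length_profile(ln, n_samples) for ln in candidates]
    ref_profiles = [arc_length_profile(ln, n_samples) for ln in references]
    # bin edges come from high-resolution range profiles so that the binning
    # does not move with the sampling density (otherwise every entry is
    # perturbed through edge shifts whenever n_samples changes)
    n_range = max(4096, n_samples)
    range_profiles = [
        arc_length_profile(ln, n_range) for ln in (*candidates, *references)
    ]
    edges = shared_bin_edges(range_profiles, bins, absolute)
    cand_hists = [
        curvature_histogram(p, edges, scaled, absolute) for p in cand_profiles
    ]
    ref_hists = [curvature_histogram(p, edges, scaled, absolute) for p in ref_profiles]
    values = np.array(
        [[histogram_difference(r, c) for c in cand_hists] for r in ref_hists]
    )
    return SimilarityMatrix(
        row_labels=tuple(ln.label for ln in references),
        col_labels=tuple(ln.label for ln in candidates),
        values=values,
        metadata={
            "bin_edges": edges,
            "bins": bins,
            "scaled": scaled,
            "absolute": absolute,
            "n_samples": n_samples,
        },
    )
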