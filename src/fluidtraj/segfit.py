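"""Per-segment polynomial fits with continuity enforced across segments.

The trajectory is partitioned into trend segments (maximal runs of one
trend label). Each segment gets its own low-degree polynomial in
calendar day — the first by ordinary least squares, every later one by
least squares *anchored* so that its value at the segment's first
observed day equals the previous segment's fitted value at its last
observed day. The composite curve is therefore continuous while its
derivative may jump at segment boundaries, which is exactly the
signature of a reactivation or a response to treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError
from .synthetic import Trajectory

#: Hard cap on the per-segment polynomial degree. Quadratics capture the
#: smooth monotone arcs seen in real TRO segments without overfitting;
#: keeping the degree low is the main guard that keeps the residual an
#: honest noise estimate.
DEGREE_CAP = 2


@dataclass(frozen=True)
class Segment:
    """Inclusive point-index range [start_idx, end_idx] sharing one trend label."""

    start_idx: int
    end_idx: int
    label: str

    def __post_init__(self) -> None:
        if self.start_idx < 0 or self.end_idx < self.start_idx:
            raise InvalidArgumentError("segment indices must satisfy 0 <= start <= end")

    @property
    def n_points(self) -> int:
        return self.end_idx - self.start_idx + 1


@dataclass(frozen=True)
class SegmentedFit:
    """Continuity-constrained piecewise-polynomial fit of one trajectory.

    ``coefficients[i]`` are ascending powers of ``(day - origins[i])``,
    where ``origins[i]`` is segment *i*'s first observed day.
    ``continuity_gaps[i]`` is the absolute mismatch at boundary *i*
    between segment *i*'s fitted start and segment *i-1*'s fitted end —
    zero up to floating point by construction.
    """

    segments: tuple[Segment, ...]
    coefficients: tuple[np.ndarray, ...]
    origins: tuple[float, ...]
    fitted: np.ndarray
    continuity_gaps: np.ndarray

    def predict(self, segment_index: int, days) -> np.ndarray:
        """Evaluate segment ``segment_index``'s polynomial at arbitrary days."""
        t = np.asarray(days, dtype=float) - self.origins[segment_index]
        return np.polynomial.polynomial.polyval(t, self.coefficients[segment_index])


def segments_from_labels(labels: list[str]) -> list[Segment]:
    """Run-length encode point labels into contiguous segments."""
    if not labels:
        raise InvalidArgumentError("labels must be non-empty")
    segments: list[Segment] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segments.append(Segment(start_idx=start, end_idx=i - 1, label=labels[start]))
            start = i
    return segments


def choose_degree(segment_length: int, max_degree: int = DEGREE_CAP, cap: int = DEGREE_CAP) -> int:
    """Polynomial degree for a segment: ``min(max_degree, n - 1, cap)``, floored at 0."""
    if segment_length < 1:
        raise InvalidArgumentError("segment_length must be >= 1")
    return max(0, min(max_degree, segment_length - 1, cap))


def _fit_free(t: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    """Unconstrained least-squares polynomial, ascending coefficients."""
    return np.polynomial.polynomial.polyfit(t, y, degree)


def _fit_anchored(t: np.ndarray, y: np.ndarray, degree: int, anchor: float) -> np.ndarray:
    """Least squares subject to p(0) = anchor; t[0] must be 0.

    Fixing the constant term at the anchor turns the constraint into an
    ordinary regression of (y - anchor) on the intercept-free basis
    t, t^2, ..., t^degree.
    """
    if degree == 0:
        return np.array([anchor])
    basis = np.vstack([t**j for j in range(1, degree + 1)]).T
    coef, *_ = np.linalg.lstsq(basis, y - anchor, rcond=None)
    return np.concatenate([[anchor], coef])


def fit_segments(
    trajectory: Trajectory,
    segments: list[Segment],
    max_degree: int = DEGREE_CAP,
) -> SegmentedFit:
    """Fit each segment's polynomial, anchoring all but the first.

    The first segment is fitted by ordinary least squares of degree
    ``choose_degree``; every later segment is constrained to pass, at
    its first observed day, through the previous segment's fitted value
    at its last observed day. Fitted values are evaluated at the
    observed days only.
    """
    if max_degree < 1:
        raise InvalidArgumentError("max_degree must be >= 1")
    if not segments:
        raise InvalidArgumentError("segments must be non-empty")
    if segments[0].start_idx != 0 or segments[-1].end_idx != len(trajectory) - 1:
        raise InvalidArgumentError("segments must cover the whole trajectory")
    for prev, cur in zip(segments, segments[1:]):
        if cur.start_idx != prev.end_idx + 1:
            raise InvalidArgumentError("segments must be contiguous and ordered")

    days = trajectory.days.astype(float)
    y = trajectory.tro
    fitted = np.empty(len(trajectory))
    coeffs: list[np.ndarray] = []
    origins: list[float] = []
    gaps: list[float] = []
    anchor: float | None = None

    for seg in segments:
        sl = slice(seg.start_idx, seg.end_idx + 1)
        d, yy = days[sl], y[sl]
        t = d - d[0]
        degree = choose_degree(seg.n_points, max_degree)
        if anchor is None:
            coef = _fit_free(t, yy, degree)
        else:
            coef = _fit_anchored(t, yy, degree, anchor)
        vals = np.polynomial.polynomial.polyval(t, coef)
        fitted[sl] = vals
        coeffs.append(np.atleast_1d(coef))
        origins.append(float(d[0]))
        if anchor is not None:
            gaps.append(abs(float(vals[0]) - anchor))
        anchor = float(vals[-1])

    return SegmentedFit(
        segments=tuple(segments),
        coefficients=tuple(coeffs),
        origins=tuple(origins),
        fitted=fitted,
        continuity_gaps=np.asarray(gaps),
    )
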