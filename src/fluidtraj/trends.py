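"""Trend labeling of TRO trajectories via CUSUM-GLR mean-shift detection.

Every point of a trajectory is labeled *incline*, *plateau* or
*decline*. Changepoints in the mean level are found offline with the
generalized-likelihood-ratio statistic for an unknown mean shift in
Gaussian noise, applied recursively (binary segmentation). Stretches
between changepoints are then labeled by the sign of their
least-squares slope against calendar day, and boundary points whose
values agree better with the neighbouring stretch are iteratively
reassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError
from .synthetic import Trajectory

logger = logging.getLogger(__name__)

INCLINE = "incline"
PLATEAU = "plateau"
DECLINE = "decline"

#: Variance floor (VU^2) so that noiseless step fixtures still register
#: an infinite-likelihood shift instead of dividing by zero.
VARIANCE_FLOOR = 1e-6

#: Detection cutoff for the GLR statistic. Calibrated by simulation
#: (scripts/calibrate_glr_threshold.py) so that ~5% of pure-noise
#: 28-point series produce a false changepoint.
DEFAULT_GLR_THRESHOLD = 10.62


@dataclass(frozen=True)
class LabelingConfig:
    """Tuning knobs of the trend labeler.

    glr_threshold
        Cutoff *h* on the GLR statistic; a split is accepted only when
        its statistic reaches *h*.
    min_segment_len
        Minimum points on each side of a changepoint; a trend period of
        fewer points cannot support a label.
    slope_tolerance
        Absolute least-squares slope (VU/day) below which a stretch is a
        plateau rather than an incline/decline.
    max_iterations
        Cap on the questionable-point resolution loop.
    """

    glr_threshold: float = DEFAULT_GLR_THRESHOLD
    min_segment_len: int = 3
    slope_tolerance: float = 0.2
    max_iterations: int = 20

    def __post_init__(self) -> None:
        if self.glr_threshold <= 0:
            raise InvalidArgumentError("glr_threshold must be positive")
        if self.min_segment_len < 2:
            raise InvalidArgumentError("min_segment_len must be >= 2")
        if self.slope_tolerance < 0:
            raise InvalidArgumentError("slope_tolerance must be >= 0")
        if self.max_iterations < 1:
            raise InvalidArgumentError("max_iterations must be >= 1")


def noise_variance(y: np.ndarray) -> float:
    """Robust noise variance from successive differences.

    ``sigma = MAD(diff(y)) * 1.4826 / sqrt(2)`` — the median absolute
    deviation of first differences is insensitive to level shifts and
    transient bumps, so the GLR statistic keeps its power when the
    segment under test contains unmodeled structure (a pooled residual
    variance would absorb the very shift being tested and mask it).
    """
    y = np.asarray(y, dtype=float)
    d = np.diff(y)
    if d.size == 0:
        return 0.0
    mad = float(np.median(np.abs(d - np.median(d))))
    sigma = mad * 1.4826 / np.sqrt(2.0)
    return sigma * sigma


def glr_statistic(y: np.ndarray, k: int) -> float:
    """GLR statistic for a mean shift at split ``k``.

    Splits ``y`` into ``y[:k]`` and ``y[k:]`` and returns
    ``(n_L n_R / n) (mean_L - mean_R)^2 / sigma^2`` with the robust
    difference-based variance of :func:`noise_variance`, floored at
    :data:`VARIANCE_FLOOR`.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    left, right = y[:k], y[k:]
    n_l, n_r = left.size, right.size
    if n_l == 0 or n_r == 0:
        raise InvalidArgumentError("split must leave points on both sides")
    sigma2 = max(noise_variance(y), VARIANCE_FLOOR)
    return float((n_l * n_r / n) * (left.mean() - right.mean()) ** 2 / sigma2)


def _best_split(y: np.ndarray, lo: int, hi: int, min_len: int) -> tuple[int, float]:
    """Best split k (lo+min_len <= k <= hi-min_len) of y[lo:hi] and its statistic."""
    best_k, best_g = -1, -np.inf
    seg = y[lo:hi]
    for k in range(min_len, (hi - lo) - min_len + 1):
        g = glr_statistic(seg, k)
        if g > best_g:
            best_k, best_g = lo + k, g
    return best_k, best_g


def detect_changepoints(trajectory: Trajectory, config: LabelingConfig | None = None) -> list[int]:
    """Find mean-shift changepoints by recursive binary segmentation.

    Returns sorted interior point indices ``k`` (the stretch boundary
    lies between points ``k-1`` and ``k``); each accepted split attains
    a GLR statistic of at least ``config.glr_threshold`` within its
    sub-segment and leaves ``min_segment_len`` points on both sides.
    Series shorter than ``2 * min_segment_len`` return no changepoints.
    """
    config = config or LabelingConfig()
    y = trajectory.tro
    cps: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        if hi - lo < 2 * config.min_segment_len:
            return
        k, g = _best_split(y, lo, hi, config.min_segment_len)
        if k < 0 or g < config.glr_threshold:
            return
        cps.append(k)
        recurse(lo, k)
        recurse(k, hi)

    recurse(0, len(y))
    return sorted(cps)


def _stretch_bounds(n: int, changepoints: list[int]) -> list[tuple[int, int]]:
    """Half-open [start, stop) bounds of the stretches cut at changepoints."""
    edges = [0, *changepoints, n]
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def _ols_line(days: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares (intercept, slope) of y on day; slope 0 for degenerate stretches."""
    if y.size < 2 or np.ptp(days) == 0:
        return float(y.mean()), 0.0
    slope, intercept = np.polyfit(days.astype(float), y, 1)
    return float(intercept), float(slope)


def label_points(
    trajectory: Trajectory,
    changepoints: list[int],
    config: LabelingConfig | None = None,
) -> list[str]:
    """Label every point incline/plateau/decline by its stretch's slope.

    Within each inter-changepoint stretch the least-squares slope
    against actual day spacing decides the common label: incline above
    ``slope_tolerance`` VU/day, decline below its negative, plateau
    otherwise.
    """
    config = config or LabelingConfig()
    labels = [PLATEAU] * len(trajectory)
    for start, stop in _stretch_bounds(len(trajectory), list(changepoints)):
        _, slope = _ols_line(trajectory.days[start:stop], trajectory.tro[start:stop])
        if slope > config.slope_tolerance:
            lab = INCLINE
        elif slope < -config.slope_tolerance:
            lab = DECLINE
        else:
            lab = PLATEAU
        for i in range(start, stop):
            labels[i] = lab
    return labels


def resolve_questionable_points(
    trajectory: Trajectory,
    labels: list[str],
    changepoints: list[int],
    config: LabelingConfig | None = None,
) -> tuple[list[str], list[int]]:
    """Iteratively reassign boundary points to the better-fitting stretch.

    A point adjacent to a changepoint (within ``min_segment_len`` of it)
    moves to the neighbouring stretch when the neighbour's least-squares
    line predicts it strictly better than its own stretch's line; ties
    leave the point in place (strict improvement beyond a 1e-9 VU
    margin, so ties are decided stably under floating point). Iterates
    to a fixed point (or ``max_iterations``, logged); stretches are then
    relabeled from their slopes. Deterministic.
    """
    tie_eps = 1e-9
    config = config or LabelingConfig()
    if not changepoints:
        return list(labels), list(changepoints)

    days, y = trajectory.days.astype(float), trajectory.tro
    cps = list(changepoints)
    n = len(trajectory)

    for _ in range(config.max_iterations):
        moved = False
        bounds = _stretch_bounds(n, cps)
        lines = [_ols_line(trajectory.days[s:e], y[s:e]) for s, e in bounds]

        new_cps: list[int] = []
        for b_idx, cp in enumerate(cps):
            left = bounds[b_idx]
            right = bounds[b_idx + 1]
            li, ls = lines[b_idx]
            ri, rs = lines[b_idx + 1]
            cp_new = cp
            # last point of the left stretch: does the right line explain it better?
            p = cp - 1
            if left[1] - left[0] > 1 and cp - p <= config.min_segment_len:
                r_own = abs(y[p] - (li + ls * days[p]))
                r_other = abs(y[p] - (ri + rs * days[p]))
                if r_other < r_own - tie_eps:
                    cp_new = cp - 1
                    moved = True
            if cp_new == cp:
                # first point of the right stretch: does the left line win?
                p = cp
                if right[1] - right[0] > 1 and p - cp + 1 <= config.min_segment_len:
                    r_own = abs(y[p] - (ri + rs * days[p]))
                    r_other = abs(y[p] - (li + ls * days[p]))
                    if r_other < r_own - tie_eps:
                        cp_new = cp + 1
                        moved = True
            new_cps.append(cp_new)

        # drop collisions (a stretch consumed entirely by its neighbours)
        cps = sorted({cp for cp in new_cps if 0 < cp < n})
        if not moved:
            break
    else:
        logger.warning(
            "questionable-point resolution did not converge within %d iterations",
            config.max_iterations,
        )

    return label_points(trajectory, cps, config), cps
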