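"""Synthetic TRO-trajectory cohorts for testing the change-detection pipeline.

The generator emulates five weeks of near-daily home-OCT self-imaging:
each eye contributes an irregular series of total hypo-reflective volume
(TRO) measurements in volume units (VU; 1 VU = 1 nL of retinal fluid).
Ground truth is two classes — *stable* (flat mean) and *changing*
(a consistent rise, fall, or rise-then-fall in TRO). Mean curves are
piecewise linear; measurement noise is additive Gaussian truncated at
zero (TRO cannot be negative); days are dropped independently to mimic
missed tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError

ShapeKind = Literal["stable", "rise", "fall", "rise_fall"]

STABLE = "stable"
CHANGING = "changing"


@dataclass(frozen=True)
class TrajectoryShape:
    """Mean-curve description for one simulated eye.

    Parameters
    ----------
    kind
        ``"stable"`` (flat), ``"rise"`` / ``"fall"`` (single linear ramp
        of total height *amplitude* over *ramp_days*), or ``"rise_fall"``
        (reactivation followed by treatment response: up-ramp then
        down-ramp of the same height).
    amplitude
        Total height of the change in VU; must be 0 exactly when
        ``kind == "stable"`` and positive otherwise.
    onset_day
        First day whose mean lies strictly off baseline.
    ramp_days
        Duration of each linear ramp, in days.
    baseline
        Pre-change mean TRO in VU.
    """

    kind: ShapeKind
    amplitude: float = 0.0
    onset_day: int = 0
    ramp_days: int = 1
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("stable", "rise", "fall", "rise_fall"):
            raise InvalidArgumentError(f"unknown shape kind {self.kind!r}")
        if self.baseline < 0:
            raise InvalidArgumentError("baseline must be >= 0")
        if self.kind == "stable":
            if self.amplitude != 0:
                raise InvalidArgumentError("stable shapes must have amplitude 0")
        else:
            if self.amplitude <= 0:
                raise InvalidArgumentError("changing shapes need amplitude > 0")
            if self.ramp_days < 1:
                raise InvalidArgumentError("ramp_days must be a positive integer")
            if self.kind == "fall" and self.baseline < self.amplitude:
                raise InvalidArgumentError(
                    "fall shapes need baseline >= amplitude to keep TRO non-negative"
                )

    def mean_curve(self, days: np.ndarray) -> np.ndarray:
        """Noise-free mean TRO at integer day indices ``days``.

        The ramp leaves baseline after day ``onset_day - 1`` and reaches
        full amplitude at day ``onset_day + ramp_days - 1``.
        """
        d = np.asarray(days, dtype=float)
        if self.kind == "stable":
            return np.full_like(d, self.baseline)
        frac = np.clip((d - (self.onset_day - 1)) / self.ramp_days, 0.0, 1.0)
        if self.kind == "rise":
            return self.baseline + self.amplitude * frac
        if self.kind == "fall":
            return self.baseline - self.amplitude * frac
        # rise_fall: symmetric down-ramp follows immediately after the peak
        peak_day = self.onset_day + self.ramp_days - 1
        down = np.clip((d - peak_day) / self.ramp_days, 0.0, 1.0)
        return self.baseline + self.amplitude * (frac - down)


@dataclass(frozen=True)
class Trajectory:
    """One eye's TRO series: strictly increasing day indices and values in VU."""

    eye_id: str
    days: np.ndarray
    tro: np.ndarray
    label: Optional[str] = None

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        tro = np.asarray(self.tro, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "tro", tro)
        if days.size == 0:
            raise InvalidArgumentError("trajectory must contain at least one point")
        if days.size != tro.size:
            raise InvalidArgumentError("days and tro must have equal length")
        if np.any(np.diff(days) <= 0):
            raise InvalidArgumentError("days must be strictly increasing")
        if not np.all(np.isfinite(tro)) or np.any(tro < 0):
            raise InvalidArgumentError("tro values must be finite and non-negative")
        if self.label is not None and self.label not in (STABLE, CHANGING):
            raise InvalidArgumentError(f"label must be stable/changing, got {self.label!r}")

    def __len__(self) -> int:
        return int(self.days.size)

    @property
    def n_tests(self) -> int:
        return len(self)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated cohort.

    Defaults emulate the study conditions: 5-week monitoring
    (``days_total=35``) with roughly 28 tests per eye
    (``test_rate=0.8``), ~36% of trajectories changing, change
    amplitudes 5–40 VU and per-eye noise SD 1–4 VU.
    """

    n_trajectories: int = 300
    prop_changing: float = 0.361
    days_total: int = 35
    test_rate: float = 0.8
    noise_sd_range: tuple[float, float] = (1.0, 4.0)
    amplitude_range: tuple[float, float] = (5.0, 40.0)
    baseline_range: tuple[float, float] = (0.0, 20.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trajectories < 0:
            raise InvalidArgumentError("n_trajectories must be non-negative")
        if not 0.0 <= self.prop_changing <= 1.0:
            raise InvalidArgumentError("prop_changing must lie in [0, 1]")
        if self.days_total < 1:
            raise InvalidArgumentError("days_total must be a positive integer")
        if not 0.0 < self.test_rate <= 1.0:
            raise InvalidArgumentError("test_rate must lie in (0, 1]")
        if self.noise_sd_range[0] <= 0 or self.noise_sd_range[0] > self.noise_sd_range[1]:
            raise InvalidArgumentError("noise_sd_range must be a positive interval")
        if self.amplitude_range[0] <= 0 or self.amplitude_range[0] > self.amplitude_range[1]:
            raise InvalidArgumentError("amplitude_range must be a positive interval")


def simulate_trajectory(
    shape: TrajectoryShape,
    noise_sd: float,
    days_total: int,
    test_rate: float = 1.0,
    seed: int = 0,
    eye_id: str = "eye",
) -> Trajectory:
    """Simulate one eye's TRO series.

    The mean curve follows ``shape``; observed TRO is
    ``max(0, mean + N(0, noise_sd))``; each day is retained independently
    with probability ``test_rate`` (the first day is always retained so
    the series is never empty). The label is ``"stable"`` iff the shape
    is stable.
    """
    if days_total < 1:
        raise InvalidArgumentError("days_total must be >= 1")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    if not 0.0 < test_rate <= 1.0:
        raise InvalidArgumentError("test_rate must lie in (0, 1]")
    if shape.kind != "stable" and shape.onset_day + shape.ramp_days > days_total:
        raise InvalidArgumentError("onset_day + ramp_days must not exceed days_total")

    rng = np.random.default_rng(seed)
    days = np.arange(days_total)
    mean = shape.mean_curve(days)
    noise = rng.normal(0.0, noise_sd, size=days_total) if noise_sd > 0 else np.zeros(days_total)
    tro = np.maximum(0.0, mean + noise)
    keep = rng.random(days_total) < test_rate
    keep[0] = True
    label = STABLE if shape.kind == "stable" else CHANGING
    return Trajectory(eye_id=eye_id, days=days[keep], tro=tro[keep], label=label)


def _sample_changing_shape(rng: np.random.Generator, config: CohortConfig) -> TrajectoryShape:
    kind = rng.choice(["rise", "fall", "rise_fall"])
    amplitude = rng.uniform(*config.amplitude_range)
    baseline = rng.uniform(*config.baseline_range)
    n_ramps = 2 if kind == "rise_fall" else 1
    max_ramp = max(2, config.days_total // (2 * n_ramps))
    ramp_days = int(rng.integers(max(2, max_ramp // 2), max_ramp + 1))
    onset_day = int(rng.integers(1, config.days_total - n_ramps * ramp_days + 1))
    if kind == "fall":
        baseline = amplitude + rng.uniform(0.0, config.baseline_range[1])
    return TrajectoryShape(
        kind=kind, amplitude=amplitude, onset_day=onset_day,
        ramp_days=ramp_days, baseline=baseline,
    )


def simulate_cohort(config: CohortConfig) -> list[Trajectory]:
    """Simulate a labeled cohort.

    Exactly ``round(n_trajectories * prop_changing)`` trajectories get a
    non-stable shape; per-trajectory noise SD is drawn uniformly from
    ``noise_sd_range``. The same config (and seed) always reproduces the
    identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    n_changing = int(round(config.n_trajectories * config.prop_changing))
    cohort: list[Trajectory] = []
    for i in range(config.n_trajectories):
        if i < n_changing:
            shape = _sample_changing_shape(rng, config)
        else:
            shape = TrajectoryShape(kind="stable", baseline=rng.uniform(*config.baseline_range))
        noise_sd = rng.uniform(*config.noise_sd_range)
        child_seed = int(rng.integers(0, 2**31 - 1))
        cohort.append(
            simulate_trajectory(
                shape, noise_sd, config.days_total, config.test_rate,
                seed=child_seed, eye_id=f"eye{i:04d}",
            )
        )
    return cohort


def generative_snr_table(config: CohortConfig) -> pd.DataFrame:
    """Per-trajectory generative amplitude, noise SD and their ratio.

    Replays the cohort's parameter draws (same stream as
    :func:`simulate_cohort`) without simulating observations; used to
    compare estimated SNR scores against the generative a/sigma.
    """
    rng = np.random.default_rng(config.seed)
    n_changing = int(round(config.n_trajectories * config.prop_changing))
    rows = []
    for i in range(config.n_trajectories):
        if i < n_changing:
            shape = _sample_changing_shape(rng, config)
        else:
            shape = TrajectoryShape(kind="stable", baseline=rng.uniform(*config.baseline_range))
        noise_sd = rng.uniform(*config.noise_sd_range)
        rng.integers(0, 2**31 - 1)  # consume the child seed draw
        rows.append(
            {
                "eye_id": f"eye{i:04d}",
                "kind": shape.kind,
                "amplitude_vu": shape.amplitude,
                "noise_sd_vu": noise_sd,
                "snr_true": shape.amplitude / noise_sd,
            }
        )
    return pd.DataFrame(rows)


def cohort_to_frame(cohort: Sequence[Trajectory]) -> pd.DataFrame:
    """Long-format table: one row per test (eye_id, day, tro_vu, label)."""
    frames = []
    for t in cohort:
        frames.append(
            pd.DataFrame(
                {
                    "eye_id": t.eye_id,
                    "day": t.days,
                    "tro_vu": t.tro,
                    "label": t.label if t.label is not None else "",
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["eye_id", "day", "tro_vu", "label"])
    return pd.concat(frames, ignore_index=True)


def write_cohort_csv(cohort: Sequence[Trajectory], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)
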