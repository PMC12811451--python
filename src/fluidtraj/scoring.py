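"""Trajectory-level change scores: signal, noise, SNR, RCV, amplitude.

The personalized score treats the segmented fit as the clean trajectory
and the residual scatter as the eye's total measurement variation SD_T
(device noise, fixation, diurnal biology, segmentation error alike).
Signal is the fitted curve's full excursion A = max - min; the SNR
score A / SD_T is the eye's own change statistic, and the reference
change value RCV = sqrt(2) * Z * SD_T is the smallest change unlikely
to be noise for that eye. The population comparator scores the raw
excursion (trajectory max - min) against one fixed cutoff for everyone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .exceptions import InvalidArgumentError
from .segfit import SegmentedFit
from .synthetic import CHANGING, STABLE, Trajectory

PERSONALIZED = "personalized"
POPULATION = "population"


@dataclass(frozen=True)
class ScoreParameters:
    """Cutoffs and constants of the two classification rules.

    z
        Number of SDs in the reference change value; 1.96 is the
        laboratory-medicine standard (two-sided P < 0.05), giving the
        familiar 2.8 x SD_T interval.
    snr_cutoff
        Personalized rule: call a trajectory changing when its SNR
        score strictly exceeds this (default 2.8, the RCV multiple).
    vu_cutoff
        Population rule: call changing when the raw excursion strictly
        exceeds this many VU (default 10, the common fixed threshold).
    noise_floor
        Lower bound on SD_T in VU so noiseless fixtures keep a finite
        (huge) SNR.
    snr_denominator
        "rmse" divides the signal by root-mean-square residual (an SD,
        dimensionally consistent with the RCV); "mse" divides by the
        raw mean squared error, kept for sensitivity analysis.
    """

    z: float = 1.96
    snr_cutoff: float = 2.8
    vu_cutoff: float = 10.0
    noise_floor: float = 1e-6
    snr_denominator: Literal["rmse", "mse"] = "rmse"

    def __post_init__(self) -> None:
        if min(self.z, self.snr_cutoff, self.vu_cutoff, self.noise_floor) <= 0:
            raise InvalidArgumentError("all score parameters must be strictly positive")
        if self.snr_denominator not in ("rmse", "mse"):
            raise InvalidArgumentError("snr_denominator must be 'rmse' or 'mse'")


@dataclass(frozen=True)
class ScoreResult:
    """All change scores for one trajectory.

    signal_a and pop_amplitude are both excursions in VU, but signal_a
    is taken over the *fitted* curve (so smoothing can leave it below
    the raw pop_amplitude); noise_sdt is the SD_T estimate; rcv is
    sqrt(2) * z * noise_sdt.
    """

    signal_a: float
    noise_sdt: float
    snr: float
    pop_amplitude: float
    rcv: float
    argmax_day: int
    argmin_day: int


def compute_signal(fit: SegmentedFit, trajectory: Trajectory) -> tuple[float, int, int]:
    """Fitted-curve excursion: (max - min, day of max, day of min).

    Extrema are searched over the fitted values at observed days only;
    ties resolve to the earliest day.
    """
    fitted = fit.fitted
    if fitted.size == 0:
        raise InvalidArgumentError("fit is empty")
    i_max = int(np.argmax(fitted))
    i_min = int(np.argmin(fitted))
    signal = float(fitted[i_max] - fitted[i_min])
    return signal, int(trajectory.days[i_max]), int(trajectory.days[i_min])


def compute_noise(
    trajectory: Trajectory,
    fit: SegmentedFit,
    params: ScoreParameters | None = None,
) -> float:
    """SD_T estimate: root-mean-square residual, floored at noise_floor."""
    params = params or ScoreParameters()
    if len(trajectory) != fit.fitted.size:
        raise InvalidArgumentError("trajectory and fit lengths differ")
    mse = float(np.mean((trajectory.tro - fit.fitted) ** 2))
    return max(np.sqrt(mse), params.noise_floor)


def compute_snr(
    signal_a: float,
    noise_sdt: float,
    params: ScoreParameters | None = None,
) -> float:
    """SNR score: signal divided by SD_T (or by MSE under the variant)."""
    params = params or ScoreParameters()
    if signal_a < 0 or noise_sdt < 0:
        raise InvalidArgumentError("signal and noise must be non-negative")
    denom = noise_sdt if params.snr_denominator == "rmse" else noise_sdt**2
    denom = max(denom, params.noise_floor)
    return float(signal_a / denom)


def rcv_threshold(noise_sdt: float, z: float = 1.96) -> float:
    """Reference change value: sqrt(2) * z * SD_T, in VU."""
    return float(np.sqrt(2.0) * z * noise_sdt)


def pop_amplitude(trajectory: Trajectory) -> float:
    """Raw excursion of the series: trajectory max - trajectory min, in VU."""
    return float(np.max(trajectory.tro) - np.min(trajectory.tro))


def score_trajectory(
    trajectory: Trajectory,
    fit: SegmentedFit,
    params: ScoreParameters | None = None,
) -> ScoreResult:
    """Assemble the full :class:`ScoreResult` for one trajectory."""
    params = params or ScoreParameters()
    signal, d_max, d_min = compute_signal(fit, trajectory)
    noise = compute_noise(trajectory, fit, params)
    return ScoreResult(
        signal_a=signal,
        noise_sdt=noise,
        snr=compute_snr(signal, noise, params),
        pop_amplitude=pop_amplitude(trajectory),
        rcv=rcv_threshold(noise, params.z),
        argmax_day=d_max,
        argmin_day=d_min,
    )


def classify_trajectory(
    score: ScoreResult,
    params: ScoreParameters | None = None,
    method: str = PERSONALIZED,
) -> str:
    """Call a trajectory stable/changing under one of the two rules.

    Strict inequality at the cutoff: a score exactly at the threshold
    is called stable.
    """
    params = params or ScoreParameters()
    if method == PERSONALIZED:
        return CHANGING if score.snr > params.snr_cutoff else STABLE
    if method == POPULATION:
        return CHANGING if score.pop_amplitude > params.vu_cutoff else STABLE
    raise InvalidArgumentError(f"unknown method {method!r}")
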