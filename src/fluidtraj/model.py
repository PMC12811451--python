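"""Model/Results facade over the per-trajectory analysis chain.

`TrajectoryModel` bundles the four stages — CUSUM-GLR trend labeling,
segmentation, continuity-constrained polynomial fitting, and
signal/noise scoring — behind a statsmodels-style interface: build the
model from data, call :meth:`TrajectoryModel.fit`, and read estimates,
diagnostics and a text summary off the returned
:class:`TrajectoryResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import scoring, segfit, trends
from .exceptions import InvalidArgumentError
from .scoring import ScoreParameters, ScoreResult
from .segfit import SegmentedFit
from .synthetic import Trajectory
from .trends import LabelingConfig


class TrajectoryModel:
    """Personalized change model for one eye's TRO trajectory.

    Parameters
    ----------
    trajectory
        The eye's day-indexed TRO series (VU), optionally labeled.
    labeling
        Trend-labeling configuration (GLR threshold, minimum segment
        length, plateau slope tolerance).
    max_degree
        Per-segment polynomial degree cap (default 2).
    score_params
        Cutoffs for the personalized and population classification
        rules.

    Examples
    --------
    >>> model = TrajectoryModel.from_dataframe(df)   # eye_id, day, tro_vu
    >>> res = model.fit()
    >>> res.score.snr, res.calls["personalized"]
    """

    def __init__(
        self,
        trajectory: Trajectory,
        labeling: LabelingConfig | None = None,
        max_degree: int = segfit.DEGREE_CAP,
        score_params: ScoreParameters | None = None,
    ) -> None:
        self.trajectory = trajectory
        self.labeling = labeling or LabelingConfig()
        self.max_degree = max_degree
        self.score_params = score_params or ScoreParameters()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        eye_id: str | None = None,
        **kwargs,
    ) -> "TrajectoryModel":
        """Build from a long-format frame with columns eye_id, day, tro_vu.

        With several eyes in ``data``, ``eye_id`` selects one.
        """
        required = {"eye_id", "day", "tro_vu"}
        missing = required - set(data.columns)
        if missing:
            raise InvalidArgumentError(f"missing columns: {sorted(missing)}")
        if eye_id is None:
            ids = data["eye_id"].unique()
            if len(ids) != 1:
                raise InvalidArgumentError(
                    "data holds several eyes; pass eye_id to select one"
                )
            eye_id = ids[0]
        sub = data[data["eye_id"] == eye_id].sort_values("day")
        if sub.empty:
            raise InvalidArgumentError(f"no rows for eye {eye_id!r}")
        label = None
        if "label" in sub.columns:
            first = str(sub["label"].iloc[0])
            label = first if first in ("stable", "changing") else None
        traj = Trajectory(
            eye_id=str(eye_id),
            days=sub["day"].to_numpy(dtype=int),
            tro=sub["tro_vu"].to_numpy(dtype=float),
            label=label,
        )
        return cls(traj, **kwargs)

    def fit(self) -> "TrajectoryResults":
        """Run label -> resolve -> segment -> fit -> score."""
        traj = self.trajectory
        cps = trends.detect_changepoints(traj, self.labeling)
        labels = trends.label_points(traj, cps, self.labeling)
        labels, cps = trends.resolve_questionable_points(traj, labels, cps, self.labeling)
        segments = segfit.segments_from_labels(labels)
        fit = segfit.fit_segments(traj, segments, self.max_degree)
        score = scoring.score_trajectory(traj, fit, self.score_params)
        return TrajectoryResults(
            model=self, changepoints=cps, trend_labels=labels,
            segmented_fit=fit, score=score,
        )


@dataclass(frozen=True)
class TrajectoryResults:
    """Fitted trajectory: trend labels, piecewise fit, and change scores."""

    model: TrajectoryModel
    changepoints: list[int]
    trend_labels: list[str]
    segmented_fit: SegmentedFit
    score: ScoreResult

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.segmented_fit.fitted

    @property
    def resid(self) -> np.ndarray:
        return self.model.trajectory.tro - self.segmented_fit.fitted

    @property
    def calls(self) -> dict[str, str]:
        """Stable/changing call under each rule."""
        p = self.model.score_params
        return {
            scoring.PERSONALIZED: scoring.classify_trajectory(self.score, p, scoring.PERSONALIZED),
            scoring.POPULATION: scoring.classify_trajectory(self.score, p, scoring.POPULATION),
        }

    def to_frame(self) -> pd.DataFrame:
        """Per-point table: day, observed, fitted, segment id, trend label."""
        traj = self.model.trajectory
        seg_ids = np.empty(len(traj), dtype=int)
        for i, seg in enumerate(self.segmented_fit.segments):
            seg_ids[seg.start_idx : seg.end_idx + 1] = i
        return pd.DataFrame(
            {
                "eye_id": traj.eye_id,
                "day": traj.days,
                "tro_vu": traj.tro,
                "fitted_vu": self.segmented_fit.fitted,
                "segment_id": seg_ids,
                "trend": self.trend_labels,
            }
        )

    def summary(self) -> str:
        """Plain-text summary table of the fitted trajectory."""
        traj = self.model.trajectory
        s = self.score
        p = self.model.score_params
        lines = [
            "Personalized TRO change analysis".center(58),
            "=" * 58,
            f"{'Eye:':<26}{traj.eye_id:>32}",
            f"{'Tests (days spanned):':<26}{f'{len(traj)} ({traj.days[-1] - traj.days[0] + 1})':>32}",
            f"{'Segments (changepoints):':<26}{f'{len(self.segmented_fit.segments)} ({len(self.changepoints)})':>32}",
            "-" * 58,
            f"{'Signal A (fit max-min):':<32}{s.signal_a:>18.3f} VU",
            f"{'Noise SD_T (RMS resid):':<32}{s.noise_sdt:>18.3f} VU",
            f"{'SNR score:':<32}{s.snr:>18.3f}",
            f"{'RCV (sqrt2*Z*SD_T, Z=' + format(p.z, '.2f') + '):':<32}{s.rcv:>18.3f} VU",
            f"{'Raw amplitude (max-min):':<32}{s.pop_amplitude:>18.3f} VU",
            "-" * 58,
            f"{'Call @ SNR > ' + format(p.snr_cutoff, '.2f') + ':':<32}{self.calls['personalized']:>22}",
            f"{'Call @ amplitude > ' + format(p.vu_cutoff, '.0f') + ' VU:':<32}{self.calls['population']:>22}",
        ]
        if traj.label is not None:
            lines.append(f"{'Ground truth:':<32}{traj.label:>22}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Day vs TRO with the piecewise fit overlaid, color-coded by trend.

        Requires matplotlib (the ``plot`` extra); never needed by the
        pipeline itself.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        traj = self.model.trajectory
        colors = {"incline": "tab:red", "plateau": "tab:gray", "decline": "tab:green"}
        for lab in colors:
            mask = np.array(self.trend_labels) == lab
            if mask.any():
                ax.scatter(traj.days[mask], traj.tro[mask], s=18, color=colors[lab], label=lab)
        ax.plot(traj.days, self.segmented_fit.fitted, color="tab:blue", lw=2, label="fit")
        ax.set_xlabel("day")
        ax.set_ylabel("TRO (VU)")
        ax.set_title(f"{traj.eye_id}: SNR {self.score.snr:.2f}")
        ax.legend(loc="best", fontsize=8)
        return ax
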