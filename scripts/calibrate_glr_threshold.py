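"""Calibrate the default GLR detection threshold.

Simulates pure-noise 28-point series (standard normal, the typical
number of tests per eye) and finds the threshold h at which ~5% of
null series yield at least one changepoint. A series alarms iff the
maximum top-level GLR statistic reaches h, so the 95th percentile of
that maximum is the calibrated default stored in
fluidtraj.trends.DEFAULT_GLR_THRESHOLD.

Usage: python scripts/calibrate_glr_threshold.py [--n 4000] [--seed 20240601]
"""

import argparse

import numpy as np

from fluidtraj.trends import LabelingConfig, glr_statistic


def max_null_statistic(rng: np.random.Generator, n_points: int, min_len: int) -> float:
    y = rng.normal(0.0, 1.0, size=n_points)
    return max(
        glr_statistic(y, k) for k in range(min_len, n_points - min_len + 1)
    )


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=4000, help="number of null series")
    ap.add_argument("--n-points", type=int, default=28, help="tests per series")
    ap.add_argument("--alpha", type=float, default=0.05, help="target false-alarm rate")
    ap.add_argument("--seed", type=int, default=20240601)
    args = ap.parse_args()

    cfg = LabelingConfig()
    rng = np.random.default_rng(args.seed)
    stats = np.array(
        [max_null_statistic(rng, args.n_points, cfg.min_segment_len) for _ in range(args.n)]
    )
    h = float(np.quantile(stats, 1.0 - args.alpha))
    print(f"null series: {args.n}, points per series: {args.n_points}")
    print(f"{(1 - args.alpha) * 100:.0f}th percentile of max GLR statistic: h = {h:.2f}")
    print(f"false-alarm rate at h: {np.mean(stats >= h):.4f}")
    print(f"false-alarm rate at current default ({cfg.glr_threshold}): "
          f"{np.mean(stats >= cfg.glr_threshold):.4f}")


if __name__ == "__main__":
    main()
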