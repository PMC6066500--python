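"""Pursuit-tracking scores, speed calibration, and pre/post percent change.

The tracking task samples target and cursor positions at 30 samples/s.  Per
sample, the error is the Euclidean pixel distance between cursor and target
centers; a distance strictly below 32 pixels counts as a success.  The
Success Rate (SR) score is the percent of successful samples.  The Error
Rate (ER) score weights each sample by its distance magnitude: here it is
the mean distance, clipped at a reference distance ``d_ref`` and expressed
as a percent of ``d_ref`` — a bounded score that falls as pursuit improves.

Speed calibration: rounds of increasing target speed trace out a falling
sigmoid of SR against speed.  A four-parameter logistic is fitted; the
"maximum-error" speed is where the fitted curve has completed 95% of its
fall to the lower asymptote, and the training speed is 60% of that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TrackingTrace",
    "SessionScore",
    "CalibrationCurve",
    "distance_series",
    "success_rate",
    "error_rate",
    "fit_calibration",
    "percent_change",
    "score_battery",
]

SUCCESS_RADIUS_PX = 32.0
DEFAULT_D_REF_PX = 128.0  # 4x the success radius


@dataclass
class TrackingTrace:
    """Per-sample target and cursor pixel coordinates at fixed rate."""

    t: np.ndarray
    target_xy: np.ndarray  # (n, 2)
    cursor_xy: np.ndarray  # (n, 2)
    fs: float = 30.0
    speed: float = 0.0     # target path speed setting, pixels/s

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.target_xy = np.asarray(self.target_xy, float)
        self.cursor_xy = np.asarray(self.cursor_xy, float)
        n = len(self.t)
        if self.target_xy.shape != (n, 2) or self.cursor_xy.shape != (n, 2):
            raise ValueError("t, target_xy, cursor_xy lengths must agree")
        if not (np.all(np.isfinite(self.target_xy)) and np.all(np.isfinite(self.cursor_xy))):
            raise ValueError("coordinates must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "t": self.t,
                "target_x": self.target_xy[:, 0],
                "target_y": self.target_xy[:, 1],
                "cursor_x": self.cursor_xy[:, 0],
                "cursor_y": self.cursor_xy[:, 1],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fs: float = 30.0, speed: float = 0.0) -> "TrackingTrace":
        df = pd.read_csv(path)
        return cls(
            t=df["t"].to_numpy(),
            target_xy=df[["target_x", "target_y"]].to_numpy(),
            cursor_xy=df[["cursor_x", "cursor_y"]].to_numpy(),
            fs=fs, speed=speed,
        )


def distance_series(trace: TrackingTrace) -> np.ndarray:
    """Per-sample Euclidean cursor-target distance in pixels."""
    dx = trace.cursor_xy[:, 0] - trace.target_xy[:, 0]
    dy = trace.cursor_xy[:, 1] - trace.target_xy[:, 1]
    return np.sqrt(dx * dx + dy * dy)


def success_rate(trace: TrackingTrace, threshold_px: float = SUCCESS_RADIUS_PX) -> float:
    """Percent of samples with distance strictly below the threshold."""
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    d = distance_series(trace)
    return 100.0 * float(np.count_nonzero(d < threshold_px)) / trace.n_samples


def error_rate(trace: TrackingTrace, d_ref: float = DEFAULT_D_REF_PX) -> float:
    """Distance-weighted error percent: mean of min(d, d_ref) over d_ref."""
    if d_ref <= 0:
        raise ValueError("d_ref must be positive")
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    d = np.minimum(distance_series(trace), d_ref)
    return 100.0 * float(d.mean()) / d_ref


@dataclass
class SessionScore:
    """SR/ER scores of a (possibly multi-run) tracking session."""

    sr: float
    er: float
    n_samples: int
    n_runs: int = 1
    threshold_px: float = SUCCESS_RADIUS_PX
    per_run: list[tuple[float, float]] = field(default_factory=list)


def score_battery(
    traces: list[TrackingTrace],
    threshold_px: float = SUCCESS_RADIUS_PX,
    d_ref: float = DEFAULT_D_REF_PX,
) -> SessionScore:
    """Score repeated runs; session score is the unweighted mean across runs."""
    if not traces:
        raise ValueError("no runs to score")
    per_run = [(success_rate(tr, threshold_px), error_rate(tr, d_ref)) for tr in traces]
    sr = float(np.mean([s for s, _ in per_run]))
    er = float(np.mean([e for _, e in per_run]))
    return SessionScore(
        sr=sr, er=er, n_samples=sum(tr.n_samples for tr in traces),
        n_runs=len(traces), threshold_px=threshold_px, per_run=per_run,
    )


def percent_change(pre: float, post: float, improvement_direction: str = "higher_better") -> float:
    """Relative pre-to-post change in percent, signed so improvement is positive.

    ``higher_better`` (SR): 100*(post-pre)/pre.  ``lower_better`` (ER):
    100*(pre-post)/pre, so a falling error is a positive gain.
    """
    if pre == 0:
        raise ValueError("percent change undefined for pre == 0")
    if improvement_direction == "higher_better":
        return 100.0 * (post - pre) / pre
    if improvement_direction == "lower_better":
        return 100.0 * (pre - post) / pre
    raise ValueError(f"unknown improvement_direction {improvement_direction!r}")


@dataclass
class CalibrationCurve:
    """Fitted SR-vs-speed sigmoid and the derived training speed."""

    rounds: list[tuple[float, float]]  # (speed, sr)
    upper: float
    lower: float
    v50: float
    slope: float
    v_maxerr: float
    v_train: float

    def predict(self, v) -> np.ndarray:
        return _logistic(np.asarray(v, float), self.upper, self.lower, self.v50, self.slope)

    def to_dict(self) -> dict:
        return {
            "rounds": [list(r) for r in self.rounds],
            "fit": {"upper": self.upper, "lower": self.lower, "v50": self.v50, "slope": self.slope},
            "v_maxerr": self.v_maxerr,
            "v_train": self.v_train,
        }


def _logistic(v, upper, lower, v50, slope):
    return lower + (upper - lower) / (1.0 + np.exp((v - v50) / slope))


def fit_calibration(
    rounds: list[tuple[float, float]],
    tail_fraction: float = 0.05,
    train_fraction: float = 0.6,
) -> CalibrationCurve:
    """Fit the decreasing 4-parameter logistic SR(v) and derive the training speed.

    ``v_maxerr`` is the speed at which the fitted curve has fallen to within
    ``tail_fraction`` of its lower asymptote (closed form
    ``v50 + slope*log((1-tail)/tail)``); ``v_train = train_fraction * v_maxerr``.
    """
    if len(rounds) < 5:
        raise ValueError("calibration needs >= 5 rounds")
    v = np.asarray([r[0] for r in rounds], float)
    sr = np.asarray([r[1] for r in rounds], float)
    if np.ptp(sr) < 1e-9:
        raise ValueError("degenerate calibration: all rounds have equal SR")
    span = np.ptp(v)
    if span <= 0:
        raise ValueError("degenerate calibration: all rounds at one speed")
    if sr.max() - sr.min() < 20.0:
        raise ValueError(
            "calibration rounds do not span both an easy (high-SR) and hard (low-SR) regime"
        )
    p0 = (float(sr.max()), float(sr.min()), float(np.median(v)), span / 6.0)
    bounds = ([0.0, -5.0, v.min() - span, 1e-6], [110.0, 100.0, v.max() + span, 10.0 * span])
    try:
        popt, _ = curve_fit(_logistic, v, sr, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise ValueError(f"calibration fit did not converge: {exc}") from exc
    upper, lower, v50, slope = map(float, popt)
    if upper <= lower:
        raise ValueError("calibration fit degenerate: upper asymptote <= lower asymptote")
    v_maxerr = v50 + slope * float(np.log((1.0 - tail_fraction) / tail_fraction))
    v_train = train_fraction * v_maxerr
    return CalibrationCurve(
        rounds=[(float(a), float(b)) for a, b in rounds],
        upper=upper, lower=lower, v50=v50, slope=slope,
        v_maxerr=v_maxerr, v_train=v_train,
    )
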