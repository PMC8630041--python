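"""Response-locked classification images and impact curves.

A classification image (CI) is the map of noise weights obtained by
correlating trial-by-trial stimulus noise with the behavioural
response.  Here the analysis is locked backward from the response:
for every lag ``l`` (in frames) before the bound crossing, the kernel is

    MeanKernel(x, l) = mu1(x, l) - mu0(x, l),

where mu1 averages the noise-only contrast on the chosen (= target,
since error trials are excluded) side and mu0 on the unchosen side.
Right-target trials are mirrored onto a canonical orientation (fields
swapped, bar order reversed) so kernels pool across sides.

Because reaction times vary, the number of trials contributing at lag
``l`` shrinks as ``l`` grows; cells with fewer than ``min_count``
trials are masked (NaN), not zeroed.

Lag 0 is the noise frame during which the bound crossing occurred.
The lag axis in ms is ``l * frame_ms`` plus a configurable motor-delay
back-shift (default 250 ms) so that simulated kernels share the axis of
button-press-locked data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .observer import TrialRecord
from .stimulus import FRAME_MS

#: Default analysis window: 36 frames ~ 1200 ms before the response.
DEFAULT_MAX_LAG = 36
DEFAULT_MIN_COUNT = 10
DEFAULT_MOTOR_SHIFT_MS = 250.0


@dataclass
class ClassificationImage:
    """Space x lag kernel with per-lag trial counts.

    ``kernel[x, l]`` is the weight of bar ``x`` at ``l`` frames before the
    crossing; masked cells are NaN.  ``lag_ms`` includes the motor-delay
    back-shift, so it reads as milliseconds before the button press.
    """

    kernel: np.ndarray
    n_trials_per_lag: np.ndarray
    lag_ms: np.ndarray
    space_axis: np.ndarray
    motor_shift_ms: float = DEFAULT_MOTOR_SHIFT_MS
    statistic: str = "mean"  # "mean" or "variance"

    @property
    def n_lags(self) -> int:
        return self.kernel.shape[1]


@dataclass
class ImpactCurves:
    """Lag profiles of the CI averaged over designated bar sets."""

    central: np.ndarray
    adjacent: np.ndarray
    lag_ms: np.ndarray
    central_bars: Tuple[int, ...] = (7, 8)
    adjacent_bars: Tuple[int, ...] = (6, 9)
    se_central: Optional[np.ndarray] = None
    se_adjacent: Optional[np.ndarray] = None

    def stacked(self) -> np.ndarray:
        """Central and adjacent curves as one (2, n_lags) array."""
        return np.vstack([self.central, self.adjacent])


RT_GROUP_WINDOWS: Dict[str, Tuple[float, float]] = {
    "short": (0.0, 50.0),
    "intermediate": (25.0, 75.0),
    "long": (50.0, 100.0),
}


def usable_trials(trials: Iterable[TrialRecord]) -> List[TrialRecord]:
    """Correct, non-timeout trials — the set every kernel is computed from."""
    return [t for t in trials if t.correct and not t.timeout]


def _canonical_noise(trial: TrialRecord) -> Tuple[np.ndarray, np.ndarray]:
    """(chosen-side, unchosen-side) noise in canonical orientation.

    Right-target trials are mirrored: fields swapped and bar order
    reversed within each field, so that a mirrored copy of every trial
    produces a bit-identical kernel.
    """
    if trial.target_side == "left":
        return trial.noise_left, trial.noise_right
    return trial.noise_right[::-1], trial.noise_left[::-1]


def _kernel_from_arrays(
    chosen: np.ndarray,
    unchosen: np.ndarray,
    crossing: np.ndarray,
    max_lag: int,
    min_count: int,
    motor_shift_ms: float,
    statistic: str = "mean",
) -> ClassificationImage:
    """Kernel estimator on pre-stacked canonical noise arrays.

    ``chosen``/``unchosen`` are (n_trials, n_bars, n_frames) noise
    records already in canonical orientation; ``crossing`` holds each
    trial's 0-based crossing frame.
    """
    if chosen.shape[0] == 0:
        raise ValueError("no usable (correct, non-timeout) trials to analyze")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    n_bars = chosen.shape[1]
    if statistic == "variance":
        chosen = chosen ** 2
        unchosen = unchosen ** 2
    n_lags = max_lag + 1
    kernel = np.full((n_bars, n_lags), np.nan)
    counts = np.zeros(n_lags, dtype=int)
    rows = np.arange(chosen.shape[0])
    for lag in range(n_lags):
        valid = crossing >= lag
        counts[lag] = int(valid.sum())
        if counts[lag] >= min_count:
            frames = crossing[valid] - lag
            mu1 = chosen[rows[valid], :, frames].mean(axis=0)
            mu0 = unchosen[rows[valid], :, frames].mean(axis=0)
            kernel[:, lag] = mu1 - mu0
    lag_ms = np.arange(n_lags) * FRAME_MS + motor_shift_ms
    return ClassificationImage(
        kernel=kernel,
        n_trials_per_lag=counts,
        lag_ms=lag_ms,
        space_axis=np.arange(n_bars),
        motor_shift_ms=motor_shift_ms,
        statistic=statistic,
    )


def _locked_kernel(
    trials: Sequence[TrialRecord],
    max_lag: int,
    min_count: int,
    motor_shift_ms: float,
    statistic: str,
) -> ClassificationImage:
    kept = usable_trials(trials)
    if not kept:
        raise ValueError("no usable (correct, non-timeout) trials to analyze")
    chosen = np.stack([_canonical_noise(t)[0] for t in kept])
    unchosen = np.stack([_canonical_noise(t)[1] for t in kept])
    k = np.array([t.crossing_frame for t in kept])
    return _kernel_from_arrays(
        chosen, unchosen, k, max_lag, min_count, motor_shift_ms, statistic
    )


def response_locked_kernel(
    trials: Sequence[TrialRecord],
    max_lag: int = DEFAULT_MAX_LAG,
    min_count: int = DEFAULT_MIN_COUNT,
    motor_shift_ms: float = DEFAULT_MOTOR_SHIFT_MS,
) -> ClassificationImage:
    """Mean kernel mu1 - mu0, locked backward from the bound crossing."""
    return _locked_kernel(trials, max_lag, min_count, motor_shift_ms, "mean")


def variance_kernel(
    trials: Sequence[TrialRecord],
    max_lag: int = DEFAULT_MAX_LAG,
    min_count: int = DEFAULT_MIN_COUNT,
    motor_shift_ms: float = DEFAULT_MOTOR_SHIFT_MS,
) -> ClassificationImage:
    """Second-moment kernel: mean squared noise, chosen minus unchosen side."""
    return _locked_kernel(trials, max_lag, min_count, motor_shift_ms, "variance")


def impact_curves(
    ci: ClassificationImage,
    central_bars: Sequence[int] = (7, 8),
    adjacent_bars: Sequence[int] = (6, 9),
) -> ImpactCurves:
    """Lag-wise means of the kernel over the central and flanking bar sets."""
    central_bars = tuple(central_bars)
    adjacent_bars = tuple(adjacent_bars)
    if set(central_bars) & set(adjacent_bars):
        raise ValueError("central and adjacent bar sets must be disjoint")
    n_bars = ci.kernel.shape[0]
    for b in central_bars + adjacent_bars:
        if not 0 <= b < n_bars:
            raise ValueError(f"bar index {b} outside [0, {n_bars})")
    return ImpactCurves(
        central=ci.kernel[list(central_bars)].mean(axis=0),
        adjacent=ci.kernel[list(adjacent_bars)].mean(axis=0),
        lag_ms=ci.lag_ms.copy(),
        central_bars=central_bars,
        adjacent_bars=adjacent_bars,
    )


def rt_split(trials: Sequence[TrialRecord], group: str) -> List[TrialRecord]:
    """Overlapping 50% RT windows: short [0,50], intermediate [25,75], long [50,100].

    The split is computed separately within each ramp-rate (alpha)
    condition; sorting is stable with trial order as the tiebreak, so
    permuting the input does not change membership.
    """
    if group not in RT_GROUP_WINDOWS:
        raise ValueError(f"unknown RT group {group!r}; use one of {sorted(RT_GROUP_WINDOWS)}")
    kept = usable_trials(trials)
    if len(kept) < 4:
        raise ValueError("need at least 4 usable trials to split by RT")
    lo_pct, hi_pct = RT_GROUP_WINDOWS[group]
    out: List[TrialRecord] = []
    for alpha in sorted({t.alpha for t in kept}):
        cond = [t for t in kept if t.alpha == alpha]
        order = sorted(range(len(cond)), key=lambda i: (cond[i].rt_ms, i))
        n = len(cond)
        lo = int(n * lo_pct) // 100
        hi = int(n * hi_pct) // 100
        out.extend(cond[i] for i in order[lo:hi])
    return out


@dataclass
class RTSummary:
    """Per-condition reaction-time summary plus the pooled cumulative histogram."""

    table: pd.DataFrame
    ecdf: Dict[float, Tuple[np.ndarray, np.ndarray]]


def rt_summary(
    trials: Sequence[TrialRecord],
    grid_ms: Optional[np.ndarray] = None,
) -> RTSummary:
    """Mean log10 RT (with geometric-mean back-transform), linear mean with
    standard error, and an empirical cumulative RT distribution per alpha."""
    kept = usable_trials(trials)
    if not kept:
        raise ValueError("no usable trials")
    if grid_ms is None:
        grid_ms = np.arange(0.0, 8001.0, 50.0)
    rows = []
    ecdf: Dict[float, Tuple[np.ndarray, np.ndarray]] = {}
    for alpha in sorted({t.alpha for t in kept}):
        rts = np.array([t.rt_ms for t in kept if t.alpha == alpha])
        logs = np.log10(rts)
        cdf = np.searchsorted(np.sort(rts), grid_ms, side="right") / rts.size
        ecdf[alpha] = (grid_ms.copy(), cdf)
        rows.append(
            {
                "alpha": alpha,
                "n": rts.size,
                "mean_log10_rt": logs.mean(),
                "geo_mean_rt_ms": 10.0 ** logs.mean(),
                "mean_rt_ms": rts.mean(),
                "sem_rt_ms": rts.std(ddof=1) / np.sqrt(rts.size) if rts.size > 1 else np.nan,
            }
        )
    return RTSummary(table=pd.DataFrame(rows), ecdf=ecdf)


def average_kernels(kernels: Sequence[ClassificationImage]) -> Tuple[ClassificationImage, np.ndarray]:
    """Unweighted across-observer mean kernel and its standard error.

    Cells masked in any observer are masked in the average.
    """
    if not kernels:
        raise ValueError("no kernels to average")
    shapes = {k.kernel.shape for k in kernels}
    if len(shapes) != 1:
        raise ValueError("kernels must share a shape to be averaged")
    stack = np.stack([k.kernel for k in kernels])
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / np.sqrt(len(kernels)) if len(kernels) > 1 else np.full_like(mean, np.nan)
    out = ClassificationImage(
        kernel=mean,
        n_trials_per_lag=np.sum([k.n_trials_per_lag for k in kernels], axis=0),
        lag_ms=kernels[0].lag_ms.copy(),
        space_axis=kernels[0].space_axis.copy(),
        motor_shift_ms=kernels[0].motor_shift_ms,
        statistic=kernels[0].statistic,
    )
    return out, se
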