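"""Kinetic-curve transforms: baseline removal, monotone smoothing,
replicate averaging, endpoint extraction and time-shift estimation.

Redox dye conversion is cumulative, so a well's signal should never
decrease; apparent decreases are imaging noise.  The smoother therefore
searches for the smallest centred moving-average window that removes
every negative slope, capped at a 25-point window, which in practice
suffices for plate-reader curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .plate_io import KineticSeries

logger = logging.getLogger(__name__)

#: slopes more negative than this (in signal units per point) count as decreases
MONOTONE_TOL = 1e-9

#: largest smoothing window tried by default
DEFAULT_W_MAX = 25


@dataclass
class SmoothedCurve:
    """A monotone-smoothed kinetic curve.

    ``window`` is the odd moving-average width that achieved
    monotonicity (1 = input already monotone).  If even the maximum
    window left decreases, ``residual_negative_slopes`` counts them
    before the final running-maximum pass that enforces the invariant.
    """

    strain_id: str
    condition_id: str
    replicate: int | str
    times: np.ndarray
    signals: np.ndarray
    window: int
    residual_negative_slopes: int = 0

    def label(self) -> str:
        return f"({self.strain_id}, {self.condition_id}, rep {self.replicate})"

    def to_series(self) -> KineticSeries:
        return KineticSeries(
            strain_id=self.strain_id,
            condition_id=self.condition_id,
            replicate=self.replicate,
            times=self.times.copy(),
            signals=self.signals.copy(),
        )


def baseline_transform(series: KineticSeries) -> KineticSeries:
    """Anchor a raw curve at zero: subtract the first sample, floor at 0.

    Keeps the arbitrary-unit scale of the instrument while removing
    well-to-well offsets in the initial dye state.
    """
    shifted = np.maximum(series.signals - series.signals[0], 0.0)
    return series.copy_with(signals=shifted)


def moving_average(signals: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with the window truncated at the array bounds.

    At index ``i`` the mean is taken over
    ``signals[max(0, i-h) : min(n, i+h+1)]`` with ``h = (window-1)//2``,
    so the output has the same length as the input and interior points
    see the full window.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    x = np.asarray(signals, dtype=float)
    if window == 1:
        return x.copy()
    n = x.size
    h = (window - 1) // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def _is_nondecreasing(x: np.ndarray, tol: float = MONOTONE_TOL) -> bool:
    return bool(np.all(np.diff(x) >= -tol))


def smooth_monotone(series: KineticSeries, w_max: int = DEFAULT_W_MAX) -> SmoothedCurve:
    """Smooth with the smallest odd moving-average window giving a monotone curve.

    Windows 1, 3, 5, … ``w_max`` are tried in turn; the first whose
    centred moving average has no negative slope is returned.  If none
    succeeds, the ``w_max`` average is taken, the residual decreases are
    counted, and a running-maximum pass enforces monotonicity so that
    downstream endpoint extraction always sees a cumulative curve.
    """
    if w_max % 2 == 0 or w_max < 1:
        raise ValidationError(f"w_max must be odd and >= 1, got {w_max}")
    for window in range(1, w_max + 1, 2):
        smoothed = moving_average(series.signals, window)
        if _is_nondecreasing(smoothed):
            return SmoothedCurve(
                strain_id=series.strain_id,
                condition_id=series.condition_id,
                replicate=series.replicate,
                times=series.times.copy(),
                signals=smoothed,
                window=window,
            )
    smoothed = moving_average(series.signals, w_max)
    residual = int(np.sum(np.diff(smoothed) < -MONOTONE_TOL))
    logger.debug(
        "series %s: %d negative slopes remain at window %d; applying running max",
        series.label(),
        residual,
        w_max,
    )
    return SmoothedCurve(
        strain_id=series.strain_id,
        condition_id=series.condition_id,
        replicate=series.replicate,
        times=series.times.copy(),
        signals=np.maximum.accumulate(smoothed),
        window=w_max,
        residual_negative_slopes=residual,
    )


def aggregate_replicates(series_group: Sequence) -> KineticSeries:
    """Pointwise mean of replicate curves sharing a strain, condition and grid.

    Accepts :class:`KineticSeries` or :class:`SmoothedCurve` objects;
    the result carries replicate label ``"mean"``.
    """
    group = list(series_group)
    if not group:
        raise ValidationError("aggregate_replicates: empty replicate group")
    first = group[0]
    for s in group[1:]:
        if (s.strain_id, s.condition_id) != (first.strain_id, first.condition_id):
            raise ValidationError(
                f"aggregate_replicates: mixed identities {s.label()} vs {first.label()}"
            )
        if s.times.size != first.times.size or not np.allclose(
            s.times, first.times, rtol=0, atol=1e-9
        ):
            raise ValidationError(
                f"aggregate_replicates: time grid of {s.label()} does not match "
                f"{first.label()}"
            )
    mean = np.mean([s.signals for s in group], axis=0)
    return KineticSeries(
        strain_id=first.strain_id,
        condition_id=first.condition_id,
        replicate="mean",
        times=first.times.copy(),
        signals=mean,
    )


def endpoint_signal(curve, t_end: float) -> float:
    """Signal at the latest sampled time at or before ``t_end`` (no interpolation).

    On the standard 0.25-h grid the 50-h endpoint is exact (index 200
    from t = 0) and the 24-h thermal-stress endpoint is index 96.
    """
    times = curve.times
    if t_end < times[0] - 1e-9:
        raise ValidationError(
            f"endpoint {t_end} h precedes first sample at {times[0]} h "
            f"for {curve.label()}"
        )
    idx = int(np.searchsorted(times, t_end + 1e-9, side="right")) - 1
    return float(curve.signals[idx])


def estimate_time_shift(
    curve_ref,
    curve_test,
    max_shift: float | None = None,
    min_overlap_fraction: float = 0.5,
) -> float:
    """Delay (hours) of a test progress curve relative to a reference.

    Both curves must be non-decreasing on the same time grid.  The
    shift δ ≥ 0 minimising the mean squared difference between
    ``curve_test(t)`` and ``curve_ref(t − δ)`` over the overlapping
    window is found by exhaustive search on the sampling grid, so the
    resolution equals the grid step (15 min on standard plates).  Ties
    resolve to the smallest shift; identical curves give 0.
    """
    for c in (curve_ref, curve_test):
        if not _is_nondecreasing(c.signals):
            raise ValidationError(
                f"estimate_time_shift: curve {c.label()} is not non-decreasing"
            )
    if curve_ref.times.size != curve_test.times.size or not np.allclose(
        curve_ref.times, curve_test.times, rtol=0, atol=1e-9
    ):
        raise ValidationError("estimate_time_shift: curves are on different time grids")

    ref = curve_ref.signals
    test = curve_test.signals
    n = ref.size
    step = curve_ref.step
    k_max = n - max(2, int(np.ceil(min_overlap_fraction * n)))
    if max_shift is not None:
        k_max = min(k_max, int(round(max_shift / step)))
    best_k, best_mse = 0, np.inf
    for k in range(0, k_max + 1):
        diff = test[k:] - ref[: n - k]
        mse = float(np.mean(diff * diff))
        if mse < best_mse - 1e-15:
            best_k, best_mse = k, mse
    return best_k * step
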