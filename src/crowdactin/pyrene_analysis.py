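"""Bulk polymerization rate from pyrene fluorescence time courses.

Pyrene-labeled actin fluoresces more strongly once incorporated into
filaments, so a plate-reader trace of pyrene intensity against time is
a bulk readout of polymerization.  The rate statistic used here is the
half-maximum slope: after subtracting the mean pre-polymerization
baseline, find the first time the trace reaches half its plateau and
fit a straight line through the samples centered on that point (ten on
either side by default).  Slopes are reported in AU/s and normalized
to a control condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .synthetic_data import FluorescenceTimeSeries

__all__ = [
    "FluorescenceTimeSeries",
    "HalfMaxSlopeEstimate",
    "baseline_correct",
    "find_half_max",
    "half_max_slope",
    "assembly_rate",
    "relative_assembly_rate",
]


@dataclass
class HalfMaxSlopeEstimate:
    """Linear-fit slope around the half-maximum crossing, AU/s."""

    t_half: float
    half_max_level: float
    slope: float
    window_indices: tuple[int, int]
    n_points: int
    stderr: float = float("nan")
    r2: float = float("nan")


def baseline_correct(
    series: FluorescenceTimeSeries,
    pre_window: float = 300.0,
) -> FluorescenceTimeSeries:
    """Subtract the mean intensity over the pre-polymerization window.

    The baseline is the average over
    ``[polymerization_start − pre_window, polymerization_start)``; it is
    subtracted from every sample, so adding a constant to the raw trace
    leaves the corrected trace unchanged.
    """
    t0 = series.polymerization_start
    mask = (series.times >= t0 - pre_window) & (series.times < t0)
    if int(mask.sum()) < 2:
        raise ValueError(
            f"need at least 2 samples in the {pre_window} s pre-polymerization window"
        )
    baseline = float(series.intensities[mask].mean())
    return FluorescenceTimeSeries(
        times=series.times.copy(),
        intensities=series.intensities - baseline,
        polymerization_start=t0,
        label=series.label,
    )


def find_half_max(
    series: FluorescenceTimeSeries,
    plateau: str = "top5",
) -> tuple[float, float]:
    """Locate the half-maximum crossing of a baseline-corrected trace.

    The plateau level is the mean of the top 5% of post-start
    intensities (``plateau="top5"``, robust to single-sample noise) or
    the global maximum (``plateau="max"``).  Returns ``(t_half,
    half_max_level)`` where ``t_half`` is the time of the first sample
    at or above half the plateau after the polymerization start.
    """
    post = series.times >= series.polymerization_start
    vals = series.intensities[post]
    if plateau == "top5":
        k = max(1, int(np.ceil(0.05 * vals.size)))
        level = float(np.sort(vals)[-k:].mean())
    elif plateau == "max":
        level = float(vals.max())
    else:
        raise ValueError(f"unknown plateau policy {plateau!r}")
    if level <= 0:
        raise ValueError("non-positive plateau: is the series baseline-corrected?")
    half = level / 2.0
    crossing = np.nonzero(post & (series.intensities >= half))[0]
    if crossing.size == 0:
        raise ValueError("series never reaches the half-maximum level")
    return float(series.times[crossing[0]]), half


def half_max_slope(
    series: FluorescenceTimeSeries,
    t_half: float,
    n_side: int = 10,
    include_center: bool = True,
) -> HalfMaxSlopeEstimate:
    """OLS slope over the samples centered on the half-max point.

    The window is the ``n_side`` samples on either side of the half-max
    sample plus, by default, the center itself (21 points for
    ``n_side=10``).  ``include_center=False`` drops the center sample
    (20 points).  The window must fit entirely inside the series — no
    silent clipping.
    """
    if n_side < 1:
        raise ValueError("n_side must be at least 1")
    center = int(np.argmin(np.abs(series.times - t_half)))
    first, last = center - n_side, center + n_side
    if first < 0 or last >= series.times.size:
        raise ValueError(
            f"half-max window [{first}, {last}] extends past the series "
            f"(0, {series.times.size - 1})"
        )
    idx = np.arange(first, last + 1)
    if not include_center:
        idx = idx[idx != center]
    res = stats.linregress(series.times[idx], series.intensities[idx])
    return HalfMaxSlopeEstimate(
        t_half=float(series.times[center]),
        half_max_level=float(series.intensities[center]),
        slope=float(res.slope),
        window_indices=(int(first), int(last)),
        n_points=int(idx.size),
        stderr=float(res.stderr),
        r2=float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0,
    )


def assembly_rate(
    series: FluorescenceTimeSeries,
    pre_window: float = 300.0,
    n_side: int = 10,
    plateau: str = "top5",
    include_center: bool = True,
) -> HalfMaxSlopeEstimate:
    """Full pipeline: baseline-correct, find half max, fit the slope."""
    corrected = baseline_correct(series, pre_window=pre_window)
    t_half, _ = find_half_max(corrected, plateau=plateau)
    return half_max_slope(corrected, t_half, n_side=n_side, include_center=include_center)


def relative_assembly_rate(
    slopes_by_condition: Mapping[str, float],
    control_label: str,
) -> dict[str, float]:
    """Normalize half-max slopes to the control condition.

    The control maps to exactly 1.0; a zero or negative control slope
    is rejected.
    """
    if control_label not in slopes_by_condition:
        raise ValueError(f"control label {control_label!r} not among conditions")
    control = float(slopes_by_condition[control_label])
    if control <= 0:
        raise ValueError("control slope must be positive")
    return {k: float(v) / control for k, v in slopes_by_condition.items()}
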