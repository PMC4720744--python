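"""Slope and Level Change (SLC) for AB series.

SLC is a descriptive, unstandardized three-step procedure:

1. **Baseline trend** — the mean of the first differences of the
   baseline phase: the average change from one baseline session to the
   next.  By telescoping this equals
   ``(last_pre - first_pre) / (n_pre - 1)``.
2. **Slope change** — the baseline trend is removed positionally from
   the whole series (``y*_t = y_t - (t - 1) * trend``, first session
   unmoved); the slope change is then the mean of first differences of
   the corrected intervention phase: average per-session change after
   controlling for baseline linear trend.
3. **Net level change** — the slope change is additionally removed
   positionally within the intervention phase
   (``y**_j = y*_{n_pre+j} - (j - 1) * slope_change``); the level change
   is the difference between the mean of the doubly corrected
   intervention values and the mean of the detrended baseline values.

All outputs stay in raw score units; the sign is interpreted by the
caller against the series' aim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TwoPhaseSeries
from .errors import ValidationError


@dataclass(frozen=True)
class SlcResult:
    """SLC estimates plus the intermediate corrected series (useful for
    plotting original vs. detrended data)."""

    baseline_trend: float  # score units per session
    slope_change: float  # score units per session, after detrending
    level_change: float  # score units, from doubly corrected means
    detrended: tuple[float, ...]  # full series after baseline-trend removal
    post_doubly_corrected: tuple[float, ...]  # post phase after slope-change removal

    def to_dict(self) -> dict:
        return {
            "baseline_trend": self.baseline_trend,
            "slope_change": self.slope_change,
            "level_change": self.level_change,
        }


def baseline_trend(series: TwoPhaseSeries) -> float:
    """Mean of baseline first differences; requires ``n_pre >= 2``."""
    if series.n_pre < 2:
        raise ValidationError("baseline-too-short", "baseline trend needs >= 2 baseline points")
    return float(np.mean(np.diff(series.pre)))


def detrend(series: TwoPhaseSeries, trend: float) -> np.ndarray:
    """Remove ``trend`` positionally from the whole series:
    ``y*_t = y_t - (t - 1) * trend`` with the first session unmoved."""
    y = np.asarray(series.scores, dtype=float)
    t = np.arange(len(y))
    return y - t * trend


def slope_change(series: TwoPhaseSeries) -> float:
    """Mean of first differences of the detrended intervention phase."""
    _check_lengths(series)
    corrected = detrend(series, baseline_trend(series))
    return float(np.mean(np.diff(corrected[series.n_pre :])))


def level_change(series: TwoPhaseSeries) -> float:
    """Difference of corrected phase means after removing baseline trend
    (whole series) and slope change (within the intervention phase)."""
    return slc(series).level_change


def slc(series: TwoPhaseSeries) -> SlcResult:
    """Run the full SLC decomposition."""
    _check_lengths(series)
    b = baseline_trend(series)
    star = detrend(series, b)
    post_star = star[series.n_pre :]
    sc = float(np.mean(np.diff(post_star)))
    j = np.arange(series.n_post)
    post_dstar = post_star - j * sc
    lc = float(np.mean(post_dstar) - np.mean(star[: series.n_pre]))
    return SlcResult(
        baseline_trend=b,
        slope_change=sc,
        level_change=lc,
        detrended=tuple(float(x) for x in star),
        post_doubly_corrected=tuple(float(x) for x in post_dstar),
    )


def _check_lengths(series: TwoPhaseSeries) -> None:
    if series.n_pre < 2:
        raise ValidationError("baseline-too-short", "SLC needs >= 2 baseline points")
    if series.n_post < 2:
        raise ValidationError("post-too-short", "SLC needs >= 2 intervention points")
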