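"""Quantitative constructions behind structured visual analysis.

These helpers compute the numbers that the classical visual aids for AB
single-case data draw: per-phase range lines, central-tendency lines,
the two-standard-deviation band projected from the baseline, per-phase
ordinary-least-squares trend lines, the split-middle (resistant) trend
line, the projected stability envelope around it, and the immediacy
contrast at the phase change.

Conventions shared by the band and the envelope: a point exactly on a
limit counts as *inside* (strict inequality defines "outside"), which
favors the no-change reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core import TwoPhaseSeries
from .errors import ValidationError


# ---------------------------------------------------------------------------
# Range lines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RangeLines:
    pre_min: float
    pre_max: float
    post_min: float
    post_max: float
    overlapping: bool  # do the two [min, max] intervals intersect?

    def to_dict(self) -> dict:
        return {
            "pre": [self.pre_min, self.pre_max],
            "post": [self.post_min, self.post_max],
            "overlapping": self.overlapping,
        }


def range_lines(series: TwoPhaseSeries) -> RangeLines:
    """Per-phase minimum and maximum, plus whether the ranges intersect
    (a coarse overlap statement)."""
    a, b = series.pre, series.post
    lo1, hi1 = float(a.min()), float(a.max())
    lo2, hi2 = float(b.min()), float(b.max())
    return RangeLines(lo1, hi1, lo2, hi2, overlapping=max(lo1, lo2) <= min(hi1, hi2))


# ---------------------------------------------------------------------------
# Two-standard-deviation band
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SdBand:
    """Baseline mean ± k·SD projected across the intervention phase.

    Under a normal, stationary no-change model fewer than 5% of
    intervention points are expected outside a 2-SD band; many points
    outside suggest change beyond baseline variability.  The aid is
    descriptive: behavioral data are rarely normal or independent.
    """

    center: float
    sd: float
    k: float
    lower: float
    upper: float
    outside_post: tuple[int, ...]  # 1-based indices within the post phase
    outside_fraction: float

    def to_dict(self) -> dict:
        return {
            "center": self.center,
            "sd": self.sd,
            "k": self.k,
            "lower": self.lower,
            "upper": self.upper,
            "outside_post": list(self.outside_post),
            "outside_fraction": self.outside_fraction,
        }


def sd_band(
    series: TwoPhaseSeries,
    k: float = 2.0,
    ddof: int = 1,
    center: Literal["mean", "median"] = "mean",
) -> SdBand:
    """Band from the baseline only, projected over the intervention phase.

    ``center="mean"`` is the classical construction; a median-centered
    variant is available for skewed baselines.  Points strictly outside
    ``[center - k*sd, center + k*sd]`` are counted.
    """
    if series.n_pre < 2:
        raise ValidationError("baseline-too-short", "SD band needs >= 2 baseline points")
    pre = series.pre
    c = float(np.mean(pre)) if center == "mean" else float(np.median(pre))
    s = float(np.std(pre, ddof=ddof))
    lo, hi = c - k * s, c + k * s
    outside = tuple(int(i + 1) for i, y in enumerate(series.post) if y < lo or y > hi)
    return SdBand(
        center=c,
        sd=s,
        k=float(k),
        lower=lo,
        upper=hi,
        outside_post=outside,
        outside_fraction=len(outside) / series.n_post,
    )


# ---------------------------------------------------------------------------
# Trend lines: OLS and split-middle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendLine:
    """A line ``score = intercept + slope * session`` fitted over one
    phase; projection beyond the fitted range is permitted."""

    slope: float
    intercept: float
    method: Literal["ols", "split-middle"]
    t_start: int
    t_end: int

    def predict(self, t) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t, dtype=float)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "method": self.method,
            "fitted_sessions": [self.t_start, self.t_end],
        }


def ols_trend(scores: Sequence[float], t_offset: int = 0) -> TrendLine:
    """Least-squares line through ``(t_offset + 1 .. t_offset + n, scores)``.

    Used for plotting and narrative description of within-phase trend.
    """
    y = np.asarray(scores, dtype=float)
    if len(y) < 2:
        raise ValidationError("phase-too-short", "OLS trend needs >= 2 points")
    t = t_offset + np.arange(1, len(y) + 1, dtype=float)
    slope, intercept = np.polyfit(t, y, 1)
    return TrendLine(float(slope), float(intercept), "ols", int(t[0]), int(t[-1]))


def split_middle(
    scores: Sequence[float],
    t_offset: int = 0,
    odd_middle: Literal["both", "drop"] = "both",
) -> TrendLine:
    """Resistant trend through the median points of the two phase halves.

    The phase is split in half; for odd length the middle observation
    belongs to *both* halves by default (``odd_middle="both"``), or can
    be dropped from both (``"drop"``).  Each half is summarized by
    (median session, median score) and the line passes through those two
    points.
    """
    y = np.asarray(scores, dtype=float)
    n = len(y)
    if n < 2:
        raise ValidationError("phase-too-short", "split-middle needs >= 2 points")
    t = t_offset + np.arange(1, n + 1, dtype=float)
    if n % 2 == 0:
        first, second = slice(0, n // 2), slice(n // 2, n)
    elif odd_middle == "both":
        first, second = slice(0, n // 2 + 1), slice(n // 2, n)
    else:
        first, second = slice(0, n // 2), slice(n // 2 + 1, n)
    t1, y1 = float(np.median(t[first])), float(np.median(y[first]))
    t2, y2 = float(np.median(t[second])), float(np.median(y[second]))
    if t1 == t2:
        raise ValidationError("degenerate-split", "half median sessions coincide")
    slope = (y2 - y1) / (t2 - t1)
    return TrendLine(slope, y1 - slope * t1, "split-middle", int(t[0]), int(t[-1]))


# ---------------------------------------------------------------------------
# Stability envelope
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvelopeResult:
    """Split-middle baseline trend with a projected stability envelope.

    The envelope half-width is a fraction (default 25%) of the baseline
    median; a phase is called trend-stable when at least ``criterion``
    (default 80%) of its points fall inside.  The baseline containment
    describes the stability of the baseline itself; the containment of
    the *projected* intervention points assesses change: post points
    inside the projection behave as the baseline trend predicts.
    """

    trend: TrendLine
    half_width: float
    baseline_within_fraction: float
    post_within_fraction: float
    stable: bool  # applies `criterion` to the post containment
    criterion: float
    post_direction: Literal["above", "below", "mixed", "inside"]

    def to_dict(self) -> dict:
        return {
            "trend": self.trend.to_dict(),
            "half_width": self.half_width,
            "baseline_within_fraction": self.baseline_within_fraction,
            "post_within_fraction": self.post_within_fraction,
            "stable": self.stable,
            "criterion": self.criterion,
            "post_direction": self.post_direction,
        }


def stability_envelope(
    series: TwoPhaseSeries,
    fraction: float = 0.25,
    criterion: float = 0.80,
    odd_middle: Literal["both", "drop"] = "both",
) -> EnvelopeResult:
    """Fit split-middle on the baseline, build the envelope, project it.

    ``fraction`` scales the baseline median into the envelope half-width;
    ``criterion`` is the containment proportion required for the
    trend-stability verdict, applied to the projected intervention
    points (the baseline containment is reported alongside).
    """
    if series.n_pre < 2:
        raise ValidationError("baseline-too-short", "envelope needs >= 2 baseline points")
    line = split_middle(series.pre, t_offset=0, odd_middle=odd_middle)
    hw = fraction * float(np.median(series.pre))
    times = series.times.astype(float)
    fit = line.predict(times)
    lo, hi = fit - hw, fit + hw
    y = np.asarray(series.scores, dtype=float)
    inside = (y >= lo) & (y <= hi)  # on-limit counts as inside
    base_frac = float(np.mean(inside[: series.n_pre]))
    post_inside = inside[series.n_pre :]
    post_frac = float(np.mean(post_inside))
    post_y = y[series.n_pre :]
    above = post_y > hi[series.n_pre :]
    below = post_y < lo[series.n_pre :]
    if above.any() and below.any():
        direction = "mixed"
    elif above.any():
        direction = "above"
    elif below.any():
        direction = "below"
    else:
        direction = "inside"
    return EnvelopeResult(
        trend=line,
        half_width=hw,
        baseline_within_fraction=base_frac,
        post_within_fraction=post_frac,
        stable=post_frac >= criterion,
        criterion=criterion,
        post_direction=direction,
    )


# ---------------------------------------------------------------------------
# Immediacy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Immediacy:
    value: float  # mean(first `window` post) - mean(last `window` pre)
    window: int
    label: Literal["improvement", "deterioration", "no-change"]

    def to_dict(self) -> dict:
        return {"value": self.value, "window": self.window, "label": self.label}


def immediacy(series: TwoPhaseSeries, window: int = 3) -> Immediacy:
    """Contrast the first ``window`` intervention sessions against the
    last ``window`` baseline sessions; the label interprets the sign
    against the series' aim."""
    if window < 1 or window > min(series.n_pre, series.n_post):
        raise ValidationError("window-too-large", f"window {window} exceeds a phase length")
    delta = float(np.mean(series.post[:window]) - np.mean(series.pre[-window:]))
    if delta == 0:
        label = "no-change"
    elif (delta < 0) == (series.aim == "decrease"):
        label = "improvement"
    else:
        label = "deterioration"
    return Immediacy(value=delta, window=window, label=label)
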