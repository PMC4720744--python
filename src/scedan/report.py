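"""Compose all analyses into a three-part assessment report.

The report mirrors how two-phase single-case data are assessed in
practice: a *visual* part (range lines, central tendencies, the 2-SD
band, the split-middle trend with projected stability envelope, the
immediacy contrast), a *quantitative* part (NAP and the slope-and-level
change decomposition), and a *substantive* part (a clinical cut-off
check, when a cut-off is supplied).

The report never aggregates the three parts into a single verdict —
when components disagree, adjudication belongs to the analyst — and it
speaks of "behavioral change", never of a causal intervention effect:
an AB design by itself cannot separate the two.  It only flags
disagreement patterns (e.g. the sign of the level-change estimate
against the direction of band exceedance) without resolving them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import nonoverlap, slc as slc_mod, visual_aids
from .core import TwoPhaseSeries, phase_descriptives
from .errors import ValidationError
from .nonoverlap import DEFAULT_BANDS

#: Baseline length below which the report warns that the phase is
#: shorter than the commonly cited minimum of five measurements.
MIN_RECOMMENDED_BASELINE = 5


@dataclass(frozen=True)
class AnalysisConfig:
    """All knobs of :func:`analyze`, echoed verbatim into the report."""

    cutoff: Optional[float] = None  # clinical cut-off, score units
    final_k: int = 3  # final-k sessions rule for the cut-off check
    sd_k: float = 2.0  # SD-band multiplier
    envelope_fraction: float = 0.25  # envelope half-width as fraction of baseline median
    stability_criterion: float = 0.80  # containment proportion for "stable"
    immediacy_window: int = 3
    tie_tol: float = 0.0  # NAP tie tolerance
    ddof: int = 1  # sample (n-1) SD convention
    bands: tuple = DEFAULT_BANDS  # NAP category boundaries
    scale_min: Optional[float] = None  # plausible measurement range, for
    scale_max: Optional[float] = None  # projection warnings

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "final_k": self.final_k,
            "sd_k": self.sd_k,
            "envelope_fraction": self.envelope_fraction,
            "stability_criterion": self.stability_criterion,
            "immediacy_window": self.immediacy_window,
            "tie_tol": self.tie_tol,
            "ddof": self.ddof,
            "bands": [list(b) for b in self.bands],
            "scale_min": self.scale_min,
            "scale_max": self.scale_max,
        }


@dataclass(frozen=True)
class CutoffAssessment:
    """Which intervention sessions sit strictly on the functional side
    of a clinical cut-off, and whether the final ``k`` all do."""

    cutoff: float
    k: int
    functional_sessions: tuple[int, ...]  # 1-based within the post phase
    final_k_all_functional: bool

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "k": self.k,
            "functional_sessions": list(self.functional_sessions),
            "final_k_all_functional": self.final_k_all_functional,
        }


def cutoff_assessment(series: TwoPhaseSeries, cutoff: float, k: int = 3) -> CutoffAssessment:
    """List post sessions strictly past the cut-off in the improvement
    direction (below it when the aim is a decrease); a score exactly at
    the cut-off is *not* functional."""
    if not np.isfinite(cutoff):
        raise ValidationError("invalid-cutoff", "cutoff must be finite")
    post = series.post
    if series.aim == "decrease":
        ok = post < cutoff
    else:
        ok = post > cutoff
    sessions = tuple(int(i + 1) for i in np.flatnonzero(ok))
    kk = min(k, series.n_post)
    return CutoffAssessment(
        cutoff=float(cutoff),
        k=k,
        functional_sessions=sessions,
        final_k_all_functional=bool(ok[-kk:].all()),
    )


@dataclass(frozen=True)
class AnalysisReport:
    """Machine-readable result of :func:`analyze`; every numeric field
    traces to exactly one module operation."""

    series: TwoPhaseSeries
    descriptives_pre: object
    descriptives_post: object
    nap: nonoverlap.NapResult
    slc: slc_mod.SlcResult
    ranges: visual_aids.RangeLines
    sd_band: visual_aids.SdBand
    envelope: visual_aids.EnvelopeResult
    immediacy: visual_aids.Immediacy
    cutoff: Optional[CutoffAssessment]
    warnings: tuple[dict, ...]
    disagreements: tuple[dict, ...]
    config: AnalysisConfig

    def to_dict(self) -> dict:
        return {
            "series": self.series.to_dict(),
            "descriptives": {
                "pre": self.descriptives_pre.to_dict(),
                "post": self.descriptives_post.to_dict(),
            },
            "nap": self.nap.to_dict(),
            "slc": self.slc.to_dict(),
            "range_lines": self.ranges.to_dict(),
            "sd_band": self.sd_band.to_dict(),
            "stability_envelope": self.envelope.to_dict(),
            "immediacy": self.immediacy.to_dict(),
            "cutoff_assessment": self.cutoff.to_dict() if self.cutoff else None,
            "warnings": [dict(w) for w in self.warnings],
            "disagreements": [dict(d) for d in self.disagreements],
            "config": self.config.to_dict(),
        }

    def to_json(self) -> str:
        """Deterministic serialization: stable key order (construction
        order), floats rounded to 4 decimals."""
        return json.dumps(_round_floats(self.to_dict()), indent=2, allow_nan=False)


def _round_floats(obj):
    if isinstance(obj, float):
        return round(obj, 4)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def analyze(series: TwoPhaseSeries, config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run every analysis module on ``series`` and assemble the report.

    A pure function of ``(series, config)``: repeated calls give
    byte-identical JSON.  Module errors propagate with the originating
    module prefixed to the message.
    """
    cfg = config or AnalysisConfig()
    d_pre, d_post = _run("core", phase_descriptives, series, ddof=cfg.ddof)
    nap_res = _run("nonoverlap", nonoverlap.nap, series, tie_tol=cfg.tie_tol, bands=cfg.bands)
    slc_res = _run("slc", slc_mod.slc, series)
    ranges = _run("visual_aids", visual_aids.range_lines, series)
    band = _run("visual_aids", visual_aids.sd_band, series, k=cfg.sd_k, ddof=cfg.ddof)
    env = _run(
        "visual_aids",
        visual_aids.stability_envelope,
        series,
        fraction=cfg.envelope_fraction,
        criterion=cfg.stability_criterion,
    )
    window = min(cfg.immediacy_window, series.n_pre, series.n_post)
    imm = _run("visual_aids", visual_aids.immediacy, series, window=window)
    cut = (
        _run("report", cutoff_assessment, series, cutoff=cfg.cutoff, k=cfg.final_k)
        if cfg.cutoff is not None
        else None
    )

    warnings = _collect_warnings(series, env, cfg)
    disagreements = _collect_disagreements(series, slc_res, band, env)

    return AnalysisReport(
        series=series,
        descriptives_pre=d_pre,
        descriptives_post=d_post,
        nap=nap_res,
        slc=slc_res,
        ranges=ranges,
        sd_band=band,
        envelope=env,
        immediacy=imm,
        cutoff=cut,
        warnings=tuple(warnings),
        disagreements=tuple(disagreements),
        config=cfg,
    )


def _run(module: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except ValidationError as exc:
        raise ValidationError(exc.code, f"[{module}] {exc}") from exc


def _collect_warnings(series, env, cfg) -> list[dict]:
    out = []
    if series.n_pre < MIN_RECOMMENDED_BASELINE:
        out.append(
            {
                "code": "short-baseline",
                "message": (
                    f"baseline has {series.n_pre} sessions, below the commonly "
                    f"recommended minimum of {MIN_RECOMMENDED_BASELINE}"
                ),
            }
        )
    if env.baseline_within_fraction < cfg.stability_criterion:
        out.append(
            {
                "code": "unstable-baseline",
                "message": (
                    "baseline containment in its own stability envelope is "
                    f"{env.baseline_within_fraction:.2f} < criterion {cfg.stability_criterion:.2f}; "
                    "trend projection is unreliable"
                ),
            }
        )
    # projection leaving the plausible measurement range
    post_times = series.times[series.n_pre :].astype(float)
    fit = env.trend.predict(post_times)
    lo, hi = fit - env.half_width, fit + env.half_width
    if (cfg.scale_min is not None and lo.min() < cfg.scale_min) or (
        cfg.scale_max is not None and hi.max() > cfg.scale_max
    ):
        out.append(
            {
                "code": "projection-out-of-range",
                "message": (
                    "the projected stability envelope exits the plausible "
                    "measurement range; projected values that far out are not "
                    "interpretable"
                ),
            }
        )
    return out


def _collect_disagreements(series, slc_res, band, env) -> list[dict]:
    """Flag sign conflicts between components without resolving them."""
    out = []
    improving_level = (slc_res.level_change < 0) == (series.aim == "decrease")
    if band.outside_post:
        post = series.post
        below = any(post[i - 1] < band.lower for i in band.outside_post)
        above = any(post[i - 1] > band.upper for i in band.outside_post)
        band_dir = "below" if below and not above else "above" if above and not below else "mixed"
        improving_band = (band_dir == "below") == (series.aim == "decrease")
        if band_dir != "mixed" and slc_res.level_change != 0 and improving_level != improving_band:
            out.append(
                {
                    "code": "level-vs-band",
                    "message": (
                        f"SLC level change ({slc_res.level_change:+.2f}) and 2-SD band "
                        f"exceedance direction ({band_dir}) point in opposite directions"
                    ),
                }
            )
    if env.post_direction not in ("inside", "mixed"):
        improving_env = (env.post_direction == "below") == (series.aim == "decrease")
        if slc_res.slope_change != 0:
            improving_slope = (slc_res.slope_change < 0) == (series.aim == "decrease")
            if improving_env != improving_slope:
                out.append(
                    {
                        "code": "slope-vs-envelope",
                        "message": (
                            f"SLC slope change ({slc_res.slope_change:+.2f}) and envelope "
                            f"exceedance direction ({env.post_direction}) disagree"
                        ),
                    }
                )
    return out
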