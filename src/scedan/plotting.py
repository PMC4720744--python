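"""Figure rendering for the visual-analysis aids.

Produces one panel per aid — range bars, phase medians, the projected
2-SD band, and the split-middle trend with its stability envelope —
plus a combined figure that overlays per-phase OLS trend lines.  Every
panel draws the phase-change line at the A/B boundary and, when a
clinical cut-off is configured, a horizontal reference at the cut-off.

Filenames are deterministic: ``range_lines.<fmt>``, ``medians.<fmt>``,
``sd_band.<fmt>``, ``stability_envelope.<fmt>``, ``combined.<fmt>``.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import TwoPhaseSeries
from .errors import ValidationError
from .report import AnalysisReport
from .visual_aids import ols_trend

PANELS = ("range_lines", "medians", "sd_band", "stability_envelope", "combined")


def render_plots(report: AnalysisReport, out_dir, fmt: str = "png") -> list[str]:
    """Write the four aid panels and the combined figure; returns the
    file paths written."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write-probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise ValidationError("io-error", f"cannot write to {out}: {exc}") from exc

    series = report.series
    paths = []
    for name in PANELS:
        fig, ax = plt.subplots(figsize=(6.5, 4.0))
        _base_panel(ax, series, report)
        getattr(_Panels, name)(ax, series, report)
        ax.legend(loc="best", fontsize=8)
        path = out / f"{name}.{fmt}"
        fig.savefig(path, format=fmt)
        plt.close(fig)
        paths.append(str(path))
    return paths


def _base_panel(ax, series: TwoPhaseSeries, report: AnalysisReport) -> None:
    t = series.times
    ax.plot(t, series.scores, "o-", color="0.2", lw=1, ms=4, label=series.label or "scores")
    ax.axvline(series.n_pre + 0.5, color="0.5", ls="--", lw=1)
    cfg = report.config
    if cfg.cutoff is not None:
        ax.axhline(cfg.cutoff, color="firebrick", ls=":", lw=1.2, label=f"cut-off {cfg.cutoff:g}")
    ax.set_xlabel("session")
    ax.set_ylabel("score")


class _Panels:
    @staticmethod
    def range_lines(ax, series, report):
        r = report.ranges
        ax.hlines([r.pre_min, r.pre_max], 1, series.n_pre, color="tab:blue", lw=1.5, label="pre range")
        ax.hlines([r.post_min, r.post_max], series.n_pre + 1, series.n, color="tab:orange", lw=1.5, label="post range")
        ax.set_title("Range lines")

    @staticmethod
    def medians(ax, series, report):
        ax.hlines(report.descriptives_pre.median, 1, series.n_pre, color="tab:blue", lw=1.5, label="pre median")
        ax.hlines(report.descriptives_post.median, series.n_pre + 1, series.n, color="tab:orange", lw=1.5, label="post median")
        ax.set_title("Phase medians")

    @staticmethod
    def sd_band(ax, series, report):
        b = report.sd_band
        ax.axhline(b.center, color="tab:blue", lw=1.2, label="baseline mean")
        for y in (b.lower, b.upper):
            ax.axhline(y, color="tab:blue", ls="--", lw=1)
        ax.set_title(f"{b.k:g}-SD band projected from baseline")

    @staticmethod
    def stability_envelope(ax, series, report):
        env = report.envelope
        t = series.times.astype(float)
        fit = env.trend.predict(t)
        ax.plot(t, fit, color="tab:green", lw=1.2, label="split-middle trend")
        ax.fill_between(t, fit - env.half_width, fit + env.half_width, color="tab:green", alpha=0.15, label="stability envelope")
        ax.set_title("Split-middle trend + stability envelope")

    @staticmethod
    def combined(ax, series, report):
        pre_line = ols_trend(series.pre, t_offset=0)
        post_line = ols_trend(series.post, t_offset=series.n_pre)
        t_pre = np.arange(1, series.n_pre + 1, dtype=float)
        t_post = np.arange(series.n_pre + 1, series.n + 1, dtype=float)
        ax.plot(t_pre, pre_line.predict(t_pre), color="tab:blue", lw=1.2, label="OLS pre")
        ax.plot(t_post, post_line.predict(t_post), color="tab:orange", lw=1.2, label="OLS post")
        env = report.envelope
        t = series.times.astype(float)
        fit = env.trend.predict(t)
        ax.fill_between(t, fit - env.half_width, fit + env.half_width, color="tab:green", alpha=0.12, label="envelope")
        b = report.sd_band
        for y in (b.lower, b.upper):
            ax.axhline(y, color="tab:blue", ls="--", lw=0.8)
        ax.set_title("Combined view")
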