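"""Data model and I/O for two-phase (AB) single-case series.

A :class:`TwoPhaseSeries` holds one behavioral measurement recorded over
consecutive sessions, split into a pre-intervention (baseline, phase A)
block and a post-intervention (phase B) block, together with the
improvement direction ("aim"): whether lower or higher scores represent
improvement.  Session times are implicitly ``1..n_pre+n_post`` with no
gaps and no missing scores; incomplete series are rejected rather than
imputed.

Two on-disk layouts are supported:

* "long" CSV with columns ``Time,Score,Phase`` where Phase is a block of
  0s followed by a block of 1s;
* "phases" CSV with columns ``pre,post`` of possibly unequal length,
  blank-padded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

Aim = Literal["decrease", "increase"]

_AIMS = ("decrease", "increase")


@dataclass(frozen=True)
class TwoPhaseSeries:
    """An ordered AB series with phase split and improvement direction.

    Attributes
    ----------
    scores:
        All measurements in session order (baseline first), arbitrary
        score units (e.g. ECBI Intensity T-scores).
    n_pre, n_post:
        Number of baseline / intervention sessions; ``n_pre + n_post``
        equals ``len(scores)``.
    aim:
        ``"decrease"`` if lower scores are improvement (e.g. disruptive
        behavior), ``"increase"`` otherwise.  Consumed by every
        directional operation.
    label:
        Free-text identifier used in reports and plots.
    """

    scores: tuple[float, ...]
    n_pre: int
    n_post: int
    aim: Aim = "decrease"
    label: str = ""

    def __post_init__(self):
        if self.aim not in _AIMS:
            raise ValidationError("invalid-aim", f"aim must be one of {_AIMS}, got {self.aim!r}")
        if self.n_pre < 1 or self.n_post < 1:
            raise ValidationError("phase-empty", "each phase needs at least one score")
        if len(self.scores) != self.n_pre + self.n_post:
            raise ValidationError(
                "length-mismatch",
                f"{len(self.scores)} scores but n_pre+n_post = {self.n_pre + self.n_post}",
            )
        for x in self.scores:
            if not math.isfinite(x):
                raise ValidationError("invalid-score", f"non-finite score {x!r}")

    # -- convenience views -------------------------------------------------

    @property
    def n(self) -> int:
        return self.n_pre + self.n_post

    @property
    def pre(self) -> np.ndarray:
        """Baseline scores as a float array."""
        return np.asarray(self.scores[: self.n_pre], dtype=float)

    @property
    def post(self) -> np.ndarray:
        """Intervention scores as a float array."""
        return np.asarray(self.scores[self.n_pre :], dtype=float)

    @property
    def times(self) -> np.ndarray:
        """Session indices 1..n (1-based, derived from position)."""
        return np.arange(1, self.n + 1)

    def to_dict(self) -> dict:
        return {
            "scores": list(self.scores),
            "n_pre": self.n_pre,
            "n_post": self.n_post,
            "aim": self.aim,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoPhaseSeries":
        return cls(
            scores=tuple(float(x) for x in d["scores"]),
            n_pre=int(d["n_pre"]),
            n_post=int(d["n_post"]),
            aim=d.get("aim", "decrease"),
            label=d.get("label", ""),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "TwoPhaseSeries":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class PhaseDescriptives:
    """Per-phase summary statistics in score units."""

    phase: Literal["pre", "post"]
    n: int
    minimum: float
    maximum: float
    mean: float
    median: float
    sd: float
    sd_defined: bool = True  # False when n == 1 (sd reported as 0)

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "n": self.n,
            "minimum": self.minimum,
            "maximum": self.maximum,
            "mean": self.mean,
            "median": self.median,
            "sd": self.sd,
            "sd_defined": self.sd_defined,
        }


def make_series(
    pre_scores: Sequence[float],
    post_scores: Sequence[float],
    aim: Aim = "decrease",
    label: str = "",
) -> TwoPhaseSeries:
    """Build a validated :class:`TwoPhaseSeries` from the two phase lists.

    Raises
    ------
    ValidationError
        ``"phase-empty"`` if either phase is empty, ``"invalid-score"``
        if any value is NaN/inf or not numeric.
    """
    pre = _coerce_scores(pre_scores)
    post = _coerce_scores(post_scores)
    if len(pre) == 0 or len(post) == 0:
        raise ValidationError("phase-empty", "both phases must contain at least one score")
    return TwoPhaseSeries(
        scores=tuple(pre) + tuple(post),
        n_pre=len(pre),
        n_post=len(post),
        aim=aim,
        label=label,
    )


def _coerce_scores(values: Iterable) -> list[float]:
    out = []
    for v in values:
        try:
            x = float(v)
        except (TypeError, ValueError) as exc:
            raise ValidationError("invalid-score", f"cannot interpret {v!r} as a score") from exc
        if not math.isfinite(x):
            raise ValidationError("invalid-score", f"non-finite score {v!r}")
        out.append(x)
    return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_long_csv(path, aim: Aim = "decrease", sep: str = ",", label: str = "") -> TwoPhaseSeries:
    """Read a long-format CSV (``Time,Score,Phase``) into a series.

    ``Phase`` must be a contiguous block of 0s followed by a contiguous
    block of 1s; ``Time`` must be 1..n in order (it is validated, but the
    internal representation derives time from row position).

    Raises
    ------
    ValidationError
        ``"phase-empty"`` for an empty file or a missing phase,
        ``"non-contiguous-phases"`` if a 0 follows a 1,
        ``"bad-time-index"`` if Time is not 1..n consecutive,
        ``"bad-header"`` if the required columns are missing.
    """
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise ValidationError("phase-empty", "empty input file") from None
    missing = {"Time", "Score", "Phase"} - set(df.columns)
    if missing:
        raise ValidationError("bad-header", f"missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValidationError("phase-empty", "no data rows")

    phase = df["Phase"].to_numpy()
    if not np.isin(phase, (0, 1)).all():
        raise ValidationError("non-contiguous-phases", "Phase values must be 0 or 1")
    # once phase hits 1 it must stay 1
    if np.any(np.diff(phase.astype(int)) < 0):
        raise ValidationError("non-contiguous-phases", "Phase 0 found after a Phase 1 row")

    times = df["Time"].to_numpy()
    if not np.array_equal(times, np.arange(1, len(df) + 1)):
        raise ValidationError("bad-time-index", "Time must be consecutive 1..n")

    n_pre = int((phase == 0).sum())
    n_post = len(df) - n_pre
    if n_pre == 0 or n_post == 0:
        raise ValidationError("phase-empty", "both phases must be present")
    scores = _coerce_scores(df["Score"].tolist())
    return TwoPhaseSeries(tuple(scores), n_pre, n_post, aim=aim, label=label)


def write_long_csv(series: TwoPhaseSeries, path, sep: str = ",") -> None:
    """Write the long layout; numeric content round-trips through
    :func:`read_long_csv` bit-identically for plain decimal inputs."""
    df = pd.DataFrame(
        {
            "Time": series.times,
            "Score": [repr(s) if s != int(s) else str(int(s)) for s in series.scores],
            "Phase": [0] * series.n_pre + [1] * series.n_post,
        }
    )
    df.to_csv(path, sep=sep, index=False)


def read_phases_csv(path, aim: Aim = "decrease", sep: str = ",", label: str = "") -> TwoPhaseSeries:
    """Read a two-column CSV (``pre,post``) with blank padding for the
    shorter phase."""
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise ValidationError("phase-empty", "empty input file") from None
    missing = {"pre", "post"} - set(df.columns)
    if missing:
        raise ValidationError("bad-header", f"missing columns: {sorted(missing)}")
    pre = df["pre"].dropna().tolist()
    post = df["post"].dropna().tolist()
    return make_series(pre, post, aim=aim, label=label)


def write_phases_csv(series: TwoPhaseSeries, path, sep: str = ",") -> None:
    n = max(series.n_pre, series.n_post)
    pre = list(series.pre) + [np.nan] * (n - series.n_pre)
    post = list(series.post) + [np.nan] * (n - series.n_post)
    pd.DataFrame({"pre": pre, "post": post}).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def phase_descriptives(series: TwoPhaseSeries, ddof: int = 1) -> tuple[PhaseDescriptives, PhaseDescriptives]:
    """Per-phase min/max/mean/median/sd.

    The standard deviation uses the sample (n−1) convention by default
    (``ddof=1``); for a single-point phase the sd is undefined and is
    reported as 0 with ``sd_defined=False``.
    """
    return (
        _describe("pre", series.pre, ddof),
        _describe("post", series.post, ddof),
    )


def _describe(phase: str, x: np.ndarray, ddof: int) -> PhaseDescriptives:
    defined = len(x) > ddof
    sd = float(np.std(x, ddof=ddof)) if defined else 0.0
    return PhaseDescriptives(
        phase=phase,
        n=len(x),
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        mean=float(np.mean(x)),
        median=float(np.median(x)),
        sd=sd,
        sd_defined=defined,
    )
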