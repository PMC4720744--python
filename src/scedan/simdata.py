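"""Synthetic AB-series generation.

The generator mirrors the slope-and-level-change decomposition exactly,
so the SLC estimators recover the generating parameters to machine
precision in the noiseless case:

    y_t       = level + trend*(t-1)                                   t <= n_pre
    y_{n_pre+j} = level + trend*(n_pre+j-1) + level_change
                  + slope_change*(j-1)                                j = 1..n_post

On top of the deterministic part sits a zero-mean AR(1) noise process —
the standard serial-dependence assumption for measurements repeated on
the same individual — with innovations i.i.d. N(0, noise_sd²).  Note
that ``noise_sd`` parameterizes the *innovation*, not the marginal noise
SD (which is ``noise_sd / sqrt(1 - phi²)`` at stationarity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import TwoPhaseSeries, Aim, make_series
from .errors import ValidationError
from .nonoverlap import nap

_BURN_IN = 100  # AR(1) warm-up steps towards stationarity


@dataclass(frozen=True)
class SimulationSpec:
    """Generative parameters for one synthetic AB series."""

    n_pre: int = 5
    n_post: int = 10
    level: float = 0.0  # baseline intercept, score units
    trend: float = 0.0  # baseline slope per session
    level_change: float = 0.0  # additive post-phase shift
    slope_change: float = 0.0  # extra post-phase slope per post-session
    phi: float = 0.0  # AR(1) coefficient, |phi| < 1
    noise_sd: float = 1.0  # innovation SD
    aim: Aim = "decrease"
    seed: int = 0

    def __post_init__(self):
        if self.n_pre < 1 or self.n_post < 1:
            raise ValidationError("invalid-spec", "phase counts must be >= 1")
        if not abs(self.phi) < 1:
            raise ValidationError("invalid-spec", f"|phi| must be < 1, got {self.phi}")
        if self.noise_sd < 0:
            raise ValidationError("invalid-spec", "noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return {
            "n_pre": self.n_pre,
            "n_post": self.n_post,
            "level": self.level,
            "trend": self.trend,
            "level_change": self.level_change,
            "slope_change": self.slope_change,
            "phi": self.phi,
            "noise_sd": self.noise_sd,
            "aim": self.aim,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        return cls(**d)


def deterministic_part(spec: SimulationSpec) -> np.ndarray:
    """The noiseless series implied by the spec."""
    t = np.arange(spec.n_pre + spec.n_post, dtype=float)  # 0-based position
    y = spec.level + spec.trend * t
    j = np.arange(spec.n_post, dtype=float)
    y[spec.n_pre :] += spec.level_change + spec.slope_change * j
    return y


def ar1_noise(n: int, phi: float, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean AR(1) draw of length ``n`` with a burn-in for
    stationarity; ``noise_sd`` scales the innovations."""
    if noise_sd == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, noise_sd, size=_BURN_IN + n)
    e = np.empty(_BURN_IN + n)
    e[0] = innov[0]
    for t in range(1, _BURN_IN + n):
        e[t] = phi * e[t - 1] + innov[t]
    return e[_BURN_IN:]


def simulate_ab(spec: SimulationSpec) -> TwoPhaseSeries:
    """Generate one AB series; identical specs (including seed) produce
    bit-identical series."""
    rng = np.random.default_rng(spec.seed)
    y = deterministic_part(spec) + ar1_noise(spec.n_pre + spec.n_post, spec.phi, spec.noise_sd, rng)
    return make_series(y[: spec.n_pre], y[spec.n_pre :], aim=spec.aim, label=f"sim-seed{spec.seed}")


def null_nap_calibration(
    n_pre: int = 5,
    n_post: int = 10,
    reps: int = 10_000,
    seed: int = 0,
    noise_sd: float = 1.0,
    aim: Aim = "decrease",
) -> tuple[float, float]:
    """Monte Carlo mean of NAP under a no-effect null.

    Each replicate draws both phases i.i.d. from the same continuous
    (normal) distribution — no trend, no level or slope change, no
    serial dependence — so the expected NAP is the chance level 0.5.

    Returns
    -------
    (mean, se):
        Monte Carlo mean of NAP (proportion scale) and its standard
        error; ``se`` is NaN for a single replicate.
    """
    if reps < 1:
        raise ValidationError("invalid-spec", "reps must be >= 1")
    rng = np.random.default_rng(seed)
    values = np.empty(reps)
    for r in range(reps):
        y = rng.normal(0.0, noise_sd, size=n_pre + n_post)
        s = make_series(y[:n_pre], y[n_pre:], aim=aim)
        values[r] = nap(s).nap
    mean = float(values.mean())
    se = float(values.std(ddof=1) / math.sqrt(reps)) if reps > 1 else float("nan")
    return mean, se


def series_from_pair_counts(
    n_pre: int,
    n_post: int,
    n_improving: int,
    n_ties: int = 0,
    aim: Aim = "decrease",
) -> TwoPhaseSeries:
    """Construct a series realizing given NAP pairwise counts exactly.

    Useful for building fixtures that reproduce a published pairwise
    tally (improving / tied / deteriorating counts) without the raw
    data.  Baseline scores are placed on a fixed grid; each intervention
    score is positioned to contribute a chosen number of improving
    pairs; ties are realized as exact equality with a baseline score.
    """
    total = n_pre * n_post
    if n_improving < 0 or n_ties < 0 or n_improving + n_ties > total:
        raise ValidationError("invalid-spec", "pair counts must be non-negative and sum <= n_pre*n_post")
    if n_ties > n_post:
        raise ValidationError(
            "invalid-spec",
            "this constructor realizes at most one tie per intervention score",
        )
    if n_improving > (n_post - n_ties) * n_pre:
        raise ValidationError("invalid-spec", "pair counts not realizable")
    pre = [float(10 * (i + 1)) for i in range(n_pre)]  # distinct grid 10, 20, ...
    # a tie at the *worst* baseline value adds a single tied pair and no
    # improving pairs (it deteriorates against every other baseline score)
    tie_value = max(pre) if aim == "decrease" else min(pre)
    post: list[float] = [tie_value] * n_ties
    remaining = n_improving
    for _ in range(n_post - n_ties):
        c = min(n_pre, remaining)
        remaining -= c
        # a value strictly between grid points improves exactly c of the
        # baseline scores and ties none
        post.append(float(10 * (n_pre - c) + 5) if aim == "decrease" else float(10 * c + 5))
    return make_series(pre, post, aim=aim, label="pair-count fixture")
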