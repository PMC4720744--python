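"""Non-overlap of All Pairs (NAP).

NAP compares every baseline score against every intervention score —
``n_pre * n_post`` ordered pairs — and reports the proportion of pairs
in which the intervention value improves the baseline value, with exact
ties counting as half an improvement:

    NAP = (#improving + 0.5 * #ties) / (n_pre * n_post)

"Improves" follows the series' aim: post < pre when a decrease is the
goal, post > pre otherwise.  NAP is an ordinal measure — invariant under
any strictly increasing rescaling of the scores — and coincides with the
nonparametric probability of superiority: the probability that a
randomly chosen intervention point improves a randomly chosen baseline
point.  Under no behavioral change its chance level is 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import TwoPhaseSeries
from .errors import ValidationError

#: Default interpretive bands: upper bound of each category, upper-closed.
#: Only the small/medium boundary (0.65) is universal in the NAP
#: literature for AB data; the medium/large split at 0.92 follows the
#: index's original calibration and is configurable.
DEFAULT_BANDS: tuple[tuple[str, float], ...] = (
    ("small", 0.65),
    ("medium", 0.92),
    ("large", 1.0),
)


@dataclass(frozen=True)
class NapResult:
    """Pairwise counts plus the NAP value and interpretive category."""

    n_comparisons: int
    n_improving: int
    n_ties: int
    n_deteriorating: int
    nap: float
    nap_percent: float
    category: str

    def to_dict(self) -> dict:
        return {
            "comparisons": self.n_comparisons,
            "improving": self.n_improving,
            "ties": self.n_ties,
            "deteriorating": self.n_deteriorating,
            "nap": self.nap,
            "nap_percent": self.nap_percent,
            "category": self.category,
        }


def pairwise_counts(series: TwoPhaseSeries, tie_tol: float = 0.0) -> tuple[int, int, int]:
    """Count (improving, tied, deteriorating) pairs over all
    ``n_pre * n_post`` ordered (pre, post) pairs.

    A pair is *improving* when the post value improves the pre value in
    the direction of ``series.aim``; values within ``tie_tol`` of each
    other (default: exact equality) are ties.
    """
    if tie_tol < 0:
        raise ValidationError("invalid-tolerance", "tie_tol must be >= 0")
    sign = -1.0 if series.aim == "decrease" else 1.0
    improving = ties = 0
    for a in series.pre:
        for b in series.post:
            d = sign * (b - a)  # > 0 means the post value is better
            if abs(b - a) <= tie_tol:
                ties += 1
            elif d > 0:
                improving += 1
    total = series.n_pre * series.n_post
    return improving, ties, total - improving - ties


def nap(
    series: TwoPhaseSeries,
    tie_tol: float = 0.0,
    bands: Sequence[tuple[str, float]] = DEFAULT_BANDS,
) -> NapResult:
    """Compute NAP with its pairwise counts and interpretive category."""
    improving, ties, deteriorating = pairwise_counts(series, tie_tol=tie_tol)
    total = improving + ties + deteriorating
    value = (improving + 0.5 * ties) / total
    return NapResult(
        n_comparisons=total,
        n_improving=improving,
        n_ties=ties,
        n_deteriorating=deteriorating,
        nap=value,
        nap_percent=round(100.0 * value, 2),
        category=classify_nap(value, bands),
    )


def classify_nap(value: float, bands: Sequence[tuple[str, float]] = DEFAULT_BANDS) -> str:
    """Map a NAP proportion to its category label.

    ``bands`` is a sequence of ``(label, upper_bound)`` pairs with
    strictly increasing bounds ending at 1.0; each band is closed at its
    upper end, so 0.65 itself is still "small" under the defaults.
    """
    if not 0.0 <= value <= 1.0:
        raise ValidationError("invalid-bands", f"nap value {value} outside [0, 1]")
    bounds = [b for _, b in bands]
    if not bands or bounds != sorted(bounds) or len(set(bounds)) != len(bounds) or bounds[-1] != 1.0:
        raise ValidationError("invalid-bands", "bands must have increasing upper bounds ending at 1.0")
    for label, upper in bands:
        if value <= upper:
            return label
    raise ValidationError("invalid-bands", "bands do not cover [0, 1]")
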