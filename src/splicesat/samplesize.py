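"""Binomial sample-size calculation for splicing-event detection.

If an event of interest is observed in any given sample with probability
``po`` and samples are independent, the probability of seeing it at least
once in ``n`` samples (the detection power) is ``1 - (1 - po)^n``.
Requiring power ``pw`` and solving for ``n`` gives

    n = ln(1 - pw) / ln(1 - po),

rounded up to the next integer — except that an exactly integral quotient
is kept as-is, since it already achieves the requested power with
equality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "SampleSizeResult",
    "required_samples",
    "achieved_power",
    "power_table",
    "categorize",
    "adjust_observation_probability",
]

#: Rule-of-thumb observation-probability bands.
RARE_BELOW = 0.15
REGULAR_ABOVE = 0.5


def categorize(po: float) -> str:
    """Rule-of-thumb band: rare (<0.15), occasional (0.15-0.5), regular (>0.5).

    Band edges are assigned to "occasional".
    """
    if po < RARE_BELOW:
        return "rare"
    if po > REGULAR_ABOVE:
        return "regular"
    return "occasional"


@dataclass(frozen=True)
class SampleSizeResult:
    """Required batch size for one observation probability / power pair."""

    po: float
    pw: float
    n_required: int
    achieved_power: float
    category: str

    def __str__(self) -> str:
        return (
            f"po={self.po:g} ({self.category}): n={self.n_required} "
            f"samples, achieved power {self.achieved_power:.3f} (>= {self.pw:g})"
        )


def required_samples(po: float, pw: float) -> SampleSizeResult:
    """Smallest batch size detecting an event with power ``pw``.

    Parameters
    ----------
    po : float
        Per-sample observation probability of the event, in (0, 1).
        (``po = 1`` would trivially need a single sample.)
    pw : float
        Required detection power, in (0, 1).
    """
    if not 0.0 < po < 1.0:
        raise ValueError(
            f"po must be in (0, 1), got {po}; po=1 trivially needs n=1"
        )
    if not 0.0 < pw < 1.0:
        raise ValueError(
            f"pw must be in (0, 1), got {pw}; pw=1 is unattainable for po<1"
        )
    quotient = math.log1p(-pw) / math.log1p(-po)
    n = max(1, math.ceil(quotient))
    # Guard the ceiling against representation error on near-integral
    # quotients: n must be minimal with achieved power >= pw.
    while n > 1 and achieved_power(po, n - 1) >= pw:
        n -= 1
    while achieved_power(po, n) < pw:
        n += 1
    return SampleSizeResult(
        po=po,
        pw=pw,
        n_required=n,
        achieved_power=achieved_power(po, n),
        category=categorize(po),
    )


def achieved_power(po: float, n: int) -> float:
    """Detection power of ``n`` samples: ``1 - (1 - po)^n``."""
    if not 0.0 < po <= 1.0:
        raise ValueError(f"po must be in (0, 1], got {po}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if po == 1.0:
        return 1.0
    return -math.expm1(n * math.log1p(-po))


DEFAULT_PO_GRID = (0.1, 0.15, 0.2, 0.5, 0.8)


def power_table(
    po_values: Sequence[float] = DEFAULT_PO_GRID, pw: float = 0.8
) -> list[SampleSizeResult]:
    """Required sample sizes over a grid of observation probabilities."""
    return [required_samples(po, pw) for po in po_values]


def adjust_observation_probability(po: float, adjustment) -> float:
    """Rescale ``po`` with a user-supplied alignment-depth adjustment.

    Observation probabilities depend on a sample's alignment depth: the
    same event is seen more reliably in deeper samples.  This package does
    not prescribe a depth model; ``adjustment`` is any callable mapping a
    probability to the depth-adjusted probability (e.g. one calibrated on
    a pilot batch).  The result is validated to stay in (0, 1] so it can
    feed straight into :func:`required_samples`.
    """
    adjusted = float(adjustment(po))
    if not 0.0 < adjusted <= 1.0:
        raise ValueError(
            f"depth adjustment mapped po={po} to {adjusted}, outside (0, 1]"
        )
    return adjusted
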