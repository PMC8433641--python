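"""Shared summary statistics, recovery arithmetic and acceptance rules.

Every stage of an assay-validation report reduces to a handful of
primitives: mean / sample SD / %CV of replicate measurements, percent
recovery of a spiked amount, signed percent relative error (%RE) of a
back-calculated concentration, and the pass/fail comparison of an
observed statistic against a guideline band.  They live here so that
all stages agree on conventions (n-1 standard deviation, full-precision
arithmetic with rounding deferred to report rendering, inclusive bounds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "InvalidInputError",
    "SummaryStats",
    "RecoveryResult",
    "AcceptanceRule",
    "AcceptanceOutcome",
    "summarize",
    "recovery",
    "percent_re",
    "check_rule",
]


class InvalidInputError(ValueError):
    """Raised when an operation receives input violating its preconditions."""


@dataclass(frozen=True)
class SummaryStats:
    """Replicate summary: count, mean, sample SD and coefficient of variation.

    ``sd`` is NaN when fewer than two values are available; ``cv_percent``
    is NaN when the mean is zero (flagged undefined rather than infinite)
    or when the SD itself is unavailable.
    """

    n: int
    mean: float
    sd: float
    cv_percent: float

    @property
    def sd_available(self) -> bool:
        return not math.isnan(self.sd)

    @property
    def cv_defined(self) -> bool:
        return not math.isnan(self.cv_percent)


@dataclass(frozen=True)
class RecoveryResult:
    """Percent recovery of a found concentration against the added amount."""

    added_conc: float
    found_conc: float
    recovery_percent: float


@dataclass(frozen=True)
class AcceptanceRule:
    """An inclusive acceptance band on a named metric (one bound may be open).

    Guideline limits are phrased as bands ("in the range of 80-110%",
    "%CV less than 2"); both bounds are treated as passing values.
    """

    metric_name: str
    lower: Optional[float] = None
    upper: Optional[float] = None
    context: str = ""

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise InvalidInputError("acceptance rule needs at least one bound")
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise InvalidInputError(
                f"lower bound {self.lower} exceeds upper bound {self.upper}"
            )


@dataclass(frozen=True)
class AcceptanceOutcome:
    rule: AcceptanceRule
    observed: float
    passed: bool


def summarize(values: Iterable[float]) -> SummaryStats:
    """Mean, sample (n-1) standard deviation and %CV of a replicate series.

    Parameters
    ----------
    values : iterable of float
        Replicate measurements; must be non-empty.

    Returns
    -------
    SummaryStats
        Full-precision statistics; rounding is a presentation concern.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InvalidInputError("summarize requires at least one value")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("summarize requires finite values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    if math.isnan(sd) or mean == 0.0:
        cv = float("nan")
    else:
        cv = 100.0 * sd / abs(mean)
    return SummaryStats(n=int(arr.size), mean=mean, sd=sd, cv_percent=cv)


def recovery(added: float, found: float) -> RecoveryResult:
    """Percent recovery, ``100 * found / added``; ``added`` must be positive."""
    if not added > 0:
        raise InvalidInputError(f"added concentration must be > 0, got {added}")
    return RecoveryResult(
        added_conc=float(added),
        found_conc=float(found),
        recovery_percent=100.0 * found / added,
    )


def percent_re(found: float, nominal: float) -> float:
    """Signed percent relative error, ``100 * (found - nominal) / nominal``."""
    if not nominal > 0:
        raise InvalidInputError(f"nominal concentration must be > 0, got {nominal}")
    return 100.0 * (found - nominal) / nominal


def check_rule(rule: AcceptanceRule, observed: float) -> AcceptanceOutcome:
    """Evaluate an observed statistic against a rule; bounds are inclusive."""
    if not math.isfinite(observed):
        raise InvalidInputError(f"observed value must be finite, got {observed}")
    ok = True
    if rule.lower is not None and observed < rule.lower:
        ok = False
    if rule.upper is not None and observed > rule.upper:
        ok = False
    return AcceptanceOutcome(rule=rule, observed=float(observed), passed=ok)


def summarize_pairs(pairs: Sequence[tuple[float, float]]) -> list[RecoveryResult]:
    """Vector form of :func:`recovery` over (added, found) pairs."""
    return [recovery(a, f) for a, f in pairs]
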