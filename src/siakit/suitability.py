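"""System suitability, robustness, solution stability and stress bookkeeping.

System suitability verifies the chromatographic system before a run:
injection repeatability (%CV of retention time and peak area over five
replicate injections), peak symmetry (USP tailing factor T), column
efficiency (theoretical plate count N) and separation (resolution Rs),
each against the usual limits (%CV < 2, T < 2, N > 2000, Rs > 2).

Vendor software reports T and N without publishing formulas; the USP
conventions are adopted here: T = W0.05 / (2 f) from the 5%-height
width and front half-width, and N = 5.54 (tR / w_half)² from the
half-height width.  When width columns are absent from an injection
table, tailing/plates are simply omitted from the report (with a note),
since many exports carry the vendor-computed values instead.

The same module holds the robustness comparison (suitability statistics
per perturbed condition), autosampler solution-stability recovery, and
the forced-degradation percent-remaining arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import (
    AcceptanceOutcome,
    AcceptanceRule,
    InvalidInputError,
    SummaryStats,
    check_rule,
    summarize,
)

__all__ = [
    "InjectionRecord",
    "SuitabilityLimits",
    "SuitabilityReport",
    "StressResult",
    "plate_count",
    "tailing_factor",
    "resolution",
    "suitability_report",
    "percent_remaining",
    "robustness_table",
]


@dataclass(frozen=True)
class InjectionRecord:
    """A single replicate injection from a suitability run."""

    injection_id: str
    retention_time: float
    peak_area: float
    width_half_height: Optional[float] = None
    width_5pct: Optional[float] = None
    front_distance_5pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise InvalidInputError("retention time must be > 0")
        if self.peak_area < 0:
            raise InvalidInputError("peak area must be >= 0")
        for name in ("width_half_height", "width_5pct", "front_distance_5pct"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise InvalidInputError(f"{name} must be > 0 when present")


@dataclass(frozen=True)
class SuitabilityLimits:
    cv_max: float = 2.0
    tailing_max: float = 2.0
    plates_min: float = 2000.0
    resolution_min: float = 2.0
    min_injections: int = 5


@dataclass(frozen=True)
class SuitabilityReport:
    rt_stats: SummaryStats
    area_stats: SummaryStats
    tailing: Optional[float]
    plates: Optional[float]
    resolution: Optional[float]
    verdicts: list[AcceptanceOutcome]
    notes: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(v.passed for v in self.verdicts)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"metric": v.rule.metric_name, "observed": v.observed,
             "lower": v.rule.lower, "upper": v.rule.upper, "passed": v.passed}
            for v in self.verdicts
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class StressResult:
    """Percent of analyte remaining after one forced-degradation condition."""

    condition: str
    incubation: str
    remaining_percent: float


def plate_count(retention_time: float, width_half_height: float) -> float:
    """USP theoretical plate count, N = 5.54 (tR / w_half)²."""
    if retention_time <= 0 or width_half_height <= 0:
        raise InvalidInputError("retention time and half-height width must be > 0")
    return 5.54 * (retention_time / width_half_height) ** 2


def tailing_factor(width_5pct: float, front_distance_5pct: float) -> float:
    """USP tailing factor, T = W0.05 / (2 f); 1.0 is a symmetric peak."""
    if width_5pct <= 0 or front_distance_5pct <= 0:
        raise InvalidInputError("5%-height widths must be > 0")
    if front_distance_5pct > width_5pct:
        raise InvalidInputError("front half-width cannot exceed the full width")
    return width_5pct / (2.0 * front_distance_5pct)


def resolution(rt1: float, rt2: float, w1: float, w2: float) -> float:
    """Baseline-width resolution, Rs = 2 (tR2 - tR1) / (w1 + w2); rt2 >= rt1."""
    if rt2 < rt1:
        raise InvalidInputError("rt2 must not precede rt1")
    if w1 <= 0 or w2 <= 0:
        raise InvalidInputError("base widths must be > 0")
    return 2.0 * (rt2 - rt1) / (w1 + w2)


def suitability_report(injections: Sequence[InjectionRecord],
                       limits: SuitabilityLimits = SuitabilityLimits(),
                       resolution_value: Optional[float] = None,
                       tailing_value: Optional[float] = None,
                       plates_value: Optional[float] = None) -> SuitabilityReport:
    """Replicate-injection summary with pass/fail against suitability limits.

    Tailing and plate count are computed from peak widths when the
    injections carry them (averaged over injections); otherwise
    vendor-reported values may be passed via ``tailing_value`` /
    ``plates_value``, and when neither is available those checks are
    omitted with a note rather than failed.
    """
    if len(injections) < limits.min_injections:
        raise InvalidInputError(
            f"need at least {limits.min_injections} injections, got {len(injections)}"
        )
    notes: list[str] = []
    rt_stats = summarize([i.retention_time for i in injections])
    area_stats = summarize([i.peak_area for i in injections])
    verdicts = [
        check_rule(AcceptanceRule("rt_cv_percent", upper=limits.cv_max,
                                  context="suitability"), rt_stats.cv_percent),
        check_rule(AcceptanceRule("area_cv_percent", upper=limits.cv_max,
                                  context="suitability"), area_stats.cv_percent),
    ]

    tailing = tailing_value
    if tailing is None:
        ts = [tailing_factor(i.width_5pct, i.front_distance_5pct)
              for i in injections
              if i.width_5pct is not None and i.front_distance_5pct is not None]
        tailing = float(np.mean(ts)) if ts else None
    if tailing is not None:
        verdicts.append(check_rule(
            AcceptanceRule("tailing_factor", upper=limits.tailing_max,
                           context="suitability"), tailing))
    else:
        notes.append("tailing factor unavailable: no 5%-height widths")

    plates = plates_value
    if plates is None:
        ns = [plate_count(i.retention_time, i.width_half_height)
              for i in injections if i.width_half_height is not None]
        plates = float(np.mean(ns)) if ns else None
    if plates is not None:
        verdicts.append(check_rule(
            AcceptanceRule("plate_count", lower=limits.plates_min,
                           context="suitability"), plates))
    else:
        notes.append("plate count unavailable: no half-height widths")

    if resolution_value is not None:
        verdicts.append(check_rule(
            AcceptanceRule("resolution", lower=limits.resolution_min,
                           context="suitability"), resolution_value))

    return SuitabilityReport(
        rt_stats=rt_stats, area_stats=area_stats, tailing=tailing,
        plates=plates, resolution=resolution_value, verdicts=verdicts,
        notes=notes,
    )


def percent_remaining(stressed_response: float, control_response: float) -> float:
    """Percent analyte remaining, 100 * stressed / control (same nominal conc).

    Values above 100% are reported as computed (area-normalisation drift
    in real stress tables can push a stable condition slightly over).
    """
    if control_response <= 0:
        raise InvalidInputError("control response must be > 0")
    return 100.0 * stressed_response / control_response


def robustness_table(variant_runs: Mapping[str, Sequence[InjectionRecord]],
                     limits: SuitabilityLimits = SuitabilityLimits()) -> pd.DataFrame:
    """Per-condition suitability statistics for robustness comparison.

    Each perturbed condition (mobile-phase variation, column batch, ...)
    gets the same summary a suitability run would; a ``passed`` flag
    marks conditions violating any limit.
    """
    if len(variant_runs) < 2:
        raise InvalidInputError("robustness comparison needs at least two conditions")
    rows = []
    for cond, injections in variant_runs.items():
        rep = suitability_report(injections, limits=limits)
        rows.append({
            "condition": cond,
            "rt_cv_percent": rep.rt_stats.cv_percent,
            "area_cv_percent": rep.area_stats.cv_percent,
            "tailing_factor": rep.tailing,
            "plate_count": rep.plates,
            "passed": rep.passed,
        })
    return pd.DataFrame(rows)
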