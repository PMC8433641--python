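"""LOD/LOQ stage: noise estimation, signal-to-noise, and limit assessment.

Detection and quantitation limits are established here from the
signal-to-noise ratio of low-concentration injections against a blank
(diluent) trace.  Acceptance follows the usual bioanalytical rules:
LOD needs mean S/N >= 3 with injection %CV < 15; LOQ needs S/N >= 10
with recovery inside 80-110% and %CV < 15.

The noise measurement convention must be stated because S/N depends on
it: the default is peak-to-peak noise (max - min of the blank window)
with S/N = 2*signal/amplitude, the pharmacopoeial 2H/h form; an RMS
alternative (sample SD of the blank, S/N = signal/amplitude) is
available.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .stats import (
    AcceptanceRule,
    InvalidInputError,
    RecoveryResult,
    SummaryStats,
    check_rule,
    recovery,
    summarize,
)

__all__ = [
    "NoiseMethod",
    "NoiseEstimate",
    "SnResult",
    "LodLoqAssessment",
    "estimate_noise",
    "signal_to_noise",
    "assess_lod",
    "assess_loq",
]

SN_MIN_LOD = 3.0
SN_MIN_LOQ = 10.0
CV_MAX_LIMIT = 15.0
RECOVERY_BAND = (80.0, 110.0)


class NoiseMethod(enum.Enum):
    PEAK_TO_PEAK = "peak_to_peak"
    RMS = "rms"


@dataclass(frozen=True)
class NoiseEstimate:
    method: NoiseMethod
    amplitude: float
    window: str = "blank trace"
    degenerate: bool = False


@dataclass(frozen=True)
class SnResult:
    signal: float
    noise: NoiseEstimate
    sn: float
    convention: str


@dataclass(frozen=True)
class LodLoqAssessment:
    """Verdict at a detection/quantitation limit with its supporting stats."""

    nominal_conc: float
    sn_values: list[float]
    summary: SummaryStats
    verdict: bool
    reasons: list[str]
    recoveries: list[RecoveryResult] = field(default_factory=list)


def estimate_noise(blank_values: Sequence[float],
                   method: "str | NoiseMethod" = NoiseMethod.PEAK_TO_PEAK,
                   window: str = "blank trace") -> NoiseEstimate:
    """Noise amplitude of a blank trace.

    peak_to_peak -> max - min; rms -> sample SD.  A constant blank gives
    zero amplitude and is flagged degenerate rather than raising.
    """
    method = NoiseMethod(method) if not isinstance(method, NoiseMethod) else method
    arr = np.asarray(blank_values, dtype=float)
    if arr.size < 2:
        raise InvalidInputError("noise estimation needs at least two blank samples")
    if method is NoiseMethod.PEAK_TO_PEAK:
        amp = float(arr.max() - arr.min())
    else:
        amp = float(arr.std(ddof=1))
    return NoiseEstimate(method=method, amplitude=amp, window=window,
                         degenerate=amp == 0.0)


def signal_to_noise(signal: float, noise: NoiseEstimate) -> SnResult:
    """S/N under the noise estimate's convention.

    Peak-to-peak amplitude h gives sn = 2*signal/h (signal measured as
    peak height H above baseline, the 2H/h pharmacopoeial form); RMS
    amplitude gives sn = signal/amplitude.  A non-positive signal yields
    sn = 0.
    """
    if noise.amplitude <= 0:
        raise InvalidInputError("noise amplitude must be > 0 for S/N")
    if signal <= 0:
        return SnResult(signal=float(signal), noise=noise, sn=0.0,
                        convention=noise.method.value)
    if noise.method is NoiseMethod.PEAK_TO_PEAK:
        sn = 2.0 * signal / noise.amplitude
    else:
        sn = signal / noise.amplitude
    return SnResult(signal=float(signal), noise=noise, sn=sn,
                    convention=noise.method.value)


def _sn_list(responses: Sequence[float], noise: NoiseEstimate) -> list[float]:
    return [signal_to_noise(r, noise).sn for r in responses]


def assess_lod(responses: Sequence[float], noise: NoiseEstimate,
               conc: float) -> LodLoqAssessment:
    """LOD verdict: mean S/N >= 3 and response %CV < 15 over the injections."""
    if len(responses) < 3:
        raise InvalidInputError("LOD assessment needs at least three injections")
    sn_values = _sn_list(responses, noise)
    stats = summarize(responses)
    reasons = []
    mean_sn = float(np.mean(sn_values))
    if not mean_sn >= SN_MIN_LOD:
        reasons.append(f"mean S/N {mean_sn:.2f} < {SN_MIN_LOD:g}")
    if not (stats.cv_defined and stats.cv_percent < CV_MAX_LIMIT):
        reasons.append(f"response %CV {stats.cv_percent:.2f} not < {CV_MAX_LIMIT:g}")
    return LodLoqAssessment(
        nominal_conc=float(conc), sn_values=sn_values, summary=stats,
        verdict=not reasons, reasons=reasons,
    )


def assess_loq(added: float, found: Sequence[float],
               sn_values: Sequence[float]) -> LodLoqAssessment:
    """LOQ verdict: mean S/N >= 10, recovery in 80-110%, found %CV < 15.

    The S/N criterion applies to the mean across injections (an
    individual injection may dip below 10 while the level still
    quantifies reliably on average).
    """
    if len(found) < 3 or len(sn_values) < 3:
        raise InvalidInputError("LOQ assessment needs at least three injections")
    recs = [recovery(added, f) for f in found]
    stats = summarize(found)
    band = AcceptanceRule("recovery_percent", *RECOVERY_BAND, context="LOQ")
    reasons = []
    mean_sn = float(np.mean(sn_values))
    if not mean_sn >= SN_MIN_LOQ:
        reasons.append(f"mean S/N {mean_sn:.2f} < {SN_MIN_LOQ:g}")
    bad_rec = [r.recovery_percent for r in recs
               if not check_rule(band, r.recovery_percent).passed]
    if bad_rec:
        reasons.append(
            f"{len(bad_rec)} recovery value(s) outside {RECOVERY_BAND[0]:g}-{RECOVERY_BAND[1]:g}%"
        )
    if not (stats.cv_defined and stats.cv_percent < CV_MAX_LIMIT):
        reasons.append(f"found-conc %CV {stats.cv_percent:.2f} not < {CV_MAX_LIMIT:g}")
    return LodLoqAssessment(
        nominal_conc=float(added), sn_values=[float(s) for s in sn_values],
        summary=stats, verdict=not reasons, reasons=reasons, recoveries=recs,
    )
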