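"""Seeded synthetic peak-table generators emulating the assay's instrument.

No raw detector data ship with a typical validation report, so every
pipeline input can instead be simulated with the statistical structure
the analysis assumes:

* calibration responses linear in concentration over 0.10-25 µg/mL with
  heteroscedastic Gaussian noise whose SD grows with the expected
  response (sd(y) = sqrt((cv * E[y])² + sd0²), proportional-dominant by
  default with cv = 2%);
* replicate suitability injections with sub-percent CV on retention
  time and area, optionally with an exponentially modified Gaussian
  peak sampled on a time grid so width-based metrics have ground truth;
* zero-mean Gaussian blank traces for S/N noise estimation;
* first/zero/second-order decay time courses (C0 = 5 µg/mL, triplicate,
  13 points over 24 h by default) with the same noise model.

Determinism: each generator derives its random stream from the spec's
integer seed plus a fixed per-kind stream tag, so identical specs give
byte-identical tables and adding a new fixture kind never perturbs the
existing ones.  Negative simulated responses/concentrations are
resampled (not clipped) so log transforms stay valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationData
from .kinetics import KineticTimeCourse, ReactionOrder
from .stats import InvalidInputError
from .suitability import InjectionRecord

__all__ = [
    "NoiseModel",
    "CalibrationSimSpec",
    "DecaySimSpec",
    "SuitabilitySimSpec",
    "gen_calibration",
    "gen_decay",
    "gen_suitability",
    "gen_blank",
    "gen_peak",
    "measure_peak",
]

# fixed stream tags: one integer seed drives an independent stream per fixture kind
_STREAMS = {"calibration": 1, "decay": 2, "suitability": 3, "blank": 4, "peak": 5}


def _rng(seed: int, kind: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[kind], int(seed)])


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian noise with SD = sqrt((cv * mean)² + sd0²).

    ``cv`` is the proportional part (fraction of the expected value),
    ``sd0`` the additive floor in response units.
    """

    cv: float = 0.02
    sd0: float = 0.0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.sd0 < 0:
            raise InvalidInputError("noise parameters must be >= 0")

    def sd(self, mean) -> np.ndarray:
        mean = np.asarray(mean, dtype=float)
        return np.sqrt((self.cv * mean) ** 2 + self.sd0**2)

    def perturb(self, mean, rng: np.random.Generator,
                positive: bool = True, max_resample: int = 100) -> np.ndarray:
        """Draw mean + noise; resample any non-positive draws."""
        mean = np.asarray(mean, dtype=float)
        sd = self.sd(mean)
        out = rng.normal(mean, sd)
        if positive:
            for _ in range(max_resample):
                bad = out <= 0
                if not bad.any():
                    break
                out[bad] = rng.normal(mean[bad], sd[bad])
            else:
                raise InvalidInputError("could not draw positive values; noise too large")
        return out


@dataclass(frozen=True)
class CalibrationSimSpec:
    """Design of a simulated calibration run (defaults: the 6-level
    0.10-25 µg/mL triplicate design with slope ~7000, small negative
    intercept, 2% proportional noise)."""

    levels: tuple[float, ...] = (0.10, 1.0, 3.0, 8.0, 15.0, 25.0)
    replicates: int = 3
    true_slope: float = 7000.0
    true_intercept: float = -60.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        if np.any(lv <= 0) or np.unique(lv).size != lv.size:
            raise InvalidInputError("levels must be positive and distinct")
        if self.replicates < 1:
            raise InvalidInputError("replicates must be >= 1")


@dataclass(frozen=True)
class DecaySimSpec:
    """Design of a simulated degradation time course (defaults: C0 = 5
    µg/mL, first order, 13 equispaced points over 0-24 h, triplicate,
    2% proportional noise)."""

    c0: float = 5.0
    k_true: float = 0.045
    order: ReactionOrder = ReactionOrder.FIRST
    times: tuple[float, ...] = tuple(float(t) for t in np.linspace(0.0, 24.0, 13))
    replicates: int = 3
    noise: NoiseModel = field(default_factory=NoiseModel)
    condition: str = "pH 1.2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c0 <= 0 or self.k_true <= 0:
            raise InvalidInputError("c0 and k_true must be > 0")
        if self.replicates < 1 or len(self.times) < 3:
            raise InvalidInputError("need >= 1 replicate and >= 3 time points")
        object.__setattr__(self, "order", ReactionOrder.parse(self.order))

    def true_curve(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.order is ReactionOrder.ZERO:
            return self.c0 - self.k_true * t
        if self.order is ReactionOrder.FIRST:
            return self.c0 * np.exp(-self.k_true * t)
        return self.c0 / (1.0 + self.k_true * self.c0 * t)


@dataclass(frozen=True)
class SuitabilitySimSpec:
    """Design of a simulated suitability run (five injections with
    sub-percent CVs around the observed retention time / area scale)."""

    n_injections: int = 5
    rt_mean: float = 2.43
    rt_cv: float = 0.002
    area_mean: float = 56000.0
    area_cv: float = 0.005
    peak_sigma_min: float = 0.02
    peak_tau_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_injections < 1:
            raise InvalidInputError("need at least one injection")
        if self.rt_mean <= 0 or self.area_mean <= 0:
            raise InvalidInputError("means must be > 0")
        if not (0 <= self.rt_cv < 0.5 and 0 <= self.area_cv < 0.5):
            raise InvalidInputError("CVs must be small non-negative fractions")


def gen_calibration(spec: CalibrationSimSpec) -> CalibrationData:
    """Simulate replicate calibration responses y = a + b x + ε."""
    rng = _rng(spec.seed, "calibration")
    conc, resp, rep = [], [], []
    for lev in spec.levels:
        mu = spec.true_intercept + spec.true_slope * lev
        y = spec.noise.perturb(np.full(spec.replicates, mu), rng)
        conc.extend([lev] * spec.replicates)
        resp.extend(y.tolist())
        rep.extend(range(1, spec.replicates + 1))
    return CalibrationData(
        conc=np.array(conc), response=np.array(resp), replicate=np.array(rep)
    )


def gen_decay(spec: DecaySimSpec) -> list[KineticTimeCourse]:
    """Simulate replicate decay time courses under the spec's rate law."""
    rng = _rng(spec.seed, "decay")
    t = np.asarray(spec.times, dtype=float)
    truth = spec.true_curve(t)
    if np.any(truth <= 0):
        raise InvalidInputError("true curve hits zero inside the time grid")
    return [
        KineticTimeCourse(
            condition=spec.condition, replicate_id=f"rep{j + 1}",
            times=t, concentrations=spec.noise.perturb(truth, rng),
        )
        for j in range(spec.replicates)
    ]


def gen_suitability(spec: SuitabilitySimSpec) -> list[InjectionRecord]:
    """Simulate replicate suitability injections.

    Width fields are derived from the spec's peak shape: a Gaussian of
    SD sigma (optionally exponentially tailed with time constant tau)
    has half-height width 2.355 sigma; the 5%-height width and front
    half-width are measured numerically from the synthetic peak so the
    tailing factor has a shape-consistent ground truth.
    """
    rng = _rng(spec.seed, "suitability")
    rts = rng.normal(spec.rt_mean, spec.rt_cv * spec.rt_mean, spec.n_injections)
    areas = rng.normal(spec.area_mean, spec.area_cv * spec.area_mean, spec.n_injections)
    records = []
    for i in range(spec.n_injections):
        t, y = gen_peak(rt=float(rts[i]), sigma=spec.peak_sigma_min,
                        tau=spec.peak_tau_min, area=float(areas[i]))
        widths = measure_peak(t, y)
        records.append(InjectionRecord(
            injection_id=f"inj{i + 1}",
            retention_time=float(rts[i]),
            peak_area=float(areas[i]),
            width_half_height=widths["width_half_height"],
            width_5pct=widths["width_5pct"],
            front_distance_5pct=widths["front_distance_5pct"],
        ))
    return records


def gen_blank(n: int, sd: float, seed: int) -> np.ndarray:
    """Zero-mean Gaussian blank trace for noise estimation."""
    if n < 2:
        raise InvalidInputError("need at least two blank samples")
    if sd < 0:
        raise InvalidInputError("sd must be >= 0")
    rng = _rng(seed, "blank")
    if sd == 0:
        return np.zeros(n)
    return rng.normal(0.0, sd, n)


def gen_peak(rt: float, sigma: float, tau: float = 0.0, area: float = 1.0,
             n_grid: int = 4001, span_sigmas: float = 12.0) -> tuple[np.ndarray, np.ndarray]:
    """Sample a single chromatographic peak on a time grid.

    ``tau = 0`` gives a pure Gaussian centred at ``rt``; ``tau > 0`` an
    exponentially modified Gaussian (tailing) computed by direct
    convolution quadrature on the grid.
    """
    if sigma <= 0:
        raise InvalidInputError("sigma must be > 0")
    half = span_sigmas * sigma + 6.0 * tau
    t = np.linspace(rt - half, rt + half, n_grid)
    gauss = np.exp(-0.5 * ((t - rt) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    if tau > 0:
        dt = t[1] - t[0]
        decay_len = int(np.ceil(8.0 * tau / dt)) + 1
        s = np.arange(decay_len) * dt
        kernel = np.exp(-s / tau) / tau
        kernel /= kernel.sum() * dt
        y = np.convolve(gauss, kernel)[: t.size] * dt
    else:
        y = gauss
    return t, area * y


def measure_peak(t: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Numeric width measurements of a single sampled peak.

    Returns the half-height width, the 5%-height width, the front
    half-width at 5% height (apex to leading edge) and the baseline
    (4 sigma-equivalent, 13.4%-height) width, by linear interpolation of
    the level crossings.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    apex = int(np.argmax(y))
    ymax = y[apex]
    if ymax <= 0:
        raise InvalidInputError("peak has no positive apex")

    def crossings(level: float) -> tuple[float, float]:
        thresh = level * ymax
        left = np.nonzero(y[: apex + 1] < thresh)[0]
        right = np.nonzero(y[apex:] < thresh)[0]
        if left.size == 0 or right.size == 0:
            raise InvalidInputError("peak not resolved to baseline on the grid")
        i = left[-1]
        frac = (thresh - y[i]) / (y[i + 1] - y[i])
        t_left = t[i] + frac * (t[i + 1] - t[i])
        j = apex + right[0]
        frac = (y[j - 1] - thresh) / (y[j - 1] - y[j])
        t_right = t[j - 1] + frac * (t[j] - t[j - 1])
        return t_left, t_right

    l50, r50 = crossings(0.5)
    l05, r05 = crossings(0.05)
    # 4-sigma Gaussian baseline width corresponds to the 13.4%-height crossing
    lb, rb = crossings(np.exp(-2.0))
    t_apex = t[apex]
    return {
        "width_half_height": r50 - l50,
        "width_5pct": r05 - l05,
        "front_distance_5pct": t_apex - l05,
        "width_base": rb - lb,
        "apex_time": t_apex,
    }
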