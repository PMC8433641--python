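"""Degradation-kinetics stage: rate-law fitting, order selection, k and t½.

A drug degrading in buffer at fixed pH and temperature is screened
against the three common integrated rate laws by linearising each:

========  =================  ==================  =====================
order     linear transform   rate constant       half-life
========  =================  ==================  =====================
zero      C  vs t            k = -slope          t½ = C0 / (2 k)
first     ln C  vs t         k = -slope          t½ = ln 2 / k
second    1/C  vs t          k = +slope          t½ = 1 / (k C0)
========  =================  ==================  =====================

The order is chosen by the graphic method: fit every replicate under
every order, average r² (on the transformed scale, i.e. the scale of
the fitted line) per order, and pick the maximum, breaking ties toward
the lower order.

Replicate aggregation: each replicate time course is fitted on its own;
k and t½ are then averaged across replicates (mean ± sample SD).  Note
this makes the reported mean t½ differ from ln2 / k_mean — by Jensen's
inequality mean(ln2 / k_i) >= ln2 / mean(k_i) for positive k_i — which
is the convention real stability reports follow.

``DegradationKinetics(timecourses)`` is the model object;
``fit(order)`` and ``select_order()`` return a :class:`KineticsResults`
with the per-order r² table, k_mean ± SD, t½ mean ± SD and ``summary()``.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stats import InvalidInputError, summarize

__all__ = [
    "ReactionOrder",
    "KineticTimeCourse",
    "KineticFit",
    "DegradationKinetics",
    "KineticsResults",
    "fit_order",
    "select_order",
    "half_life",
    "summarize_kinetics",
]

ORDER_SEQUENCE = ("zero", "first", "second")


class ReactionOrder(enum.Enum):
    """Rate-law order with its linearising transform and slope sign."""

    ZERO = "zero"
    FIRST = "first"
    SECOND = "second"

    @classmethod
    def parse(cls, label: "str | ReactionOrder") -> "ReactionOrder":
        if isinstance(label, ReactionOrder):
            return label
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            raise InvalidInputError(f"unknown reaction order {label!r}") from None

    def transform(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        if self is ReactionOrder.ZERO:
            return conc
        if np.any(conc <= 0):
            bad = int(np.argmax(conc <= 0))
            raise InvalidInputError(
                f"non-positive concentration at index {bad} "
                f"({conc[bad]!r}) invalid for {self.value}-order transform"
            )
        if self is ReactionOrder.FIRST:
            return np.log(conc)
        return 1.0 / conc

    def k_from_slope(self, slope: float) -> float:
        # degradation depletes C: slope < 0 for zero/first, > 0 for second
        return slope if self is ReactionOrder.SECOND else -slope

    def c0_from_intercept(self, intercept: float) -> float:
        if self is ReactionOrder.ZERO:
            return intercept
        if self is ReactionOrder.FIRST:
            return math.exp(intercept)
        return 1.0 / intercept if intercept != 0 else float("nan")


@dataclass(frozen=True)
class KineticTimeCourse:
    """One replicate's concentration-time series under one condition."""

    condition: str
    replicate_id: str
    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape:
            raise InvalidInputError("times and concentrations must align")
        if t.size < 3:
            raise InvalidInputError("need at least three time points")
        if np.any(t < 0):
            raise InvalidInputError("times must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    def drop_nonpositive(self) -> "KineticTimeCourse":
        """Remove fully-degraded points (C <= 0) before log/reciprocal fits."""
        mask = self.concentrations > 0
        n_dropped = int((~mask).sum())
        if n_dropped:
            warnings.warn(
                f"{self.condition}/{self.replicate_id}: dropped {n_dropped} "
                "non-positive concentration point(s) before transform",
                stacklevel=2,
            )
        return KineticTimeCourse(self.condition, self.replicate_id,
                                 self.times[mask], self.concentrations[mask])


@dataclass(frozen=True)
class KineticFit:
    """Least-squares fit of one replicate under one rate law."""

    order: ReactionOrder
    condition: str
    replicate_id: str
    k: float
    c0_est: float
    r2: float
    slope: float
    intercept: float

    @property
    def t_half(self) -> float:
        return half_life(self.k, self.order, self.c0_est)


def fit_order(tc: KineticTimeCourse,
              order: "str | ReactionOrder") -> KineticFit:
    """OLS of the order's transform of concentration on time.

    r² is computed on the transformed scale — the scale on which the
    rate law is a straight line.
    """
    order = ReactionOrder.parse(order)
    y = order.transform(tc.concentrations)
    t = tc.times
    slope, intercept = np.polyfit(t, y, 1)
    fitted = intercept + slope * t
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return KineticFit(
        order=order, condition=tc.condition, replicate_id=tc.replicate_id,
        k=order.k_from_slope(float(slope)), c0_est=order.c0_from_intercept(float(intercept)),
        r2=r2, slope=float(slope), intercept=float(intercept),
    )


def half_life(k: float, order: "str | ReactionOrder", c0: Optional[float] = None) -> float:
    """Half-life from the rate constant (C0 needed for zero/second order)."""
    order = ReactionOrder.parse(order)
    if not k > 0:
        raise InvalidInputError(f"rate constant must be > 0, got {k}")
    if order is ReactionOrder.FIRST:
        return math.log(2.0) / k
    if c0 is None or not c0 > 0:
        raise InvalidInputError(f"{order.value}-order half-life needs C0 > 0")
    if order is ReactionOrder.ZERO:
        return c0 / (2.0 * k)
    return 1.0 / (k * c0)


@dataclass(frozen=True)
class KineticsResults:
    """Aggregated kinetics for one condition.

    Carries the chosen (or requested) order, per-replicate fits, the
    per-order mean-r² table used for selection, and k / t½ means with
    sample SDs (t½ computed per replicate, then averaged).
    """

    condition: str
    order: ReactionOrder
    fits: list[KineticFit]
    r2_by_order: dict[ReactionOrder, float]
    k_mean: float
    k_sd: float
    t_half_mean: float
    t_half_sd: float
    n_replicates: int

    def summary(self) -> pd.DataFrame:
        rows = {
            "condition": self.condition,
            "chosen_order": self.order.value,
            "n_replicates": self.n_replicates,
            "k_mean": self.k_mean,
            "k_sd": self.k_sd,
            "t_half_mean_h": self.t_half_mean,
            "t_half_sd_h": self.t_half_sd,
        }
        for o in ReactionOrder:
            if o in self.r2_by_order:
                rows[f"r2_{o.value}"] = self.r2_by_order[o]
        return pd.DataFrame({"value": rows})


def summarize_kinetics(fits: Sequence[KineticFit]) -> KineticsResults:
    """Mean ± sample SD of k and of per-replicate t½ for one condition/order."""
    if not fits:
        raise InvalidInputError("need at least one replicate fit")
    conditions = {f.condition for f in fits}
    orders = {f.order for f in fits}
    if len(conditions) > 1 or len(orders) > 1:
        raise InvalidInputError("all fits must share condition and order")
    ks = summarize([f.k for f in fits])
    th = summarize([f.t_half for f in fits])
    order = fits[0].order
    return KineticsResults(
        condition=fits[0].condition, order=order, fits=list(fits),
        r2_by_order={order: float(np.mean([f.r2 for f in fits]))},
        k_mean=ks.mean, k_sd=ks.sd, t_half_mean=th.mean, t_half_sd=th.sd,
        n_replicates=len(fits),
    )


class DegradationKinetics:
    """Kinetic model for the replicate time courses of one condition.

    ``fit(order)`` aggregates per-replicate fits under a stated order;
    ``select_order()`` additionally chooses the order by highest mean r².
    """

    def __init__(self, timecourses: Sequence[KineticTimeCourse],
                 drop_nonpositive: bool = True):
        if not timecourses:
            raise InvalidInputError("need at least one replicate time course")
        conditions = {tc.condition for tc in timecourses}
        if len(conditions) > 1:
            raise InvalidInputError(
                f"time courses span several conditions: {sorted(conditions)}"
            )
        if drop_nonpositive:
            timecourses = [tc.drop_nonpositive() for tc in timecourses]
        self.timecourses = list(timecourses)
        self.condition = next(iter(conditions))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       condition_col: str = "condition",
                       replicate_col: str = "replicate",
                       time_col: str = "time_h",
                       conc_col: str = "conc_ug_ml",
                       **kwargs) -> "DegradationKinetics":
        tcs = []
        for (cond, rep), grp in df.groupby([condition_col, replicate_col], sort=True):
            grp = grp.sort_values(time_col)
            tcs.append(KineticTimeCourse(
                condition=str(cond), replicate_id=str(rep),
                times=grp[time_col].to_numpy(dtype=float),
                concentrations=grp[conc_col].to_numpy(dtype=float),
            ))
        return cls(tcs, **kwargs)

    def fit(self, order: "str | ReactionOrder") -> KineticsResults:
        order = ReactionOrder.parse(order)
        fits = [fit_order(tc, order) for tc in self.timecourses]
        return summarize_kinetics(fits)

    def select_order(self,
                     orders: Sequence["str | ReactionOrder"] = ORDER_SEQUENCE
                     ) -> KineticsResults:
        """Fit all candidate orders; keep the one with highest mean r².

        Ties break toward the lower order (the sequence is tried in
        increasing order and only a strictly larger mean r² replaces the
        incumbent).
        """
        parsed = [ReactionOrder.parse(o) for o in orders]
        if not parsed:
            raise InvalidInputError("need at least one candidate order")
        results = {o: self.fit(o) for o in parsed}
        r2_table = {o: results[o].r2_by_order[o] for o in parsed}
        best = parsed[0]
        for o in parsed[1:]:
            if r2_table[o] > r2_table[best]:
                best = o
        chosen = results[best]
        return KineticsResults(
            condition=chosen.condition, order=best, fits=chosen.fits,
            r2_by_order=r2_table, k_mean=chosen.k_mean, k_sd=chosen.k_sd,
            t_half_mean=chosen.t_half_mean, t_half_sd=chosen.t_half_sd,
            n_replicates=chosen.n_replicates,
        )


def select_order(tcs: Sequence[KineticTimeCourse],
                 orders: Sequence["str | ReactionOrder"] = ORDER_SEQUENCE
                 ) -> KineticsResults:
    """Functional form of ``DegradationKinetics(tcs).select_order(orders)``."""
    return DegradationKinetics(tcs).select_order(orders)
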