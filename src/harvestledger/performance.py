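"""Error decomposition for AGB estimators: trueness, precision, accuracy.

Terminology follows ISO 5725: the mean error (ME) expresses trueness
(systematic error), the standard deviation of the error (STDEV) expresses
precision (random error), and the root mean square error (RMSE) expresses
accuracy (total error). All three use population (1/n) forms, so the
identity RMSE^2 = ME^2 + STDEV^2 holds exactly.

Per tree, error is eps = AGB_est - AGB_ref and relative error is
RE = |eps| / AGB_ref. The summed relative error compares cumulative
estimated and reference AGB, quantifying how random error averages out
when up-scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, PairingError


@dataclass(frozen=True)
class ErrorRecord:
    """Per-tree estimator error (kg and unsigned %)."""

    tree_id: str
    agb_ref: float
    agb_est: float

    @property
    def epsilon(self) -> float:
        return self.agb_est - self.agb_ref

    @property
    def relative_error(self) -> float:
        return 100.0 * abs(self.epsilon) / self.agb_ref


@dataclass(frozen=True)
class PerformanceTable:
    """Decomposed performance of one estimation method."""

    method: str
    n: int
    mre: float            # mean tree-scale relative error, %
    me: float             # mean error (trueness), kg
    stdev: float          # sd of error (precision), kg, population form
    rmse: float           # root mean square error (accuracy), kg
    summed_ref: float     # kg
    summed_est: float     # kg
    summed_re: float      # % error in cumulative AGB


def error_records(refs: Mapping[str, float],
                  ests: Mapping[str, float]) -> list[ErrorRecord]:
    """Pair reference and estimated AGB by tree id."""
    if set(refs) != set(ests):
        only_ref = sorted(set(refs) - set(ests))
        only_est = sorted(set(ests) - set(refs))
        raise PairingError(
            f"unmatched tree ids (reference only: {only_ref}, "
            f"estimate only: {only_est})")
    return [ErrorRecord(tid, refs[tid], ests[tid]) for tid in refs]


def mean_relative_error(records: Sequence[ErrorRecord]) -> float:
    """Mean tree-scale relative error (%)."""
    if not records:
        raise DomainError("no error records")
    return float(np.mean([r.relative_error for r in records]))


def summed_relative_error(records: Sequence[ErrorRecord]) -> float:
    """Relative error (%) in up-scaled (cumulative) AGB."""
    if not records:
        raise DomainError("no error records")
    ref = sum(r.agb_ref for r in records)
    est = sum(r.agb_est for r in records)
    return 100.0 * abs(est - ref) / ref


def trueness_precision_accuracy(records: Sequence[ErrorRecord],
                                method: str = "") -> PerformanceTable:
    """ME / STDEV / RMSE decomposition (population forms)."""
    if not records:
        raise DomainError("no error records")
    eps = np.array([r.epsilon for r in records])
    me = float(np.mean(eps))
    stdev = float(np.sqrt(np.mean((eps - me) ** 2)))
    rmse = float(np.sqrt(np.mean(eps ** 2)))
    return PerformanceTable(
        method=method,
        n=len(records),
        mre=mean_relative_error(records),
        me=me,
        stdev=stdev,
        rmse=rmse,
        summed_ref=float(sum(r.agb_ref for r in records)),
        summed_est=float(sum(r.agb_est for r in records)),
        summed_re=summed_relative_error(records),
    )


@dataclass(frozen=True)
class ErrorSizeSlope:
    """OLS slope of error magnitude against reference AGB."""

    metric: str             # 'absolute' (|eps|, kg/kg) or 'relative' (%/kg)
    slope: float
    stderr: float
    ci_low: float           # 95 % confidence bounds
    ci_high: float
    size_dependent: bool    # True when 0 is excluded at 95 %


def error_size_slope(records: Sequence[ErrorRecord],
                     metric: str = "absolute",
                     confidence: float = 0.95) -> ErrorSizeSlope:
    """Regress error magnitude on tree size (reference AGB).

    A slope whose confidence interval excludes zero flags size-dependent
    (multiplicative-like) error; an interval containing zero is consistent
    with additive error. ``metric='absolute'`` uses |eps| (kg), ``'relative'``
    uses RE (%).
    """
    if len(records) < 3:
        raise DomainError("slope needs >= 3 records")
    x = np.array([r.agb_ref for r in records])
    if np.ptp(x) == 0:
        raise DomainError("degenerate size variance: slope undefined")
    if metric == "absolute":
        y = np.array([abs(r.epsilon) for r in records])
    elif metric == "relative":
        y = np.array([r.relative_error for r in records])
    else:
        raise DomainError(f"unknown slope metric {metric!r}")
    fit = stats.linregress(x, y)
    stderr = 0.0 if math.isnan(fit.stderr) else float(fit.stderr)
    dof = len(records) - 2
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, dof)
    lo = fit.slope - tcrit * stderr
    hi = fit.slope + tcrit * stderr
    return ErrorSizeSlope(metric=metric, slope=float(fit.slope),
                          stderr=stderr, ci_low=float(lo),
                          ci_high=float(hi),
                          size_dependent=not (lo <= 0.0 <= hi))
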