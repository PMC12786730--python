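"""Trapezoidal AUC of count/PI trajectories and the EVOC viability score.

The AUC over the culture schedule is the integrative viability readout; the
EVOC score compares two arms of the same tumor as the ratio of the control
arm's PI AUC to the experimental arm's.  Scores above 1 indicate lower
proliferative viability in the experimental arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from evocquant.errors import ValidationError


@dataclass(frozen=True)
class TrajectorySeries:
    """Ordered per-sample time course of one quantity (counts or PI %)."""

    sample_id: str
    quantity: str
    days: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.values):
            raise ValidationError("days and values must have equal length")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValidationError("days must be strictly increasing")
        if any(v < 0 for v in self.values):
            raise ValidationError("values must be non-negative")


@dataclass(frozen=True)
class AUCResult:
    """Trapezoidal AUC of one series, in value-units x days."""

    sample_id: str
    quantity: str
    auc: float
    days_used: tuple[float, ...]


@dataclass(frozen=True)
class EvocScore:
    """Ratio of control to experimental PI AUC (> 1: lower viability in
    the experimental arm)."""

    score: float
    auc_control: float
    auc_experimental: float


def trapezoid_auc(days, values) -> float:
    """Trapezoidal-rule area under a time course.

    ``sum_i (d[i+1] - d[i]) * (v[i] + v[i+1]) / 2`` — exact for piecewise
    linear curves, handles non-uniform spacing.
    """
    d = np.asarray(days, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.size != v.size:
        raise ValidationError("days and values must have equal length")
    if d.size < 2:
        raise ValidationError("AUC needs at least 2 time points")
    if np.any(np.diff(d) <= 0):
        raise ValidationError("days must be strictly increasing")
    return float(np.sum(np.diff(d) * (v[:-1] + v[1:]) / 2.0))


def auc_of_series(series: TrajectorySeries) -> AUCResult:
    """AUC of a TrajectorySeries, keeping sample/quantity metadata."""
    return AUCResult(sample_id=series.sample_id, quantity=series.quantity,
                     auc=trapezoid_auc(series.days, series.values),
                     days_used=tuple(series.days))


def evoc_score(control: TrajectorySeries,
               experimental: TrajectorySeries) -> EvocScore:
    """EVOC score: control PI AUC divided by experimental PI AUC.

    Both series must be PI trajectories on identical day grids; missing
    days are never interpolated.
    """
    for s in (control, experimental):
        if s.quantity != "PI":
            raise ValidationError("EVOC score is defined on PI series")
    if tuple(control.days) != tuple(experimental.days):
        raise ValidationError("control and experimental day grids differ")
    auc_c = trapezoid_auc(control.days, control.values)
    auc_e = trapezoid_auc(experimental.days, experimental.values)
    if auc_e == 0:
        raise ValidationError("experimental AUC is zero: score undefined")
    return EvocScore(score=auc_c / auc_e, auc_control=auc_c,
                     auc_experimental=auc_e)
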