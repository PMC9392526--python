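"""Least-squares linear trend with one additive offset per participant.

The model for score ``y`` of participant ``p`` at visit with time code
``x_t`` is::

    y_pt = a_p + b * x_t + e_pt

fit by ordinary least squares over the observed (non-missing) cells only;
missing cells are deleted listwise at the cell level.  The participant
offsets ``a_p`` absorb between-subject level differences, so the shared
slope ``b`` measures within-person change per unit of time coding.

By the Frisch-Waugh-Lovell theorem the slope equals the "within" estimator

    b = sum_p sum_t (x_t - xbar_p) y_pt / sum_p sum_t (x_t - xbar_p)^2

with participant-wise centered time codes; :func:`within_slope` exposes that
closed form, which the permutation engine uses for speed, and the full
:func:`fit_trend` solves the dummy-variable design by ``lstsq`` (minimum-norm
on rank deficiency).  The two agree to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrendError",
    "ScoreSeries",
    "TrendFit",
    "assign_time_codes",
    "build_design",
    "fit_trend",
    "within_slope",
]

from .instruments import TIMEPOINTS

#: Months-since-baseline coding for the five visits under the calendar
#: scheme (treatment lasts about six weeks; follow-ups at 1, 3, 6 months
#: after completion).
CALENDAR_MONTHS: dict[str, float] = {"pre": 0.0, "post": 1.5, "m1": 3.0, "m3": 5.0, "m6": 8.0}


class TrendError(ValueError):
    """Raised when a trend fit is not identifiable or a series is invalid."""


@dataclass(frozen=True)
class ScoreSeries:
    """One score's participant-by-visit grid, the unit of inference.

    ``values`` is a ``len(participants) x len(timepoints)`` float array with
    NaN marking missing cells; ``time_codes`` aligns with ``timepoints``.
    """

    score_name: str
    participants: tuple[str, ...]
    timepoints: tuple[str, ...]
    time_codes: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.time_codes, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "time_codes", codes)
        object.__setattr__(self, "values", vals)
        if codes.ndim != 1 or len(codes) != len(self.timepoints):
            raise TrendError(f"{self.score_name}: time_codes misaligned with timepoints")
        if np.any(np.diff(codes) <= 0):
            raise TrendError(f"{self.score_name}: time_codes must be strictly increasing")
        if vals.shape != (len(self.participants), len(self.timepoints)):
            raise TrendError(f"{self.score_name}: values grid has wrong shape {vals.shape}")

    @property
    def n_obs(self) -> int:
        """Number of non-missing cells."""
        return int(np.isfinite(self.values).sum())

    def observed_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass(frozen=True)
class TrendFit:
    """Fitted participant-offset linear trend."""

    score_name: str
    slope: float
    offsets: dict[str, float]
    fitted: np.ndarray
    residual_ss: float
    df: int
    n_obs_used: int
    informative_participants: frozenset


def assign_time_codes(timepoints: tuple[str, ...] | list[str], scheme: str = "ordinal") -> np.ndarray:
    """Numeric time codes for an ordered subset of the canonical visits.

    ``ordinal`` (default) assigns consecutive integers 0, 1, 2, ... to the
    visits actually collected, so a score missing one scheduled visit keeps
    unit spacing.  ``calendar`` uses months since baseline.
    """
    unknown = [t for t in timepoints if t not in TIMEPOINTS]
    if unknown:
        raise TrendError(f"unknown timepoint labels {unknown}")
    order = [TIMEPOINTS.index(t) for t in timepoints]
    if sorted(order) != order or len(set(order)) != len(order):
        raise TrendError("timepoints must be an ordered subset of "
                         f"{TIMEPOINTS}")
    if scheme == "ordinal":
        return np.arange(len(timepoints), dtype=float)
    if scheme == "calendar":
        return np.array([CALENDAR_MONTHS[t] for t in timepoints])
    raise TrendError(f"unknown time-coding scheme {scheme!r}")


def build_design(series: ScoreSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dummy-variable design over the observed cells.

    Returns ``(X, y, cells)``: one row per non-missing cell, one indicator
    column per participant (kept even for participants with fewer than two
    observations) followed by the time-code column; no global intercept —
    the offsets span it.  ``cells`` holds the (participant, visit) index of
    each row.
    """
    mask = series.observed_mask()
    if not mask.any():
        raise TrendError(f"{series.score_name}: no observed cells")
    rows, cols = np.nonzero(mask)
    n = len(rows)
    n_p = len(series.participants)
    X = np.zeros((n, n_p + 1))
    X[np.arange(n), rows] = 1.0
    X[:, n_p] = series.time_codes[cols]
    y = series.values[rows, cols]
    return X, y, np.column_stack([rows, cols])


def _slope_denominator(series: ScoreSeries) -> tuple[np.ndarray, float]:
    """Participant-centered time codes over observed cells and their SS."""
    mask = series.observed_mask()
    codes = np.where(mask, np.broadcast_to(series.time_codes, mask.shape), 0.0)
    counts = np.maximum(mask.sum(axis=1), 1)
    means = codes.sum(axis=1) / counts
    centered = np.where(mask, codes - means[:, None], 0.0)
    return centered, float(np.sum(centered**2))


def within_slope(series: ScoreSeries) -> float:
    """Closed-form slope of the participant-offset model.

    Equals the ``lstsq`` slope of :func:`fit_trend`; requires at least one
    participant observed at two distinct time codes.
    """
    centered, denom = _slope_denominator(series)
    if denom <= 0.0:
        raise TrendError(
            f"{series.score_name}: slope not identifiable (no participant has "
            "two observations at distinct time codes)"
        )
    vals = np.where(series.observed_mask(), series.values, 0.0)
    return float(np.sum(centered * vals) / denom)


def fit_trend(series: ScoreSeries) -> TrendFit:
    """Fit the participant-offset linear trend by least squares.

    Minimizes ``sum (y_pt - a_p - b x_t)^2`` over observed cells.  Offsets
    of participants with no observations are reported as 0 (minimum-norm
    solution).  ``df = n_obs - n_participant_columns - 1``.
    """
    mask = series.observed_mask()
    obs_per_p = mask.sum(axis=1)
    _, denom = _slope_denominator(series)
    if denom <= 0.0:
        raise TrendError(
            f"{series.score_name}: slope not identifiable (no participant has "
            "two observations at distinct time codes)"
        )
    X, y, _ = build_design(series)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    n_p = len(series.participants)
    slope = float(coef[n_p])
    offsets = {p: float(coef[i]) for i, p in enumerate(series.participants)}
    fitted = np.array(
        [[offsets[p] + slope * c for c in series.time_codes] for p in series.participants]
    )
    resid = np.where(mask, series.values - fitted, 0.0)
    informative = frozenset(
        p for p, k in zip(series.participants, obs_per_p) if k >= 2
    )
    return TrendFit(
        score_name=series.score_name,
        slope=slope,
        offsets=offsets,
        fitted=fitted,
        residual_ss=float(np.sum(resid**2)),
        df=int(mask.sum()) - n_p - 1,
        n_obs_used=int(mask.sum()),
        informative_participants=informative,
    )
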