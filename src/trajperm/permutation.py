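"""Within-participant permutation test of the fitted linear slope.

Under the null hypothesis of no time trend, a participant's observed scores
are exchangeable across that participant's own visits.  The empirical null
is therefore built by shuffling each participant's observed values among
their observed time codes, independently per participant; missing cells
never move (a missing point is never exchanged with a valid one).  The
Monte Carlo distribution comprises ``n_perm`` permuted slope replicates plus
the observed slope as one additional sample, so the smallest attainable
p-value is ``1/(n_perm + 1)`` — ``1/100000`` at the default 99,999
iterations.

Because the permutation leaves every participant's set of observed time
codes fixed, the within-estimator denominator is constant across replicates
and each replicate slope is a dot product of centered codes with shuffled
values; the engine vectorizes this over all replicates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .trend import ScoreSeries, TrendError, _slope_denominator, within_slope

__all__ = [
    "PermutationResult",
    "permute_within_participants",
    "permutation_pvalue",
    "exhaustive_pvalue",
]

#: Default number of Monte Carlo permutation iterations (the observed slope
#: is counted as one further sample, for 100,000 total).
DEFAULT_N_PERM: int = 99_999

#: Maximum within-participant arrangement-group size accepted by the
#: exhaustive enumerator.
MAX_EXHAUSTIVE: int = 1_000_000

_SIDEDNESS = ("two_sided", "one_sided_negative", "one_sided_positive")

# Relative tolerance when comparing replicate extremity to the observed
# statistic, so exact ties (e.g. constant data) count as extreme.
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class PermutationResult:
    """Empirical-null summary for one score's slope."""

    score_name: str
    observed_slope: float
    n_samples: int
    n_at_least_as_extreme: int
    p_value: float
    sidedness: str
    seed: int | None
    exhaustive: bool


def _extremity(slopes: np.ndarray | float, sidedness: str):
    if sidedness == "two_sided":
        return np.abs(slopes)
    if sidedness == "one_sided_negative":
        return -np.asarray(slopes)
    if sidedness == "one_sided_positive":
        return np.asarray(slopes)
    raise ValueError(f"unknown sidedness {sidedness!r}; expected one of {_SIDEDNESS}")


def _count_extreme(perm_stats: np.ndarray, obs_stat: float) -> int:
    tol = _TIE_RTOL * max(1.0, abs(obs_stat))
    return int(np.sum(perm_stats >= obs_stat - tol))


def permute_within_participants(
    series: ScoreSeries, rng: np.random.Generator
) -> ScoreSeries:
    """One random within-participant rearrangement of a series.

    Each participant's observed values are reassigned uniformly at random
    among that participant's observed visits; missing cells stay missing.
    The multiset of every participant's values is unchanged.
    """
    values = series.values.copy()
    mask = series.observed_mask()
    for i in range(values.shape[0]):
        idx = np.nonzero(mask[i])[0]
        if len(idx) > 1:
            values[i, idx] = values[i, idx[rng.permutation(len(idx))]]
    return ScoreSeries(
        series.score_name, series.participants, series.timepoints, series.time_codes, values
    )


def _replicate_slopes(
    series: ScoreSeries, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Slopes of ``n_perm`` within-participant permutation replicates."""
    centered, denom = _slope_denominator(series)
    mask = series.observed_mask()
    total = np.zeros(n_perm)
    for i in range(mask.shape[0]):
        idx = np.nonzero(mask[i])[0]
        k = len(idx)
        if k < 2:
            continue
        c = centered[i, idx]
        v = series.values[i, idx]
        if np.ptp(v) == 0.0:
            total += c.sum() * v[0]  # constant row: any arrangement identical
            continue
        order = np.argsort(rng.random((n_perm, k)), axis=1)
        total += v[order] @ c
    return total / denom


def permutation_pvalue(
    series: ScoreSeries,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    sidedness: str = "two_sided",
) -> PermutationResult:
    """Monte Carlo permutation p-value for the observed slope.

    ``p = #{samples at least as extreme as observed} / (n_perm + 1)`` where
    the observed slope is always one of the samples, so ``p >= 1/(n_perm+1)``
    and p-values live on the lattice ``k/(n_perm+1)``.  Deterministic given
    ``seed``.  Ties count as extreme (conservative).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = within_slope(series)  # raises TrendError if unidentifiable
    rng = np.random.default_rng(seed)
    perm = _replicate_slopes(series, n_perm, rng)
    obs_stat = float(_extremity(observed, sidedness))
    count = 1 + _count_extreme(_extremity(perm, sidedness), obs_stat)
    n_samples = n_perm + 1
    return PermutationResult(
        score_name=series.score_name,
        observed_slope=observed,
        n_samples=n_samples,
        n_at_least_as_extreme=count,
        p_value=count / n_samples,
        sidedness=sidedness,
        seed=seed,
        exhaustive=False,
    )


def _group_size(counts: list[int]) -> int:
    size = 1
    for k in counts:
        size *= math.factorial(k)
    return size


def exhaustive_pvalue(series: ScoreSeries, sidedness: str = "two_sided") -> PermutationResult:
    """Exact p-value over the full within-participant permutation group.

    Enumerates every combination of per-participant arrangements (the
    identity — i.e. the observed series — included exactly once).  Refuses
    groups larger than ``MAX_EXHAUSTIVE`` combinations.
    """
    observed = within_slope(series)
    centered, denom = _slope_denominator(series)
    mask = series.observed_mask()

    per_p: list[np.ndarray] = []  # per participant: slope contributions of each arrangement
    counts: list[int] = []
    for i in range(mask.shape[0]):
        idx = np.nonzero(mask[i])[0]
        k = len(idx)
        if k < 2:
            continue
        counts.append(k)
        c = centered[i, idx]
        v = series.values[i, idx]
        per_p.append(
            np.array([np.dot(np.asarray(perm), c) for perm in itertools.permutations(v)])
        )
    size = _group_size(counts)
    if size > MAX_EXHAUSTIVE:
        raise TrendError(
            f"{series.score_name}: permutation group has {size} arrangements "
            f"(> {MAX_EXHAUSTIVE}); use permutation_pvalue instead"
        )
    slopes = np.zeros(1)
    for contrib in per_p:
        slopes = (slopes[:, None] + contrib[None, :]).ravel()
    slopes /= denom
    obs_stat = float(_extremity(observed, sidedness))
    count = _count_extreme(_extremity(slopes, sidedness), obs_stat)
    return PermutationResult(
        score_name=series.score_name,
        observed_slope=observed,
        n_samples=len(slopes),
        n_at_least_as_extreme=count,
        p_value=count / len(slopes),
        sidedness=sidedness,
        seed=None,
        exhaustive=True,
    )
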