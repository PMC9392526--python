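"""Benjamini-Hochberg false-discovery-rate control across scores.

The step-up procedure: sort the m p-values ascending, find
``k* = max{k : p_(k) <= k*q/m}``, and reject every p-value at or below the
data-dependent threshold ``p_(k*)`` (no rejection if no k qualifies).  Ties
at the threshold are rejected together; flags are returned in input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FdrResult", "bh_correct"]


@dataclass(frozen=True)
class FdrResult:
    """Outcome of a BH correction over one family of p-values."""

    score_names: tuple[str, ...]
    p_values: tuple[float, ...]
    q_level: float
    m: int
    threshold: float
    survivors: tuple[bool, ...]

    def as_dict(self) -> dict:
        return {
            "q": self.q_level,
            "m": self.m,
            "threshold": self.threshold,
            "n_survivors": int(sum(self.survivors)),
            "survivors": {
                n: bool(s) for n, s in zip(self.score_names, self.survivors)
            },
        }


def bh_correct(
    p_values,
    q_level: float = 0.05,
    score_names=None,
) -> FdrResult:
    """Benjamini-Hochberg step-up correction.

    Parameters
    ----------
    p_values
        Sequence of p-values in [0, 1] (or a mapping name -> p).
    q_level
        Target false-discovery rate, in (0, 1).  Default 0.05.
    score_names
        Optional labels aligned with ``p_values``.

    Returns
    -------
    FdrResult
        With ``threshold`` the largest rejected p-value (0.0 if none) and
        ``survivors`` flags in input order.
    """
    if isinstance(p_values, dict):
        if score_names is not None:
            raise ValueError("pass score_names either in the mapping or separately, not both")
        score_names = tuple(p_values.keys())
        p_values = tuple(p_values.values())
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to correct")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q_level < 1:
        raise ValueError("q_level must lie in (0, 1)")
    m = p.size
    if score_names is None:
        score_names = tuple(f"p{i}" for i in range(m))
    elif len(score_names) != m:
        raise ValueError("score_names misaligned with p_values")

    order = np.sort(p)
    crit = q_level * np.arange(1, m + 1) / m
    passing = np.nonzero(order <= crit)[0]
    threshold = float(order[passing[-1]]) if passing.size else 0.0
    survivors = tuple(bool(v <= threshold) for v in p) if passing.size else (False,) * m
    return FdrResult(
        score_names=tuple(score_names),
        p_values=tuple(float(v) for v in p),
        q_level=q_level,
        m=m,
        threshold=threshold,
        survivors=survivors,
    )
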