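"""Questionnaire catalog, scoring, and prorated mean imputation.

Ten standardized mental-health instruments are modeled, yielding 21 score
names (instrument totals plus CAPS-5 cluster and DERS-18 subscale scores).
Scoring is summation of item responses after reverse-keying; missing item
answers are mean-imputed on the scored scale whenever at least 75% of the
items contributing to a score were answered, otherwise the score is missing.
Each computed score carries a provenance tag (``full`` / ``imputed`` /
``missing``) and the fraction of contributing items that were answered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TIMEPOINTS",
    "IMPUTATION_THRESHOLD",
    "CatalogError",
    "ScoringError",
    "InstrumentSpec",
    "ItemResponseRecord",
    "ScoreValue",
    "load_instrument_catalog",
    "default_catalog",
    "catalog_score_names",
    "impute_items",
    "score_instrument",
    "score_table",
    "classify_severity",
    "summarize_provenance",
]

#: Canonical visit labels, in collection order: pretreatment, posttreatment,
#: and 1-, 3-, 6-month follow-up.
TIMEPOINTS: tuple[str, ...] = ("pre", "post", "m1", "m3", "m6")

#: Minimum fraction of answered items required to compute (and prorate) a
#: score; below it the score is treated as missing.
IMPUTATION_THRESHOLD: float = 0.75


class CatalogError(ValueError):
    """Raised when an instrument definition or catalog override is invalid."""


class ScoringError(ValueError):
    """Raised when item responses violate an instrument's bounds."""


@dataclass(frozen=True)
class InstrumentSpec:
    """Static definition of one questionnaire.

    Parameters
    ----------
    name
        Short instrument code, e.g. ``"PHQ9"``.
    n_items
        Number of items ingested for the instrument.
    item_min, item_max
        Default per-item response bounds; ``item_bounds`` may override
        individual items.
    reverse_keyed
        0-based indices of reverse-keyed items.  Reversal maps a raw
        response ``v`` to ``item_min + item_max - v`` before summation.
    subscales
        Map of subscale key (e.g. ``"Awareness"``) to the 0-based item
        indices it sums.  Subscale score names are ``{name}_{KEY}``.
    total_items
        Item indices entering the instrument total; ``None`` means all
        items.  (The CAPS-5 total excludes the two dissociation items.)
    total_name
        Score name of the total; defaults to ``name``.
    bands
        Ordered ``(lower_bound, label)`` interpretive cutoffs for the total
        score; presentation only, never used in inference.
    schedule
        Visit labels at which the instrument was collected.
    """

    name: str
    n_items: int
    item_min: int
    item_max: int
    reverse_keyed: frozenset = frozenset()
    subscales: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    total_items: tuple[int, ...] | None = None
    total_name: str | None = None
    bands: tuple[tuple[int, str], ...] = ()
    schedule: tuple[str, ...] = TIMEPOINTS
    item_bounds: Mapping[int, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_items <= 0:
            raise CatalogError(f"{self.name}: n_items must be positive")
        if self.item_min > self.item_max:
            raise CatalogError(f"{self.name}: item_min exceeds item_max")
        seen: set[int] = set()
        for key, items in self.subscales.items():
            if not items:
                raise CatalogError(f"{self.name}: subscale {key} is empty")
            if any(i < 0 or i >= self.n_items for i in items):
                raise CatalogError(
                    f"{self.name}: subscale {key} references an item index "
                    f"outside 0..{self.n_items - 1}"
                )
            if seen.intersection(items):
                raise CatalogError(f"{self.name}: subscale item lists overlap at {key}")
            seen.update(items)
        for idx in self.reverse_keyed:
            if idx < 0 or idx >= self.n_items:
                raise CatalogError(f"{self.name}: reverse_keyed index {idx} out of range")
        if self.total_items is not None and any(
            i < 0 or i >= self.n_items for i in self.total_items
        ):
            raise CatalogError(f"{self.name}: total_items index out of range")
        unknown = set(self.schedule) - set(TIMEPOINTS)
        if unknown:
            raise CatalogError(f"{self.name}: unknown schedule labels {sorted(unknown)}")

    # -- derived structure -------------------------------------------------

    def bounds(self, item: int) -> tuple[int, int]:
        """Response bounds for one item (honoring per-item overrides)."""
        return self.item_bounds.get(item, (self.item_min, self.item_max))

    def score_items(self) -> dict[str, tuple[int, ...]]:
        """Map of every score name this instrument yields to its item set."""
        total = self.total_items if self.total_items is not None else tuple(range(self.n_items))
        out = {self.total_name or self.name: tuple(total)}
        for key, items in self.subscales.items():
            out[f"{self.name}_{key.upper()}"] = tuple(items)
        return out

    def score_range(self, score_name: str | None = None) -> tuple[int, int]:
        """(min, max) of a score; default the instrument total."""
        items = self.score_items()[score_name or self.total_name or self.name]
        lo = sum(self.bounds(i)[0] for i in items)
        hi = sum(self.bounds(i)[1] for i in items)
        return lo, hi

    def scored_value(self, item: int, value: float) -> float:
        """Item response on the scored scale (reverse-keyed if applicable)."""
        if item in self.reverse_keyed:
            lo, hi = self.bounds(item)
            return lo + hi - value
        return value


@dataclass(frozen=True)
class ItemResponseRecord:
    """Raw answers of one participant to one instrument at one visit.

    ``items`` has length ``n_items``; missing answers are ``None`` or NaN.
    """

    participant_id: str
    timepoint: str
    instrument: str
    items: tuple[float | None, ...]


@dataclass(frozen=True)
class ScoreValue:
    """One computed score with its provenance.

    ``provenance`` is ``"full"`` (all items answered), ``"imputed"``
    (>= 75% answered, the rest mean-imputed) or ``"missing"`` (< 75%
    answered; ``value`` is NaN).
    """

    participant_id: str
    timepoint: str
    score_name: str
    value: float
    provenance: str
    frac_answered: float


# ---------------------------------------------------------------------------
# default catalog
# ---------------------------------------------------------------------------

def default_catalog() -> dict[str, InstrumentSpec]:
    """Built-in definitions of the ten instruments (21 score names).

    Constants follow the standard published forms: PCL-5 as 20 items on
    0-4 (total 0-80); PHQ-9 and GAD-7 on 0-3 with the usual severity bands;
    PDEQ 10 items on 1-5 with the >15 dissociation flag; AUDIT with the >=8
    hazardous-use cutoff; DERS-18 as six 3-item subscales on 1-5 with the
    Awareness items reverse-keyed; OQ-45 on 0-4 with the 63-point clinical
    cutoff and its nine reverse-keyed items; CD-RISC-25 on 0-4 (0-100);
    CAPS-5 as 20 severity items partitioned into clusters B/C/D/E plus two
    dissociation items.  The DERS-18 was not collected at the 6-month visit
    and the CAPS-5 interview not at the 1-month visit.
    """
    catalog = {
        "PCL5": InstrumentSpec("PCL5", 20, 0, 4),
        "MISSMSF": InstrumentSpec("MISSMSF", 10, 1, 10),
        "CAPS5": InstrumentSpec(
            "CAPS5",
            22,
            0,
            4,
            subscales={
                "B": tuple(range(0, 5)),
                "C": (5, 6),
                "D": tuple(range(7, 14)),
                "E": tuple(range(14, 20)),
                "DISS": (20, 21),
            },
            total_items=tuple(range(20)),
            total_name="CAPS5_TOTAL",
            schedule=("pre", "post", "m3", "m6"),
        ),
        "PHQ9": InstrumentSpec(
            "PHQ9",
            9,
            0,
            3,
            bands=(
                (0, "minimal"),
                (5, "mild"),
                (10, "moderate"),
                (15, "moderately severe"),
                (20, "severe"),
            ),
        ),
        "GAD7": InstrumentSpec(
            "GAD7",
            7,
            0,
            3,
            bands=((0, "minimal"), (5, "mild"), (10, "moderate"), (15, "severe")),
        ),
        "PDEQ": InstrumentSpec(
            "PDEQ",
            10,
            1,
            5,
            bands=((10, "not significant"), (16, "significant dissociation")),
        ),
        "AUDIT": InstrumentSpec(
            "AUDIT",
            10,
            0,
            4,
            bands=((0, "low risk"), (8, "hazardous")),
        ),
        "DERS18": InstrumentSpec(
            "DERS18",
            18,
            1,
            5,
            reverse_keyed=frozenset({0, 3, 5}),
            subscales={
                "Awareness": (0, 3, 5),
                "Clarity": (1, 2, 4),
                "Goals": (7, 11, 14),
                "Impulse": (8, 15, 17),
                "Nonacceptance": (6, 10, 12),
                "Strategies": (9, 13, 16),
            },
            schedule=("pre", "post", "m1", "m3"),
        ),
        "OQ45": InstrumentSpec(
            "OQ45",
            45,
            0,
            4,
            reverse_keyed=frozenset({0, 11, 12, 19, 20, 23, 30, 36, 42}),
            bands=((0, "below clinical cutoff"), (63, "clinically significant")),
        ),
        "CDRISC25": InstrumentSpec("CDRISC25", 25, 0, 4),
    }
    return catalog


def catalog_score_names(catalog: Mapping[str, InstrumentSpec]) -> list[str]:
    """All score names the catalog yields, in catalog order."""
    names: list[str] = []
    for spec in catalog.values():
        names.extend(spec.score_items())
    return names


_OVERRIDABLE = {
    "n_items",
    "item_min",
    "item_max",
    "reverse_keyed",
    "subscales",
    "total_items",
    "total_name",
    "bands",
    "schedule",
    "item_bounds",
}


def load_instrument_catalog(config_path: str | None = None) -> dict[str, InstrumentSpec]:
    """Load the instrument catalog, optionally applying YAML overrides.

    The config file maps instrument name to a dict of ``InstrumentSpec``
    field overrides, e.g. ``{"PCL5": {"n_items": 17}}``.  Unknown
    instruments or fields raise :class:`CatalogError` naming the offender.
    """
    catalog = default_catalog()
    if config_path is None:
        return catalog
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return catalog
    if not isinstance(raw, dict):
        raise CatalogError("catalog config must be a mapping of instrument -> overrides")
    for inst, overrides in raw.items():
        if inst not in catalog:
            raise CatalogError(f"unknown instrument {inst!r} in catalog config")
        if not isinstance(overrides, dict):
            raise CatalogError(f"{inst}: overrides must be a mapping")
        kwargs = {
            "name": inst,
            **{f: getattr(catalog[inst], f) for f in _OVERRIDABLE},
        }
        for fieldname, value in overrides.items():
            if fieldname not in _OVERRIDABLE:
                raise CatalogError(f"{inst}: unknown field {fieldname!r}")
            if fieldname == "reverse_keyed":
                value = frozenset(value)
            elif fieldname in ("subscales",):
                value = {k: tuple(v) for k, v in value.items()}
            elif fieldname in ("total_items", "schedule"):
                value = tuple(value)
            elif fieldname == "bands":
                value = tuple((int(lo), str(lab)) for lo, lab in value)
            elif fieldname == "item_bounds":
                value = {int(k): tuple(v) for k, v in value.items()}
            kwargs[fieldname] = value
        catalog[inst] = InstrumentSpec(**kwargs)
    return catalog


# ---------------------------------------------------------------------------
# imputation and scoring
# ---------------------------------------------------------------------------

def impute_items(
    items: Sequence[float | None],
    spec: InstrumentSpec,
    item_subset: Sequence[int],
    threshold: float = IMPUTATION_THRESHOLD,
) -> tuple[np.ndarray, float, str]:
    """Prorate missing answers within one score's item subset.

    Returns ``(completed, frac_answered, provenance)`` where ``completed``
    holds scored-scale (post reverse-keying) values over ``item_subset``.
    If the answered fraction is below ``threshold`` no completion is
    attempted and every entry is NaN.  Imputation fills each missing entry
    with the mean of the answered scored values, so the resulting sum equals
    ``n_items_in_subset * mean(answered)``.
    """
    if not item_subset:
        raise ScoringError("item_subset must be non-empty")
    if not 0 < threshold <= 1:
        raise ScoringError("threshold must lie in (0, 1]")
    scored = np.full(len(item_subset), np.nan)
    for j, idx in enumerate(item_subset):
        v = items[idx]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        scored[j] = spec.scored_value(idx, float(v))
    answered = ~np.isnan(scored)
    frac = float(answered.sum()) / len(item_subset)
    if frac < threshold:
        return np.full(len(item_subset), np.nan), frac, "missing"
    if frac == 1.0:
        return scored, frac, "full"
    scored[~answered] = scored[answered].mean()
    return scored, frac, "imputed"


def _validate_record(record: ItemResponseRecord, spec: InstrumentSpec) -> None:
    if record.instrument != spec.name:
        raise ScoringError(
            f"record instrument {record.instrument!r} does not match spec {spec.name!r}"
        )
    if len(record.items) != spec.n_items:
        raise ScoringError(
            f"{spec.name} expects {spec.n_items} items, got {len(record.items)} "
            f"(participant={record.participant_id}, timepoint={record.timepoint})"
        )
    for idx, v in enumerate(record.items):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        lo, hi = spec.bounds(idx)
        if not lo <= v <= hi:
            raise ScoringError(
                f"{spec.name} item {idx} value {v} outside [{lo}, {hi}] "
                f"(participant={record.participant_id}, timepoint={record.timepoint})"
            )


def score_instrument(record: ItemResponseRecord, spec: InstrumentSpec) -> list[ScoreValue]:
    """Compute the instrument total and every subscale score for one record.

    The 75% rule is applied independently per score: a subscale may be
    computable while the total is not, and vice versa.
    """
    _validate_record(record, spec)
    out: list[ScoreValue] = []
    for score_name, item_set in spec.score_items().items():
        completed, frac, provenance = impute_items(record.items, spec, item_set)
        value = float("nan") if provenance == "missing" else float(completed.sum())
        out.append(
            ScoreValue(
                record.participant_id, record.timepoint, score_name, value, provenance, frac
            )
        )
    return out


def score_table(
    items: pd.DataFrame, catalog: Mapping[str, InstrumentSpec]
) -> pd.DataFrame:
    """Score a long item-response table into a long score table.

    ``items`` columns: ``participant_id, timepoint, instrument, item_index,
    value`` (missing answers as NaN/empty).  Returns columns
    ``participant_id, timepoint, score_name, value, provenance,
    frac_answered`` — one row per (participant, visit, score) for every
    visit at which the instrument was presented.
    """
    required = {"participant_id", "timepoint", "instrument", "item_index", "value"}
    missing_cols = required - set(items.columns)
    if missing_cols:
        raise ScoringError(f"item table lacks columns {sorted(missing_cols)}")
    rows: list[ScoreValue] = []
    for (pid, tp, inst), grp in items.groupby(
        ["participant_id", "timepoint", "instrument"], sort=False
    ):
        spec = catalog.get(inst)
        if spec is None:
            raise ScoringError(f"unknown instrument {inst!r} in item table")
        answers: list[float | None] = [None] * spec.n_items
        for idx, val in zip(grp["item_index"].to_numpy(), grp["value"].to_numpy()):
            idx = int(idx)
            if idx < 0 or idx >= spec.n_items:
                raise ScoringError(f"{inst}: item_index {idx} out of range")
            answers[idx] = None if pd.isna(val) else float(val)
        record = ItemResponseRecord(str(pid), str(tp), inst, tuple(answers))
        rows.extend(score_instrument(record, spec))
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in rows],
            "timepoint": [r.timepoint for r in rows],
            "score_name": [r.score_name for r in rows],
            "value": [r.value for r in rows],
            "provenance": [r.provenance for r in rows],
            "frac_answered": [r.frac_answered for r in rows],
        }
    )


def classify_severity(value: float, spec: InstrumentSpec) -> str | None:
    """Interpretive band of a total score; ``None`` for a missing score.

    Fractional scores are classified by the band whose closed integer
    interval contains ``floor(value)``.  Bands are presentation-only.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if not spec.bands:
        raise CatalogError(f"{spec.name} defines no interpretive bands")
    anchor = math.floor(value)
    label = None
    for lower, band in spec.bands:
        if anchor >= lower:
            label = band
    return label


def summarize_provenance(
    scores: pd.DataFrame | Iterable[ScoreValue],
) -> tuple[float, float, float]:
    """Fractions of score values that are full / imputed / missing."""
    if isinstance(scores, pd.DataFrame):
        prov = scores["provenance"]
        n = len(prov)
        if n == 0:
            raise ScoringError("empty score collection")
        counts = prov.value_counts()
        return tuple(
            float(counts.get(k, 0)) / n for k in ("full", "imputed", "missing")
        )  # type: ignore[return-value]
    vals = list(scores)
    if not vals:
        raise ScoringError("empty score collection")
    n = len(vals)
    return (
        sum(v.provenance == "full" for v in vals) / n,
        sum(v.provenance == "imputed" for v in vals) / n,
        sum(v.provenance == "missing" for v in vals) / n,
    )
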