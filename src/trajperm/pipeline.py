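"""End-to-end orchestration: score, fit, permute, correct, report.

``run_pipeline`` takes either a long item-response CSV or a pre-computed
score CSV, fits the participant-offset trend for each of the catalog's 21
scores, runs the within-participant permutation test with a per-score child
seed derived from the master seed, applies Benjamini-Hochberg FDR across
the family, and writes machine-readable results plus a human-readable
summary table (per-visit mean ± SD, slope to one decimal, p-value, FDR
survivor flag, with dashes at uncollected visits).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .instruments import (
    TIMEPOINTS,
    InstrumentSpec,
    catalog_score_names,
    load_instrument_catalog,
    score_table,
    summarize_provenance,
)
from .multiplicity import FdrResult, bh_correct
from .permutation import DEFAULT_N_PERM, PermutationResult, permutation_pvalue
from .trend import ScoreSeries, TrendError, TrendFit, assign_time_codes, fit_trend

__all__ = [
    "RunConfig",
    "PipelineError",
    "read_scores_csv",
    "read_items_csv",
    "series_from_scores",
    "score_seed",
    "run_pipeline",
    "write_report",
]

SCORE_COLUMNS = ["participant_id", "timepoint", "score_name", "value", "provenance", "frac_answered"]
ITEM_COLUMNS = ["participant_id", "timepoint", "instrument", "item_index", "value"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Settings for one analysis run."""

    input_path: str | Path
    input_kind: str = "scores"  # "scores" or "items"
    catalog_config: str | Path | None = None
    time_scheme: str = "ordinal"
    n_perm: int = DEFAULT_N_PERM
    seed: int = 0
    sidedness: str = "two_sided"
    q_level: float = 0.05
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.input_kind not in ("scores", "items"):
            raise ValueError("input_kind must be 'scores' or 'items'")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "timepoint": str})
    missing = set(columns) - set(df.columns)
    if missing:
        raise PipelineError(f"{path}: missing columns {sorted(missing)}")
    bad_tp = set(df["timepoint"].dropna()) - set(TIMEPOINTS)
    if bad_tp:
        raise PipelineError(f"{path}: unknown timepoints {sorted(bad_tp)}")
    return df


def read_items_csv(path: str | Path) -> pd.DataFrame:
    """Read a long item-response CSV (empty ``value`` = missing answer)."""
    df = _read_csv(path, ITEM_COLUMNS)
    bad = df[~df["value"].isna() & pd.to_numeric(df["value"], errors="coerce").isna()]
    if len(bad):
        raise PipelineError(
            f"{path}: non-numeric value at line {int(bad.index[0]) + 2}"  # header is line 1
        )
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return df


def read_scores_csv(
    path: str | Path, catalog: Mapping[str, InstrumentSpec] | None = None
) -> pd.DataFrame:
    """Read a long score CSV, rejecting score names absent from the catalog."""
    df = _read_csv(path, SCORE_COLUMNS[:4])
    catalog = catalog if catalog is not None else load_instrument_catalog()
    known = set(catalog_score_names(catalog))
    unknown = set(df["score_name"]) - known
    if unknown:
        raise PipelineError(f"{path}: unknown score names {sorted(unknown)}")
    bad = df[~df["value"].isna() & pd.to_numeric(df["value"], errors="coerce").isna()]
    if len(bad):
        raise PipelineError(f"{path}: non-numeric value at line {int(bad.index[0]) + 2}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return df


def series_from_scores(
    scores: pd.DataFrame,
    score_name: str,
    schedule: tuple[str, ...],
    time_scheme: str = "ordinal",
) -> ScoreSeries:
    """Pivot one score's long rows into a participant-by-visit grid.

    The grid covers every participant in the table and the instrument's
    collected visits in canonical order; cells with no row, or a missing
    score value, are NaN.
    """
    participants = tuple(sorted(set(scores["participant_id"])))
    timepoints = tuple(t for t in TIMEPOINTS if t in schedule)
    codes = assign_time_codes(timepoints, time_scheme)
    sub = scores[scores["score_name"] == score_name]
    grid = np.full((len(participants), len(timepoints)), np.nan)
    p_idx = {p: i for i, p in enumerate(participants)}
    t_idx = {t: i for i, t in enumerate(timepoints)}
    for pid, tp, val in zip(sub["participant_id"], sub["timepoint"], sub["value"]):
        if tp in t_idx:
            grid[p_idx[pid], t_idx[tp]] = val
    return ScoreSeries(score_name, participants, timepoints, codes, grid)


def score_seed(master_seed: int, index: int) -> int:
    """Per-score child seed derived from the master seed (stable, < 2^31)."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _score_schedules(catalog: Mapping[str, InstrumentSpec]) -> dict[str, tuple[str, ...]]:
    out = {}
    for spec in catalog.values():
        for score_name in spec.score_items():
            out[score_name] = spec.schedule
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute score → fit → permute → correct → report.

    Returns a results dict with per-score fits and permutation results, the
    FDR outcome, provenance fractions (item input only), and — when
    ``config.out_dir`` is set — writes ``scores.csv``, ``results.csv``,
    ``fdr.json`` and ``report.txt`` there.  Deterministic given the seed.
    """
    catalog = load_instrument_catalog(
        None if config.catalog_config is None else str(config.catalog_config)
    )
    provenance = None
    try:
        if config.input_kind == "items":
            items = read_items_csv(config.input_path)
            scores = score_table(items, catalog)
            provenance = summarize_provenance(scores)
        else:
            scores = read_scores_csv(config.input_path, catalog)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
        raise PipelineError(f"scoring stage failed: {exc}") from exc

    schedules = _score_schedules(catalog)
    score_names = catalog_score_names(catalog)
    fits: dict[str, TrendFit] = {}
    perms: dict[str, PermutationResult] = {}
    for i, name in enumerate(score_names):
        series = series_from_scores(scores, name, schedules[name], config.time_scheme)
        if series.n_obs == 0:
            continue  # score entirely absent from this input
        try:
            fits[name] = fit_trend(series)
            perms[name] = permutation_pvalue(
                series,
                n_perm=config.n_perm,
                seed=score_seed(config.seed, i),
                sidedness=config.sidedness,
            )
        except TrendError as exc:
            raise PipelineError(f"trend stage failed for {name}: {exc}") from exc

    if not perms:
        raise PipelineError("permutation stage: no analyzable scores in input")
    fdr = bh_correct({n: r.p_value for n, r in perms.items()}, q_level=config.q_level)

    results = {
        "scores": scores,
        "fits": fits,
        "permutations": perms,
        "fdr": fdr,
        "provenance": provenance,
        "settings": {
            "n_perm": config.n_perm,
            "seed": config.seed,
            "sidedness": config.sidedness,
            "q_level": config.q_level,
            "time_scheme": config.time_scheme,
        },
    }
    if config.out_dir is not None:
        _write_outputs(results, catalog, Path(config.out_dir))
    return results


def _results_frame(results: dict) -> pd.DataFrame:
    fdr: FdrResult = results["fdr"]
    surv = dict(zip(fdr.score_names, fdr.survivors))
    rows = []
    for name, fit in results["fits"].items():
        perm: PermutationResult = results["permutations"][name]
        rows.append(
            {
                "score_name": name,
                "slope": fit.slope,
                "n_obs": fit.n_obs_used,
                "df": fit.df,
                "residual_ss": fit.residual_ss,
                "p_value": perm.p_value,
                "n_samples": perm.n_samples,
                "seed": perm.seed,
                "fdr_survivor": surv[name],
            }
        )
    return pd.DataFrame(rows)


def write_report(
    results: dict,
    catalog: Mapping[str, InstrumentSpec],
    path: str | Path,
) -> None:
    """Write the human-readable per-score summary table.

    One row per catalog score: per-visit mean ± SD (dash where the
    instrument was not collected or nothing observed), slope to one
    decimal, p-value, and the FDR survivor star.
    """
    scores: pd.DataFrame = results["scores"]
    fdr: FdrResult = results["fdr"]
    surv = dict(zip(fdr.score_names, fdr.survivors))
    schedules = _score_schedules(catalog)
    lines = []
    header = ["Score"] + list(TIMEPOINTS) + ["Est slope", "p value", "FDR"]
    lines.append("\t".join(header))
    for name in catalog_score_names(catalog):
        cells = [name]
        sub = scores[scores["score_name"] == name]
        for tp in TIMEPOINTS:
            if tp not in schedules[name]:
                cells.append("—")
                continue
            vals = sub.loc[sub["timepoint"] == tp, "value"].dropna()
            if len(vals) == 0:
                cells.append("—")
            elif len(vals) == 1:
                cells.append(f"{vals.mean():.1f}")
            else:
                cells.append(f"{vals.mean():.1f} ± {vals.std(ddof=1):.1f}")
        fit = results["fits"].get(name)
        perm = results["permutations"].get(name)
        if fit is None or perm is None:
            cells += ["—", "—", ""]
        else:
            cells += [f"{fit.slope:.1f}", f"{perm.p_value:.5f}", "*" if surv[name] else ""]
        lines.append("\t".join(cells))
    lines.append("")
    lines.append(
        f"FDR threshold (BH, q={fdr.q_level}): {fdr.threshold:.5f}; "
        f"{sum(fdr.survivors)} of {fdr.m} scores survive."
    )
    s = results["settings"]
    lines.append(
        f"Permutation settings: n_perm={s['n_perm']}, master seed={s['seed']}, "
        f"sidedness={s['sidedness']}, time coding={s['time_scheme']}."
    )
    if results.get("provenance") is not None:
        f_full, f_imp, f_miss = results["provenance"]
        lines.append(
            f"Score provenance: {f_full:.1%} full, {f_imp:.1%} imputed, {f_miss:.1%} missing."
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _write_outputs(results: dict, catalog: Mapping[str, InstrumentSpec], out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        p = out_dir / "scores.csv"
        results["scores"].to_csv(p, index=False)
        written.append(p)
        p = out_dir / "results.csv"
        _results_frame(results).to_csv(p, index=False)
        written.append(p)
        p = out_dir / "fdr.json"
        p.write_text(json.dumps(results["fdr"].as_dict(), indent=2) + "\n")
        written.append(p)
        p = out_dir / "report.txt"
        write_report(results, catalog, p)
        written.append(p)
    except Exception:
        for f in written:
            f.unlink(missing_ok=True)
        raise
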