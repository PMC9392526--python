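"""Instrument catalog, scoring, 75%-rule imputation, and severity bands."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trajperm.instruments import (
    CatalogError,
    InstrumentSpec,
    ItemResponseRecord,
    ScoringError,
    catalog_score_names,
    classify_severity,
    default_catalog,
    impute_items,
    load_instrument_catalog,
    score_instrument,
    score_table,
    summarize_provenance,
)


class TestCatalog:
    def test_yields_21_score_names(self, catalog):
        names = catalog_score_names(catalog)
        assert len(names) == 21
        assert len(set(names)) == 21

    @pytest.mark.parametrize(
        "inst, score, rng",
        [
            ("PHQ9", "PHQ9", (0, 27)),
            ("GAD7", "GAD7", (0, 21)),
            ("PCL5", "PCL5", (0, 80)),
            ("MISSMSF", "MISSMSF", (10, 100)),
            ("PDEQ", "PDEQ", (10, 50)),
            ("CDRISC25", "CDRISC25", (0, 100)),
            ("DERS18", "DERS18", (18, 90)),
            ("DERS18", "DERS18_IMPULSE", (3, 15)),
            ("CAPS5", "CAPS5_TOTAL", (0, 80)),
            ("CAPS5", "CAPS5_DISS", (0, 8)),
        ],
    )
    def test_score_ranges(self, catalog, inst, score, rng):
        assert catalog[inst].score_range(score) == rng

    def test_ders18_has_six_subscales(self, catalog):
        keys = set(catalog["DERS18"].subscales)
        assert keys == {"Awareness", "Clarity", "Goals", "Impulse", "Nonacceptance", "Strategies"}

    def test_schedule_gaps(self, catalog):
        assert "m6" not in catalog["DERS18"].schedule
        assert "m1" not in catalog["CAPS5"].schedule
        assert catalog["PHQ9"].schedule == ("pre", "post", "m1", "m3", "m6")

    def test_caps5_clusters_partition_severity_items(self, catalog):
        spec = catalog["CAPS5"]
        sizes = {k: len(v) for k, v in spec.subscales.items()}
        assert sizes == {"B": 5, "C": 2, "D": 7, "E": 6, "DISS": 2}
        severity = sorted(
            i for k, v in spec.subscales.items() if k != "DISS" for i in v
        )
        assert tuple(severity) == spec.total_items

    def test_overlapping_subscales_rejected(self):
        with pytest.raises(CatalogError, match="overlap"):
            InstrumentSpec("X", 4, 0, 3, subscales={"a": (0, 1), "b": (1, 2)})

    def test_yaml_override_and_validation(self, tmp_path):
        cfg = tmp_path / "cat.yaml"
        cfg.write_text("PCL5:\n  n_items: 17\n")
        cat = load_instrument_catalog(str(cfg))
        assert cat["PCL5"].n_items == 17
        assert cat["PCL5"].score_range() == (0, 68)
        cfg.write_text("PCL5:\n  n_item: 17\n")
        with pytest.raises(CatalogError, match="n_item"):
            load_instrument_catalog(str(cfg))


class TestImputation:
    def test_phq9_eight_of_nine_prorated(self, catalog):
        spec = catalog["PHQ9"]
        items = [1.0] * 8 + [None]
        completed, frac, prov = impute_items(items, spec, list(range(9)))
        assert prov == "imputed"
        assert frac == pytest.approx(8 / 9)
        assert completed[-1] == pytest.approx(1.0)

    def test_gad7_five_of_seven_below_threshold(self, catalog):
        spec = catalog["GAD7"]
        items = [2.0] * 5 + [None, None]
        _, frac, prov = impute_items(items, spec, list(range(7)))
        assert prov == "missing"
        assert frac < 0.75

    def test_complete_answers_identity(self, catalog):
        spec = catalog["PHQ9"]
        items = [float(i % 4) % 4 for i in range(9)]
        completed, frac, prov = impute_items(items, spec, list(range(9)))
        assert prov == "full" and frac == 1.0
        assert list(completed) == items

    def test_reverse_keyed_imputes_on_scored_scale(self, catalog):
        # OQ-45 item 0 is reverse-keyed on 0-4, so a raw 0 scores as 4.  With
        # the reversed item missing, the fill must be the mean of the scored
        # (post-reversal) values, not of the raw answers.
        spec = catalog["OQ45"]
        items = [None] * 45
        items[1] = items[2] = items[3] = 4.0
        completed, frac, prov = impute_items(items, spec, [0, 1, 2, 3])
        assert prov == "imputed"
        assert frac == 0.75
        assert list(completed) == [4.0, 4.0, 4.0, 4.0]


class TestScoring:
    def _record(self, spec, fill):
        return ItemResponseRecord("P1", "pre", spec.name, tuple(fill))

    def test_pdeq_minimum_total(self, catalog):
        spec = catalog["PDEQ"]
        scores = score_instrument(self._record(spec, [1.0] * 10), spec)
        (total,) = [s for s in scores if s.score_name == "PDEQ"]
        assert total.value == 10 and total.provenance == "full"

    def test_cdrisc_maximum_total(self, catalog):
        spec = catalog["CDRISC25"]
        (total,) = score_instrument(self._record(spec, [4.0] * 25), spec)
        assert total.value == 100

    def test_pcl5_maximum_total(self, catalog):
        spec = catalog["PCL5"]
        (total,) = score_instrument(self._record(spec, [4.0] * 20), spec)
        assert total.value == 80

    def test_out_of_bounds_names_coordinates(self, catalog):
        spec = catalog["PHQ9"]
        with pytest.raises(ScoringError, match="item 3.*P1.*pre"):
            score_instrument(self._record(spec, [0, 0, 0, 9] + [0] * 5), spec)

    def test_subscale_missing_total_imputed(self, catalog):
        # One missing DERS item kills its 3-item subscale (2/3 < 0.75) but
        # leaves the 18-item total imputable (17/18 >= 0.75).
        spec = catalog["DERS18"]
        fill = [3.0] * 18
        fill[7] = None  # Goals item
        by_name = {s.score_name: s for s in score_instrument(self._record(spec, fill), spec)}
        assert by_name["DERS18_GOALS"].provenance == "missing"
        assert math.isnan(by_name["DERS18_GOALS"].value)
        assert by_name["DERS18"].provenance == "imputed"
        assert by_name["DERS18_CLARITY"].provenance == "full"


class TestSeverityBands:
    @pytest.mark.parametrize(
        "inst, value, label",
        [
            ("PHQ9", 14, "moderate"),
            ("PHQ9", 14.7, "moderate"),  # floor(14.7)=14 stays in 10-14
            ("PHQ9", 15, "moderately severe"),
            ("PHQ9", 3, "minimal"),
            ("GAD7", 15.4, "severe"),
            ("PDEQ", 15, "not significant"),
            ("PDEQ", 16, "significant dissociation"),
            ("AUDIT", 8, "hazardous"),
            ("AUDIT", 7, "low risk"),
            ("OQ45", 63, "clinically significant"),
        ],
    )
    def test_band_boundaries(self, catalog, inst, value, label):
        assert classify_severity(value, catalog[inst]) == label

    def test_missing_score_gives_missing_label(self, catalog):
        assert classify_severity(float("nan"), catalog["PHQ9"]) is None


class TestProvenanceSummary:
    def test_counting(self):
        df = pd.DataFrame({"provenance": ["full"] * 19 + ["imputed"]})
        assert summarize_provenance(df) == (0.95, 0.05, 0.0)

    def test_all_full(self):
        df = pd.DataFrame({"provenance": ["full"] * 7})
        assert summarize_provenance(df) == (1.0, 0.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ScoringError):
            summarize_provenance(pd.DataFrame({"provenance": []}))


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

@st.composite
def phq9_responses(draw):
    return draw(
        st.lists(
            st.one_of(st.none(), st.integers(0, 3)), min_size=9, max_size=9
        )
    )


class TestScoringProperties:
    @given(phq9_responses())
    def test_range_and_trichotomy(self, items):
        spec = default_catalog()["PHQ9"]
        record = ItemResponseRecord("P", "pre", "PHQ9", tuple(items))
        (sv,) = score_instrument(record, spec)
        n_ans = sum(v is not None for v in items)
        assert sv.frac_answered == pytest.approx(n_ans / 9)
        if sv.frac_answered == 1.0:
            assert sv.provenance == "full"
        elif sv.frac_answered >= 0.75:
            assert sv.provenance == "imputed"
        else:
            assert sv.provenance == "missing"
        if sv.provenance == "missing":
            assert math.isnan(sv.value)
        else:
            lo, hi = spec.score_range()
            assert lo <= sv.value <= hi

    @given(phq9_responses(), st.integers(0, 8))
    def test_monotone_in_answered_items(self, items, idx):
        spec = default_catalog()["PHQ9"]
        if items[idx] is None or items[idx] >= 3:
            return
        bumped = list(items)
        bumped[idx] = items[idx] + 1
        (a,) = score_instrument(ItemResponseRecord("P", "pre", "PHQ9", tuple(items)), spec)
        (b,) = score_instrument(ItemResponseRecord("P", "pre", "PHQ9", tuple(bumped)), spec)
        if a.provenance != "missing":
            assert b.value >= a.value

    @given(phq9_responses())
    def test_imputation_idempotent(self, items):
        spec = default_catalog()["PHQ9"]
        completed, frac, prov = impute_items(items, spec, list(range(9)))
        if prov == "missing":
            return
        completed2, frac2, prov2 = impute_items(list(completed), spec, list(range(9)))
        assert prov2 == "full" and frac2 == 1.0
        assert np.allclose(completed2, completed)
        assert np.isclose(completed2.sum(), completed.sum())

    def test_75_boundary_is_ceiling(self, catalog):
        # 7/9 = 0.778 >= 0.75 computable; 6/9 = 0.667 not; 5/7 = 0.714 not.
        spec9, spec7 = catalog["PHQ9"], catalog["GAD7"]
        assert impute_items([1] * 7 + [None] * 2, spec9, range(9))[2] == "imputed"
        assert impute_items([1] * 6 + [None] * 3, spec9, range(9))[2] == "missing"
        assert impute_items([1] * 5 + [None] * 2, spec7, range(7))[2] == "missing"


def test_score_table_long_format(catalog):
    rows = []
    for item in range(9):
        rows.append(("A", "pre", "PHQ9", item, 1))
    rows.append(("A", "pre", "GAD7", 0, 2))  # 1/7 answered -> missing
    df = pd.DataFrame(rows, columns=["participant_id", "timepoint", "instrument", "item_index", "value"])
    out = score_table(df, catalog)
    by = out.set_index("score_name")
    assert by.loc["PHQ9", "value"] == 9
    assert by.loc["PHQ9", "provenance"] == "full"
    assert by.loc["GAD7", "provenance"] == "missing"
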