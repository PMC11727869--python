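"""Composition of troponin evidence and ECG flags into encounter labels."""
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from mi_phenotype.classifier import (
    PhenotypeLabel,
    Stratum,
    classify_cohort,
    classify_encounter,
    classify_frames,
)
from mi_phenotype.config import RunConfig
from mi_phenotype.ecg_nlp import EcgReport
from mi_phenotype.labs import InjuryCriteria, TroponinSeries
from mi_phenotype.synth import CohortSpec, generate_cohort, write_cohort
from conftest import T0, make_series


def make_report(text, report_id="R1", at=T0):
    return EcgReport(encounter_id="E1", reported_at=at, raw_text=text, report_id=report_id)


POSITIVE_REPORT = "Vent. rate: 84 BPM\n\nSinus rhythm\n* ACUTE MI *"
NEGATIVE_REPORT = "Vent. rate: 84 BPM\n\nSinus rhythm"


@pytest.mark.parametrize(
    "values_at_hours, report_texts, label, stratum",
    [
        ([(0, 5), (4, 20)], [POSITIVE_REPORT], "MI", "two_within_6h"),
        ([(0, 5), (4, 20)], [NEGATIVE_REPORT], "ACUTE_INJURY", "two_within_6h"),
        ([(0, 5), (4, 20)], [], "ACUTE_INJURY", "two_within_6h"),
        ([(0, 500)], [POSITIVE_REPORT], "NEITHER", "not_two_within_6h"),
        ([(0, 5), (30, 20)], [], "ACUTE_INJURY", "not_two_within_6h"),
        ([(0, 5), (30, 20)], [POSITIVE_REPORT], "MI", "not_two_within_6h"),
        ([(0, 5), (4, 7)], [POSITIVE_REPORT], "NEITHER", "two_within_6h"),
    ],
)
def test_classify_encounter(values_at_hours, report_texts, label, stratum, criteria):
    series = make_series(values_at_hours)
    reports = [make_report(t, report_id=f"R{i}") for i, t in enumerate(report_texts)]
    result = classify_encounter(series, reports, criteria, T0)
    assert result.label == PhenotypeLabel(label)
    assert result.stratum == Stratum(stratum)


def test_empty_series_is_neither(criteria):
    result = classify_encounter(TroponinSeries("E1", ()), [make_report(POSITIVE_REPORT)], criteria, T0)
    assert result.label is PhenotypeLabel.NEITHER
    assert result.n_troponins == 0


def test_discarded_report_cannot_upgrade(criteria):
    old_change = (
        "Vent. rate: 84 BPM\n\n* ACUTE MI *\n"
        "When compared with ECG of 01-JAN-2015 10:00, No significant change was found"
    )
    result = classify_encounter(
        make_series([(0, 5), (4, 20)]), [make_report(old_change)], criteria, datetime(2015, 3, 1)
    )
    assert result.label is PhenotypeLabel.ACUTE_INJURY
    assert result.n_reports_retained == 0


def test_evidence_trail_fields(criteria):
    result = classify_encounter(
        make_series([(0, 5), (4, 20)]), [make_report(POSITIVE_REPORT)], criteria, T0
    )
    assert result.injury_evidence.basis == "pair_within_window"
    assert result.positive_report_ids == ("R1",)
    row = result.to_row()
    assert row["qualifying_pair_values"] == "5;20"
    assert row["qualifying_pair_gap_hours"] == "4"


def test_also_check_extremes_switch():
    """Two close draws failing pairwise can still qualify via extremes, if enabled."""
    # pairs 0h/1h within window fail (delta 5); extremes over 30 h pass
    series = make_series([(0, 5), (1, 10), (30, 40)])
    # has_two_within_window -> True because of the 0/1 h pair; 40 at 30 h is alone
    criteria = InjuryCriteria()
    default = classify_encounter(series, [], criteria, T0)
    assert default.label is PhenotypeLabel.NEITHER
    flipped = classify_encounter(
        series, [], criteria, T0, config=RunConfig(also_check_extremes=True)
    )
    assert flipped.label is PhenotypeLabel.ACUTE_INJURY
    assert flipped.injury_evidence.basis == "encounter_extremes"


def _random_encounter(rng):
    n = int(rng.integers(0, 5))
    hours = sorted(rng.uniform(0, 48, size=n))
    values = rng.uniform(0, 120, size=n)
    series = make_series(list(zip(hours, values)))
    texts = []
    if rng.random() < 0.7:
        texts.append(POSITIVE_REPORT if rng.random() < 0.5 else NEGATIVE_REPORT)
    return series, [make_report(t, report_id=f"R{i}") for i, t in enumerate(texts)]


def test_label_lattice_and_report_removal_invariants(criteria):
    """MI implies injury criteria met; removing reports never affects negatives."""
    rng = np.random.default_rng(20150301)
    for _ in range(300):
        series, reports = _random_encounter(rng)
        result = classify_encounter(series, reports, criteria, T0)
        if result.label is PhenotypeLabel.MI:
            assert result.injury_evidence.met and result.positive_report_ids
        stripped = classify_encounter(series, [], criteria, T0)
        if result.label is PhenotypeLabel.MI:
            assert stripped.label is PhenotypeLabel.ACUTE_INJURY
        else:
            assert stripped.label == result.label


def test_adding_measurement_never_demotes(criteria):
    """Label monotonicity under added measurements.

    A new draw can move an encounter from the extremes stratum into the
    within-window stratum, whose pairwise-only rule is stricter; monotonicity
    therefore holds under the configuration that keeps the extremes fallback
    available in both strata.
    """
    rng = np.random.default_rng(42)
    order = {"NEITHER": 0, "ACUTE_INJURY": 1, "MI": 2}
    config = RunConfig(also_check_extremes=True)
    for _ in range(200):
        series, reports = _random_encounter(rng)
        before = classify_encounter(series, reports, criteria, T0, config=config)
        extra_h, extra_v = float(rng.uniform(0, 48)), float(rng.uniform(0, 120))
        pts = [
            ((m.taken_at - T0).total_seconds() / 3600, m.value_ngl) for m in series.measurements
        ] + [(extra_h, extra_v)]
        for r in reports:
            r.discarded, r.body = False, ""
        after = classify_encounter(make_series(pts), reports, criteria, T0, config=config)
        assert order[after.label.value] >= order[before.label.value]


def test_stratum_switch_can_demote_under_default_rules(criteria):
    """Documented edge of the default stratum-specific rules: a new draw close
    in time to an existing one moves the encounter to the within-window
    stratum, where the pairwise rule alone may fail despite qualifying
    encounter extremes."""
    series = make_series([(0, 5), (30, 40)])
    assert classify_encounter(series, [], criteria, T0).label is PhenotypeLabel.ACUTE_INJURY
    extended = make_series([(0, 5), (29.5, 40), (30, 40)])
    assert classify_encounter(extended, [], criteria, T0).label is PhenotypeLabel.NEITHER
    fallback = classify_encounter(
        extended, [], criteria, T0, config=RunConfig(also_check_extremes=True)
    )
    assert fallback.label is PhenotypeLabel.ACUTE_INJURY


def test_classify_cohort_files(tmp_path, criteria):
    tables = generate_cohort(CohortSpec(n_encounters=50, seed=3))
    paths = write_cohort(tables, tmp_path)
    frame = classify_cohort(paths["labs"], paths["reports"])
    # one row per distinct encounter, sorted
    assert list(frame["encounter_id"]) == sorted(set(frame["encounter_id"]))
    expected_ids = set(tables.labs.encounter_id) | set(tables.reports.encounter_id)
    assert set(frame["encounter_id"]) == expected_ids
    # determinism: a second run is identical
    again = classify_cohort(paths["labs"], paths["reports"])
    pd.testing.assert_frame_equal(frame, again)


def test_classify_cohort_empty_inputs(tmp_path):
    labs = tmp_path / "labs.csv"
    reports = tmp_path / "reports.csv"
    labs.write_text("encounter_id,taken_at,value\n")
    reports.write_text("encounter_id,reported_at,text\n")
    frame = classify_cohort(labs, reports)
    assert frame.empty


def test_report_only_encounter_is_neither(tmp_path):
    labs = tmp_path / "labs.csv"
    reports = tmp_path / "reports.csv"
    labs.write_text("encounter_id,taken_at,value\n")
    reports.write_text(
        'encounter_id,reported_at,text\nE9,2015-03-01T08:00:00,"Sinus rhythm\n* ACUTE MI *"\n'
    )
    frame = classify_cohort(labs, reports)
    assert list(frame["label"]) == ["NEITHER"]
    assert list(frame["n_troponins"]) == [0]
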