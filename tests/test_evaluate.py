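"""Agreement statistics: SMC, contingency tables, coverage tables."""
import pandas as pd
import pytest

from mi_phenotype.ecg_nlp import EcgReport
from mi_phenotype.evaluate import (
    build_contingency,
    coverage_table,
    percent,
    round_half_up,
    simple_matching_coefficient,
    smc_from_counts,
)
from mi_phenotype.labs import InjuryCriteria
from conftest import T0, make_series


def frame(rows, columns):
    return pd.DataFrame(rows, columns=columns)


def pheno(*items):
    return frame(
        [{"encounter_id": e, "label": l, "stratum": s} for e, l, s in items],
        ["encounter_id", "label", "stratum"],
    )


def hist(*items):
    return frame(
        [{"encounter_id": e, "mi_status": s} for e, s in items], ["encounter_id", "mi_status"]
    )


class TestSMC:
    def test_perfect_agreement(self):
        p = pheno(("a", "MI", "two_within_6h"), ("b", "NEITHER", "two_within_6h"))
        h = hist(("a", "yes"), ("b", "no"))
        assert simple_matching_coefficient(p, h, {"MI"}).smc == 1.0

    def test_total_disagreement(self):
        p = pheno(("a", "MI", "two_within_6h"), ("b", "NEITHER", "two_within_6h"))
        h = hist(("a", "no"), ("b", "yes"))
        assert simple_matching_coefficient(p, h, {"MI"}).smc == 0.0

    def test_maybe_excluded(self):
        p = pheno(("a", "MI", "two_within_6h"), ("b", "MI", "two_within_6h"))
        h = hist(("a", "yes"), ("b", "maybe"))
        res = simple_matching_coefficient(p, h, {"MI"})
        assert (res.n_agree, res.n_total) == (1, 1)

    def test_stratum_filter(self):
        p = pheno(("a", "MI", "two_within_6h"), ("b", "NEITHER", "not_two_within_6h"))
        h = hist(("a", "yes"), ("b", "yes"))
        res = simple_matching_coefficient(p, h, {"MI"}, "two_within_6h")
        assert (res.n_agree, res.n_total) == (1, 1)

    def test_acute_injury_in_positive_set(self):
        p = pheno(("a", "ACUTE_INJURY", "two_within_6h"))
        h = hist(("a", "yes"),)
        assert simple_matching_coefficient(p, h, {"MI"}).smc == 0.0
        assert simple_matching_coefficient(p, h, {"MI", "ACUTE_INJURY"}).smc == 1.0

    def test_disjoint_keys_error(self):
        with pytest.raises(ValueError):
            simple_matching_coefficient(
                pheno(("a", "MI", "two_within_6h")), hist(("b", "yes")), {"MI"}
            )

    def test_unknown_positive_label_error(self):
        with pytest.raises(ValueError):
            simple_matching_coefficient(
                pheno(("a", "MI", "two_within_6h")), hist(("a", "yes")), {"MJ"}
            )

    def test_symmetric_under_vector_swap(self):
        """SMC depends only on the agreement pattern, not which source is which."""
        p = pheno(
            ("a", "MI", "x"), ("b", "NEITHER", "x"), ("c", "MI", "x"), ("d", "NEITHER", "x")
        )
        h = hist(("a", "yes"), ("b", "yes"), ("c", "no"), ("d", "no"))
        forward = simple_matching_coefficient(p, h, {"MI"})
        swapped_p = pheno(
            ("a", "MI", "x"), ("b", "MI", "x"), ("c", "NEITHER", "x"), ("d", "NEITHER", "x")
        )
        swapped_h = hist(("a", "yes"), ("b", "no"), ("c", "yes"), ("d", "no"))
        backward = simple_matching_coefficient(swapped_p, swapped_h, {"MI"})
        assert forward.smc == backward.smc

    def test_order_invariance(self):
        p = pheno(("a", "MI", "x"), ("b", "NEITHER", "x"))
        h = hist(("b", "no"), ("a", "yes"))
        assert simple_matching_coefficient(p, h, {"MI"}).smc == 1.0

    def test_from_counts_matches_vector_path(self):
        counts = {
            "ACUTE_INJURY": {"yes": 3, "no": 2},
            "MI": {"yes": 5, "no": 1},
            "NEITHER": {"yes": 2, "no": 7},
        }
        res = smc_from_counts(counts, {"MI"})
        assert res.n_total == 20
        assert res.n_agree == 5 + 2 + 7


class TestRounding:
    def test_half_up(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(12.35, 1) == 12.4

    def test_percent(self):
        assert percent(1, 3) == 33.3
        assert percent(0, 0) == 0.0


class TestContingency:
    def test_single_encounter(self):
        table = build_contingency(pheno(("a", "MI", "two_within_6h")), hist(("a", "yes")))
        assert table.counts.loc["MI", ("yes", "two_within_6h")] == 1
        assert table.counts.values.sum() == 1

    def test_cells_partition_encounters(self):
        p = pheno(
            ("a", "MI", "two_within_6h"),
            ("b", "ACUTE_INJURY", "not_two_within_6h"),
            ("c", "NEITHER", "two_within_6h"),
            ("d", "NEITHER", "not_two_within_6h"),
        )
        h = hist(("a", "yes"), ("b", "no"), ("c", "maybe"), ("d", "no"))
        table = build_contingency(p, h)
        assert table.counts.values.sum() == 4
        assert "maybe" in table.counts.columns.get_level_values("mi_status")

    def test_unknown_label_is_hard_error(self):
        with pytest.raises(ValueError):
            build_contingency(pheno(("a", "WEIRD", "two_within_6h")), hist(("a", "yes")))

    def test_display_includes_totals(self):
        p = pheno(("a", "MI", "two_within_6h"), ("b", "NEITHER", "two_within_6h"))
        h = hist(("a", "yes"), ("b", "no"))
        disp = build_contingency(p, h).to_display()
        assert disp.loc["MI", "yes/two_within_6h"] == "1 (100.0)"
        assert disp.loc["Total", "Total"] == "2"


def _report(eid, text, at):
    return EcgReport(encounter_id=eid, reported_at=at, raw_text=text, report_id=f"{eid}-R0")


class TestCoverage:
    def make_inputs(self):
        series = {
            # two values, peak below URL: counts for measurements, nothing else
            "a": make_series([(0, 2), (3, 13)], encounter_id="a"),
            # qualifying rise within window
            "b": make_series([(0, 5), (4, 40)], encounter_id="b"),
        }
        reports = {
            # the only report is an uninformative old-comparison: discarded
            "a": [
                _report(
                    "a",
                    "When compared with ECG of 01-JAN-2014 08:00, No significant change was found",
                    T0,
                )
            ],
        }
        historical = hist(("a", "yes"), ("b", "yes"))
        return series, reports, historical

    def test_rows(self):
        series, reports, historical = self.make_inputs()
        table = coverage_table(series, reports, historical, InjuryCriteria())
        col = ("yes", "n")
        assert table.loc["at_least_2_measurements", col] == 2
        assert table.loc["any_value_elevated", col] == 1  # only b
        assert table.loc["absolute_change_within_window", col] == 1
        assert table.loc["relative_change_within_window", col] == 1  # 5 -> 40
        # discarded report still counts as "have a report" but not in flag rows
        assert table.loc["at_least_one_report", col] == 1
        assert table.loc["infarction_noted", col] == 0
        assert table.loc["at_least_2_measurements", ("yes", "pct")] == 100.0

    def test_empty_cohort(self):
        table = coverage_table({}, {}, hist(("z", "no")), InjuryCriteria())
        assert (table[("no", "n")] == 0).all()
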