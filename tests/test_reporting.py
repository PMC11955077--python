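import logging
import math

import numpy as np
import pytest

from adaptrial import (
    ParticipantRecord,
    baseline_summary,
    final_analysis,
    read_participants,
)
from adaptrial.reporting import ParticipantDataError
from conftest import samples_from_diff  # noqa: F401  (shared fixture module)
from test_posterior import FLAT_ORACLE_180_VS_150

HEADER = "participant_id,age_years,sex,arm,enrol_week,attended\n"


def write_csv(tmp_path, rows, name="participants.csv"):
    path = tmp_path / name
    path.write_text(HEADER + "".join(r + "\n" for r in rows))
    return path


def make_records(n_c, s_c, n_i, s_i, age=30, start_id=0):
    recs = []
    for i in range(n_c):
        recs.append(ParticipantRecord(f"c{start_id + i}", age, "control", 1, i < s_c))
    for i in range(n_i):
        recs.append(ParticipantRecord(f"i{start_id + i}", age, "intervention", 1, i < s_i))
    return recs


class TestReadParticipants:
    def test_well_formed_rows(self, tmp_path):
        path = write_csv(
            tmp_path,
            [
                "p1,25,female,intervention,1,true",
                "p2,40,male,control,1,false",
                "p3,44,female,control,2,1",
                "p4,61,other/unknown,intervention,2,no",
            ],
        )
        recs = read_participants(path)
        assert len(recs) == 4
        assert recs[0].attended is True and recs[1].attended is False
        assert recs[2].age_group == "18-44" and recs[3].age_group == "45plus"

    def test_underage_row_rejected_with_line_number(self, tmp_path):
        path = write_csv(
            tmp_path, ["p1,25,female,control,1,true", "p2,17,male,control,1,true"]
        )
        with pytest.raises(ParticipantDataError, match=r"line 3.*17"):
            read_participants(path)

    def test_non_boolean_attended_rejected(self, tmp_path):
        path = write_csv(tmp_path, ["p1,25,female,control,1,maybe"])
        with pytest.raises(ParticipantDataError, match="line 2"):
            read_participants(path)

    def test_all_bad_rows_listed(self, tmp_path):
        path = write_csv(
            tmp_path,
            ["p1,17,female,control,1,true", "p2,25,male,armwrestling,1,true"],
        )
        with pytest.raises(ParticipantDataError, match=r"2 invalid row\(s\)"):
            read_participants(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("participant_id,age_years,arm,enrol_week,attended\n")
        with pytest.raises(ParticipantDataError, match="sex"):
            read_participants(path)

    def test_empty_file_warns(self, tmp_path, caplog):
        path = write_csv(tmp_path, [])
        with caplog.at_level(logging.WARNING):
            recs = read_participants(path)
        assert recs == []
        assert any("no rows" in m for m in caplog.messages)


class TestBaselineSummary:
    def test_age_mean_and_sample_sd(self):
        recs = [
            ParticipantRecord("a", 20, "control", 1, True),
            ParticipantRecord("b", 40, "control", 1, False),
        ]
        row = baseline_summary(recs).table.loc["control"]
        assert row["age_mean"] == pytest.approx(30.0)
        assert row["age_sd"] == pytest.approx(math.sqrt(200), rel=1e-6)  # 14.142

    def test_single_sex_is_100_percent(self):
        recs = [ParticipantRecord(f"p{i}", 30, "control", 1, True, sex="female") for i in range(5)]
        row = baseline_summary(recs).table.loc["control"]
        assert row["sex_female_pct"] == 100.0
        assert row["sex_male_n"] == 0

    def test_single_record_sd_missing(self):
        row = baseline_summary([ParticipantRecord("a", 30, "control", 1, True)]).table.loc["control"]
        assert math.isnan(row["age_sd"])

    def test_age_outliers_flagged(self):
        recs = [ParticipantRecord(f"p{i}", 30, "control", 1, True) for i in range(20)]
        recs[10] = ParticipantRecord("odd", 95, "control", 1, True)
        recs += [ParticipantRecord("x", 28, "intervention", 1, True)] * 0
        out = baseline_summary(recs).age_outliers
        assert out == ("odd",)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            baseline_summary([])


class TestFinalAnalysis:
    def test_all_young_dataset_partition(self, flat_prior, thresholds):
        """45+ group not estimable; the all-adults group carries the same
        counts (and hence the same posterior, up to MC error) as 18-44."""
        recs = make_records(60, 20, 60, 30, age=30)
        rep = final_analysis(recs, flat_prior, thresholds, n_draws=10_000, seed=3)
        assert not rep.group("45plus").estimable
        g_young, g_all = rep.group("18-44"), rep.group("all")
        assert (g_young.control, g_young.intervention) == (g_all.control, g_all.intervention)
        assert g_all.summary.prob_diff_positive == pytest.approx(
            g_young.summary.prob_diff_positive, abs=0.02
        )

    def test_group_partition_identity(self, prior, thresholds):
        recs = make_records(30, 10, 30, 12, age=30) + make_records(20, 9, 20, 7, age=50, start_id=100)
        rep = final_analysis(recs, prior, thresholds, n_draws=2_000, seed=1)
        for arm in ("control", "intervention"):
            young = getattr(rep.group("18-44"), arm)
            old = getattr(rep.group("45plus"), arm)
            full = getattr(rep.group("all"), arm)
            assert young.n + old.n == full.n
            assert young.successes + old.successes == full.successes

    def test_flat_prior_group_matches_beta_oracle(self, flat_prior, thresholds):
        recs = make_records(300, 150, 300, 180)
        rep = final_analysis(recs, flat_prior, thresholds, n_draws=20_000, seed=2)
        assert rep.group("18-44").summary.prob_diff_positive == pytest.approx(
            FLAT_ORACLE_180_VS_150, abs=0.01
        )

    def test_identical_outcomes_near_symmetric(self, prior, thresholds):
        recs = make_records(100, 50, 100, 50)
        g = final_analysis(recs, prior, thresholds, n_draws=10_000, seed=5).group("18-44")
        assert g.summary.mean_diff == pytest.approx(0.0, abs=0.01)
        assert g.summary.prob_diff_positive == pytest.approx(0.5, abs=0.03)

    def test_intention_to_treat_counts_every_record(self, prior, thresholds):
        recs = make_records(30, 10, 30, 10)
        flipped = list(recs)
        idx = next(i for i, r in enumerate(flipped) if r.arm == "control" and not r.attended)
        r = flipped[idx]
        flipped[idx] = ParticipantRecord(r.participant_id, r.age_years, r.arm, r.enrol_week, True)
        a = final_analysis(recs, prior, thresholds, n_draws=2_000, seed=9)
        b = final_analysis(flipped, prior, thresholds, n_draws=2_000, seed=9)
        assert b.group("all").control.successes == a.group("all").control.successes + 1

    def test_report_reproducible_bit_for_bit(self, prior, thresholds):
        recs = make_records(40, 15, 40, 18)
        a = final_analysis(recs, prior, thresholds, n_draws=2_000, seed=77)
        b = final_analysis(recs, prior, thresholds, n_draws=2_000, seed=77)
        assert a.to_dict() == b.to_dict()
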