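"""Participant-level data handling and the final intention-to-treat analysis.

The final analysis re-runs the posterior engine on the accrued attendance
counts for three groups — young adults 18-44 (the primary-outcome stratum
that drives stopping), adults 45 and older, and all adults — and reports, per
group, the posterior probability of each arm being superior, the probability
of a negligible (< 1 percentage point) difference, and the mean attendance
probability and effect difference with 95% credible intervals.  Every
validated participant is analysed in the arm they were randomized to,
regardless of protocol adherence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .decisions import DecisionThresholds
from .posterior import ArmCounts, InterimData, PosteriorSummary, sample_posterior, summarize_posterior
from .priors import PriorSpec
from .simulate import _as_seedseq, _child

logger = logging.getLogger(__name__)

__all__ = [
    "ParticipantRecord",
    "ParticipantDataError",
    "BaselineSummary",
    "GroupReport",
    "FinalReport",
    "read_participants",
    "baseline_summary",
    "final_analysis",
]

REQUIRED_COLUMNS = ("participant_id", "age_years", "sex", "arm", "enrol_week", "attended")
AGE_GROUPS = ("18-44", "45plus", "all")

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}
_SEXES = {"female", "male", "other/unknown"}


class ParticipantDataError(ValueError):
    """Participant CSV failed validation; the message lists offending lines."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One enrolled participant (intention-to-treat unit)."""

    participant_id: str
    age_years: int
    arm: str  # "intervention" | "control"
    enrol_week: int
    attended: bool
    sex: str = "other/unknown"

    @property
    def age_group(self) -> str:
        return "18-44" if self.age_years <= 44 else "45plus"


def _parse_bool(value: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"not a boolean: {value!r}")


def read_participants(path: str | Path) -> list[ParticipantRecord]:
    """Read and validate the participant CSV.

    The file must carry the header
    ``participant_id,age_years,sex,arm,enrol_week,attended``.  Any malformed
    row (age below 18, unknown arm, non-boolean attended flag, non-positive
    enrolment week) is reported with its file line number; if any row fails,
    a :class:`ParticipantDataError` listing all offending lines is raised so
    no participant can be dropped silently.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParticipantDataError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        logger.warning("participant file %s contains a header but no rows", path)
        return []

    records: list[ParticipantRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        problems = []
        pid = row.participant_id.strip()
        if not pid:
            problems.append("empty participant_id")
        try:
            age = int(row.age_years)
            if age < 18:
                problems.append(f"age_years {age} below eligibility (adults 18+)")
        except ValueError:
            age = -1
            problems.append(f"non-integer age_years {row.age_years!r}")
        arm = row.arm.strip().lower()
        if arm not in ("intervention", "control"):
            problems.append(f"unknown arm {row.arm!r}")
        try:
            week = int(row.enrol_week)
            if week < 1:
                problems.append(f"enrol_week must be positive, got {week}")
        except ValueError:
            week = -1
            problems.append(f"non-integer enrol_week {row.enrol_week!r}")
        try:
            attended = _parse_bool(row.attended)
        except ValueError:
            attended = False
            problems.append(f"non-boolean attended {row.attended!r}")
        sex = row.sex.strip().lower() or "other/unknown"
        if sex not in _SEXES:
            sex = "other/unknown"

        if problems:
            errors.append(f"line {line}: " + "; ".join(problems))
        else:
            records.append(ParticipantRecord(pid, age, arm, week, attended, sex))

    if errors:
        raise ParticipantDataError(
            f"{len(errors)} invalid row(s) in {path}:\n" + "\n".join(errors)
        )
    return records


@dataclass(frozen=True)
class BaselineSummary:
    """Per-arm baseline table plus ids of age outliers (> 3 sd from the arm mean)."""

    table: pd.DataFrame
    age_outliers: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "by_arm": self.table.to_dict(orient="index"),
            "age_outliers": list(self.age_outliers),
        }


def baseline_summary(records: list[ParticipantRecord]) -> BaselineSummary:
    """Baseline characteristics per arm: n, sex frequencies and percentages,
    age mean and sample standard deviation (n-1 denominator; reported missing
    for single-participant arms)."""
    if not records:
        raise ValueError("records must be non-empty")
    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "arm": [r.arm for r in records],
            "age_years": [r.age_years for r in records],
            "sex": [r.sex for r in records],
        }
    )
    rows = {}
    outliers: list[str] = []
    for arm, g in df.groupby("arm"):
        n = len(g)
        mean = float(g["age_years"].mean())
        sd = float(g["age_years"].std(ddof=1)) if n > 1 else float("nan")
        row = {"n": n, "age_mean": mean, "age_sd": sd}
        for sex in sorted(_SEXES):
            count = int((g["sex"] == sex).sum())
            row[f"sex_{sex}_n"] = count
            row[f"sex_{sex}_pct"] = 100.0 * count / n
        rows[arm] = row
        if n > 1 and sd > 0:
            far = g.loc[(g["age_years"] - mean).abs() > 3 * sd, "participant_id"]
            outliers.extend(far.tolist())
    return BaselineSummary(table=pd.DataFrame.from_dict(rows, orient="index"), age_outliers=tuple(outliers))


@dataclass(frozen=True)
class GroupReport:
    """Final-analysis quantities for one age group."""

    group: str
    estimable: bool
    control: ArmCounts | None
    intervention: ArmCounts | None
    summary: PosteriorSummary | None

    def to_dict(self) -> dict:
        d: dict = {"group": self.group, "estimable": self.estimable}
        if self.control is not None and self.intervention is not None:
            d["n_control"] = self.control.n
            d["successes_control"] = self.control.successes
            d["n_intervention"] = self.intervention.n
            d["successes_intervention"] = self.intervention.successes
        if self.summary is not None:
            s = self.summary
            d.update(
                prob_superior_intervention=s.prob_diff_positive,
                prob_superior_control=s.prob_diff_negative,
                prob_negligible=s.prob_negligible,
                negligible_margin=s.negligible_margin,
                mean_p_control=s.mean_p_control,
                ci95_p_control=list(s.ci95_p_control),
                mean_p_intervention=s.mean_p_intervention,
                ci95_p_intervention=list(s.ci95_p_intervention),
                mean_diff=s.mean_diff,
                ci95_diff=list(s.ci95_diff),
            )
        return d


@dataclass(frozen=True)
class FinalReport:
    """Intention-to-treat final analysis for the 18-44, 45+ and all-adults groups."""

    groups: tuple[GroupReport, ...]
    seed: int

    def group(self, name: str) -> GroupReport:
        for g in self.groups:
            if g.group == name:
                return g
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {"seed": self.seed, "groups": [g.to_dict() for g in self.groups]}


def _group_counts(records: list[ParticipantRecord], group: str) -> InterimData:
    if group == "all":
        sel = records
    else:
        sel = [r for r in records if r.age_group == group]
    by_arm = {}
    for arm in ("control", "intervention"):
        arm_recs = [r for r in sel if r.arm == arm]
        by_arm[arm] = ArmCounts(n=len(arm_recs), successes=sum(r.attended for r in arm_recs))
    return InterimData(control=by_arm["control"], intervention=by_arm["intervention"])


def final_analysis(
    records: list[ParticipantRecord],
    prior: PriorSpec | None = None,
    thresholds: DecisionThresholds | None = None,
    n_draws: int = 10_000,
    seed: int = 0,
) -> FinalReport:
    """Run the final intention-to-treat analysis across the three age groups.

    A group with zero participants in either arm is reported as not estimable
    and the analysis continues with the remaining groups.  Re-running with the
    same seed reproduces the report bit for bit.
    """
    if not records:
        raise ValueError("records must be non-empty")
    prior = prior or PriorSpec()
    thresholds = thresholds or DecisionThresholds()
    root = _as_seedseq(seed)

    reports = []
    for gi, group in enumerate(AGE_GROUPS):
        data = _group_counts(records, group)
        if data.control.n == 0 or data.intervention.n == 0:
            logger.warning("group %s has an empty arm; reported as not estimable", group)
            reports.append(GroupReport(group, False, data.control, data.intervention, None))
            continue
        samples = sample_posterior(data, prior, n_draws=n_draws, seed=_child(root, 4, gi))
        summary = summarize_posterior(samples, negligible_margin=thresholds.negligible_D)
        reports.append(GroupReport(group, True, data.control, data.intervention, summary))
    return FinalReport(groups=tuple(reports), seed=seed)
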