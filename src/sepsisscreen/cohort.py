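"""Cohort construction: inclusion/exclusion rules and flow accounting.

Inclusion: adults (>= 18 completed years) with suspected infection, defined
as a chief complaint of fever, a high ED body temperature (>= 37.5 C), or an
ED diagnosis of infection.  Exclusions, applied in a fixed documented
precedence order: trauma, cardiac arrest, death on arrival, transfer to
another hospital, and six or more of the seven vital-sign parameters missing
at either stage.  Only the *attribution* of an exclusion reason depends on
this order; cohort membership does not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import EXCLUSION_REASONS, STAGES, VITALS
from .errors import DataError

__all__ = [
    "CohortFlow", "flag_suspected_infection", "count_missing_vitals",
    "apply_exclusions", "build_cohort",
]

#: body-temperature stages consulted by the "high body temperature" clause
BT_STAGES_DEFAULT = ("ed",)


@dataclass
class CohortFlow:
    """Fig-1-style accounting: every input record lands in exactly one bin."""

    n_input: int = 0
    n_excluded_by_reason: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in EXCLUSION_REASONS}
    )
    n_eligible: int = 0

    def check_conservation(self) -> None:
        total = self.n_eligible + sum(self.n_excluded_by_reason.values())
        if total != self.n_input:
            raise DataError(
                f"flow accounting violated: {total} != n_input {self.n_input}"
            )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_by_reason": dict(self.n_excluded_by_reason),
            "n_eligible": self.n_eligible,
        }

    def log_lines(self) -> list[str]:
        lines = [f"{self.n_input} records assessed"]
        for r, n in self.n_excluded_by_reason.items():
            if n:
                lines.append(f"  excluded ({r.replace('_', ' ')}): {n}")
        lines.append(f"{self.n_eligible} eligible patients with suspected infection")
        return lines

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def flag_suspected_infection(
    record: pd.Series | pd.DataFrame, bt_stages: tuple[str, ...] = BT_STAGES_DEFAULT
) -> bool | pd.Series:
    """Suspected infection: fever complaint OR BT >= 37.5 C OR ED infection diagnosis.

    A null body temperature simply fails the BT clause.  ``bt_stages``
    selects which stage(s) the temperature clause consults (default: ED).
    """
    if isinstance(record, pd.DataFrame):
        hot = pd.Series(False, index=record.index)
        for s in bt_stages:
            hot = hot | (record[f"bt_{s}"] >= 37.5)
        return (
            record["chief_complaint_fever"].astype(bool)
            | hot
            | record["ed_infection_diagnosis"].astype(bool)
        )
    hot = any(
        pd.notna(record[f"bt_{s}"]) and record[f"bt_{s}"] >= 37.5 for s in bt_stages
    )
    return bool(
        record["chief_complaint_fever"] or hot or record["ed_infection_diagnosis"]
    )


def count_missing_vitals(record: pd.Series | pd.DataFrame, stage: str):
    """Number of nulls among the seven vital parameters at one stage (0-7)."""
    if stage not in STAGES:
        raise DataError(f"unknown stage {stage!r} (expected one of {STAGES})")
    cols = [f"{v}_{stage}" for v in VITALS]
    if isinstance(record, pd.DataFrame):
        return record[cols].isna().sum(axis=1)
    return int(pd.isna([record[c] for c in cols]).sum())


def apply_exclusions(record: pd.Series, max_missing: int = 5) -> str:
    """First matching exclusion reason, or ``"eligible"``.

    Assumes the record already passed the age and suspected-infection gates.
    Precedence: trauma, cardiac arrest, death on arrival, transfer out,
    insufficient vitals (>= 6 of 7 missing at either stage).
    """
    for reason in ("trauma", "cardiac_arrest", "death_on_arrival", "transfer_out"):
        if bool(record.get(reason, False)):
            return reason
    for stage in STAGES:
        if count_missing_vitals(record, stage) > max_missing:
            return "insufficient_vitals"
    return "eligible"


def build_cohort(
    records: pd.DataFrame,
    bt_stages: tuple[str, ...] = BT_STAGES_DEFAULT,
    max_missing: int = 5,
) -> tuple[pd.DataFrame, CohortFlow]:
    """Apply all gates; return (eligible records, flow accounting).

    Each record is counted once under its first matching reason in the
    documented precedence order (age, suspected infection, then the
    exclusion list).  Idempotent on its own output.
    """
    if records["id"].duplicated().any():
        raise DataError("duplicate patient ids")
    flow = CohortFlow(n_input=len(records))
    if len(records) == 0:
        return records.copy(), flow

    reason = pd.Series("eligible", index=records.index)
    adult = records["age"] >= 18
    reason[~adult] = "age_lt_18"
    suspected = flag_suspected_infection(records, bt_stages)
    reason[(reason == "eligible") & ~suspected] = "no_suspected_infection"

    for r in ("trauma", "cardiac_arrest", "death_on_arrival", "transfer_out"):
        if r in records.columns:
            hit = records[r].astype(bool)
            reason[(reason == "eligible") & hit] = r
    for stage in STAGES:
        too_few = count_missing_vitals(records, stage) > max_missing
        reason[(reason == "eligible") & too_few] = "insufficient_vitals"

    for r in EXCLUSION_REASONS:
        flow.n_excluded_by_reason[r] = int((reason == r).sum())
    eligible = records.loc[reason == "eligible"].copy()
    flow.n_eligible = len(eligible)
    flow.check_conservation()
    return eligible, flow
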