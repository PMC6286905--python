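"""Scan and inpatient-night accounting: empiric protocol versus predictive planning.

Under the empiric protocol every administered cycle is followed by
post-treatment dosimetry scanning (three sessions after the first cycle, one
after each later cycle) and each scanned cycle costs one inpatient night.
Under the predictive algorithm the first cycle is always scanned in full,
but later cycles are scanned only while the planner still asks for
monitoring; unscanned cycles allow same-day release.  An optional short
planar scan before release is tallied separately — it is a visual check,
not a dosimetry scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .decision import Action

__all__ = [
    "CountingRules",
    "WorkloadSummary",
    "count_empiric",
    "count_predictive",
    "percent_reduction",
    "reduction_report",
]


def percent_reduction(empiric: float, predictive: float, precision: int = 1) -> float:
    """Percentage saved by the predictive protocol, ``100 * (1 - pred/empiric)``."""
    if empiric <= 0:
        raise ValueError("empiric count must be positive")
    return round(100.0 * (1.0 - predictive / empiric), precision)


@dataclass(frozen=True)
class CountingRules:
    """How scans and nights accrue per cycle."""

    scans_first_cycle: int = 3
    scans_subsequent_cycle: int = 1
    nights_per_scanned_cycle: int = 1
    nights_per_unscanned_cycle: int = 0
    scan_minutes: float = 35.0
    release_scan_minutes: float = 15.0

    def __post_init__(self) -> None:
        if min(
            self.scans_first_cycle,
            self.scans_subsequent_cycle,
            self.nights_per_scanned_cycle,
            self.nights_per_unscanned_cycle,
        ) < 0:
            raise ValueError("counting rules must be non-negative")


@dataclass(frozen=True)
class WorkloadSummary:
    scans_empiric: int
    scans_predictive: int
    nights_empiric: int
    nights_predictive: int
    scan_reduction_pct: float
    night_reduction_pct: float
    release_scans: int
    scanner_minutes_empiric: float
    scanner_minutes_predictive: float
    per_patient: pd.DataFrame


def count_empiric(cohort, rules: CountingRules | None = None) -> tuple[int, int]:
    """Total (scans, nights) when every administered cycle is scanned."""
    rules = rules or CountingRules()
    scans = nights = 0
    for rec in cohort:
        c = rec.cycles_completed
        scans += rules.scans_first_cycle + rules.scans_subsequent_cycle * (c - 1)
        nights += rules.nights_per_scanned_cycle * c
    return scans, nights


def _scanned_cycles(rec, decisions: pd.DataFrame) -> list[bool]:
    """Per administered cycle, whether it is followed by dosimetry scanning.

    Cycle 1 always is; cycle c >= 2 only if the decision after cycle c - 1
    asked to continue with post-treatment scans.
    """
    mine = decisions[decisions["patient_id"] == rec.patient_id]
    actions = dict(zip(mine["after_cycle"], mine["action"]))
    scanned = [True]
    for c in range(2, rec.cycles_completed + 1):
        scanned.append(actions.get(c - 1) == Action.CONTINUE_WITH_PTS.value)
    return scanned


def count_predictive(
    cohort,
    decisions: pd.DataFrame,
    rules: CountingRules | None = None,
) -> tuple[int, int]:
    """Total (scans, nights) when scanning follows the planner's decisions."""
    rules = rules or CountingRules()
    known = set(decisions["patient_id"]) if len(decisions) else set()
    unknown = known - {rec.patient_id for rec in cohort}
    if unknown:
        raise ValueError(f"decisions refer to patients not in the cohort: {sorted(unknown)}")
    scans = nights = 0
    for rec in cohort:
        for c, is_scanned in enumerate(_scanned_cycles(rec, decisions), start=1):
            if is_scanned:
                scans += rules.scans_first_cycle if c == 1 else rules.scans_subsequent_cycle
                nights += rules.nights_per_scanned_cycle
            else:
                nights += rules.nights_per_unscanned_cycle
    return scans, nights


def reduction_report(
    cohort,
    decisions: pd.DataFrame,
    rules: CountingRules | None = None,
    precision: int = 1,
) -> WorkloadSummary:
    """Compare the two protocols over a cohort and report percentage reductions."""
    rules = rules or CountingRules()
    if not cohort:
        raise ValueError("cannot report reductions for an empty cohort")
    rows = []
    release_scans = 0
    for rec in cohort:
        c = rec.cycles_completed
        e_scans = rules.scans_first_cycle + rules.scans_subsequent_cycle * (c - 1)
        e_nights = rules.nights_per_scanned_cycle * c
        scanned = _scanned_cycles(rec, decisions)
        p_scans = sum(
            (rules.scans_first_cycle if i == 0 else rules.scans_subsequent_cycle)
            for i, s in enumerate(scanned)
            if s
        )
        p_nights = sum(
            rules.nights_per_scanned_cycle if s else rules.nights_per_unscanned_cycle
            for s in scanned
        )
        release_scans += sum(not s for s in scanned)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "cycles": c,
                "scans_empiric": e_scans,
                "scans_predictive": p_scans,
                "nights_empiric": e_nights,
                "nights_predictive": p_nights,
            }
        )
    per_patient = pd.DataFrame(rows)
    se, sp = int(per_patient["scans_empiric"].sum()), int(per_patient["scans_predictive"].sum())
    ne, np_ = int(per_patient["nights_empiric"].sum()), int(per_patient["nights_predictive"].sum())
    if se == 0 or ne == 0:
        raise ValueError("empiric counts are zero; reductions are undefined")
    return WorkloadSummary(
        scans_empiric=se,
        scans_predictive=sp,
        nights_empiric=ne,
        nights_predictive=np_,
        scan_reduction_pct=percent_reduction(se, sp, precision),
        night_reduction_pct=percent_reduction(ne, np_, precision),
        release_scans=release_scans,
        scanner_minutes_empiric=se * rules.scan_minutes,
        scanner_minutes_predictive=sp * rules.scan_minutes
        + release_scans * rules.release_scan_minutes,
        per_patient=per_patient,
    )
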