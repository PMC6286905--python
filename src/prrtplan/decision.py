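"""Treatment-planning decisions from fitted dose models.

After each cycle the planner asks: what is the probability that the
cumulative kidney dose at the end of treatment will exceed the safety
threshold (25 Gy by default)?  The answer drives a small set of actions:

* after cycle 1 — patients whose D1 falls below a fitted threshold T1 can
  receive all four cycles with no further dosimetry scans;
* after cycle 2 — the (D1, D2) plane splits into zones by the four-cycle
  exceedance probability P4 (A: < 10%, B: intermediate, C: > 95%) and the
  three-cycle probability P3 (D/E/F at the same levels).  Zone pairs map to
  actions: clear four cycles, give exactly three, keep scanning, refer for
  individual review, or stop;
* after cycle 3 — the fourth cycle is cleared, reviewed or withheld from
  the predicted D4.

The pre-existing ("legacy") rule — extrapolate the mean of the observed
cycles one cycle forward — is kept as a callable baseline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import LinearModelFit, exceedance_probability

__all__ = [
    "Action",
    "RiskPolicy",
    "DecisionState",
    "first_cycle_threshold",
    "classify_zones",
    "recommend",
    "plan_cohort",
    "legacy_expected_cumulative",
    "legacy_withhold",
    "perturb_for_observer_variability",
    "worst_case_variability",
    "threshold_sensitivity",
    "exceedance_grid",
]


class Action(str, enum.Enum):
    COMPLETE_ALL_FOUR_NO_PTS = "complete_all_four_no_pts"
    GIVE_THREE_ONLY_NO_PTS = "give_three_only_no_pts"
    CONTINUE_WITH_PTS = "continue_with_pts"
    INDIVIDUAL_REVIEW = "individual_review"
    STOP_NOW = "stop_now"


#: caution ranking used by the monotone-safety property: higher means the
#: action responds to a higher dose-risk situation
ACTION_CAUTION = {
    Action.COMPLETE_ALL_FOUR_NO_PTS: 0,
    Action.CONTINUE_WITH_PTS: 1,
    Action.GIVE_THREE_ONLY_NO_PTS: 2,
    Action.INDIVIDUAL_REVIEW: 3,
    Action.STOP_NOW: 4,
}


@dataclass(frozen=True)
class RiskPolicy:
    """Risk levels of the planning protocol.

    ``continue_risk`` is the exceedance probability below which further
    cycles are cleared (default 10%); ``preclusion_risk`` is the error rate
    tolerated when declaring a cycle unsafe (default 5%, applied as
    exceedance > 95%).  The asymmetry is deliberate: withholding an
    effective treatment is graded more strictly than allowing one.
    """

    dose_threshold: float = 25.0
    continue_risk: float = 0.10
    preclusion_risk: float = 0.05

    def __post_init__(self) -> None:
        if self.dose_threshold <= 0:
            raise ValueError("dose_threshold must be positive")
        if not 0 < self.continue_risk < 1 - self.preclusion_risk < 1:
            raise ValueError(
                "risk levels must satisfy 0 < continue_risk < 1 - preclusion_risk < 1"
            )


@dataclass(frozen=True)
class DecisionState:
    """Zones and recommended action at one decision point.

    Zone fields are ``None`` at decision points where the corresponding
    model is not consulted (after cycles 1 and 3).
    """

    action: Action | None
    four_cycle_zone: str | None = None
    three_cycle_zone: str | None = None
    probabilities: dict[str, float] | None = None


def legacy_expected_cumulative(doses) -> float:
    """Legacy extrapolation: cumulative dose plus the mean of observed cycles.

    Over p cycles with cumulative dose ``cum`` this is ``cum * (p + 1) / p``,
    the expected cumulative dose if the next cycle repeats the average of
    the previous ones.
    """
    doses = list(doses)
    if not doses:
        raise ValueError("need at least one dose")
    cum = float(sum(doses))
    return cum + cum / len(doses)


def legacy_withhold(doses, policy: RiskPolicy | None = None) -> bool:
    """True when the legacy rule predicts the next cycle breaks the threshold."""
    policy = policy or RiskPolicy()
    return legacy_expected_cumulative(doses) > policy.dose_threshold


def first_cycle_threshold(
    fit_simple: LinearModelFit,
    policy: RiskPolicy | None = None,
    bracket: tuple[float, float] | None = None,
    resolution: float = 1e-3,
) -> float:
    """Largest D1 at which four cycles stay below the threshold with high confidence.

    Finds, by bisection to ``resolution`` Gy, the largest first-cycle dose
    such that the probability of D1 plus the predicted D2 + D3 + D4
    exceeding ``policy.dose_threshold`` remains below ``policy.continue_risk``.
    Requires a single-predictor fit with non-negative slope (the exceedance
    must be monotone increasing over the bracket).
    """
    policy = policy or RiskPolicy()
    if len(fit_simple.predictor_labels) != 1:
        raise ValueError("first-cycle threshold needs a single-predictor fit")
    if fit_simple.coefficients[1] < 0:
        raise ValueError(
            "exceedance is not monotone increasing: the fitted slope is negative"
        )
    lo, hi = bracket if bracket is not None else (resolution, policy.dose_threshold)

    def risk(d1: float) -> float:
        return exceedance_probability(
            fit_simple, [d1], known_cumulative=d1, threshold=policy.dose_threshold
        ).probability_exceed

    if risk(lo) >= policy.continue_risk:
        raise ValueError(
            f"exceedance already {risk(lo):.3f} at the lower bracket edge "
            f"{lo:g} Gy; the continue risk is never attained"
        )
    if risk(hi) < policy.continue_risk:
        raise ValueError(
            f"exceedance stays below the continue risk up to {hi:g} Gy; "
            "widen the bracket"
        )
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if risk(mid) < policy.continue_risk:
            lo = mid
        else:
            hi = mid
    return lo


def _zone(p: float, low: float, high: float, labels: tuple[str, str, str]) -> str:
    # boundary values go to the intermediate (more monitored) zone
    if p < low:
        return labels[0]
    if p > high:
        return labels[2]
    return labels[1]


def classify_zones(
    fit_joint34: LinearModelFit,
    fit_d3: LinearModelFit,
    d1: float,
    d2: float,
    policy: RiskPolicy | None = None,
) -> DecisionState:
    """Zone pair for a patient after two cycles.

    P4 is the probability that D1 + D2 plus the predicted D3 + D4 exceeds
    the threshold; P3 the same for D1 + D2 plus the predicted D3.  Zones:
    A/D below ``continue_risk``, C/F above ``1 - preclusion_risk``, B/E in
    between (boundaries inclusive).
    """
    if d1 <= 0 or d2 <= 0:
        raise ValueError("doses must be positive")
    policy = policy or RiskPolicy()
    known = d1 + d2
    p4 = exceedance_probability(
        fit_joint34, [d1, d2], known_cumulative=known, threshold=policy.dose_threshold
    ).probability_exceed
    p3 = exceedance_probability(
        fit_d3, [d1, d2], known_cumulative=known, threshold=policy.dose_threshold
    ).probability_exceed
    high = 1 - policy.preclusion_risk
    return DecisionState(
        action=None,
        four_cycle_zone=_zone(p4, policy.continue_risk, high, ("A", "B", "C")),
        three_cycle_zone=_zone(p3, policy.continue_risk, high, ("D", "E", "F")),
        probabilities={"p_exceed_4_cycles": p4, "p_exceed_3_cycles": p3},
    )


def recommend(
    doses_so_far,
    fits: dict[str, LinearModelFit],
    policy: RiskPolicy | None = None,
    t1: float | None = None,
) -> DecisionState:
    """Recommended action after 1, 2 or 3 observed cycles.

    ``fits`` maps ``"simple"`` (D2+D3+D4 on D1), ``"joint34"`` (D3+D4 on
    D1, D2), ``"d3"`` (D3 on D1, D2) and ``"d4"`` (D4 on D1, D2, D3) to
    fitted models; only the fits the stage consults need be present.

    After cycle 2, zone pairs resolve with stopping conditions checked
    before clearances: F -> stop; C with D -> give exactly three cycles;
    A -> clear all four; E -> individual review; otherwise (B with D) ->
    keep scanning.

    ``t1`` optionally supplies a precomputed first-cycle threshold (Gy) so
    cohort-scale planning does not repeat the bisection per patient.
    """
    doses = [float(d) for d in doses_so_far]
    if not doses:
        raise ValueError("need at least one observed dose")
    if len(doses) > 3:
        raise ValueError("all four cycles given; nothing left to decide")
    if any(d <= 0 for d in doses):
        raise ValueError("doses must be positive")
    policy = policy or RiskPolicy()

    if len(doses) == 1:
        if t1 is None:
            t1 = first_cycle_threshold(fits["simple"], policy)
        action = (
            Action.COMPLETE_ALL_FOUR_NO_PTS if doses[0] < t1 else Action.CONTINUE_WITH_PTS
        )
        return DecisionState(action=action, probabilities={"first_cycle_threshold": t1})

    if len(doses) == 2:
        state = classify_zones(fits["joint34"], fits["d3"], doses[0], doses[1], policy)
        z4, z3 = state.four_cycle_zone, state.three_cycle_zone
        if z3 == "F":
            action = Action.STOP_NOW
        elif z4 == "C" and z3 == "D":
            action = Action.GIVE_THREE_ONLY_NO_PTS
        elif z4 == "A":
            action = Action.COMPLETE_ALL_FOUR_NO_PTS
        elif z3 == "E":
            action = Action.INDIVIDUAL_REVIEW
        else:  # B with D
            action = Action.CONTINUE_WITH_PTS
        return DecisionState(
            action=action,
            four_cycle_zone=z4,
            three_cycle_zone=z3,
            probabilities=state.probabilities,
        )

    known = sum(doses)
    res = exceedance_probability(
        fits["d4"], doses, known_cumulative=known, threshold=policy.dose_threshold
    )
    p = res.probability_exceed
    if p < policy.continue_risk:
        action = Action.COMPLETE_ALL_FOUR_NO_PTS
    elif p > 1 - policy.preclusion_risk:
        action = Action.STOP_NOW
    else:
        action = Action.INDIVIDUAL_REVIEW
    return DecisionState(action=action, probabilities={"p_exceed_4_cycles": p})


def plan_cohort(
    cohort,
    fits: dict[str, LinearModelFit],
    policy: RiskPolicy | None = None,
) -> pd.DataFrame:
    """Run the follow-up algorithm over a cohort.

    Decisions are made after each administered cycle while monitoring is
    still active (the previous action was ``continue_with_pts``); once a
    patient is cleared, capped or stopped, no further decisions are taken.
    Returns one row per decision with patient id, the cycle just completed,
    the action, and the zone labels where applicable.
    """
    policy = policy or RiskPolicy()
    t1 = first_cycle_threshold(fits["simple"], policy) if "simple" in fits else None
    rows = []
    for rec in cohort:
        action = Action.CONTINUE_WITH_PTS
        for cycle in range(1, min(rec.cycles_completed, 3) + 1):
            if action != Action.CONTINUE_WITH_PTS:
                break
            state = recommend(rec.doses[:cycle], fits, policy, t1=t1)
            action = state.action
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "after_cycle": cycle,
                    "action": action.value,
                    "four_cycle_zone": state.four_cycle_zone,
                    "three_cycle_zone": state.three_cycle_zone,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "after_cycle", "action", "four_cycle_zone", "three_cycle_zone"],
    )


def perturb_for_observer_variability(dose: float, relative_shift: float) -> float:
    """Dose re-read by another observer differing by ``relative_shift`` (fraction)."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    if relative_shift <= -1:
        raise ValueError("relative_shift must exceed -1 (dose must stay positive)")
    return dose * (1.0 + relative_shift)


def worst_case_variability(mean_pct: float, sd_pct: float) -> float:
    """Worst-case observer variability |mean| + sd, in percent."""
    if sd_pct < 0:
        raise ValueError("sd must be non-negative")
    return abs(mean_pct) + sd_pct


def threshold_sensitivity(
    fit: LinearModelFit,
    x0,
    known_cumulative: float,
    thresholds,
) -> pd.DataFrame:
    """Exceedance probability of one prediction at several safety thresholds.

    ``thresholds`` must be positive and sorted ascending; the returned
    probabilities are non-increasing along the list (strictly decreasing
    whenever the predictive law has positive spread).
    """
    thresholds = [float(t) for t in thresholds]
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for t in thresholds:
        res = exceedance_probability(fit, x0, known_cumulative, t)
        rows.append({"threshold_gy": t, "probability_exceed": res.probability_exceed})
    return pd.DataFrame(rows)


def exceedance_grid(
    fit: LinearModelFit,
    policy: RiskPolicy | None = None,
    d1_range: tuple[float, float] = (0.1, 12.0),
    d2_range: tuple[float, float] = (0.1, 12.0),
    step: float = 0.1,
) -> pd.DataFrame:
    """Rectangular grid of exceedance probabilities over the (D1, D2) plane.

    The fit must have predictors (D1, D2); each grid point contributes its
    own D1 + D2 to the known cumulative dose.  The long-format output
    (d1, d2, probability) replots the decision-zone contour maps directly.
    """
    if step <= 0:
        raise ValueError("grid step must be positive")
    if d1_range[1] < d1_range[0] or d2_range[1] < d2_range[0]:
        raise ValueError("grid ranges must be non-empty")
    policy = policy or RiskPolicy()
    d1s = np.round(np.arange(d1_range[0], d1_range[1] + step / 2, step), 10)
    d2s = np.round(np.arange(d2_range[0], d2_range[1] + step / 2, step), 10)
    rows = []
    for d1 in d1s:
        for d2 in d2s:
            p = exceedance_probability(
                fit, [d1, d2], known_cumulative=d1 + d2, threshold=policy.dose_threshold
            ).probability_exceed
            rows.append({"d1_gy": d1, "d2_gy": d2, "probability_exceed": p})
    return pd.DataFrame(rows)
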