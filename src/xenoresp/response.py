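"""Five-level ordinal tumor-response classification.

Categories, worst to best: PD (progressive disease), SD (stable disease),
PR (partial response), CR (complete response), MCR (maintained complete
response).  The rules, applied with precedence MCR > CR > PR > SD > PD so
every trajectory gets exactly one call:

* MCR — no measurable tumor for at least three consecutive readings, all
  falling strictly after the last treatment day;
* CR — the tumor becomes unmeasurable at least twice (consecutively or
  intermittently) but the MCR criterion is not met;
* PR — at least 50% regression from baseline at some point (min V_t/V0
  <= 0.5) with measurable tumor otherwise;
* SD — less than 50% regression throughout and no more than 25% net
  growth at the end of study;
* PD — less than 50% regression throughout and more than 25% growth at
  the end of study.

"End of study" is each animal's last available reading, which may be an
early termination at volume quadrupling.  An objective response is any of
PR, CR, MCR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from statistics import median

import numpy as np

from xenoresp.trajectory import Trajectory, relative_volumes


class ResponseCategory(IntEnum):
    """Ordinal response scale; larger is better."""

    PD = 0
    SD = 1
    PR = 2
    CR = 3
    MCR = 4


#: Categories counting as an objective response.
OBJECTIVE = frozenset({ResponseCategory.PR, ResponseCategory.CR, ResponseCategory.MCR})


@dataclass(frozen=True)
class ResponseCall:
    category: ResponseCategory
    model_id: str = ""
    animal_id: str = ""
    arm: str = ""

    @property
    def objective(self) -> bool:
        return self.category in OBJECTIVE


@dataclass
class GroupResponse:
    """One response call per (model, arm), aggregated over its animals."""

    arm: str
    per_animal: list[ResponseCall]
    group_category: ResponseCall
    model_id: str = ""


class InsufficientDataError(ValueError):
    """Trajectory too short to classify."""


def _has_unmeasurable_run(unmeasurable: np.ndarray, days: np.ndarray,
                          min_len: int, after_day: float) -> bool:
    """True if >= min_len consecutive unmeasurable readings all fall on
    days strictly greater than after_day."""
    run = 0
    for u, d in zip(unmeasurable, days):
        if u and d > after_day:
            run += 1
            if run >= min_len:
                return True
        else:
            run = 0
    return False


def classify_animal(traj: Trajectory, measurable_min: float = 0.0) -> ResponseCall:
    """Classify one animal's trajectory on the PD..MCR ordinal scale.

    ``measurable_min`` is the volume (mm^3) at or below which the tumor is
    considered unmeasurable; the default 0 treats only an exactly-zero
    recorded volume as disappeared.
    """
    if len(traj) < 2:
        raise InsufficientDataError(
            f"animal {traj.animal_id!r}: need >= 2 readings to classify, got {len(traj)}"
        )
    if measurable_min < 0:
        raise ValueError("measurable_min must be >= 0")

    rel = relative_volumes(traj)
    unmeasurable = traj.volumes <= measurable_min

    def call(cat: ResponseCategory) -> ResponseCall:
        return ResponseCall(category=cat, model_id=traj.model_id,
                            animal_id=traj.animal_id, arm=traj.arm)

    if _has_unmeasurable_run(unmeasurable, traj.days, 3, traj.treatment_end_day):
        return call(ResponseCategory.MCR)
    if int(unmeasurable.sum()) >= 2:
        return call(ResponseCategory.CR)
    if float(rel.min()) <= 0.5:
        return call(ResponseCategory.PR)
    if float(rel[-1]) <= 1.25:
        return call(ResponseCategory.SD)
    return call(ResponseCategory.PD)


def classify_group(calls: list[ResponseCall], arm: str = "", model_id: str = "") -> GroupResponse:
    """Aggregate per-animal calls into one group call.

    The group ordinal is the median of the per-animal ordinals; a
    non-integer median is rounded down, i.e. toward the worse response.
    """
    if not calls:
        raise ValueError("cannot aggregate an empty list of response calls")
    med = median(int(c.category) for c in calls)
    cat = ResponseCategory(int(np.floor(med)))
    if not arm:
        arm = calls[0].arm
    if not model_id:
        model_id = calls[0].model_id
    return GroupResponse(
        arm=arm, per_animal=list(calls),
        group_category=ResponseCall(category=cat, model_id=model_id, arm=arm),
        model_id=model_id,
    )


def objective_response_count(groups: list[GroupResponse]) -> int:
    """Number of groups whose aggregated call is an objective response."""
    return sum(1 for g in groups if g.group_category.objective)
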