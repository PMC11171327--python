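"""Tumor-volume trajectories and time-to-event computation.

The event of interest is a quadrupling of tumor volume relative to the
day-0 (treatment-start) measurement.  When the quadrupling threshold is
crossed between two weekly measurements, the exact event day is estimated
by interpolating between the bracketing measurements on the log-volume
scale, i.e. assuming exponential (log-linear) growth across the interval.
Animals whose tumors never reach the threshold are censored at their last
observed measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Volume substituted for an unmeasurable (zero) reading when it is the
#: lower bracket of a log-scale interpolation; keeps the logarithm defined.
DEFAULT_FLOOR_VOLUME = 1.0

TRAJECTORY_COLUMNS = ["model", "animal_id", "arm", "day", "volume_mm3"]


class TrajectoryParseError(ValueError):
    """Raised when a trajectory CSV does not conform to the schema."""


@dataclass
class Trajectory:
    """One animal's tumor-volume time series.

    Parameters
    ----------
    model_id : str
        Xenograft model identifier (e.g. a tumor line name).
    animal_id : str
        Unique animal identifier within the model.
    arm : str
        Treatment-arm label.
    days : array-like of int
        Measurement days, strictly increasing, starting at day 0
        (treatment start).
    volumes : array-like of float
        Tumor volumes in mm^3 aligned to ``days``; the day-0 volume must
        be positive.  A volume of exactly 0 encodes an unmeasurable tumor.
    treatment_end_day : float
        Day on which the last scheduled dose is given; used by the
        maintained-complete-response rule downstream.
    """

    model_id: str
    animal_id: str
    arm: str
    days: np.ndarray
    volumes: np.ndarray
    treatment_end_day: float = 0.0

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.days.ndim != 1 or self.volumes.ndim != 1:
            raise ValueError("days and volumes must be one-dimensional")
        if len(self.days) != len(self.volumes):
            raise ValueError("days and volumes must have equal length")
        if len(self.days) < 1:
            raise ValueError("trajectory must contain at least one reading")
        if self.days[0] != 0:
            raise ValueError("first measurement must be at day 0")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if self.volumes[0] <= 0:
            raise ValueError("baseline (day 0) volume must be positive")
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be non-negative")

    def __len__(self) -> int:
        return len(self.days)

    @property
    def baseline(self) -> float:
        return float(self.volumes[0])


@dataclass
class EventResult:
    """Time-to-event outcome for one animal.

    ``status`` is ``"event"`` if the tumor reached 4x its baseline volume
    (time interpolated on the log scale where needed), ``"censored"``
    otherwise (time = last observed day).
    """

    time_days: float
    status: str  # "event" | "censored"
    threshold_volume: float
    model_id: str = ""
    animal_id: str = ""
    arm: str = ""

    @property
    def observed(self) -> bool:
        return self.status == "event"


def event_time(traj: Trajectory, floor_volume: float = DEFAULT_FLOOR_VOLUME) -> EventResult:
    """Time to volume quadrupling with log-linear interpolation.

    The event threshold is ``4 * V0``.  The first measurement at or above
    the threshold defines the event interval; within it the event day is

        t = t_prev + (t_i - t_prev) * ln(E / V_prev) / ln(V_i / V_prev)

    i.e. the crossing time of the exponential through the two bracketing
    points.  If the threshold is hit exactly on a measurement day, that day
    is returned without interpolation.  If the preceding reading is
    unmeasurable (volume 0, regrowth from complete regression),
    ``floor_volume`` is substituted so the logarithm is defined.

    Animals that never reach the threshold are censored at their last
    measurement day; no extrapolation past the observation window is done.
    """
    v0 = traj.baseline
    threshold = 4.0 * v0
    days, volumes = traj.days, traj.volumes

    above = np.nonzero(volumes >= threshold)[0]
    if len(above) == 0:
        return EventResult(
            time_days=float(days[-1]), status="censored",
            threshold_volume=threshold, model_id=traj.model_id,
            animal_id=traj.animal_id, arm=traj.arm,
        )

    i = int(above[0])
    if i == 0 or volumes[i] == threshold or volumes[i - 1] >= threshold:
        # threshold met exactly on a reading day, or already at/above on
        # the previous reading (only possible at i=0, excluded by V0>0
        # unless threshold==V0)
        t = float(days[i])
    else:
        v_prev = volumes[i - 1]
        if v_prev <= 0:
            v_prev = floor_volume
        if volumes[i] == v_prev:  # guard: flat segment at the threshold
            t = float(days[i])
        else:
            frac = math.log(threshold / v_prev) / math.log(volumes[i] / v_prev)
            t = float(days[i - 1] + (days[i] - days[i - 1]) * frac)
    return EventResult(
        time_days=t, status="event", threshold_volume=threshold,
        model_id=traj.model_id, animal_id=traj.animal_id, arm=traj.arm,
    )


def relative_volumes(traj: Trajectory) -> np.ndarray:
    """Volumes relative to baseline, ``V_t / V0``; first element is 1."""
    return traj.volumes / traj.baseline


def read_trajectories(path, treatment_end_day: float | None = None) -> list[Trajectory]:
    """Read trajectories from CSV.

    Expected columns: ``model,animal_id,arm,day,volume_mm3`` (an optional
    ``treatment_end_day`` column is honored; the ``treatment_end_day``
    argument overrides it).  Rows are grouped by (model, animal_id) and
    sorted by day.  Duplicate (animal, day) rows are an error.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: missing required column(s) {missing}")
    if not pd.api.types.is_numeric_dtype(pd.to_numeric(df["volume_mm3"], errors="coerce")):
        raise TrajectoryParseError(f"{path}: non-numeric volume_mm3")
    bad = df[pd.to_numeric(df["volume_mm3"], errors="coerce").isna()]
    if len(bad):
        raise TrajectoryParseError(
            f"{path}: non-numeric volume_mm3 at row(s) {list(bad.index[:5])}"
        )
    df["volume_mm3"] = pd.to_numeric(df["volume_mm3"])
    df["day"] = pd.to_numeric(df["day"])

    out: list[Trajectory] = []
    for (model, animal), grp in df.groupby(["model", "animal_id"], sort=True):
        grp = grp.sort_values("day")
        dup = grp["day"].duplicated()
        if dup.any():
            d = grp.loc[dup, "day"].iloc[0]
            raise TrajectoryParseError(
                f"{path}: duplicate day {d} for animal {animal!r} of model {model!r}"
            )
        arms = grp["arm"].unique()
        if len(arms) != 1:
            raise TrajectoryParseError(
                f"{path}: inconsistent arm labels {list(arms)} for animal {animal!r}"
            )
        tend = treatment_end_day
        if tend is None:
            tend = float(grp["treatment_end_day"].iloc[0]) if "treatment_end_day" in grp else 0.0
        try:
            out.append(Trajectory(
                model_id=str(model), animal_id=str(animal), arm=str(arms[0]),
                days=grp["day"].to_numpy(), volumes=grp["volume_mm3"].to_numpy(),
                treatment_end_day=tend,
            ))
        except ValueError as exc:
            raise TrajectoryParseError(
                f"{path}: invalid trajectory for animal {animal!r}: {exc}"
            ) from exc
    return out


def write_trajectories(trajectories: list[Trajectory], path) -> None:
    """Write trajectories to CSV in the declared schema (round-trip safe)."""
    rows = []
    for t in trajectories:
        for d, v in zip(t.days, t.volumes):
            rows.append({
                "model": t.model_id, "animal_id": t.animal_id, "arm": t.arm,
                "day": int(d), "volume_mm3": v,
                "treatment_end_day": t.treatment_end_day,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_events(events: list[EventResult], path) -> None:
    """Export event results as ``model,animal_id,arm,time_days,status``."""
    pd.DataFrame([
        {"model": e.model_id, "animal_id": e.animal_id, "arm": e.arm,
         "time_days": e.time_days, "status": e.status}
        for e in events
    ]).to_csv(path, index=False)


def read_events(path) -> list[EventResult]:
    """Read an event-result CSV produced by :func:`write_events`."""
    df = pd.read_csv(path)
    return [
        EventResult(time_days=float(r.time_days), status=str(r.status),
                    threshold_volume=float("nan"), model_id=str(r.model),
                    animal_id=str(r.animal_id), arm=str(r.arm))
        for r in df.itertuples()
    ]
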