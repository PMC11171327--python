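"""Synthetic inputs with the statistical structure of a xenograft efficacy study.

Tumor-volume trajectories follow a piecewise-exponential model measured on
a weekly grid: day 0 is treatment start (pre-enrollment growth is not
simulated), volumes regress at ``k_regress`` for ``effect_days``, then
regrow at ``k_regrow``; an arm with no drug effect (``effect_days == 0``)
grows at ``k_control`` throughout.  Measurement noise is multiplicative
lognormal (caliper error scales with tumor size).  A model volume falling
below the detection limit is recorded as exactly 0 (unmeasurable), and a
series is truncated at the first reading reaching 400% of baseline — the
study-termination rule.

The module also generates 4PL dose-response plates and read-pair alignment
summaries of known species origin, so every downstream stage has a ground
truth to recover.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from xenoresp.trajectory import Trajectory
from xenoresp.rnaseq import READ_SUMMARY_COLUMNS

#: Weekly measurement cadence (days), the standard in vivo design.
DEFAULT_MEASURE_INTERVAL = 7

#: Caliper volume below which a synthetic tumor is recorded as 0 mm^3.
DEFAULT_DETECTION_LIMIT = 10.0


@dataclass
class GrowthParams:
    """Parameters of one arm's piecewise-exponential growth model.

    Rates are per-day exponential coefficients; ``v0`` must satisfy the
    enrollment rule (tumor at least 100 mm^3 at treatment start).
    """

    v0: float = 200.0
    k_control: float = 0.08
    k_regress: float = 0.0          # <= 0 during drug effect
    effect_days: float = 0.0        # 0 => no drug effect, grow at k_control
    k_regrow: float = 0.0
    cv_noise: float = 0.15
    measure_interval_days: int = DEFAULT_MEASURE_INTERVAL
    horizon_days: float = 84.0
    detection_limit_mm3: float = DEFAULT_DETECTION_LIMIT
    treatment_end_day: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v0 < 100:
            raise ValueError("v0 must be >= 100 mm^3 (enrollment rule)")
        if self.measure_interval_days < 1:
            raise ValueError("measure_interval_days must be >= 1")
        if self.cv_noise < 0:
            raise ValueError("cv_noise must be >= 0")
        if self.k_regress > 0:
            raise ValueError("k_regress must be <= 0")
        if self.effect_days < 0 or self.horizon_days <= 0:
            raise ValueError("effect_days >= 0 and horizon_days > 0 required")

    def model_volume(self, t) -> np.ndarray:
        """Noise-free model volume at day(s) t."""
        t = np.asarray(t, dtype=float)
        if self.effect_days == 0:
            logv = np.log(self.v0) + self.k_control * t
        else:
            logv = (np.log(self.v0)
                    + self.k_regress * np.minimum(t, self.effect_days)
                    + self.k_regrow * np.maximum(0.0, t - self.effect_days))
        return np.exp(logv)


@dataclass
class ArmSpec:
    name: str
    params: GrowthParams
    n_animals: int
    archetype: str = ""  # intended PD/SD/PR/CR/MCR label, for recovery tests

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")


@dataclass
class CohortSpec:
    arms: list[ArmSpec]
    model_id: str = "SYN-1"
    seed: int = 0


def _sub_rng(master_seed: int, *counters: int) -> np.random.Generator:
    """Sub-stream derivation: the master seed plus a tuple of counters
    (arm index, animal index) seeds an independent generator."""
    return np.random.default_rng([int(master_seed), *map(int, counters)])


def _simulate_with_rng(params: GrowthParams, rng: np.random.Generator,
                       model_id: str, animal_id: str, arm: str) -> Trajectory:
    days = np.arange(0.0, params.horizon_days + 0.5, params.measure_interval_days)
    model = params.model_volume(days)
    eps = (np.exp(rng.normal(0.0, params.cv_noise, size=len(days)))
           if params.cv_noise > 0 else np.ones(len(days)))
    vols = model * eps
    vols = np.where(vols < params.detection_limit_mm3, 0.0, vols)
    threshold = 4.0 * vols[0]
    keep = len(days)
    hit = np.nonzero(vols >= threshold)[0]
    hit = hit[hit > 0]
    if len(hit):
        keep = int(hit[0]) + 1  # include the terminating reading
    return Trajectory(model_id=model_id, animal_id=animal_id, arm=arm,
                      days=days[:keep], volumes=vols[:keep],
                      treatment_end_day=params.treatment_end_day)


def simulate_trajectory(params: GrowthParams,
                        model_id: str = "SYN-1",
                        animal_id: str = "a1",
                        arm: str = "arm") -> Trajectory:
    """Simulate one animal's weekly volume series.

    Measured volume is ``v_model(t) * eps`` with lognormal noise
    ``eps = exp(N(0, cv^2))``; values below the detection limit record as
    exactly 0 (unmeasurable).  The series stops at the first reading at
    or above 4x the measured baseline, or at the horizon.  Reproducible
    under ``params.seed``.
    """
    return _simulate_with_rng(params, _sub_rng(params.seed),
                              model_id=model_id, animal_id=animal_id, arm=arm)


def simulate_cohort(spec: CohortSpec) -> list[Trajectory]:
    """Simulate all animals of a cohort.

    Each animal gets an independent random sub-stream derived from the
    cohort seed and its (arm, animal) indices, so outputs are reproducible
    and order-independent.
    """
    out: list[Trajectory] = []
    for ai, arm in enumerate(spec.arms):
        for j in range(arm.n_animals):
            out.append(_simulate_with_rng(
                arm.params, _sub_rng(spec.seed, ai, j),
                model_id=spec.model_id,
                animal_id=f"{arm.name}-{j + 1:02d}", arm=arm.name,
            ))
    return out


#: Growth parameters tuned so that, noise-free, the trajectory lands in
#: the named category; with default 15% noise, per-animal calls remain
#: overwhelmingly correct.  Kinetics are in the range observed for
#: pediatric solid-tumor xenografts (doubling times ~1-2 weeks untreated).
_ARCHETYPES: dict[str, dict] = {
    "PD": dict(v0=200.0, k_control=0.08, effect_days=0.0),
    "SD": dict(v0=200.0, k_regress=-0.02, effect_days=14.0, k_regrow=0.004,
               treatment_end_day=7.0),
    "PR": dict(v0=250.0, k_regress=-0.06, effect_days=21.0, k_regrow=0.03,
               treatment_end_day=7.0),
    "CR": dict(v0=150.0, k_regress=-0.25, effect_days=21.0, k_regrow=0.4,
               treatment_end_day=21.0),
    "MCR": dict(v0=150.0, k_regress=-0.3, effect_days=84.0, k_regrow=0.0,
                treatment_end_day=7.0),
}


def archetype_growth_params(category: str, cv_noise: float = 0.15,
                            seed: int = 0, horizon_days: float = 84.0) -> GrowthParams:
    """Growth parameters whose noise-free trajectory classifies as
    ``category`` (one of PD, SD, PR, CR, MCR)."""
    if category not in _ARCHETYPES:
        raise ValueError(f"unknown archetype {category!r}; expected one of {sorted(_ARCHETYPES)}")
    return GrowthParams(cv_noise=cv_noise, seed=seed, horizon_days=horizon_days,
                        **_ARCHETYPES[category])


def archetype_cohort(n_per_arm: int = 10, cv_noise: float = 0.15,
                     seed: int = 0, model_id: str = "SYN-1") -> CohortSpec:
    """A five-arm cohort, one arm per response archetype."""
    arms = [ArmSpec(name=cat, params=archetype_growth_params(cat, cv_noise=cv_noise),
                    n_animals=n_per_arm, archetype=cat)
            for cat in ("PD", "SD", "PR", "CR", "MCR")]
    return CohortSpec(arms=arms, model_id=model_id, seed=seed)


# ---------------------------------------------------------------------------
# dose-response plates

def simulate_dose_response(top: float, bottom: float, hill: float, ic50: float,
                           concentrations, cv: float = 0.0, seed: int = 0,
                           replicates: int = 1, cell_line: str = "synthetic",
                           drug: str = "drug", arm: str = "single",
                           unit: str = "uM") -> pd.DataFrame:
    """Simulate a viability plate from a 4PL curve.

    Signal is ``4PL(conc) * (1 + N(0, cv))`` per well; a zero concentration
    reads the top asymptote.  Returns the plate table in the standard
    schema (cell_line, drug, arm, concentration, unit, replicate, signal).
    """
    rng = _sub_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    rows = []
    for rep in range(1, replicates + 1):
        clean = np.where(conc > 0,
                         bottom + (top - bottom) / (1.0 + (conc / np.where(conc > 0, ic50, 1.0)) ** hill),
                         top)
        noise = rng.normal(0.0, cv, size=len(conc)) if cv > 0 else np.zeros(len(conc))
        sig = clean * (1.0 + noise)
        for c, s in zip(conc, sig):
            rows.append({"cell_line": cell_line, "drug": drug, "arm": arm,
                         "concentration": c, "unit": unit, "replicate": rep,
                         "signal": s})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# read-pair alignment summaries

def simulate_read_pairs(n_human: int, n_mouse: int, n_ambiguous: int,
                        score_margin: float = 10.0, seed: int = 0,
                        n_unaligned: int = 0) -> pd.DataFrame:
    """Simulate per-pair alignment summaries of known species origin.

    Unambiguous pairs either align only to their true genome or align to
    both with every criterion (score, mismatches, matched length) at least
    ``score_margin``-better — in score units where applicable — toward the
    true genome.  Ambiguous pairs have identical metrics for both genomes.
    The ``true_origin`` column carries the ground truth
    (human / mouse / ambiguous / none).
    """
    rng = _sub_rng(seed)
    rows = []

    def _metrics():
        score = float(rng.integers(120, 200))
        nm = int(rng.integers(0, 4))
        mlen = int(rng.integers(150, 200))
        return score, nm, mlen

    def _pair(origin: str, idx: int):
        rid = f"{origin}_{idx:06d}"
        if origin == "none":
            return {"read_id": rid, "score_h": np.nan, "nm_h": np.nan,
                    "mlen_h": np.nan, "score_m": np.nan, "nm_m": np.nan,
                    "mlen_m": np.nan, "true_origin": origin}
        if origin == "ambiguous":
            s, nm, ml = _metrics()
            return {"read_id": rid, "score_h": s, "nm_h": nm, "mlen_h": ml,
                    "score_m": s, "nm_m": nm, "mlen_m": ml,
                    "true_origin": origin}
        s, nm, ml = _metrics()
        both = bool(rng.random() < 0.5)  # half cross-align, half genome-specific
        if both:
            worse = {"score": s - score_margin - float(rng.integers(0, 20)),
                     "nm": nm + 1 + int(rng.integers(0, 3)),
                     "mlen": max(0, ml - 10 - int(rng.integers(0, 30)))}
        else:
            worse = None
        if origin == "human":
            row = {"read_id": rid, "score_h": s, "nm_h": nm, "mlen_h": ml,
                   "score_m": np.nan, "nm_m": np.nan, "mlen_m": np.nan}
            if worse:
                row.update(score_m=worse["score"], nm_m=worse["nm"], mlen_m=worse["mlen"])
        else:
            row = {"read_id": rid, "score_m": s, "nm_m": nm, "mlen_m": ml,
                   "score_h": np.nan, "nm_h": np.nan, "mlen_h": np.nan}
            if worse:
                row.update(score_h=worse["score"], nm_h=worse["nm"], mlen_h=worse["mlen"])
        row["true_origin"] = origin
        return row

    for i in range(n_human):
        rows.append(_pair("human", i))
    for i in range(n_mouse):
        rows.append(_pair("mouse", i))
    for i in range(n_ambiguous):
        rows.append(_pair("ambiguous", i))
    for i in range(n_unaligned):
        rows.append(_pair("none", i))
    df = pd.DataFrame(rows, columns=READ_SUMMARY_COLUMNS + ["true_origin"])
    return df


# ---------------------------------------------------------------------------
# YAML cohort configuration

def cohort_from_yaml(path) -> CohortSpec:
    """Load a :class:`CohortSpec` from YAML.

    Schema::

        model: SYN-1
        seed: 1
        arms:
          - name: control
            n_animals: 8
            archetype: PD          # preset kinetics, or:
            params: {v0: 200, k_regress: -0.1, effect_days: 21, ...}

    Explicit ``params`` entries override the archetype preset field-wise.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    seed = int(cfg.get("seed", 0))
    arms = []
    for entry in cfg["arms"]:
        archetype = entry.get("archetype", "")
        if archetype:
            params = archetype_growth_params(archetype, seed=seed)
        else:
            params = GrowthParams(seed=seed)
        overrides = entry.get("params", {}) or {}
        params = dataclasses.replace(params, **overrides)
        arms.append(ArmSpec(name=entry["name"], params=params,
                            n_animals=int(entry["n_animals"]),
                            archetype=archetype))
    return CohortSpec(arms=arms, model_id=str(cfg.get("model", "SYN-1")), seed=seed)
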