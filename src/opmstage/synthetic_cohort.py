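"""Synthetic patient cohorts with the statistical structure the analysis assumes.

Each patient carries a latent disease state (occult peritoneal metastasis,
OPM), a reference-standard call (staging laparoscopy + peritoneal washing
cytology, modelled as perfect by default), a binary PET index-test result
driven by sensitivity/specificity, a disease subtype for reference-positive
patients (macroscopic/cytology combinations P1CY1, P1CY0, P0CY1), initial
and final clinical stages, and tracer-uptake values (primary-tumour SUVmax
and the two target-to-background ratios) drawn from group-specific normals
truncated at zero.

The module also provides the cohort-level tallies the pipeline consumes
(confusion table, staging-migration tally, uptake-group comparison) and a
deterministic 109-patient reference cohort matching the published 2x2 table
and stage-migration split exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

from .domain_types import (
    INITIAL_STAGES,
    OPM_SUBTYPES,
    ConfusionTable,
    PatientRecord,
)

__all__ = [
    "UptakeGroupParams",
    "DEFAULT_UPTAKE_PARAMS",
    "DEFAULT_SUBTYPE_MIX",
    "DEFAULT_STAGE_MIX",
    "generate_cohort",
    "aggregate",
    "staging_migration",
    "compute_tbr",
    "group_compare",
    "reference_cohort",
]


@dataclass(frozen=True)
class UptakeGroupParams:
    """Mean/SD of primary-tumour uptake measures within one disease group."""

    suv_max: Tuple[float, float]
    tbr1: Tuple[float, float]
    tbr2: Tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("suv_max", "tbr1", "tbr2"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} SD must be >= 0")


#: primary-tumour uptake in patients with vs without OPM (mean, SD)
DEFAULT_UPTAKE_PARAMS: Dict[str, UptakeGroupParams] = {
    "opm": UptakeGroupParams(suv_max=(18.49, 6.00), tbr1=(13.28, 4.78), tbr2=(19.65, 7.08)),
    "no_opm": UptakeGroupParams(suv_max=(14.25, 5.95), tbr1=(10.87, 4.85), tbr2=(15.00, 6.36)),
}

#: reference-positive subtype mixture (P1CY1, P1CY0, P0CY1) = (7, 6, 3)/16
DEFAULT_SUBTYPE_MIX = (7 / 16, 6 / 16, 3 / 16)

#: initial clinical-stage mixture (IIB, III, IVA), calibrated so the expected
#: stage-migration split among index-positive patients is 5:10:2
DEFAULT_STAGE_MIX = (5 / 17, 10 / 17, 2 / 17)


def _check_mixture(name: str, mix: Sequence[float], k: int) -> np.ndarray:
    arr = np.asarray(mix, dtype=float)
    if arr.shape != (k,):
        raise ValueError(f"{name} must have {k} entries, got {arr.shape}")
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError(f"{name} entries must be probabilities in [0, 1]")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1, got {arr.sum()!r}")
    return arr


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated at zero (proper renormalised truncation)."""
    if sd == 0:
        return np.full(size, max(mean, 0.0))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    n: int = 109,
    prevalence: float = 16 / 109,
    sens: float = 0.75,
    spec: float = 88 / 93,
    subtype_mix: Sequence[float] = DEFAULT_SUBTYPE_MIX,
    stage_mix: Sequence[float] = DEFAULT_STAGE_MIX,
    uptake_params: Mapping[str, UptakeGroupParams] = None,
    seed: int = 0,
    lap_false_negative_rate: float = 0.0,
    cytology_blind: bool = False,
) -> list:
    """Simulate a staging cohort of *n* patients.

    Data-generating process, per patient:

    * ``true_opm ~ Bernoulli(prevalence)``;
    * ``pet_result ~ Bernoulli(sens)`` for true positives, ``Bernoulli(1 - spec)``
      for true negatives;
    * ``lap_result = true_opm`` — the reference standard is treated as perfect;
      a nonzero *lap_false_negative_rate* flips reference-positive calls
      negative with that probability (off by default);
    * subtypes for true positives drawn from *subtype_mix* over
      ``(P1CY1, P1CY0, P0CY1)``; with *cytology_blind* set, P0CY1 patients
      (cytology-only disease, nothing macroscopic for PET to see) are forced
      PET-negative;
    * ``initial_stage`` drawn from *stage_mix* over ``(IIB, III, IVA)``;
      ``final_stage = "IVB"`` exactly when the reference call is positive;
    * uptake values drawn from the group-specific (OPM vs no-OPM) normals
      truncated at zero.

    Reproducible: the same (seed, parameters) always yields the same cohort.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, v in (("prevalence", prevalence), ("sens", sens), ("spec", spec),
                    ("lap_false_negative_rate", lap_false_negative_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    sub_mix = _check_mixture("subtype_mix", subtype_mix, 3)
    stg_mix = _check_mixture("stage_mix", stage_mix, 3)
    if uptake_params is None:
        uptake_params = DEFAULT_UPTAKE_PARAMS

    rng = np.random.default_rng(seed)
    true_opm = rng.random(n) < prevalence
    u_pet = rng.random(n)
    pet = np.where(true_opm, u_pet < sens, u_pet < (1.0 - spec))
    lap = true_opm.copy()
    if lap_false_negative_rate > 0:
        lap &= ~(rng.random(n) < lap_false_negative_rate)
    subtype_idx = rng.choice(3, size=n, p=sub_mix)
    stage_idx = rng.choice(3, size=n, p=stg_mix)

    # group-specific uptake draws (sampled for everyone, selected per group)
    opm_p, neg_p = uptake_params["opm"], uptake_params["no_opm"]
    uptake = {}
    for meas in ("suv_max", "tbr1", "tbr2"):
        pos_draw = _truncated_normal(rng, *getattr(opm_p, meas), n)
        neg_draw = _truncated_normal(rng, *getattr(neg_p, meas), n)
        uptake[meas] = np.where(true_opm, pos_draw, neg_draw)

    records = []
    width = len(str(n))
    for i in range(n):
        subtype = OPM_SUBTYPES[subtype_idx[i]] if true_opm[i] else "none"
        pet_i = bool(pet[i])
        if cytology_blind and subtype == "P0CY1":
            pet_i = False
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:0{width}d}",
                true_opm=bool(true_opm[i]),
                opm_subtype=subtype,
                pet_result=pet_i,
                lap_result=bool(lap[i]),
                initial_stage=INITIAL_STAGES[stage_idx[i]],
                final_stage="IVB" if lap[i] else INITIAL_STAGES[stage_idx[i]],
                suv_max=float(uptake["suv_max"][i]),
                tbr1=float(uptake["tbr1"][i]),
                tbr2=float(uptake["tbr2"][i]),
            )
        )
    return records


def aggregate(records: Sequence[PatientRecord]) -> ConfusionTable:
    """Cross-tabulate the index test against the reference-standard call."""
    if not records:
        raise ValueError("empty cohort")
    tp = sum(r.pet_result and r.lap_result for r in records)
    fp = sum(r.pet_result and not r.lap_result for r in records)
    fn = sum(not r.pet_result and r.lap_result for r in records)
    tn = sum(not r.pet_result and not r.lap_result for r in records)
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def staging_migration(records: Sequence[PatientRecord]) -> Dict[Tuple[str, str], int]:
    """Stage migration induced by the index test.

    Every index-test-positive patient is upstaged to metastatic stage IVB by
    the test's reading, whatever the reference standard later concludes; the
    tally maps ``(initial_stage, "IVB")`` to the number of index-positive
    patients making that transition.  Cohort-fraction percentages are left
    to the caller (counts divided by ``len(records)``).
    """
    tally: Dict[Tuple[str, str], int] = {}
    for r in records:
        if r.pet_result:
            key = (r.initial_stage, "IVB")
            tally[key] = tally.get(key, 0) + 1
    return tally


def compute_tbr(
    tumor_suvmax: float, background_suvmax: float, background_suvmean: float
) -> Tuple[float, float]:
    """Target-to-background ratios of a lesion.

    TBR1 = tumour SUVmax / background SUVmax;
    TBR2 = tumour SUVmax / background SUVmean (mediastinal blood pool).
    Because a region's SUVmean never exceeds its SUVmax, TBR2 >= TBR1.
    """
    if background_suvmax <= 0 or background_suvmean <= 0:
        raise ValueError("background uptake must be positive")
    return tumor_suvmax / background_suvmax, tumor_suvmax / background_suvmean


def group_compare(
    values_a: Sequence[float], values_b: Sequence[float], equal_var: bool = True
) -> Tuple[float, float]:
    """Two-sided two-sample t test for an uptake-group comparison.

    Pooled-variance (Student) by default; ``equal_var=False`` gives Welch.
    Returns ``(t, p)``.  When the pooled variance is zero the statistic is
    undefined and ``(nan, nan)`` is returned as an explicit marker.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return (math.nan, math.nan)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def reference_cohort() -> list:
    """Deterministic 109-patient cohort matching the published tallies.

    Construction (no randomness): 12 true positives, 5 false positives,
    4 false negatives (3 of them cytology-only P0CY1 disease), 88 true
    negatives; reference-positive subtypes split 7 P1CY1 / 6 P1CY0 /
    3 P0CY1; initial stages of the 17 index-positive patients split
    5 IIB / 10 III / 2 IVA.  Uptake values are set to the group means.
    """
    opm_u = DEFAULT_UPTAKE_PARAMS["opm"]
    neg_u = DEFAULT_UPTAKE_PARAMS["no_opm"]

    # (count, true_opm, subtype, pet) blocks; subtype split puts the three
    # cytology-only cases among the false negatives
    blocks = [
        (7, True, "P1CY1", True),   # macroscopic + cytology, detected
        (5, True, "P1CY0", True),   # macroscopic only, detected
        (1, True, "P1CY0", False),  # macroscopic only, missed
        (3, True, "P0CY1", False),  # cytology only, missed
        (5, False, "none", True),   # false positives
        (88, False, "none", False),  # true negatives
    ]
    # initial stages of the 17 PET-positives, in block order (12 TP then 5 FP)
    pos_stages = ["IIB"] * 5 + ["III"] * 10 + ["IVA"] * 2
    records = []
    i = 0
    pos_i = 0
    for count, opm, subtype, pet in blocks:
        for _ in range(count):
            i += 1
            if pet:
                initial = pos_stages[pos_i]
                pos_i += 1
            else:
                initial = "III"
            u = opm_u if opm else neg_u
            records.append(
                PatientRecord(
                    patient_id=f"R{i:03d}",
                    true_opm=opm,
                    opm_subtype=subtype,
                    pet_result=pet,
                    lap_result=opm,
                    initial_stage=initial,
                    final_stage="IVB" if opm else initial,
                    suv_max=u.suv_max[0],
                    tbr1=u.tbr1[0],
                    tbr2=u.tbr2[0],
                )
            )
    return records
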