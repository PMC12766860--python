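"""Decision-tree cost model for four preoperative staging strategies.

The model compares, for a cohort of locally advanced gastric-cancer patients,
four ways of deciding who proceeds to curative-intent gastrectomy:

* **S1** — no staging: every patient undergoes gastrectomy.
* **S2** — staging laparoscopy (with peritoneal cytology) for all; only
  laparoscopy-negative patients undergo gastrectomy.
* **S3** — PET/CT for all; only PET-negative patients undergo gastrectomy.
* **S4** — PET/CT for all; PET-positives get a confirmatory laparoscopy
  (the arbiter), PET-negatives and PET-positive/laparoscopy-negative
  patients undergo gastrectomy.

Branch probabilities are the observed cohort frequencies; terminal costs are
the sums of the unit procedure costs along each path.  Patients found
metastatic by the strategy's decision rule are spared gastrectomy.

"Futile gastrectomy prevented" counts reference-positive patients whom the
strategy spares gastrectomy; "missed OPM" counts reference-positive patients
who still undergo gastrectomy.
"""

from __future__ import annotations

from typing import Dict

from .domain_types import (
    ChanceNode,
    CohortCounts,
    CostInputs,
    StrategyModel,
    StrategyOutcome,
    TerminalNode,
)

__all__ = [
    "STRATEGY_IDS",
    "STRATEGY_LABELS",
    "derive_unit_costs",
    "build_strategies",
    "build_strategies_from_rates",
    "strategy_expected_costs",
    "evaluate",
    "tally_outcomes",
    "compare",
]

STRATEGY_IDS = ("S1", "S2", "S3", "S4")

STRATEGY_LABELS = {
    "S1": "gastrectomy for all (no staging)",
    "S2": "laparoscopic staging for all",
    "S3": "PET/CT for all",
    "S4": "PET/CT for all, laparoscopy for PET-positives",
}


def derive_unit_costs(
    s1_cost: float, s3_delta: float, s2_delta: float, counts: CohortCounts
) -> CostInputs:
    """Back-solve unit procedure costs from per-patient strategy aggregates.

    The published cost results report only per-patient aggregates: the S1
    total, the S3 change relative to S1 (negative = saving) and the S2 change
    relative to S1.  With the branch frequencies fixed by the cohort's 2x2
    table, the strategy definitions form a triangular linear system:

    * ``c_gast = s1_cost`` (S1 is a pure gastrectomy pathway);
    * ``s1_cost + s3_delta = c_pet + (pet_neg/n) * c_gast``;
    * ``s1_cost + s2_delta = c_lap + (ref_neg/n) * c_gast`` (the S2
      gastrectomy branch holds the laparoscopy-negative patients).

    Raises ``ValueError("inconsistent aggregates")`` if any solved unit cost
    is non-positive.
    """
    n = counts.n
    c_gast = s1_cost
    c_pet = (s1_cost + s3_delta) - (counts.pet_neg / n) * c_gast
    c_lap = (s1_cost + s2_delta) - (counts.ref_neg / n) * c_gast
    if c_gast <= 0 or c_pet <= 0 or c_lap <= 0:
        raise ValueError(
            "inconsistent aggregates: solved unit costs "
            f"(c_pet={c_pet:.2f}, c_lap={c_lap:.2f}, c_gast={c_gast:.2f}) "
            "must all be positive"
        )
    return CostInputs(c_pet=c_pet, c_lap=c_lap, c_gast=c_gast)


def _strategy_trees(
    prev_pos: float, p_tp: float, p_fp: float, p_fn: float, p_tn: float, costs: CostInputs
) -> Dict[str, StrategyModel]:
    """Build the four trees from joint cell probabilities of (PET, reference)."""
    c_pet, c_lap, c_gast = costs.c_pet, costs.c_lap, costs.c_gast
    prev_neg = 1.0 - prev_pos

    s1 = StrategyModel(
        "S1",
        ChanceNode(
            (
                (prev_pos, TerminalNode(c_gast, {"gastrectomy", "reference_positive"})),
                (prev_neg, TerminalNode(c_gast, {"gastrectomy"})),
            )
        ),
        STRATEGY_LABELS["S1"],
    )

    s2 = StrategyModel(
        "S2",
        ChanceNode(
            (
                (prev_pos, TerminalNode(c_lap, {"laparoscopy", "reference_positive"})),
                (prev_neg, TerminalNode(c_lap + c_gast, {"laparoscopy", "gastrectomy"})),
            )
        ),
        STRATEGY_LABELS["S2"],
    )

    s3 = StrategyModel(
        "S3",
        ChanceNode(
            (
                (p_tp, TerminalNode(c_pet, {"pet", "reference_positive"})),
                (p_fp, TerminalNode(c_pet, {"pet"})),
                (p_fn, TerminalNode(c_pet + c_gast, {"pet", "gastrectomy", "reference_positive"})),
                (p_tn, TerminalNode(c_pet + c_gast, {"pet", "gastrectomy"})),
            )
        ),
        STRATEGY_LABELS["S3"],
    )

    pet_pos = p_tp + p_fp
    pet_neg = p_fn + p_tn
    branches = []
    if pet_pos > 0:
        pos_node = ChanceNode(
            (
                (
                    p_tp / pet_pos,
                    TerminalNode(c_pet + c_lap, {"pet", "laparoscopy", "reference_positive"}),
                ),
                (
                    p_fp / pet_pos,
                    TerminalNode(c_pet + c_lap + c_gast, {"pet", "laparoscopy", "gastrectomy"}),
                ),
            )
        )
        branches.append((pet_pos, pos_node))
    if pet_neg > 0:
        neg_node = ChanceNode(
            (
                (
                    p_fn / pet_neg,
                    TerminalNode(c_pet + c_gast, {"pet", "gastrectomy", "reference_positive"}),
                ),
                (p_tn / pet_neg, TerminalNode(c_pet + c_gast, {"pet", "gastrectomy"})),
            )
        )
        branches.append((pet_neg, neg_node))
    s4 = StrategyModel("S4", ChanceNode(tuple(branches)), STRATEGY_LABELS["S4"])

    return {"S1": s1, "S2": s2, "S3": s3, "S4": s4}


def build_strategies(counts: CohortCounts, costs: CostInputs) -> Dict[str, StrategyModel]:
    """The four strategy trees with branch probabilities set to the observed
    cohort frequencies of *counts*."""
    n = counts.n
    return _strategy_trees(
        counts.ref_pos / n,
        counts.tp / n,
        counts.fp / n,
        counts.fn / n,
        counts.tn / n,
        costs,
    )


def build_strategies_from_rates(
    prevalence: float, sensitivity: float, specificity: float, costs: CostInputs
) -> Dict[str, StrategyModel]:
    """The four strategy trees parameterised by (prevalence, sens, spec).

    Joint cell probabilities follow the usual factorisation, e.g.
    ``P(TP) = prevalence * sensitivity``.  Used by the sensitivity analyses,
    which perturb rates rather than raw counts.
    """
    for name, v in (
        ("prevalence", prevalence),
        ("sensitivity", sensitivity),
        ("specificity", specificity),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return _strategy_trees(
        prevalence,
        prevalence * sensitivity,
        (1.0 - prevalence) * (1.0 - specificity),
        prevalence * (1.0 - sensitivity),
        (1.0 - prevalence) * specificity,
        costs,
    )


def strategy_expected_costs(prevalence, sensitivity, specificity, c_pet, c_lap, c_gast):
    """Closed-form per-patient expected costs of the four strategies.

    Algebraically identical to evaluating the trees; accepts scalars or
    NumPy arrays (used to vectorise sweeps and probabilistic sensitivity
    analysis).  Returns a dict keyed by strategy id.
    """
    pet_pos = prevalence * sensitivity + (1.0 - prevalence) * (1.0 - specificity)
    pet_neg_gast = prevalence * (1.0 - sensitivity) + (1.0 - prevalence) * specificity
    return {
        "S1": c_gast + 0.0 * prevalence,  # broadcast with array inputs
        "S2": c_lap + (1.0 - prevalence) * c_gast,
        "S3": c_pet + pet_neg_gast * c_gast,
        "S4": c_pet
        + pet_pos * c_lap
        + (pet_neg_gast + (1.0 - prevalence) * (1.0 - specificity)) * c_gast,
    }


def evaluate(tree: StrategyModel) -> float:
    """Expected per-patient cost: sum over paths of probability x terminal cost."""
    return sum(p * leaf.cost for p, leaf in tree.paths())


def tally_outcomes(strategy: StrategyModel, counts: CohortCounts) -> StrategyOutcome:
    """Expected event counts for a cohort of ``counts.n`` patients.

    Walks every root-to-leaf path and accumulates ``n * path probability``
    into the count of each event tag on the terminal.  Counts are expected
    values, not resampled integers.
    """
    n = counts.n
    n_pet = n_lap = n_gast = prevented = missed = 0.0
    for p, leaf in strategy.paths():
        w = n * p
        if "pet" in leaf.labels:
            n_pet += w
        if "laparoscopy" in leaf.labels:
            n_lap += w
        if "gastrectomy" in leaf.labels:
            n_gast += w
        if "reference_positive" in leaf.labels:
            if "gastrectomy" in leaf.labels:
                missed += w
            else:
                prevented += w
    return StrategyOutcome(
        strategy_id=strategy.strategy_id,
        expected_cost=evaluate(strategy),
        n=n,
        n_pet=n_pet,
        n_laparoscopy=n_lap,
        n_gastrectomy=n_gast,
        n_futile_gastrectomy_prevented=prevented,
        n_missed_opm=missed,
    )


def compare(a: StrategyOutcome, b: StrategyOutcome) -> float:
    """Per-patient expected-cost difference ``a - b`` (antisymmetric).

    Both outcomes must refer to the same cohort size.
    """
    if a.n != b.n:
        raise ValueError(f"cohort size mismatch: {a.n} vs {b.n}")
    return a.expected_cost - b.expected_cost
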