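"""Published inputs of the prospective staging cohort the model is built on.

A single-centre prospective cohort of 109 patients with locally advanced
gastric adenocarcinoma, all staged with a fibroblast-activation-protein PET
tracer before staging laparoscopy with peritoneal washing cytology (the
reference standard).  These constants are the study's printed aggregates;
they are the only real data the package ships, and the ``reproduce``
command recomputes every in-scope result from them.
"""

from __future__ import annotations

from .domain_types import CohortCounts, ConfusionTable

#: 2x2 cross-classification of the PET index test vs the reference standard
TABLE = ConfusionTable(tp=12, fp=5, fn=4, tn=88)
COUNTS = CohortCounts.from_table(TABLE)

#: cohort size
N = 109

#: reference-positive disease subtypes (P1CY1, P1CY0, P0CY1)
SUBTYPE_COUNTS = (7, 6, 3)

#: initial stages of the 17 index-test-positive patients (IIB, III, IVA)
MIGRATION_SPLIT = {("IIB", "IVB"): 5, ("III", "IVB"): 10, ("IVA", "IVB"): 2}

#: per-patient cost aggregates of the published decision-tree analysis (USD):
#: total cost of the no-staging strategy, and the changes relative to it of
#: the PET-only and laparoscopy-only strategies
S1_TOTAL = 9550.50
S3_DELTA = -727.60
S2_DELTA = +251.70

#: primary-tumour uptake summaries (mean, SD) by group
UPTAKE_OPM = {"suv_max": (18.49, 6.00), "tbr1": (13.28, 4.78), "tbr2": (19.65, 7.08)}
UPTAKE_NO_OPM = {"suv_max": (14.25, 5.95), "tbr1": (10.87, 4.85), "tbr2": (15.00, 6.36)}
N_OPM, N_NO_OPM = 16, 93

#: headline values as printed in the study report, on their printed scales;
#: entries flagged ``reproducible=False`` are known not to follow from the
#: printed inputs by the stated formulas (the package reports its own value
#: and annotates the gap rather than imitating the print)
PUBLISHED = {
    "sensitivity_pct": {"value": 75.0, "reproducible": True},
    "specificity_pct": {"value": 94.6, "reproducible": True},
    "accuracy_pct": {"value": 91.7, "reproducible": True},
    "ppv_pct": {"value": 70.6, "reproducible": True},
    "npv_pct": {"value": 95.7, "reproducible": True},
    "lr_neg": {"value": 0.3, "reproducible": True},
    "lr_pos": {
        "value": 14.2,
        "reproducible": False,
        "note": "formula on the 2x2 counts gives 13.95; the printed rounding path is unstated",
    },
    "auc": {
        "value": 0.83,
        "reproducible": False,
        "note": "single-threshold trapezoid (sens+spec)/2 gives 0.848; the printed 0.83 procedure is unstated",
    },
    "upstaged_pct": {"value": 15.6, "reproducible": True},
    "lap_reduction_pct": {"value": 84.0, "reproducible": True},
    "futile_prevented_pct": {"value": 11.0, "reproducible": True},
    "s1_total": {"value": 9550.50, "reproducible": True},
    "s2_minus_s3": {"value": 979.30, "reproducible": True},
    "s2_minus_s4": {
        "value": 232.30,
        "reproducible": False,
        "note": "forward evaluation of the stated branch structure gives 283.30; the printed costing of the combined strategy is unstated",
    },
}
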