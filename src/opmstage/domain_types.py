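"""Shared data types for the staging-test evaluation and cost model.

Everything downstream (diagnostic metrics, decision trees, sensitivity
analyses, synthetic cohorts) operates on the types defined here.  The module
performs validation only; all computation lives in the sibling modules.

Conventions
-----------
* Currency is USD per patient, held as floats with cent precision and
  compared at a tolerance of 0.005 (half a cent); display uses 2 decimals.
* Stage labels form a closed enumeration: initial clinical stages are
  ``IIB``, ``III``, ``IVA``; the metastatic final stage adds ``IVB``.
  Unknown labels are rejected at construction/parse time.
* Booleans serialise to CSV as 0/1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence, Union

import pandas as pd
import yaml

__all__ = [
    "CURRENCY_TOL",
    "INITIAL_STAGES",
    "FINAL_STAGES",
    "OPM_SUBTYPES",
    "COHORT_CSV_COLUMNS",
    "ConfusionTable",
    "validate",
    "Estimate",
    "DiagnosticSummary",
    "ProcedureComponents",
    "CostInputs",
    "ChanceNode",
    "TerminalNode",
    "Node",
    "StrategyModel",
    "StrategyOutcome",
    "PatientRecord",
    "CohortCounts",
    "cohort_to_csv",
    "cohort_from_csv",
    "cohort_to_frame",
    "load_cost_config",
    "fmt_percent",
    "fmt_currency",
]

#: tolerance for currency comparisons (half a cent)
CURRENCY_TOL = 0.005

#: closed stage enumerations
INITIAL_STAGES = ("IIB", "III", "IVA")
FINAL_STAGES = ("IIB", "III", "IVA", "IVB")

#: reference-positive disease subtypes: macroscopic (P1) vs cytology (CY1)
OPM_SUBTYPES = ("P1CY1", "P1CY0", "P0CY1")

#: exact cohort CSV header, in order
COHORT_CSV_COLUMNS = (
    "patient_id",
    "true_opm",
    "opm_subtype",
    "pet_result",
    "lap_result",
    "initial_stage",
    "final_stage",
    "suv_max",
    "tbr1",
    "tbr2",
)

#: event tags a terminal node may carry
EVENT_TAGS = frozenset({"pet", "laparoscopy", "gastrectomy", "reference_positive"})


def fmt_percent(x: float, decimals: int = 1) -> str:
    """Format a proportion as a percentage, rounding half away from zero.

    ``fmt_percent(12/17)`` -> ``'70.6%'``; Python's banker's rounding is
    deliberately avoided so printed values follow the usual clinical style.
    """
    v = x * 100.0
    scale = 10 ** decimals
    r = math.floor(abs(v) * scale + 0.5) / scale
    r = math.copysign(r, v)
    if decimals == 0:
        return f"{int(r)}%"
    return f"{r:.{decimals}f}%"


def fmt_currency(x: float) -> str:
    """Format a per-patient cost in dollars with 2 decimals."""
    return f"${x:,.2f}"


# ---------------------------------------------------------------------------
# 2x2 cross-classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 cross-classification of the index test against the reference.

    Rows: index test (PET) positive / negative; columns: reference standard
    (laparoscopy + peritoneal cytology) positive / negative.

    Parameters
    ----------
    tp, fp, fn, tn
        Non-negative patient counts. The table must contain at least one
        patient.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer count, got {v!r}")
            if v < 0:
                raise ValueError(f"negative count: {name}={v}")
        if self.total == 0:
            raise ValueError("empty table: all four counts are zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def ref_pos(self) -> int:
        """Reference-standard positives (column total)."""
        return self.tp + self.fn

    @property
    def ref_neg(self) -> int:
        return self.fp + self.tn

    @property
    def index_pos(self) -> int:
        """Index-test positives (row total)."""
        return self.tp + self.fp

    @property
    def index_neg(self) -> int:
        return self.fn + self.tn

    @classmethod
    def from_string(cls, s: str) -> "ConfusionTable":
        """Parse ``'TP,FP,FN,TN'`` (e.g. ``'12,5,4,88'``)."""
        parts = [p.strip() for p in s.split(",")]
        if len(parts) != 4:
            raise ValueError(f"expected 4 comma-separated counts, got {s!r}")
        return cls(*(int(p) for p in parts))


def validate(table: ConfusionTable) -> ConfusionTable:
    """Return *table* unchanged if its invariants hold.

    The dataclass validates on construction; this re-checks an instance that
    may have been built through other means (e.g. ``replace``).
    """
    ConfusionTable(table.tp, table.fp, table.fn, table.tn)
    return table


# ---------------------------------------------------------------------------
# diagnostic summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Estimate:
    """A point estimate with an optional (lower, upper) confidence interval.

    ``point`` is ``None`` when the metric is undefined (zero denominator);
    an undefined metric is never silently reported as 0.
    """

    point: Union[float, None]
    lower: Union[float, None] = None
    upper: Union[float, None] = None

    def __post_init__(self) -> None:
        if self.point is not None and self.lower is not None and self.upper is not None:
            if not (self.lower - 1e-12 <= self.point <= self.upper + 1e-12):
                raise ValueError(
                    f"interval ({self.lower}, {self.upper}) does not contain point {self.point}"
                )

    @property
    def defined(self) -> bool:
        return self.point is not None


@dataclass(frozen=True)
class DiagnosticSummary:
    """All accuracy metrics of a binary test with interval estimates.

    Proportion metrics (sensitivity, specificity, accuracy, ppv, npv, auc)
    are :class:`Estimate` objects in [0, 1].  Likelihood ratios are plain
    floats in [0, inf] (``math.inf`` marks a test with perfect specificity);
    ``None`` marks an undefined ratio.
    """

    sensitivity: Estimate
    specificity: Estimate
    accuracy: Estimate
    ppv: Estimate
    npv: Estimate
    lr_pos: Union[float, None]
    lr_neg: Union[float, None]
    auc: Estimate
    ci_method: str
    ci_level: float

    def to_dict(self) -> dict:
        """JSON-friendly representation (inf -> "inf", None -> "undefined")."""

        def num(v):
            if v is None:
                return "undefined"
            if isinstance(v, float) and math.isinf(v):
                return "inf"
            return v

        out: dict = {"ci_method": self.ci_method, "ci_level": self.ci_level}
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv", "auc"):
            est: Estimate = getattr(self, name)
            out[name] = {
                "point": num(est.point),
                "lower": num(est.lower),
                "upper": num(est.upper),
            }
        out["lr_pos"] = num(self.lr_pos)
        out["lr_neg"] = num(self.lr_neg)
        return out


# ---------------------------------------------------------------------------
# costs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProcedureComponents:
    """Itemised direct costs of one procedure.

    The unit cost of a staged procedure is
    ``surgery + anesthesia + pathology + postop_per_day * postop_days``;
    postoperative stays are 3 days after staging laparoscopy and 7 days
    after gastrectomy.
    """

    surgery: float
    anesthesia: float
    pathology: float
    postop_per_day: float
    postop_days: int

    def total(self) -> float:
        return (
            self.surgery
            + self.anesthesia
            + self.pathology
            + self.postop_per_day * self.postop_days
        )


@dataclass(frozen=True)
class CostInputs:
    """Per-patient unit costs (USD) of the three procedures.

    Parameters
    ----------
    c_pet, c_lap, c_gast
        Unit cost of a PET/CT scan, a staging laparoscopy (with cytology),
        and a gastrectomy; each must be positive.
    components
        Optional itemised breakdown keyed by ``"lap"`` / ``"gast"``.  When
        present, each breakdown must sum to its unit cost within one cent.
    """

    c_pet: float
    c_lap: float
    c_gast: float
    components: Union[Mapping[str, ProcedureComponents], None] = None

    def __post_init__(self) -> None:
        for name in ("c_pet", "c_lap", "c_gast"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be positive, got {v}")
        if self.components:
            unit = {"pet": self.c_pet, "lap": self.c_lap, "gast": self.c_gast}
            for key, comp in self.components.items():
                if key not in unit:
                    raise ValueError(f"unknown procedure {key!r} in component breakdown")
                if abs(comp.total() - unit[key]) > 0.01:
                    raise ValueError(
                        f"component sum {comp.total():.2f} does not match "
                        f"unit cost {unit[key]:.2f} for {key!r}"
                    )


# ---------------------------------------------------------------------------
# decision tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TerminalNode:
    """Leaf of a strategy tree: a per-patient cost and the events on the path."""

    cost: float
    labels: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", frozenset(self.labels))
        unknown = self.labels - EVENT_TAGS
        if unknown:
            raise ValueError(f"unknown event tags: {sorted(unknown)}")
        if self.cost < 0:
            raise ValueError(f"negative terminal cost {self.cost}")


@dataclass(frozen=True)
class ChanceNode:
    """Internal node: ``branches`` is a tuple of (probability, child) pairs."""

    branches: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "branches", tuple(self.branches))
        if not self.branches:
            raise ValueError("chance node with no branches")
        total = 0.0
        for p, child in self.branches:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"branch probability {p} outside [0, 1]")
            if not isinstance(child, (ChanceNode, TerminalNode)):
                raise TypeError(f"branch child must be a node, got {type(child)}")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"branch probabilities sum to {total!r}, not 1")


Node = Union[ChanceNode, TerminalNode]


def _check_acyclic(node: Node, seen: frozenset = frozenset()) -> None:
    if id(node) in seen:
        raise ValueError("cycle detected in decision tree")
    if isinstance(node, ChanceNode):
        seen = seen | {id(node)}
        for _, child in node.branches:
            _check_acyclic(child, seen)


@dataclass(frozen=True)
class StrategyModel:
    """One staging strategy: an identifier and the root of its decision tree."""

    strategy_id: str
    root: Node
    description: str = ""

    def __post_init__(self) -> None:
        if self.strategy_id not in ("S1", "S2", "S3", "S4"):
            raise ValueError(f"unknown strategy id {self.strategy_id!r}")
        _check_acyclic(self.root)

    def paths(self):
        """Yield (probability, terminal) over all root-to-leaf paths."""
        stack = [(1.0, self.root)]
        while stack:
            prob, node = stack.pop()
            if isinstance(node, TerminalNode):
                yield prob, node
            else:
                for p, child in node.branches:
                    stack.append((prob * p, child))


@dataclass(frozen=True)
class StrategyOutcome:
    """Expected per-patient cost and expected event counts for a cohort of n.

    Counts are expected values (branch frequencies times n), so they are
    floats and need not be integers.
    """

    strategy_id: str
    expected_cost: float
    n: int
    n_pet: float
    n_laparoscopy: float
    n_gastrectomy: float
    n_futile_gastrectomy_prevented: float
    n_missed_opm: float

    def __post_init__(self) -> None:
        if self.expected_cost < 0:
            raise ValueError("negative expected cost")
        for name in (
            "n_pet",
            "n_laparoscopy",
            "n_gastrectomy",
            "n_futile_gastrectomy_prevented",
            "n_missed_opm",
        ):
            v = getattr(self, name)
            if not (-1e-9 <= v <= self.n + 1e-9):
                raise ValueError(f"{name}={v} outside [0, {self.n}]")


# ---------------------------------------------------------------------------
# patients and cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient.

    ``true_opm`` is the latent disease state; ``lap_result`` is the reference
    standard's call (equal to ``true_opm`` unless a laparoscopy false-negative
    rate was simulated); ``pet_result`` is the index test.  ``final_stage``
    is ``IVB`` exactly when the reference standard classifies the patient as
    metastatic.
    """

    patient_id: str
    true_opm: bool
    opm_subtype: str
    pet_result: bool
    lap_result: bool
    initial_stage: str
    final_stage: str
    suv_max: float
    tbr1: float
    tbr2: float

    def __post_init__(self) -> None:
        if self.opm_subtype not in OPM_SUBTYPES + ("none",):
            raise ValueError(f"unknown OPM subtype {self.opm_subtype!r}")
        if (self.opm_subtype != "none") != self.true_opm:
            raise ValueError(
                "opm_subtype must be a P/CY subtype iff true_opm is set "
                f"(got subtype={self.opm_subtype!r}, true_opm={self.true_opm})"
            )
        if self.initial_stage not in INITIAL_STAGES:
            raise ValueError(f"unknown initial stage {self.initial_stage!r}")
        if self.final_stage not in FINAL_STAGES:
            raise ValueError(f"unknown final stage {self.final_stage!r}")
        if (self.final_stage == "IVB") != self.lap_result:
            raise ValueError("final_stage must be IVB iff the reference call is positive")
        for name in ("suv_max", "tbr1", "tbr2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CohortCounts:
    """Cohort-level tallies consistent with a :class:`ConfusionTable`."""

    n: int
    pet_pos: int
    ref_pos: int
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        table = ConfusionTable(self.tp, self.fp, self.fn, self.tn)
        if self.pet_pos != table.index_pos:
            raise ValueError("pet_pos must equal tp + fp")
        if self.ref_pos != table.ref_pos:
            raise ValueError("ref_pos must equal tp + fn")
        if self.n != table.total:
            raise ValueError("n must equal the table total")

    @classmethod
    def from_table(cls, table: ConfusionTable) -> "CohortCounts":
        return cls(
            n=table.total,
            pet_pos=table.index_pos,
            ref_pos=table.ref_pos,
            tp=table.tp,
            fp=table.fp,
            fn=table.fn,
            tn=table.tn,
        )

    @property
    def pet_neg(self) -> int:
        return self.n - self.pet_pos

    @property
    def ref_neg(self) -> int:
        return self.n - self.ref_pos

    @property
    def table(self) -> ConfusionTable:
        return ConfusionTable(self.tp, self.fp, self.fn, self.tn)


# ---------------------------------------------------------------------------
# external interfaces: cohort CSV and cost config
# ---------------------------------------------------------------------------


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame in the canonical column order (booleans as 0/1)."""
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in fields(r)}
        d["true_opm"] = int(d["true_opm"])
        d["pet_result"] = int(d["pet_result"])
        d["lap_result"] = int(d["lap_result"])
        rows.append(d)
    return pd.DataFrame(rows, columns=list(COHORT_CSV_COLUMNS))


def cohort_to_csv(records: Sequence[PatientRecord], path) -> None:
    """Write the cohort CSV with the exact canonical header.

    Floats use 17 significant digits so a write/read cycle is lossless.
    """
    cohort_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def cohort_from_csv(path) -> list:
    """Read a cohort CSV back into :class:`PatientRecord` objects.

    Rejects files whose header deviates from the canonical schema and any
    row with an out-of-enumeration stage or subtype label.
    """
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    if tuple(df.columns) != COHORT_CSV_COLUMNS:
        raise ValueError(
            f"unexpected cohort CSV header {list(df.columns)}; "
            f"expected {list(COHORT_CSV_COLUMNS)}"
        )
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                true_opm=bool(int(row.true_opm)),
                opm_subtype=str(row.opm_subtype),
                pet_result=bool(int(row.pet_result)),
                lap_result=bool(int(row.lap_result)),
                initial_stage=str(row.initial_stage),
                final_stage=str(row.final_stage),
                suv_max=float(row.suv_max),
                tbr1=float(row.tbr1),
                tbr2=float(row.tbr2),
            )
        )
    return records


def _flatten(d: Mapping, prefix: str = "") -> dict:
    out: dict = {}
    for k, v in d.items():
        key = f"{prefix}.{k}" if prefix else str(k)
        if isinstance(v, Mapping):
            out.update(_flatten(v, key))
        else:
            out[key] = v
    return out


_COMPONENT_KEYS = ("surgery", "anesthesia", "pathology", "postop_per_day", "postop_days")


def load_cost_config(path) -> dict:
    """Parse a YAML cost configuration into a normalised dict.

    Two forms are accepted (and may be mixed):

    * unit costs — ``costs.pet``, ``costs.lap``, ``costs.gast``, optionally
      with per-component keys such as ``costs.lap.surgery``;
    * a derivation block — ``derive.s1_total``, ``derive.s3_delta``,
      ``derive.s2_delta`` — from which unit costs are back-solved against a
      confusion table (see :func:`opmstage.cost_model.derive_unit_costs`).

    Returns a dict with at most the keys ``"costs"`` (a :class:`CostInputs`)
    and ``"derive"`` (a dict of the three aggregates).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError(f"cost config {path} is not a key-value mapping")
    flat = _flatten(raw)

    out: dict = {}
    if any(k.startswith("derive.") for k in flat):
        try:
            out["derive"] = {
                "s1_total": float(flat["derive.s1_total"]),
                "s3_delta": float(flat["derive.s3_delta"]),
                "s2_delta": float(flat["derive.s2_delta"]),
            }
        except KeyError as e:
            raise ValueError(f"derivation block missing key {e}") from None

    cost_keys = [k for k in flat if k.startswith("costs.")]
    if cost_keys:
        components = {}
        unit = {}
        for proc in ("pet", "lap", "gast"):
            comp_keys = [k for k in cost_keys if k.startswith(f"costs.{proc}.")]
            if comp_keys:
                vals = {}
                for ck in _COMPONENT_KEYS:
                    full = f"costs.{proc}.{ck}"
                    if full not in flat:
                        raise ValueError(f"component breakdown for {proc!r} missing {ck!r}")
                    vals[ck] = flat[full]
                comp = ProcedureComponents(
                    surgery=float(vals["surgery"]),
                    anesthesia=float(vals["anesthesia"]),
                    pathology=float(vals["pathology"]),
                    postop_per_day=float(vals["postop_per_day"]),
                    postop_days=int(vals["postop_days"]),
                )
                components[proc] = comp
                unit[proc] = comp.total()
            elif f"costs.{proc}" in flat:
                unit[proc] = float(flat[f"costs.{proc}"])
        if set(unit) == {"pet", "lap", "gast"}:
            out["costs"] = CostInputs(
                c_pet=unit["pet"],
                c_lap=unit["lap"],
                c_gast=unit["gast"],
                components=components or None,
            )
        elif unit:
            raise ValueError(
                f"incomplete unit costs: got {sorted(unit)}, need pet, lap and gast"
            )
    if not out:
        raise ValueError("cost config contains neither unit costs nor a derivation block")
    return out
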