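"""Diagnostic-accuracy metrics for a binary index test against a reference.

All metrics derive from a single 2x2 table, so the ROC curve of the index
test has exactly one operating point and the area under it is the trapezoid
through (0, 0), (1 - specificity, sensitivity) and (1, 1), i.e.
``(sensitivity + specificity) / 2``.  Interval estimates for proportions use
the Wilson score interval by default (Clopper-Pearson optionally); the AUC
interval uses the Hanley-McNeil standard error.
"""

from __future__ import annotations

import math
from typing import Tuple, Union

from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .domain_types import ConfusionTable, DiagnosticSummary, Estimate, validate

__all__ = [
    "CI_METHODS",
    "proportion_ci",
    "likelihood_ratios",
    "binary_auc",
    "compute_metrics",
]

#: offered interval methods -> statsmodels method label
CI_METHODS = {"wilson": "wilson", "clopper-pearson": "beta"}


def proportion_ci(
    k: int, n: int, ci_level: float = 0.95, method: str = "wilson"
) -> Tuple[float, float]:
    """Confidence interval for a binomial proportion ``k / n``.

    Parameters
    ----------
    k, n
        Successes and trials, ``0 <= k <= n``, ``n >= 1``.
    ci_level
        Two-sided confidence level in (0, 1).
    method
        ``"wilson"`` (score interval, default) or ``"clopper-pearson"``
        (exact beta inversion).

    Returns
    -------
    (lower, upper) with ``0 <= lower <= k/n <= upper <= 1``.
    """
    if not 0 < ci_level < 1:
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    try:
        sm_method = CI_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown CI method {method!r}; offered: {sorted(CI_METHODS)}"
        ) from None
    lower, upper = proportion_confint(k, n, alpha=1.0 - ci_level, method=sm_method)
    # guard against round-off leaking outside [0, 1] or past the point
    p = k / n
    lower = min(max(float(lower), 0.0), p)
    upper = max(min(float(upper), 1.0), p)
    return lower, upper


def _ratio(num: int, den: int) -> Union[float, None]:
    """num/den as a proportion, or None when the denominator is empty."""
    return num / den if den > 0 else None


def likelihood_ratios(table: ConfusionTable) -> Tuple[Union[float, None], Union[float, None]]:
    """Positive and negative likelihood ratios of the index test.

    LR+ = sensitivity / (1 - specificity); LR- = (1 - sensitivity) / specificity.
    A perfectly specific test yields ``LR+ = inf``; a metric whose defining
    sensitivity or specificity has an empty denominator, or an LR- with zero
    specificity, is returned as ``None`` (undefined).
    """
    sens = _ratio(table.tp, table.ref_pos)
    spec = _ratio(table.tn, table.ref_neg)
    lr_pos: Union[float, None]
    lr_neg: Union[float, None]
    if sens is None or spec is None:
        return None, None
    lr_pos = math.inf if spec == 1.0 else sens / (1.0 - spec)
    lr_neg = None if spec == 0.0 else (1.0 - sens) / spec
    return lr_pos, lr_neg


def binary_auc(table: ConfusionTable, ci_level: float = 0.95) -> Tuple[float, Tuple[float, float]]:
    """AUC of the single-threshold ROC, with a Hanley-McNeil interval.

    The ROC of a binary test is the polyline (0,0) -> (1-spec, sens) -> (1,1);
    its trapezoidal area is ``(sens + spec) / 2``.  The standard error uses
    the Hanley-McNeil formula with ``n_pos = tp + fn`` and ``n_neg = fp + tn``:

        SE^2 = [A(1-A) + (n_pos-1)(Q1 - A^2) + (n_neg-1)(Q2 - A^2)] / (n_pos n_neg)

    with ``Q1 = A/(2-A)`` and ``Q2 = 2A^2/(1+A)``; the normal interval is
    clipped to [0, 1].
    """
    sens = _ratio(table.tp, table.ref_pos)
    spec = _ratio(table.tn, table.ref_neg)
    if sens is None or spec is None:
        raise ValueError("AUC undefined: sensitivity or specificity has no cases")
    a = (sens + spec) / 2.0
    n_pos, n_neg = table.ref_pos, table.ref_neg
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    z = norm.ppf(0.5 + ci_level / 2.0)
    lower = min(max(a - z * se, 0.0), a)
    upper = max(min(a + z * se, 1.0), a)
    return a, (lower, upper)


def compute_metrics(
    table: ConfusionTable, ci_level: float = 0.95, ci_method: str = "wilson"
) -> DiagnosticSummary:
    """All accuracy metrics of the index test from a 2x2 table.

    Point estimates: sensitivity ``tp/(tp+fn)``, specificity ``tn/(fp+tn)``,
    accuracy ``(tp+tn)/total``, PPV ``tp/(tp+fp)``, NPV ``tn/(fn+tn)``; each
    defined proportion carries an interval at ``ci_level``.  A metric with a
    zero denominator is reported as undefined, never as 0.  Likelihood ratios
    and the single-threshold AUC are included.
    """
    validate(table)

    def est(k: int, n: int) -> Estimate:
        if n == 0:
            return Estimate(None)
        lo, hi = proportion_ci(k, n, ci_level, ci_method)
        return Estimate(k / n, lo, hi)

    sensitivity = est(table.tp, table.ref_pos)
    specificity = est(table.tn, table.ref_neg)
    accuracy = est(table.tp + table.tn, table.total)
    ppv = est(table.tp, table.index_pos)
    npv = est(table.tn, table.index_neg)
    lr_pos, lr_neg = likelihood_ratios(table)
    if sensitivity.defined and specificity.defined:
        a, (lo, hi) = binary_auc(table, ci_level)
        auc = Estimate(a, lo, hi)
    else:
        auc = Estimate(None)
    return DiagnosticSummary(
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        auc=auc,
        ci_method=ci_method,
        ci_level=ci_level,
    )
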