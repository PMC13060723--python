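"""Diagnostic-accuracy statistics with 95% confidence intervals.

Proportion statistics (PPV, NPV, sensitivity, specificity, accuracy) use an
exact Clopper-Pearson interval by default (Wilson and Wald available);
likelihood ratios use the standard log-transform interval.  Statistics with
an empty denominator return ``None`` (an "undefined" marker) rather than
raising.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as _sps

from panctriage.cohort import CohortConfig, EventTimeline, ToolEvaluation


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def flagged(self) -> int:
        return self.tp + self.fp

    @property
    def cancers(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class StatWithCI:
    estimate: float
    ci_low: float
    ci_high: float
    method: str

    def scaled(self, factor: float) -> "StatWithCI":
        return StatWithCI(self.estimate * factor, self.ci_low * factor,
                          self.ci_high * factor, self.method)


def binomial_ci(
    successes: int, n: int, level: float = 0.95, method: str = "clopper-pearson"
) -> tuple[float, float]:
    """Two-sided binomial confidence interval for successes/n."""
    if n <= 0 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: {successes}/{n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    p = successes / n
    if method == "clopper-pearson":
        low = 0.0 if successes == 0 else float(_sps.beta.ppf(alpha / 2, successes, n - successes + 1))
        high = 1.0 if successes == n else float(_sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
        return low, high
    if method == "wilson":
        z = _sps.norm.ppf(1 - alpha / 2)
        denom = 1 + z**2 / n
        centre = (p + z**2 / (2 * n)) / denom
        half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        return max(0.0, centre - half), min(1.0, centre + half)
    if method == "wald":
        z = _sps.norm.ppf(1 - alpha / 2)
        half = z * math.sqrt(p * (1 - p) / n)
        return max(0.0, p - half), min(1.0, p + half)
    raise ValueError(f"unknown CI method: {method!r}")


def _proportion_stat(
    successes: int, n: int, level: float, method: str
) -> Optional[StatWithCI]:
    if n == 0:
        return None
    low, high = binomial_ci(successes, n, level, method)
    return StatWithCI(successes / n, low, high, method)


def ppv(cm: ConfusionMatrix, level: float = 0.95, method: str = "clopper-pearson") -> Optional[StatWithCI]:
    """Positive predictive value tp/(tp+fp); None when nobody is flagged."""
    return _proportion_stat(cm.tp, cm.tp + cm.fp, level, method)


def npv(cm: ConfusionMatrix, level: float = 0.95, method: str = "clopper-pearson") -> Optional[StatWithCI]:
    return _proportion_stat(cm.tn, cm.tn + cm.fn, level, method)


def sensitivity(cm: ConfusionMatrix, level: float = 0.95, method: str = "clopper-pearson") -> Optional[StatWithCI]:
    return _proportion_stat(cm.tp, cm.tp + cm.fn, level, method)


def specificity(cm: ConfusionMatrix, level: float = 0.95, method: str = "clopper-pearson") -> Optional[StatWithCI]:
    return _proportion_stat(cm.tn, cm.tn + cm.fp, level, method)


def accuracy(cm: ConfusionMatrix, level: float = 0.95, method: str = "clopper-pearson") -> Optional[StatWithCI]:
    return _proportion_stat(cm.tp + cm.tn, cm.total, level, method)


def lr_points(sens: float, spec: float) -> tuple[Optional[float], Optional[float]]:
    """Point likelihood ratios from sensitivity and specificity.

    LR+ = sens/(1-spec); LR- = (1-sens)/spec.  None where the denominator
    is zero.
    """
    lr_plus = sens / (1 - spec) if spec < 1 else None
    lr_minus = (1 - sens) / spec if spec > 0 else None
    return lr_plus, lr_minus


def likelihood_ratios(
    cm: ConfusionMatrix, level: float = 0.95
) -> tuple[Optional[StatWithCI], Optional[StatWithCI]]:
    """LR+ and LR- with log-transform confidence intervals."""
    if cm.tp + cm.fn == 0 or cm.fp + cm.tn == 0:
        return None, None
    sens = cm.tp / (cm.tp + cm.fn)
    spec = cm.tn / (cm.fp + cm.tn)
    z = _sps.norm.ppf(1 - (1 - level) / 2)

    lr_plus = None
    if spec < 1 and sens > 0:
        est = sens / (1 - spec)
        # var(ln LR+) = (1-sens)/tp + spec/fp   (delta method)
        se = math.sqrt((1 - sens) / cm.tp + spec / cm.fp) if cm.tp > 0 and cm.fp > 0 else None
        if se is not None:
            lr_plus = StatWithCI(est, est * math.exp(-z * se), est * math.exp(z * se), "log")
        else:
            lr_plus = StatWithCI(est, float("nan"), float("nan"), "log")

    lr_minus = None
    if spec > 0 and sens < 1:
        est = (1 - sens) / spec
        se = math.sqrt(sens / cm.fn + (1 - spec) / cm.tn) if cm.fn > 0 and cm.tn > 0 else None
        if se is not None:
            lr_minus = StatWithCI(est, est * math.exp(-z * se), est * math.exp(z * se), "log")
        else:
            lr_minus = StatWithCI(est, float("nan"), float("nan"), "log")
    elif spec > 0 and sens == 1:
        lr_minus = StatWithCI(0.0, 0.0, 0.0, "log")
    return lr_plus, lr_minus


def confusion_from_evaluations(evaluations: Sequence[ToolEvaluation]) -> ConfusionMatrix:
    """2x2 counts over the eligible evaluations of a single tool."""
    elig = [e for e in evaluations if e.eligible]
    if not elig:
        raise ValueError("no eligible evaluations")
    tools = {e.tool for e in elig}
    if len(tools) > 1:
        raise ValueError(f"mixed tools in evaluation set: {sorted(tools)}")
    tp = sum(1 for e in elig if e.flagged and e.outcome_cancer_12m)
    fp = sum(1 for e in elig if e.flagged and not e.outcome_cancer_12m)
    fn = sum(1 for e in elig if not e.flagged and e.outcome_cancer_12m)
    tn = len(elig) - tp - fp - fn
    return ConfusionMatrix(tp, fp, fn, tn)


def per_symptom_ppv(
    timelines: Sequence[EventTimeline],
    symptom_code: str,
    config: CohortConfig,
    level: float = 0.95,
    method: str = "clopper-pearson",
) -> Optional[StatWithCI]:
    """PPV of a single symptom: among patients with >=1 event of the code
    (index = first such event), the fraction diagnosed within follow-up."""
    presenters = 0
    hits = 0
    for tl in timelines:
        first = next((e.event_date for e in tl.events if e.symptom_code == symptom_code), None)
        if first is None:
            continue
        presenters += 1
        if tl.cancer_diagnosis is not None:
            delta = (tl.cancer_diagnosis[0] - first).days
            if 0 <= delta <= config.followup_window_days:
                hits += 1
    return _proportion_stat(hits, presenters, level, method)


def compare_proportions(
    a_present: Iterable[bool], b_present: Iterable[bool], correction: bool = False
) -> Optional[tuple[float, float]]:
    """Pearson chi-square on the 2x2 presence table for two groups.

    Returns (statistic, p-value); None for degenerate tables.
    """
    a = np.asarray(list(a_present), dtype=bool)
    b = np.asarray(list(b_present), dtype=bool)
    if a.size == 0 or b.size == 0:
        return None
    table = np.array([[a.sum(), a.size - a.sum()], [b.sum(), b.size - b.sum()]])
    if (table.sum(axis=0) == 0).any():
        return None
    chi2, p, _, _ = _sps.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def compare_distributions(
    a_values: Iterable[float], b_values: Iterable[float]
) -> Optional[tuple[float, float]]:
    """Mann-Whitney U (two-sided, tie-corrected normal approximation)."""
    a = np.asarray(list(a_values), dtype=float)
    b = np.asarray(list(b_values), dtype=float)
    if a.size == 0 or b.size == 0:
        return None
    res = _sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
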