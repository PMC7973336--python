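"""Margin-level diagnostic accuracy, exact confidence intervals, activity-
threshold ROC analysis, subgroup summaries and rate ratios.

All diagnostic statistics operate on per-margin confusion matrices comparing
the FAR call against histopathology.  Sensitivity/specificity/accuracy
intervals are exact binomial (Clopper-Pearson); predictive-value intervals
default to the logit-transformed normal interval because the exact method is
not appropriate reporting convention for post-test probabilities — the
method used is always labelled in the output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import beta, norm

from .quant import round_half_up

__all__ = [
    "ConfusionMatrix",
    "MetricEstimate",
    "DiagnosticSummary",
    "RocCurve",
    "confusion",
    "diagnostic_metrics",
    "clopper_pearson",
    "logit_interval",
    "roc_activity_threshold",
    "rate_ratio",
    "subgroup_analysis",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Margin-level counts: FAR call (rows) vs histopathology (columns)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its confidence interval and the interval method."""

    value: float
    ci: tuple[float, float]
    method: str

    @property
    def percent(self) -> float:
        """Point estimate as a percentage, one decimal, half-up."""
        return round_half_up(100.0 * self.value, 1)

    @property
    def ci_percent(self) -> tuple[float, float]:
        return (
            round_half_up(100.0 * self.ci[0], 2),
            round_half_up(100.0 * self.ci[1], 2),
        )


@dataclass(frozen=True)
class DiagnosticSummary:
    """Sensitivity, specificity, PPV, NPV and accuracy with 95% CIs.

    A metric whose denominator is zero is ``None`` (explicitly undefined),
    never 0 or 100%.
    """

    sensitivity: MetricEstimate | None
    specificity: MetricEstimate | None
    ppv: MetricEstimate | None
    npv: MetricEstimate | None
    accuracy: MetricEstimate | None
    n_margins: int

    def as_dict(self) -> dict:
        out: dict = {"n_margins": self.n_margins}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            m: MetricEstimate | None = getattr(self, name)
            if m is None:
                out[name] = None
            else:
                out[name] = {
                    "percent": m.percent,
                    "ci_percent": list(m.ci_percent),
                    "ci_method": m.method,
                }
        return out


def confusion(margins) -> ConfusionMatrix:
    """Tabulate margin records into a confusion matrix.

    ``margins`` may be a pandas DataFrame with ``histo_status``/``far_status``
    columns or an iterable of :class:`~farkit.margins.MarginRecord`.  Records
    with a missing status are excluded with a log entry.
    """
    if isinstance(margins, pd.DataFrame):
        histo = margins["histo_status"]
        far = margins["far_status"]
        pairs = list(zip(histo, far))
    else:
        pairs = [(m.histo_status, m.far_status) for m in margins]
    tp = fp = fn = tn = 0
    excluded = 0
    for h, f in pairs:
        if h not in ("positive", "negative") or f not in ("positive", "negative"):
            excluded += 1
            continue
        if f == "positive":
            tp += h == "positive"
            fp += h == "negative"
        else:
            fn += h == "positive"
            tn += h == "negative"
    if excluded:
        logger.warning("confusion: excluded %d records with missing status", excluded)
    return ConfusionMatrix(tp, fp, fn, tn)


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval.

    Beta-quantile formulation of the binomial tail inversion:
    ``lower = Beta(alpha/2; k, n-k+1)``, ``upper = Beta(1-alpha/2; k+1, n-k)``,
    with lower = 0 at k = 0 and upper = 1 at k = n.
    """
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: {successes}/{n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    k = successes
    lower = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def logit_interval(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Normal interval on the log-odds scale, back-transformed.

    Used for predictive values; degenerates to (0,1)-clamped bounds when the
    count is 0 or n (where the logit is undefined).
    """
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: {successes}/{n}")
    if successes == 0 or successes == n:
        return clopper_pearson(successes, n, level)
    p = successes / n
    z = float(norm.ppf(0.5 + level / 2))
    lo = math.log(p / (1 - p))
    se = math.sqrt(1.0 / successes + 1.0 / (n - successes))
    a, b = lo - z * se, lo + z * se
    expit = lambda t: 1.0 / (1.0 + math.exp(-t))
    return expit(a), expit(b)


def _estimate(k: int, n: int, level: float, method: str) -> MetricEstimate | None:
    if n == 0:
        return None
    fn = clopper_pearson if method == "clopper-pearson" else logit_interval
    return MetricEstimate(value=k / n, ci=fn(k, n, level), method=method)


def diagnostic_metrics(
    cm: ConfusionMatrix,
    *,
    level: float = 0.95,
    ppv_npv_method: str = "logit",
) -> DiagnosticSummary:
    """Sensitivity, specificity, PPV, NPV and overall accuracy from a matrix.

    Metrics with a zero denominator are reported as ``None``.  Predictive
    values are additionally undefined in strata without any condition
    positives (PPV) or negatives (NPV): with zero prevalence no diagnostic
    performance can be established, so reporting PPV = 0% would be
    misleading.  Percentages round to one decimal place (half-up) via
    :attr:`MetricEstimate.percent`.
    """
    pv = "logit" if ppv_npv_method == "logit" else "clopper-pearson"
    has_pos = cm.tp + cm.fn > 0
    has_neg = cm.tn + cm.fp > 0
    return DiagnosticSummary(
        sensitivity=_estimate(cm.tp, cm.tp + cm.fn, level, "clopper-pearson"),
        specificity=_estimate(cm.tn, cm.tn + cm.fp, level, "clopper-pearson"),
        ppv=_estimate(cm.tp, cm.tp + cm.fp, level, pv) if has_pos else None,
        npv=_estimate(cm.tn, cm.tn + cm.fn, level, pv) if has_neg else None,
        accuracy=_estimate(cm.tp + cm.tn, cm.total, level, "clopper-pearson"),
        n_margins=cm.total,
    )


# ---------------------------------------------------------------------------
# activity-threshold ROC analysis


@dataclass
class RocCurve:
    """Per-threshold FAR performance in the >= T activity subgroup.

    This is *not* a standard classifier ROC: each grid point T restricts the
    cohort to patients whose decay-corrected activity is at least T and
    re-tabulates FAR-vs-histopathology performance within that subgroup.
    ``sensitivity``/``specificity`` are NaN where the subgroup lacks positive
    (resp. negative) margins.
    """

    thresholds: np.ndarray
    matrices: list[ConfusionMatrix]
    sensitivity: np.ndarray
    specificity: np.ndarray
    selected_threshold: float | None
    selection_criterion: str
    scores: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if len(self.thresholds) > 1 and not (np.diff(self.thresholds) > 0).all():
            raise ValueError("threshold grid must be strictly increasing")


def _binom_ll(k: int, n: int) -> float:
    if n == 0:
        return 0.0
    p = k / n
    return float(xlogy(k, p) + xlogy(n - k, 1 - p))


def _lr_split_score(act, histo_pos, far_pos, T) -> float | None:
    """Binomial log-likelihood gain of splitting detection rates at T,
    stratified by histopathology status (the maxstat-style changepoint
    profile).  None when either side of a stratum is empty."""
    hi = act >= T
    score = 0.0
    for grp in (histo_pos, ~histo_pos):
        n_hi = int((grp & hi).sum())
        n_lo = int((grp & ~hi).sum())
        if n_hi == 0 or n_lo == 0:
            return None
        k_hi = int((grp & hi & far_pos).sum())
        k_lo = int((grp & ~hi & far_pos).sum())
        score += (
            _binom_ll(k_hi, n_hi)
            + _binom_ll(k_lo, n_lo)
            - _binom_ll(k_hi + k_lo, n_hi + n_lo)
        )
    return score


def roc_activity_threshold(
    cohort,
    *,
    increment: float = 1.0,
    criterion: str = "lr",
) -> RocCurve:
    """Sweep decay-corrected activity thresholds and select an operating point.

    For each threshold T on the ``increment``-MBq grid spanning the observed
    decay-corrected activities, the margin-level confusion matrix restricted
    to patients with activity >= T is tabulated and its sensitivity and
    specificity recorded.

    Selection criteria
    ------------------
    ``"lr"`` (default)
        Maximally selected binomial likelihood-ratio split statistic,
        stratified by histopathology status.  This changepoint profile
        concentrates on the activity at which FAR detection rates change and
        is stable against the small-sample flutter of the deep subgroup tail.
    ``"youden"``
        Maximise Youden's J = sensitivity + specificity - 1 of the >= T
        subgroup, ties broken to the lowest T.  Recorded for reference; with
        few positive margins this rule is noisy (see docs/methods.md).

    A cohort with no positive (or no negative) margins returns the curve
    with ``selected_threshold=None`` and criterion ``"undefined"``.
    """
    if criterion not in ("lr", "youden"):
        raise ValueError(f"unknown criterion {criterion!r}")
    patients, margins = cohort.patients, cohort.margins
    decayed = patients.set_index("patient_id")["decayed_mbq"]
    if decayed.nunique() < 2:
        raise ValueError("need >= 2 distinct decayed activities")
    act = margins["patient_id"].map(decayed).to_numpy(dtype=float)
    histo_pos = (margins["histo_status"] == "positive").to_numpy()
    far_pos = (margins["far_status"] == "positive").to_numpy()

    lo = math.floor(decayed.min())
    hi = math.ceil(decayed.max())
    thresholds = np.arange(lo, hi + increment / 2, increment, dtype=float)

    matrices, sens, spec, scores = [], [], [], []
    for T in thresholds:
        sel = act >= T
        tp = int((sel & histo_pos & far_pos).sum())
        fp = int((sel & ~histo_pos & far_pos).sum())
        fn = int((sel & histo_pos & ~far_pos).sum())
        tn = int((sel & ~histo_pos & ~far_pos).sum())
        cm = ConfusionMatrix(tp, fp, fn, tn)
        matrices.append(cm)
        sens.append(tp / (tp + fn) if tp + fn else np.nan)
        spec.append(tn / (tn + fp) if tn + fp else np.nan)
        if criterion == "lr":
            s = _lr_split_score(act, histo_pos, far_pos, T)
            scores.append(np.nan if s is None else s)
        else:
            s_, p_ = sens[-1], spec[-1]
            scores.append(s_ + p_ - 1 if not (np.isnan(s_) or np.isnan(p_)) else np.nan)
    sens, spec, scores = map(np.asarray, (sens, spec, scores))

    if not histo_pos.any() or histo_pos.all() or np.all(np.isnan(scores)):
        logger.warning("degenerate cohort: threshold selection undefined")
        selected, crit = None, "undefined"
    else:
        best = np.nanmax(scores)
        # ties broken to the lowest threshold
        selected = float(thresholds[np.argmax(scores >= best - 1e-12)])
        crit = criterion
    return RocCurve(
        thresholds=thresholds,
        matrices=matrices,
        sensitivity=sens,
        specificity=spec,
        selected_threshold=selected,
        selection_criterion=crit,
        scores=scores,
    )


def rate_ratio(
    cm_a: ConfusionMatrix, cm_b: ConfusionMatrix
) -> tuple[float | None, float | None]:
    """Per-margin TP- and FP-rate ratios between two cohorts.

    Rates are events per assessed margin — ``tp/total`` and ``fp/total`` —
    so the ratio compares how often FAR raises a true (resp. false) alarm per
    margin in cohort A versus cohort B.  A zero reference rate yields
    ``None`` with a log entry.
    """
    if cm_a.total == 0 or cm_b.total == 0:
        raise ValueError("both cohorts must contain margins")

    def _ratio(a_num, b_num):
        rb = b_num / cm_b.total
        if rb == 0:
            logger.warning("rate_ratio: zero reference rate; ratio undefined")
            return None
        return (a_num / cm_a.total) / rb

    return _ratio(cm_a.tp, cm_b.tp), _ratio(cm_a.fp, cm_b.fp)


def subgroup_analysis(
    margins: pd.DataFrame,
    stratifier: str | pd.Series | dict,
    *,
    level: float = 0.95,
) -> dict[str, tuple[ConfusionMatrix, DiagnosticSummary]]:
    """Per-stratum confusion matrices and diagnostic summaries.

    ``stratifier`` is a margin-table column name, a patient_id -> label
    mapping, or a per-row Series.  Rows with a null label are excluded with
    a logged count.  Strata without histopathology positives simply report
    sensitivity/PPV as undefined (``None``).
    """
    if isinstance(stratifier, str):
        labels = margins[stratifier]
    elif isinstance(stratifier, dict):
        labels = margins["patient_id"].map(stratifier)
    else:
        labels = stratifier
    labels = pd.Series(labels).reindex(margins.index)
    excluded = int(labels.isna().sum())
    if excluded:
        logger.warning("subgroup_analysis: excluded %d unlabelled margins", excluded)
    out: dict[str, tuple[ConfusionMatrix, DiagnosticSummary]] = {}
    for label, grp in margins[labels.notna()].groupby(labels.dropna(), sort=True):
        cm = confusion(grp)
        out[str(label)] = (cm, diagnostic_metrics(cm, level=level))
    return out
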