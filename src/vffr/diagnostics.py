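"""Diagnostic-performance statistics for virtual-FFR indices against invasive FFR.

A vessel is functionally significant (diseased) when invasive FFR <= 0.80; a
virtual index calls it positive when the index value is <= the cutoff (lower
values mean more severe ischemia, so the ROC orientation negates scores
internally).  The layer provides:

* confusion matrices and the full family of derived indices — accuracy,
  sensitivity, specificity, predictive values, likelihood ratios, Youden
  index (sens/100 + spec/100 - 1), false discovery/omission rates — each with
  its conventional 95% CI family:

  - exact Clopper–Pearson (beta-quantile) intervals for accuracy,
    sensitivity and specificity;
  - Mercaldo standard-logit intervals for PPV and NPV (variance propagated
    from sensitivity, specificity and sample prevalence);
  - Simel log-method intervals for the likelihood ratios;

* ROC analysis with the Mann–Whitney (tie-corrected) AUC and the
  Youden-optimal cutoff;
* Pearson/Spearman correlation and Bland–Altman limits of agreement
  (mean difference +/- 1.96 SD);
* a side-by-side two-method comparison report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedCohort",
    "ConfusionMatrix",
    "CIEstimate",
    "DiagnosticIndices",
    "AgreementSummary",
    "RocResult",
    "MethodComparisonReport",
    "confusion_at_cutoff",
    "diagnostic_indices",
    "clopper_pearson",
    "roc_analysis",
    "correlation",
    "bland_altman",
    "compare_methods",
]

_Z95 = stats.norm.ppf(0.975)

#: FFR threshold defining functionally significant stenosis.
FFR_POSITIVITY_THRESHOLD = 0.80


@dataclass(frozen=True)
class PairedCohort:
    """Per-vessel paired records: a virtual index value and invasive FFR.

    Ground-truth positivity is invasive FFR <= ``ffr_threshold`` (0.80).
    """

    vessel_id: np.ndarray
    index_value: np.ndarray
    invasive_ffr: np.ndarray
    ffr_threshold: float = FFR_POSITIVITY_THRESHOLD

    def __post_init__(self) -> None:
        vid = np.asarray(self.vessel_id)
        x = np.asarray(self.index_value, dtype=float)
        y = np.asarray(self.invasive_ffr, dtype=float)
        if not (vid.size == x.size == y.size):
            raise ValueError("cohort columns must have equal length")
        if x.size < 2:
            raise ValueError("a cohort needs at least 2 vessels")
        if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
            raise ValueError("cohort contains missing/non-finite values")
        if np.any(x <= 0) or np.any(x > 1) or np.any(y <= 0) or np.any(y > 1):
            raise ValueError("index and FFR values must lie in (0, 1]")
        object.__setattr__(self, "vessel_id", vid)
        object.__setattr__(self, "index_value", x)
        object.__setattr__(self, "invasive_ffr", y)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, index_col: str, ffr_col: str = "ffr", id_col: str = "vessel_id"
    ) -> "PairedCohort":
        return cls(df[id_col].to_numpy(), df[index_col].to_numpy(), df[ffr_col].to_numpy())

    @property
    def n(self) -> int:
        return int(self.index_value.size)

    @property
    def truth_positive(self) -> np.ndarray:
        return self.invasive_ffr <= self.ffr_threshold


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.tn, self.fn):
            if v < 0 or int(v) != v:
                raise ValueError("confusion-matrix counts must be non-negative integers")
        if self.n < 1:
            raise ValueError("confusion matrix must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        """Diseased vessels (by the reference standard)."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


class CIEstimate(Tuple[float, float, float]):
    """(value, lo, hi) triple; ``None`` members signal an undefined index."""

    __slots__ = ()

    def __new__(cls, value, lo, hi):
        return super().__new__(cls, (value, lo, hi))

    @property
    def value(self):
        return self[0]

    @property
    def lo(self):
        return self[1]

    @property
    def hi(self):
        return self[2]


@dataclass(frozen=True)
class DiagnosticIndices:
    """Point estimates (percent scale) with 95% CIs, plus ratio statistics."""

    accuracy: CIEstimate
    sensitivity: CIEstimate
    specificity: CIEstimate
    ppv: CIEstimate
    npv: CIEstimate
    plr: CIEstimate
    nlr: CIEstimate
    youden: float
    false_discovery_rate_pct: Optional[float]
    false_omission_rate_pct: Optional[float]
    misclassified_pct: float
    cm: ConfusionMatrix = field(repr=False)

    def as_dict(self) -> dict:
        def tup(e):
            return None if e.value is None else {"value": e.value, "ci": [e.lo, e.hi]}

        return {
            "accuracy_pct": tup(self.accuracy),
            "sensitivity_pct": tup(self.sensitivity),
            "specificity_pct": tup(self.specificity),
            "ppv_pct": tup(self.ppv),
            "npv_pct": tup(self.npv),
            "plr": tup(self.plr),
            "nlr": tup(self.nlr),
            "youden": self.youden,
            "false_discovery_rate_pct": self.false_discovery_rate_pct,
            "false_omission_rate_pct": self.false_omission_rate_pct,
            "misclassified_pct": self.misclassified_pct,
            "confusion": {"tp": self.cm.tp, "fp": self.cm.fp, "tn": self.cm.tn, "fn": self.cm.fn},
        }


@dataclass(frozen=True)
class AgreementSummary:
    """Bland–Altman agreement: mean difference and 95% limits of agreement."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutoff: float
    optimal_sensitivity: float
    optimal_specificity: float
    optimal_youden: float


def confusion_at_cutoff(cohort: PairedCohort, cutoff: float) -> ConfusionMatrix:
    """Cross-tabulate (index <= cutoff) against (invasive FFR <= 0.80)."""
    pred = cohort.index_value <= cutoff
    truth = cohort.truth_positive
    return ConfusionMatrix(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> Tuple[float, float]:
    """Exact binomial (beta-quantile) confidence interval for a proportion."""
    if trials < 1 or successes < 0 or successes > trials:
        raise ValueError("need 0 <= successes <= trials, trials >= 1")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    hi = 1.0 if successes == trials else float(stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return lo, hi


def _cp_pct(successes: int, trials: int, level: float) -> CIEstimate:
    if trials == 0:
        return CIEstimate(None, None, None)
    lo, hi = clopper_pearson(successes, trials, level)
    return CIEstimate(100.0 * successes / trials, 100.0 * lo, 100.0 * hi)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _inv_logit(t: float) -> float:
    return 1.0 / (1.0 + math.exp(-t))


def _mercaldo_pv(cm: ConfusionMatrix, which: str, z: float) -> CIEstimate:
    """Standard-logit interval for PPV/NPV with variance from sens/spec."""
    n1, n0 = cm.n_positive, cm.n_negative
    if n1 == 0 or n0 == 0:
        return CIEstimate(None, None, None)
    sens, spec = cm.tp / n1, cm.tn / n0
    if which == "ppv":
        denom = cm.tp + cm.fp
        if denom == 0:
            return CIEstimate(None, None, None)
        pv = cm.tp / denom
        if sens in (0.0,) or spec == 1.0 or pv in (0.0, 1.0):
            # degenerate counts: fall back to exact binomial on the column
            return _cp_pct(cm.tp, denom, 0.95)
        var = (1 - sens) / (sens * n1) + spec / ((1 - spec) * n0)
    else:
        denom = cm.tn + cm.fn
        if denom == 0:
            return CIEstimate(None, None, None)
        pv = cm.tn / denom
        if spec == 0.0 or sens == 1.0 or pv in (0.0, 1.0):
            return _cp_pct(cm.tn, denom, 0.95)
        var = sens / ((1 - sens) * n1) + (1 - spec) / (spec * n0)
    half = z * math.sqrt(var)
    centre = _logit(pv)
    return CIEstimate(100.0 * pv, 100.0 * _inv_logit(centre - half), 100.0 * _inv_logit(centre + half))


def _simel_lr(cm: ConfusionMatrix, which: str, z: float) -> CIEstimate:
    """Log-method interval for positive/negative likelihood ratios."""
    n1, n0 = cm.n_positive, cm.n_negative
    if n1 == 0 or n0 == 0:
        return CIEstimate(None, None, None)
    sens, spec = cm.tp / n1, cm.tn / n0
    if which == "plr":
        if spec == 1.0 or sens == 0.0:
            return CIEstimate(None, None, None)
        lr = sens / (1 - spec)
        se = math.sqrt(1 / cm.tp - 1 / n1 + 1 / cm.fp - 1 / n0)
    else:
        if spec == 0.0 or sens == 1.0:
            return CIEstimate(None, None, None)
        lr = (1 - sens) / spec
        se = math.sqrt(1 / cm.fn - 1 / n1 + 1 / cm.tn - 1 / n0)
    return CIEstimate(lr, math.exp(math.log(lr) - z * se), math.exp(math.log(lr) + z * se))


def diagnostic_indices(cm: ConfusionMatrix, level: float = 0.95) -> DiagnosticIndices:
    """All confusion-matrix-derived indices with their 95% CI families.

    Indices whose denominator is zero are flagged undefined (``None``), never
    fabricated.  Point estimates are kept at full precision; formatting to the
    conventional decimals happens only in report rendering.
    """
    z = stats.norm.ppf(0.5 + level / 2)
    n1, n0 = cm.n_positive, cm.n_negative
    acc = _cp_pct(cm.tp + cm.tn, cm.n, level)
    sens = _cp_pct(cm.tp, n1, level)
    spec = _cp_pct(cm.tn, n0, level)
    ppv = _mercaldo_pv(cm, "ppv", z)
    npv = _mercaldo_pv(cm, "npv", z)
    plr = _simel_lr(cm, "plr", z)
    nlr = _simel_lr(cm, "nlr", z)
    youden = float("nan")
    if sens.value is not None and spec.value is not None:
        youden = sens.value / 100.0 + spec.value / 100.0 - 1.0
    fdr = None if ppv.value is None else 100.0 - ppv.value
    fomr = None if npv.value is None else 100.0 - npv.value
    return DiagnosticIndices(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        plr=plr,
        nlr=nlr,
        youden=youden,
        false_discovery_rate_pct=fdr,
        false_omission_rate_pct=fomr,
        misclassified_pct=100.0 * (cm.fp + cm.fn) / cm.n,
        cm=cm,
    )


def mann_whitney_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Concordance probability P(score_pos > score_neg), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n1 = int(positive.sum())
    n0 = int((~positive).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = stats.rankdata(scores)
    u = ranks[positive].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_analysis(
    cohort: PairedCohort,
    cutoff_grid: Optional[np.ndarray] = None,
    preferred_cutoff: float = 0.80,
) -> RocResult:
    """ROC curve, Mann–Whitney AUC, and the Youden-optimal cutoff.

    Lower index values predict disease, so the decision score is the negated
    index.  The threshold sweep covers the unique observed index values plus
    a 0.01-step grid on [0.50, 0.95] for conventionally reported cutoffs;
    Youden ties are broken toward the cutoff nearest ``preferred_cutoff``,
    then toward the larger cutoff.
    """
    truth = cohort.truth_positive
    if truth.all() or not truth.any():
        raise ValueError("ROC needs at least one positive and one negative vessel")
    if cutoff_grid is None:
        cutoff_grid = np.round(np.arange(0.50, 0.95 + 1e-9, 0.01), 2)
    thresholds = np.unique(np.concatenate([cohort.index_value, cutoff_grid]))
    n1 = int(truth.sum())
    n0 = int((~truth).sum())
    # vectorised sweep: predicted positive <=> index <= threshold
    pred = cohort.index_value[None, :] <= thresholds[:, None]
    tp = (pred & truth[None, :]).sum(axis=1)
    fp = (pred & ~truth[None, :]).sum(axis=1)
    sens = tp / n1
    spec = (n0 - fp) / n0
    auc = mann_whitney_auc(-cohort.index_value, truth)
    youden = sens + spec - 1.0
    best = youden.max()
    tied = np.flatnonzero(youden >= best - 1e-12)
    dist = np.abs(thresholds[tied] - preferred_cutoff)
    tied = tied[dist <= dist.min() + 1e-12]
    pick = tied[np.argmax(thresholds[tied])]
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_cutoff=float(thresholds[pick]),
        optimal_sensitivity=float(sens[pick]),
        optimal_specificity=float(spec[pick]),
        optimal_youden=float(youden[pick]),
    )


def correlation(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> Tuple[float, float]:
    """Pearson or Spearman correlation with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("correlation needs equal-length sequences of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return float(r), float(p)


def bland_altman(x: Sequence[float], y: Sequence[float]) -> AgreementSummary:
    """Bland–Altman agreement of paired measurements.

    Differences d = x - y; limits of agreement are mean(d) +/- 1.96 * SD(d)
    with the n-1 (sample) SD of the signed differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementSummary(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        n=int(d.size),
    )


def _round_half_up(x: float, decimals: int) -> float:
    scale = 10**decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def _fmt_ci_pct(e: CIEstimate) -> str:
    if e.value is None:
        return "undefined"
    return f"{_round_half_up(e.value, 1):.1f} ({_round_half_up(e.lo, 1):.1f}–{_round_half_up(e.hi, 1):.1f})"


def _fmt_ci_ratio(e: CIEstimate) -> str:
    if e.value is None:
        return "undefined"
    return f"{_round_half_up(e.value, 2):.2f} ({_round_half_up(e.lo, 2):.2f}–{_round_half_up(e.hi, 2):.2f})"


@dataclass(frozen=True)
class MethodComparisonReport:
    """Side-by-side diagnostic comparison of two virtual indices vs invasive FFR."""

    label_a: str
    label_b: str
    cutoff: float
    indices_a: DiagnosticIndices
    indices_b: DiagnosticIndices
    roc_a: RocResult
    roc_b: RocResult
    corr_a: Tuple[float, float]
    corr_b: Tuple[float, float]
    agreement_a: AgreementSummary
    agreement_b: AgreementSummary
    inter_method_corr: Tuple[float, float]
    inter_method_agreement: AgreementSummary

    def as_dict(self) -> Dict:
        def ba(a: AgreementSummary):
            return {
                "mean_diff": a.mean_diff,
                "sd_diff": a.sd_diff,
                "loa_low": a.loa_low,
                "loa_high": a.loa_high,
            }

        return {
            "cutoff": self.cutoff,
            self.label_a: {
                "indices": self.indices_a.as_dict(),
                "auc": self.roc_a.auc,
                "correlation_r": self.corr_a[0],
                "correlation_p": self.corr_a[1],
                "bland_altman": ba(self.agreement_a),
            },
            self.label_b: {
                "indices": self.indices_b.as_dict(),
                "auc": self.roc_b.auc,
                "correlation_r": self.corr_b[0],
                "correlation_p": self.corr_b[1],
                "bland_altman": ba(self.agreement_b),
            },
            "inter_method": {
                "correlation_r": self.inter_method_corr[0],
                "correlation_p": self.inter_method_corr[1],
                "bland_altman": ba(self.inter_method_agreement),
            },
        }

    def to_markdown(self) -> str:
        rows = [
            ("Accuracy, %", _fmt_ci_pct(self.indices_a.accuracy), _fmt_ci_pct(self.indices_b.accuracy)),
            ("Sensitivity, %", _fmt_ci_pct(self.indices_a.sensitivity), _fmt_ci_pct(self.indices_b.sensitivity)),
            ("Specificity, %", _fmt_ci_pct(self.indices_a.specificity), _fmt_ci_pct(self.indices_b.specificity)),
            ("Positive predictive value, %", _fmt_ci_pct(self.indices_a.ppv), _fmt_ci_pct(self.indices_b.ppv)),
            ("Negative predictive value, %", _fmt_ci_pct(self.indices_a.npv), _fmt_ci_pct(self.indices_b.npv)),
            ("Positive likelihood ratio", _fmt_ci_ratio(self.indices_a.plr), _fmt_ci_ratio(self.indices_b.plr)),
            ("Negative likelihood ratio", _fmt_ci_ratio(self.indices_a.nlr), _fmt_ci_ratio(self.indices_b.nlr)),
            ("Youden index", f"{_round_half_up(self.indices_a.youden, 3):.3f}", f"{_round_half_up(self.indices_b.youden, 3):.3f}"),
            ("AUC", f"{_round_half_up(self.roc_a.auc, 3):.3f}", f"{_round_half_up(self.roc_b.auc, 3):.3f}"),
        ]
        head = (
            f"| Statistic | {self.label_a} ≤ {self.cutoff:.2f} | {self.label_b} ≤ {self.cutoff:.2f} |\n"
            "|---|---|---|\n"
        )
        return head + "\n".join(f"| {r[0]} | {r[1]} | {r[2]} |" for r in rows)


def compare_methods(
    cohort_a: PairedCohort,
    cohort_b: PairedCohort,
    cutoff: float = 0.80,
    label_a: str = "method_a",
    label_b: str = "method_b",
) -> MethodComparisonReport:
    """Full two-method comparison at a fixed cutoff (confusion indices, AUC,
    correlation with invasive FFR, Bland–Altman), plus inter-method agreement.

    Both cohorts must cover the same vessels (shared invasive-FFR column).
    """
    ids_a = np.asarray(cohort_a.vessel_id)
    ids_b = np.asarray(cohort_b.vessel_id)
    if ids_a.size != ids_b.size or set(ids_a.tolist()) != set(ids_b.tolist()):
        raise ValueError("cohorts must cover the same vessel ids")
    # align b to a's vessel order
    order = {v: i for i, v in enumerate(ids_b.tolist())}
    perm = np.array([order[v] for v in ids_a.tolist()])
    xb = cohort_b.index_value[perm]
    ffr = cohort_a.invasive_ffr
    if not np.allclose(cohort_b.invasive_ffr[perm], ffr):
        raise ValueError("cohorts disagree on invasive FFR for shared vessels")
    cohort_b_aligned = PairedCohort(ids_a, xb, ffr, cohort_b.ffr_threshold)

    cm_a = confusion_at_cutoff(cohort_a, cutoff)
    cm_b = confusion_at_cutoff(cohort_b_aligned, cutoff)
    return MethodComparisonReport(
        label_a=label_a,
        label_b=label_b,
        cutoff=cutoff,
        indices_a=diagnostic_indices(cm_a),
        indices_b=diagnostic_indices(cm_b),
        roc_a=roc_analysis(cohort_a),
        roc_b=roc_analysis(cohort_b_aligned),
        corr_a=correlation(cohort_a.index_value, ffr),
        corr_b=correlation(xb, ffr),
        agreement_a=bland_altman(cohort_a.index_value, ffr),
        agreement_b=bland_altman(xb, ffr),
        inter_method_corr=correlation(cohort_a.index_value, xb),
        inter_method_agreement=bland_altman(cohort_a.index_value, xb),
    )
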