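"""Expression-validation statistics: ddCt, deregulation calls, paired
tests, ROC/AUC, literature risk scores, and optimal-cutpoint survival.

These are the statistics used to confirm a meta-analysis signature in
independent expression data: relative qPCR quantification by the ddCt
method (fold change = 2^-ddCt, normalized to a reference gene such as
U6), the >= 2-fold / <= 0.5-fold deregulation rule, missing-data
filtering with log2 transformation, paired tumor-vs-normal tests, ROC
analysis of classification scores, linear risk scores with published
coefficients, and Kaplan-Meier / log-rank survival comparison with an
optimal (maximum chi-square) marker cutpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "PairedExpression",
    "RiskModel",
    "HCC_RISK_MODEL",
    "GRADE_SCORE_MODEL",
    "RocResult",
    "ddct_fold_change",
    "summarize_folds",
    "classify_deregulated",
    "filter_and_log2",
    "paired_de_test",
    "roc_auc",
    "risk_score",
    "km_logrank",
    "optimal_cutoff_logrank",
]

CT_COLUMNS = ["ct_target_tumor", "ct_target_normal", "ct_ref_tumor", "ct_ref_normal"]


# ---------------------------------------------------------------------------
# ddCt quantification
# ---------------------------------------------------------------------------

def ddct_fold_change(ct: pd.DataFrame) -> pd.DataFrame:
    """Per patient x miRNA fold change from a long-format Ct table.

    ddCt = (Ct_target - Ct_reference)_tumor - (Ct_target - Ct_reference)_normal
    and fold = 2^-ddCt, so fold > 1 means higher expression in tumor.
    Rows with any missing Ct component yield a missing (NaN) cell.
    Requires columns patient, mirna plus the four Ct columns.
    """
    missing = [c for c in ["patient", "mirna", *CT_COLUMNS] if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns {missing}")
    vals = ct[CT_COLUMNS].astype(float)
    if (vals.dropna() <= 0).any().any():
        raise ValueError("Ct values must be positive cycle counts")
    ddct = (vals["ct_target_tumor"] - vals["ct_ref_tumor"]) - (
        vals["ct_target_normal"] - vals["ct_ref_normal"]
    )
    folds = ct[["patient", "mirna"]].copy()
    folds["fold"] = 2.0 ** (-ddct)
    return folds.pivot(index="patient", columns="mirna", values="fold")


def summarize_folds(folds: pd.DataFrame) -> pd.Series:
    """Per-miRNA summary fold across patients: the geometric mean.

    Equivalent to 2^-(mean ddCt), matching the averaging convention of
    ddCt quantification. NaN cells are ignored.
    """
    return 2.0 ** np.log2(folds).mean(axis=0, skipna=True)


def classify_deregulated(folds) -> pd.Series:
    """Call each summary fold up (>= 2), down (<= 0.5) or unchanged.

    Both thresholds are inclusive. Accepts a scalar or a per-miRNA
    Series of positive folds.
    """
    s = pd.Series(folds, dtype=float) if not isinstance(folds, pd.Series) else folds.astype(float)
    if (s <= 0).any() or s.isna().any():
        raise ValueError("fold changes must be positive and non-missing")
    out = pd.Series("unchanged", index=s.index, dtype=object)
    out[s >= 2.0] = "up"
    out[s <= 0.5] = "down"
    return out if isinstance(folds, pd.Series) else out.iloc[0]


# ---------------------------------------------------------------------------
# Paired expression
# ---------------------------------------------------------------------------

@dataclass
class PairedExpression:
    """Per-patient tumor/normal expression for a set of miRNAs.

    ``tumor`` and ``normal`` are patients x miRNAs DataFrames sharing the
    same index/columns; missing measurements are NaN, never silent zeros.
    """

    tumor: pd.DataFrame
    normal: pd.DataFrame
    log2_transformed: bool = False

    def __post_init__(self) -> None:
        if not self.tumor.index.equals(self.normal.index) or not self.tumor.columns.equals(
            self.normal.columns
        ):
            raise ValueError("tumor and normal matrices must share patients and miRNAs")

    @property
    def patients(self) -> list:
        return list(self.tumor.index)

    @property
    def mirnas(self) -> list:
        return list(self.tumor.columns)

    def missing_fraction(self) -> pd.Series:
        """Fraction of patients with a missing tumor or normal value, per miRNA."""
        return (self.tumor.isna() | self.normal.isna()).mean(axis=0)


def filter_and_log2(expr: PairedExpression, max_missing: float = 0.10,
                    pseudocount: float = 1.0) -> PairedExpression:
    """Drop high-missingness miRNAs, then log2-transform.

    A miRNA is excluded when its missing fraction *exceeds* ``max_missing``
    (exactly 10% missing is kept). Remaining values become
    log2(x + pseudocount); the default pseudocount of 1 suits count-like
    abundances (e.g. reads per million), use 0 for strictly positive
    continuous values.
    """
    if expr.log2_transformed:
        raise ValueError("expression is already log2-transformed")
    keep = expr.missing_fraction() <= max_missing
    if not keep.any():
        raise ValueError("every miRNA exceeds the missing-data threshold")
    cols = keep[keep].index
    return PairedExpression(
        tumor=np.log2(expr.tumor[cols] + pseudocount),
        normal=np.log2(expr.normal[cols] + pseudocount),
        log2_transformed=True,
    )


def paired_de_test(expr: PairedExpression, method: str = "wilcoxon") -> pd.DataFrame:
    """Two-sided paired test of tumor vs normal per miRNA, on log2 values.

    Default is the Wilcoxon signed-rank test (robust at small n, e.g. an
    11-pair validation cohort); ``method='ttest'`` uses the paired t-test.
    Returns statistic, p_value and the median log2 difference per miRNA.
    Requires at least 3 complete pairs per miRNA.
    """
    if expr.log2_transformed:
        t, n = expr.tumor, expr.normal
    else:
        if (expr.tumor.dropna(how="all") <= 0).any().any() or (
            expr.normal.dropna(how="all") <= 0
        ).any().any():
            raise ValueError("raw abundances must be positive for log2; filter first")
        t, n = np.log2(expr.tumor), np.log2(expr.normal)
    rows = []
    for mirna in t.columns:
        diff = (t[mirna] - n[mirna]).dropna().to_numpy()
        if diff.size < 3:
            raise ValueError(f"{mirna}: fewer than 3 complete pairs")
        if np.allclose(diff, 0):
            stat, p = 0.0, 1.0
        elif method == "wilcoxon":
            res = stats.wilcoxon(diff, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        elif method == "ttest":
            res = stats.ttest_1samp(diff, 0.0)  # paired t on the differences
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"mirna": mirna, "statistic": stat, "p_value": p,
                     "median_log2_diff": float(np.median(diff))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(scores, labels) -> RocResult:
    """AUC by the rank (Mann-Whitney) statistic, plus the ROC curve.

    AUC = P(score_pos > score_neg) + 0.5 * P(tie), computed from the sum
    of mid-ranks of the positive class. Both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    auc = float(u / (n_pos * n_neg))
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return RocResult(auc=auc, fpr=fpr, tpr=tpr, thresholds=thresholds)


# ---------------------------------------------------------------------------
# Risk scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskModel:
    """A published linear score on log2 miRNA expression."""

    coefficients: dict
    name: str = "risk"

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("risk model needs at least one coefficient")
        if not all(np.isfinite(list(self.coefficients.values()))):
            raise ValueError("coefficients must be finite")


#: Tissue-classification score from LASSO regression on TCGA liver-cancer
#: miRNA-seq data (E = log2 expression).
HCC_RISK_MODEL = RiskModel(
    coefficients={"miR-221": 0.180, "miR-21": 0.0262,
                  "miR-223": -0.007, "miR-130a": -0.185},
    name="hcc",
)

#: Tumor-grade score (well- vs moderately/poorly differentiated).
GRADE_SCORE_MODEL = RiskModel(
    coefficients={"miR-222": 0.0427, "miR-221": 0.0030, "miR-21": 0.0763,
                  "miR-214-3p": -0.0184, "miR-130a": 0.0098},
    name="grade",
)


def risk_score(expression: pd.DataFrame, model: RiskModel = HCC_RISK_MODEL,
               log2_transformed: bool = False) -> pd.Series:
    """Per-sample linear score: sum of weight x log2(expression).

    *expression* is samples x miRNAs of non-negative abundances (or
    already log2 values with ``log2_transformed=True``). Every model
    miRNA must be a column.
    """
    missing = [m for m in model.coefficients if m not in expression.columns]
    if missing:
        raise KeyError(f"expression table lacks model miRNA(s): {missing}")
    sub = expression[list(model.coefficients)].astype(float)
    e = sub if log2_transformed else np.log2(sub)
    weights = pd.Series(model.coefficients)
    return (e * weights).sum(axis=1).rename(f"{model.name}_score")


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass
class KmLogrankResult:
    chi_square: float
    p_value: float
    curves: dict = field(default_factory=dict)  # group -> (times, survival)


def _check_survival(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if not set(np.unique(event)) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    return time, event


def km_logrank(time, event, groups) -> KmLogrankResult:
    """Two-group log-rank test (1 df) with Kaplan-Meier curves.

    ``groups`` is a binary label per patient; both groups must be
    non-empty and at least one event must be observed.
    """
    time, event = _check_survival(time, event)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"need exactly two groups, got {labels.size}")
    if event.sum() < 1:
        raise ValueError("log-rank requires at least one observed event")
    a, b = (groups == labels[0]), (groups == labels[1])
    res = logrank_test(time[a], time[b], event_observed_A=event[a],
                       event_observed_B=event[b])
    curves = {}
    for lab, mask in ((labels[0], a), (labels[1], b)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask])
        sf = kmf.survival_function_
        curves[lab] = (sf.index.to_numpy(), sf.iloc[:, 0].to_numpy())
    return KmLogrankResult(chi_square=float(res.test_statistic),
                           p_value=float(res.p_value), curves=curves)


def optimal_cutoff_logrank(survival: pd.DataFrame,
                           min_group_fraction: float = 0.10) -> tuple[float, float, float]:
    """Marker cutpoint maximizing the log-rank chi-square.

    Scans every midpoint between consecutive distinct sorted marker
    values whose induced low/high groups each exceed
    ``min_group_fraction`` of the cohort, and returns
    (cutoff, chi_square, unadjusted p) for the best split. Because the
    cutpoint is chosen to minimize p, that p is anti-conservative and
    should not be read at face value. Requires columns time_months,
    event, marker; at least 2 events and 2 distinct marker values.
    """
    time, event = _check_survival(survival["time_months"], survival["event"])
    marker = np.asarray(survival["marker"], dtype=float)
    if event.sum() < 2:
        raise ValueError("cutpoint scan requires at least 2 events")
    distinct = np.unique(marker)
    if distinct.size < 2:
        raise ValueError("marker must take at least 2 distinct values")
    n = marker.size
    min_count = min_group_fraction * n
    best = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        cut = (lo + hi) / 2.0
        high = marker > cut
        if high.sum() < min_count or (~high).sum() < min_count:
            continue
        res = logrank_test(time[~high], time[high],
                           event_observed_A=event[~high],
                           event_observed_B=event[high])
        if best is None or res.test_statistic > best[1]:
            best = (cut, float(res.test_statistic), float(res.p_value))
    if best is None:
        raise ValueError("no admissible cutoff under the group-size constraint")
    return best
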