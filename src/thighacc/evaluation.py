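"""Cross-validation, confusion matrices, balanced accuracy and robustness.

Algorithms are evaluated with leave-one-subject-out (LOSO)
cross-validation: each participant's windows are predicted by models
developed on the remaining participants.  Per-participant 4x4 confusion
matrices (rows = predicted, columns = reference, class order Sedentary,
Standing, LIPA, MVPA) are summed into an overall matrix.  Per class,
one-vs-rest sensitivity TP/(TP+FN), specificity TN/(TN+FP) and balanced
accuracy (sensitivity+specificity)/2 are reported as percentages;
balanced accuracies of at least 80% count as acceptable.

Robustness checks correlate per-participant balanced accuracies with
baseline characteristics, with a Shapiro-Wilk normality gate choosing
Pearson vs Spearman (continuous) or t-test vs Mann-Whitney U (binary),
and Bonferroni (p*k) or Sidak (1-(1-p)^k) multiple-comparison
adjustment.  Measurement reliability is summarised by coefficients of
variation, CV(%) = SD/mean*100, with CV < 10% acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import CLASSES

__all__ = [
    "ConfusionMatrix",
    "ClassPerformance",
    "RobustnessResult",
    "loso_split",
    "confusion",
    "sum_matrices",
    "class_performance",
    "benchmark",
    "robustness",
    "adjust_p",
    "reliability_cv",
    "training_sample_check",
    "compare_algorithms",
]

ACCEPTABLE_BA = 80.0
SHAPIRO_ALPHA = 0.05


@dataclass
class ConfusionMatrix:
    """4x4 window counts; rows = predicted class, columns = reference class."""

    counts: np.ndarray
    participant_id: str = "overall"
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("class orders differ")
        return ConfusionMatrix(self.counts + other.counts, "overall", self.classes)


@dataclass(frozen=True)
class ClassPerformance:
    intensity_class: str
    sensitivity: float  # %
    specificity: float  # %
    balanced_accuracy: float  # %
    acceptable: bool


@dataclass
class RobustnessResult:
    characteristic: str
    test: str
    statistic: float
    p_raw: float
    p_adjusted: float = float("nan")
    adjustment: str = ""
    k: int = 1


def loso_split(participants: list[str]) -> list[tuple[list[str], str]]:
    """One (train ids, test id) fold per participant."""
    ids = list(participants)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate participant ids")
    if len(ids) < 2:
        raise ValueError("need at least 2 participants")
    return [([p for p in ids if p != test], test) for test in ids]


def confusion(
    predicted: np.ndarray,
    reference: np.ndarray,
    participant_id: str = "overall",
) -> ConfusionMatrix:
    """Count windows into a predicted-by-reference matrix."""
    pred = np.asarray(predicted, dtype=object)
    ref = np.asarray(reference, dtype=object)
    if pred.shape != ref.shape:
        raise ValueError("predicted and reference lengths differ")
    index = {c: i for i, c in enumerate(CLASSES)}
    counts = np.zeros((len(CLASSES), len(CLASSES)), dtype=int)
    for p, r in zip(pred, ref):
        if p not in index or r not in index:
            raise ValueError(f"unknown label in ({p!r}, {r!r})")
        counts[index[p], index[r]] += 1
    return ConfusionMatrix(counts, participant_id)


def sum_matrices(matrices: list[ConfusionMatrix]) -> ConfusionMatrix:
    """Element-wise sum over participants ('overall' matrix)."""
    if not matrices:
        raise ValueError("no matrices to sum")
    total = matrices[0]
    for m in matrices[1:]:
        total = total + m
    return total


def class_performance(matrix: ConfusionMatrix, intensity_class: str) -> ClassPerformance:
    """One-vs-rest sensitivity, specificity and balanced accuracy (percent)."""
    if intensity_class not in matrix.classes:
        raise ValueError(f"unknown class {intensity_class!r}")
    i = matrix.classes.index(intensity_class)
    c = matrix.counts
    tp = c[i, i]
    fn = c[:, i].sum() - tp  # reference class i, predicted otherwise
    fp = c[i, :].sum() - tp
    tn = c.sum() - tp - fn - fp
    if tp + fn == 0:
        raise ValueError(
            f"sensitivity undefined: no reference windows of class {intensity_class}"
        )
    if tn + fp == 0:
        raise ValueError(
            f"specificity undefined: every window is of class {intensity_class}"
        )
    sens = float(100.0 * tp / (tp + fn))
    spec = float(100.0 * tn / (tn + fp))
    ba = (sens + spec) / 2.0
    return ClassPerformance(
        intensity_class=intensity_class,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=ba,
        acceptable=ba >= ACCEPTABLE_BA,
    )


def benchmark(
    per_participant: list[ClassPerformance], threshold: float = ACCEPTABLE_BA
) -> float:
    """Percent of participants whose balanced accuracy reaches the threshold."""
    if not per_participant:
        raise ValueError("no participants to benchmark")
    ok = sum(1 for p in per_participant if p.balanced_accuracy >= threshold)
    return 100.0 * ok / len(per_participant)


def adjust_p(p: float, k: int, method: str = "bonferroni") -> float:
    """Bonferroni min(1, p*k) or Sidak 1-(1-p)^k adjustment."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    if method == "bonferroni":
        return min(1.0, p * k)
    if method == "sidak":
        return 1.0 - (1.0 - p) ** k
    raise ValueError(f"unknown adjustment {method!r}")


def _is_normal(values: np.ndarray) -> bool:
    return stats.shapiro(values).pvalue >= SHAPIRO_ALPHA


def robustness(
    per_participant_ba: pd.Series,
    characteristics: pd.DataFrame,
    adjustment: str = "bonferroni",
) -> list[RobustnessResult]:
    """Associate participant balanced accuracies with baseline characteristics.

    ``per_participant_ba`` is indexed by participant id; numeric columns
    of ``characteristics`` (also indexed by id) are tested by correlation
    (Pearson if both variables pass Shapiro-Wilk, else Spearman);
    two-level categorical columns by t-test (both groups normal) or
    Mann-Whitney U.  P-values are adjusted over the k tests performed.
    """
    ba = per_participant_ba.loc[characteristics.index].to_numpy(dtype=float)
    if len(ba) < 3:
        raise ValueError("need at least 3 participants")
    results: list[RobustnessResult] = []
    for col in characteristics.columns:
        series = characteristics[col]
        if pd.api.types.is_numeric_dtype(series) and series.nunique() > 2:
            x = series.to_numpy(dtype=float)
            if _is_normal(x) and _is_normal(ba):
                r, p = stats.pearsonr(x, ba)
                test = "pearson"
            else:
                r, p = stats.spearmanr(x, ba)
                test = "spearman"
            results.append(RobustnessResult(col, test, float(r), float(p)))
        else:
            levels = series.unique()
            if len(levels) != 2:
                continue  # only binary categorical characteristics are tested
            g1 = ba[(series == levels[0]).to_numpy()]
            g2 = ba[(series == levels[1]).to_numpy()]
            if len(g1) < 3 or len(g2) < 3:
                continue
            if _is_normal(g1) and _is_normal(g2):
                t, p = stats.ttest_ind(g1, g2)
                test = "t-test"
            else:
                t, p = stats.mannwhitneyu(g1, g2, alternative="two-sided")
                test = "mann-whitney"
            results.append(RobustnessResult(col, test, float(t), float(p)))
    k = len(results)
    for res in results:
        res.p_adjusted = adjust_p(res.p_raw, k, adjustment)
        res.adjustment = adjustment
        res.k = k
    return results


def reliability_cv(values: np.ndarray) -> float:
    """Coefficient of variation in percent: sample SD / arithmetic mean * 100."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 repeated measurements")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(arr.std(ddof=1) / mean * 100.0)


def summarise_cvs(cvs: np.ndarray) -> dict[str, float]:
    """Sample-based reliability summary over the moduli of per-activity CVs.

    Mean with a normal 95%-CI when the CVs pass Shapiro-Wilk, otherwise
    median with a ~95% distribution-free CI from the order statistics.
    """
    a = np.abs(np.asarray(cvs, dtype=float))
    if a.size < 3:
        raise ValueError("need at least 3 CVs to summarise")
    if _is_normal(a):
        centre = float(a.mean())
        half = 1.96 * a.std(ddof=1) / np.sqrt(a.size)
        lo, hi = centre - half, centre + half
        kind = "mean"
    else:
        centre = float(np.median(a))
        s = np.sort(a)
        n = a.size
        j = int(np.floor(n / 2 - 1.96 * np.sqrt(n) / 2))
        j = max(j, 0)
        lo, hi = float(s[j]), float(s[min(n - 1 - j, n - 1)])
        kind = "median"
    return {"summary": kind, "centre": centre, "ci_low": float(lo),
            "ci_high": float(hi), "acceptable": centre < 10.0}


def training_sample_check(
    predicted: np.ndarray, reference: np.ndarray
) -> dict[str, float]:
    """Per-class balanced accuracy of a model on its own training rows."""
    matrix = confusion(predicted, reference)
    return {
        cls: class_performance(matrix, cls).balanced_accuracy
        for cls in CLASSES
        if matrix.counts[:, CLASSES.index(cls)].sum() > 0
    }


def compare_algorithms(
    per_participant: pd.DataFrame, adjustment: str = "bonferroni"
) -> list[RobustnessResult]:
    """Pairwise comparison of algorithms' participant-specific accuracies.

    ``per_participant`` has one column per algorithm, one row per
    participant.  Shapiro-Wilk on the paired differences gates paired
    t-test vs Wilcoxon; p-values are adjusted over all pairs.
    """
    cols = list(per_participant.columns)
    results: list[RobustnessResult] = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            diff = (per_participant[a] - per_participant[b]).to_numpy(dtype=float)
            if np.allclose(diff, 0):
                results.append(RobustnessResult(f"{a} vs {b}", "identical", 0.0, 1.0))
                continue
            if _is_normal(diff):
                t, p = stats.ttest_rel(per_participant[a], per_participant[b])
                test = "paired t-test"
            else:
                t, p = stats.wilcoxon(per_participant[a], per_participant[b])
                test = "wilcoxon"
            results.append(RobustnessResult(f"{a} vs {b}", test, float(t), float(p)))
    k = len(results)
    for res in results:
        res.p_adjusted = adjust_p(res.p_raw, k, adjustment)
        res.adjustment = adjustment
        res.k = k
    return results
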