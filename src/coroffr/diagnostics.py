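"""Agreement and diagnostic-performance statistics for paired FFR tables.

Given per-vessel pairs of computed and reference (invasive) FFR, this module
reports Pearson correlation with a Fisher-z confidence interval,
Bland-Altman bias and 95% limits of agreement, relative error, the confusion
matrix at the 0.80 ischemia threshold (sensitivity, specificity, PPV, NPV,
accuracy, prevalence, Youden J), and ROC analysis (trapezoidal AUC with a
DeLong confidence interval, optimal cutoff by maximizing sensitivity +
specificity with ties broken toward 0.80).

The positive (ischemic) class is FFR <= 0.80, inclusive, everywhere.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

FFR_THRESHOLD = 0.80


@dataclass
class PairedFFRTable:
    """Rows of {vessel_id, ffr_reference, ffr_computed}, values in (0, 1.5)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"vessel_id", "ffr_reference", "ffr_computed"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"paired table missing columns: {sorted(missing)}")
        vals = self.df[["ffr_reference", "ffr_computed"]]
        if vals.isna().any().any():
            raise ValueError("paired table contains missing FFR values")
        if ((vals <= 0) | (vals >= 1.5)).any().any():
            raise ValueError("FFR values must lie in (0, 1.5)")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairedFFRTable":
        """Read a CSV with columns vessel_id, ffr_invasive, ffr_computed."""
        try:
            df = pd.read_csv(path)
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise ValueError(f"{path}: malformed CSV ({exc})") from exc
        if "ffr_invasive" in df.columns:
            df = df.rename(columns={"ffr_invasive": "ffr_reference"})
        for col in ("ffr_reference", "ffr_computed"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                raise ValueError(
                    f"{path}: non-numeric {col} at row {int(bad[0]) + 2}"
                )
            df[col] = pd.to_numeric(df[col])
        return cls(df=df)

    @property
    def reference(self) -> np.ndarray:
        return self.df["ffr_reference"].to_numpy(dtype=float)

    @property
    def computed(self) -> np.ndarray:
        return self.df["ffr_computed"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class ConfusionMetrics:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    prevalence: float
    youden_j: float


@dataclass
class DiagnosticsReport:
    n: int
    threshold: float
    pearson_r: float
    pearson_ci: tuple[float, float]
    bias: float
    loa_low: float
    loa_high: float
    mean_relative_error: float
    mean_abs_relative_error: float
    auc: float
    auc_ci: tuple[float, float]
    optimal_cutoff: float
    confusion: ConfusionMetrics
    youden_j_truncated_2dp: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_text(self) -> str:
        c = self.confusion
        lines = [
            f"Paired FFR diagnostics (n = {self.n}, ischemia threshold <= {self.threshold:.2f})",
            "",
            f"Pearson r           : {self.pearson_r:.4f} "
            f"(95% CI {self.pearson_ci[0]:.4f} to {self.pearson_ci[1]:.4f})",
            f"Bland-Altman bias   : {self.bias:+.4f} "
            f"(95% LoA {self.loa_low:+.4f} to {self.loa_high:+.4f})",
            f"Mean relative error : {self.mean_relative_error:+.4f} "
            f"(mean |rel. error| {self.mean_abs_relative_error:.4f})",
            f"AUC                 : {self.auc:.4f} "
            f"(95% CI {self.auc_ci[0]:.4f} to {self.auc_ci[1]:.4f})",
            f"Optimal cutoff      : {self.optimal_cutoff:.4f}",
            "",
            f"At threshold {self.threshold:.2f}: TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn}",
            f"  sensitivity {100 * c.sensitivity:.2f}%  specificity {100 * c.specificity:.2f}%",
            f"  PPV {100 * c.ppv:.2f}%  NPV {100 * c.npv:.2f}%  accuracy {100 * c.accuracy:.2f}%",
            f"  prevalence {100 * c.prevalence:.2f}%  Youden J {c.youden_j:.4f} "
            f"(2 dp, truncated: {self.youden_j_truncated_2dp:.2f})",
        ]
        return "\n".join(lines)


def relative_error(computed: float, reference: float) -> float:
    """(computed - reference) / reference."""
    if reference <= 0:
        raise ValueError(f"reference FFR must be positive, got {reference}")
    return (computed - reference) / reference


def bland_altman(table: PairedFFRTable) -> tuple[float, float, float]:
    """(bias, loa_low, loa_high): mean difference +/- 1.96 SD of differences."""
    if len(table) < 2:
        raise ValueError("Bland-Altman requires at least 2 rows")
    diffs = table.computed - table.reference
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def confusion_metrics(
    table: PairedFFRTable, threshold: float = FFR_THRESHOLD
) -> ConfusionMetrics:
    """Binary classification metrics at ``value <= threshold`` (ischemic)."""
    ref_pos = table.reference <= threshold
    comp_pos = table.computed <= threshold
    if ref_pos.all() or (~ref_pos).all():
        missing = "negative (FFR > threshold)" if ref_pos.all() else "positive (FFR <= threshold)"
        raise ValueError(f"reference labels contain no {missing} class")
    tp = int(np.sum(ref_pos & comp_pos))
    fn = int(np.sum(ref_pos & ~comp_pos))
    tn = int(np.sum(~ref_pos & ~comp_pos))
    fp = int(np.sum(~ref_pos & comp_pos))
    n = tp + fp + tn + fn
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return ConfusionMetrics(
        threshold=threshold,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        ppv=tp / (tp + fp) if tp + fp else float("nan"),
        npv=tn / (tn + fn) if tn + fn else float("nan"),
        accuracy=(tp + tn) / n,
        prevalence=(tp + fn) / n,
        youden_j=sens + spec - 1.0,
    )


def _delong_ci(
    labels: np.ndarray, scores: np.ndarray, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """AUC and DeLong confidence interval (labels boolean, higher score = positive)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    tz = stats.rankdata(allv)
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    auc = (float(np.sum(tz[:m])) - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    var = 0.0
    if m > 1:
        var += float(np.var(v01, ddof=1)) / m
    if n > 1:
        var += float(np.var(v10, ddof=1)) / n
    se = math.sqrt(var)
    z = stats.norm.ppf(1 - alpha / 2)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return auc, (lo, hi)


def roc_analysis(
    table: PairedFFRTable, threshold: float = FFR_THRESHOLD
) -> tuple[float, tuple[float, float], float]:
    """(auc, delong_ci, optimal_cutoff) of computed FFR against reference labels.

    Scores are ``-ffr_computed`` (lower FFR = more likely ischemic); the AUC
    is the trapezoidal area under the empirical ROC.  The optimal cutoff is
    the computed-FFR value maximizing sensitivity + specificity, ties broken
    toward the value closest to the clinical threshold.
    """
    labels = table.reference <= threshold
    if labels.all() or (~labels).all():
        missing = "negative" if labels.all() else "positive"
        raise ValueError(f"reference labels contain no {missing} class")
    scores = -table.computed
    auc, ci = _delong_ci(labels, scores)
    # cross-check against the library trapezoidal estimator
    assert abs(auc - roc_auc_score(labels, scores)) < 1e-12

    best_j = -math.inf
    best_cut = float("nan")
    for c in np.unique(table.computed):
        pred = table.computed <= c
        tp = np.sum(labels & pred)
        fn = np.sum(labels & ~pred)
        tn = np.sum(~labels & ~pred)
        fp = np.sum(~labels & pred)
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if j > best_j + 1e-12 or (
            abs(j - best_j) <= 1e-12
            and abs(c - threshold) < abs(best_cut - threshold)
        ):
            best_j = j
            best_cut = float(c)
    return auc, ci, best_cut


def pearson_with_ci(
    table: PairedFFRTable, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Pearson r with a Fisher z-transform confidence interval."""
    if len(table) < 3:
        raise ValueError("Pearson correlation requires at least 3 rows")
    x, y = table.reference, table.computed
    if np.std(x) < 1e-12 * (abs(x.mean()) + 1) or np.std(y) < 1e-12 * (abs(y.mean()) + 1):
        raise ValueError("Pearson correlation undefined for zero-variance column")
    r = float(stats.pearsonr(x, y).statistic)
    if len(table) == 3:
        # Fisher z has zero degrees of freedom at n = 3: CI is uninformative
        return r, -1.0, 1.0
    z = math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15))
    se = 1.0 / math.sqrt(len(table) - 3)
    zc = stats.norm.ppf(1 - alpha / 2)
    return r, math.tanh(z - zc * se), math.tanh(z + zc * se)


def diagnostic_report(
    table: PairedFFRTable, threshold: float = FFR_THRESHOLD
) -> DiagnosticsReport:
    """Full agreement + diagnostic-performance report for a paired table."""
    r, rlo, rhi = pearson_with_ci(table)
    bias, lo, hi = bland_altman(table)
    rel = (table.computed - table.reference) / table.reference
    auc, auc_ci, cutoff = roc_analysis(table, threshold)
    conf = confusion_metrics(table, threshold)
    return DiagnosticsReport(
        n=len(table),
        threshold=threshold,
        pearson_r=r,
        pearson_ci=(rlo, rhi),
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        mean_relative_error=float(np.mean(rel)),
        mean_abs_relative_error=float(np.mean(np.abs(rel))),
        auc=auc,
        auc_ci=auc_ci,
        optimal_cutoff=cutoff,
        confusion=conf,
        youden_j_truncated_2dp=math.trunc(conf.youden_j * 100) / 100.0,
    )
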