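"""Evaluation metrics for DDI extraction.

Per-class precision / recall / F-score / accuracy from contingency tables,
micro-averaged F (CLA, from a single global table) and macro-averaged F
(MAVG, the unweighted mean of per-class F), the 1-sigma cross-corpus
scalability score, multi-run reproducibility summaries, and Welch's t-test
for consistency comparisons between models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable", "MetricReport", "RunTrace",
    "contingency_metrics", "multiclass_report", "scalability_score",
    "reproducibility_summary", "welch_t_test", "trace_boxplot",
]


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _safe_div(num: float, den: float, warn: str | None = None,
              nan_on_degenerate: bool = False) -> float:
    if den == 0:
        if nan_on_degenerate:
            return float("nan")
        if warn:
            warnings.warn(warn, RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def contingency_metrics(table: ContingencyTable,
                        nan_on_degenerate: bool = False
                        ) -> tuple[float, float, float, float]:
    """(P, R, F, Acc) from one contingency table.

    P = TP/(TP+FP); R = TP/(TP+FN); F = 2PR/(P+R); Acc = (TP+TN)/total.
    Degenerate 0/0 ratios return 0 with a warning (or NaN when requested).
    """
    if table.total == 0:
        raise ValueError("empty contingency table")
    p = _safe_div(table.tp, table.tp + table.fp,
                  "precision undefined (no predicted positives); using 0",
                  nan_on_degenerate)
    r = _safe_div(table.tp, table.tp + table.fn,
                  "recall undefined (no gold positives); using 0",
                  nan_on_degenerate)
    f = _safe_div(2.0 * p * r, p + r, None, nan_on_degenerate)
    acc = (table.tp + table.tn) / table.total
    return p, r, f, acc


@dataclass
class MetricReport:
    per_class: dict[str, tuple[float, float, float]]  # label -> (P, R, F)
    accuracy: float
    cla: float   # micro-averaged F from the global contingency table
    mavg: float  # macro-averaged F, unweighted over classes
    tables: dict[str, ContingencyTable] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "per_class": {
                lbl: {"precision": p, "recall": r, "f_score": f}
                for lbl, (p, r, f) in self.per_class.items()
            },
            "accuracy": self.accuracy,
            "CLA": self.cla,
            "MAVG": self.mavg,
        }


def multiclass_report(predictions: list, gold: list, classes,
                      exclude: set | None = None,
                      nan_on_degenerate: bool = False) -> MetricReport:
    """One-vs-rest per-class metrics plus CLA and MAVG.

    CLA sums the per-class contingency tables into one global table and
    computes F from it; MAVG averages the per-class F-scores without
    weights.  ``exclude`` removes labels (typically NEGATIVE, the shared
    task convention) from both averages; excluded classes still get
    per-class entries.
    """
    if len(predictions) != len(gold):
        raise ValueError(
            f"{len(predictions)} predictions vs {len(gold)} gold labels")
    classes = list(classes)
    class_set = set(classes)
    for lbl in list(predictions) + list(gold):
        if lbl not in class_set:
            raise ValueError(f"label {lbl!r} not in class set")
    exclude = exclude or set()

    pred = np.asarray(predictions, dtype=object)
    gld = np.asarray(gold, dtype=object)
    per_class: dict[str, tuple[float, float, float]] = {}
    tables: dict[str, ContingencyTable] = {}
    micro = np.zeros(4, dtype=int)  # tp, fp, fn, tn
    macro_f: list[float] = []
    for lbl in classes:
        tp = int(np.sum((pred == lbl) & (gld == lbl)))
        fp = int(np.sum((pred == lbl) & (gld != lbl)))
        fn = int(np.sum((pred != lbl) & (gld == lbl)))
        tn = int(np.sum((pred != lbl) & (gld != lbl)))
        table = ContingencyTable(tp, fp, fn, tn)
        tables[lbl] = table
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p, r, f, _ = contingency_metrics(table, nan_on_degenerate)
        per_class[lbl] = (p, r, f)
        if lbl not in exclude:
            micro += (tp, fp, fn, tn)
            macro_f.append(f)
    accuracy = float(np.mean(pred == gld))
    global_table = ContingencyTable(*micro.tolist())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, _, cla, _ = contingency_metrics(global_table, nan_on_degenerate)
    mavg = float(np.mean(macro_f)) if macro_f else 0.0
    return MetricReport(per_class=per_class, accuracy=accuracy,
                        cla=cla, mavg=mavg, tables=tables)


def scalability_score(f_a: float, f_b: float) -> float:
    """1 - sigma across two corpora: one minus the population standard
    deviation of the two F-scores (equivalently 1 - |f_a - f_b| / 2).

    A model that scores similarly on both corpora scales well (score near
    1); a large gap is penalised even when the mean F is high.
    """
    for f in (f_a, f_b):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"F-score {f} outside [0, 1]")
    mu = (f_a + f_b) / 2.0
    sigma = np.sqrt(0.5 * (f_a - mu) ** 2 + 0.5 * (f_b - mu) ** 2)
    return float(1.0 - sigma)


@dataclass
class RunTrace:
    """Per-epoch F-scores of one training run."""

    run_id: str
    f_scores: np.ndarray
    seed: int = 0

    def __post_init__(self):
        self.f_scores = np.asarray(self.f_scores, dtype=float)


def reproducibility_summary(traces: list[RunTrace]) -> tuple[float, float]:
    """(sum of per-epoch variances, sum of per-epoch standard deviations)
    of the F-scores across runs.  Population (divide-by-n) convention.
    """
    if len(traces) < 2:
        raise ValueError("need at least two runs")
    lengths = {len(t.f_scores) for t in traces}
    if len(lengths) != 1:
        raise ValueError(f"unequal epoch counts across runs: {sorted(lengths)}")
    matrix = np.stack([t.f_scores for t in traces])  # (runs, epochs)
    var = matrix.var(axis=0, ddof=0)
    # epochs where every run agrees exactly are exactly zero, not float dust
    var[np.ptp(matrix, axis=0) == 0.0] = 0.0
    return float(var.sum()), float(np.sqrt(var).sum())


def welch_t_test(sample_a, sample_b, alpha: float = 0.05
                 ) -> tuple[float, float, float, bool]:
    """Welch's unequal-variance t-test, two-sided.

    Returns (t, Welch-Satterthwaite df, p, p < alpha).  When both samples
    have zero variance: equal means give (0, p=1); different means are
    reported as significant with p = 0 (the limit of vanishing variance).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0.0 and vb == 0.0:
        df = float(na + nb - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0, False
        t = np.inf if a.mean() > b.mean() else -np.inf
        return float(t), df, 0.0, True
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p), bool(p < alpha)


def trace_boxplot(traces: list[RunTrace], path, title: str = "") -> None:
    """Boxplot of F-scores per epoch across runs, written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix = np.stack([t.f_scores for t in traces])
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.boxplot(matrix, showfliers=False)
    step = max(1, matrix.shape[1] // 20)
    ax.set_xticks(range(1, matrix.shape[1] + 1, step))
    ax.set_xlabel("epoch")
    ax.set_ylabel("F-score")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
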