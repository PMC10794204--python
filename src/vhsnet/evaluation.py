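"""Classification metrics and annotator-agreement statistics.

Conventions: the 3x3 confusion matrix holds raw counts with rows indexed
by the true class and columns by the predicted class.  Three percentage
views are reported, each to one decimal: every cell as a share of all
samples, the diagonal as a share of its row (per-class accuracy /
sensitivity), and the off-diagonal cells as shares of their row (per-class
error rates).  One-vs-rest AUC, precision, specificity and sensitivity
are reported per class with argmax decisions; inter-annotator agreement
on continuous measurements uses the two-way random-effects,
absolute-agreement, single-measurement intraclass correlation ICC(2,1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from .errors import DomainError
from .geometry import CLASS_NAMES

N_CLASSES = 3


def _check_labels(y, name: str) -> np.ndarray:
    arr = np.asarray(y, dtype=int)
    if arr.ndim != 1:
        raise DomainError(f"{name} must be 1-D, got shape {arr.shape}")
    if arr.size and (arr.min() < 0 or arr.max() >= N_CLASSES):
        raise DomainError(f"{name} has labels outside {{0, 1, 2}}")
    return arr


def overall_accuracy(y_true, y_pred) -> float:
    """Fraction of samples whose predicted class equals the true class."""
    yt, yp = _check_labels(y_true, "y_true"), _check_labels(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise DomainError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if yt.size == 0:
        raise DomainError("need at least one sample")
    return float((yt == yp).mean())


@dataclass
class ConfusionMatrix:
    """Raw 3x3 counts; rows = true class, columns = predicted class."""

    counts: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def confusion(y_true, y_pred) -> ConfusionMatrix:
    yt, yp = _check_labels(y_true, "y_true"), _check_labels(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise DomainError(f"length mismatch: {yt.shape} vs {yp.shape}")
    counts = _sk_confusion(yt, yp, labels=list(range(N_CLASSES)))
    return ConfusionMatrix(counts=counts.astype(int))


def percentages(cm: ConfusionMatrix, decimals: int = 1) -> dict:
    """Percentage views of a confusion matrix, rounded to one decimal.

    ``cell_pct[i, j]`` is count/total; ``row_pct[i, j]`` is count/row-sum —
    its diagonal is the per-class correct percentage and its off-diagonal
    entries the per-class error percentages.  Rows with no samples yield
    NaN row percentages.
    """
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise DomainError("empty confusion matrix")
    cell_pct = np.round(100.0 * counts / total, decimals)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_pct = np.round(100.0 * counts / row_sums, decimals)
    return {
        "cell_pct": cell_pct,
        "row_pct": row_pct,
        "row_correct_pct": np.diag(row_pct).copy(),
    }


def one_vs_rest_metrics(y_true, class_probs) -> dict:
    """Per-class AUC / precision / specificity / sensitivity.

    ``class_probs`` rows must sum to 1; decisions are by argmax.  The AUC
    for a class absent from ``y_true`` is undefined and reported as None.
    """
    yt = _check_labels(y_true, "y_true")
    probs = np.asarray(class_probs, dtype=float)
    if probs.shape != (yt.size, N_CLASSES):
        raise DomainError(f"class_probs must be (n, 3), got {probs.shape}")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise DomainError("class_probs rows must sum to 1")
    yp = probs.argmax(axis=1)
    out = {}
    for k in range(N_CLASSES):
        pos = yt == k
        pred_pos = yp == k
        tp = int(np.sum(pos & pred_pos))
        fp = int(np.sum(~pos & pred_pos))
        fn = int(np.sum(pos & ~pred_pos))
        tn = int(np.sum(~pos & ~pred_pos))
        present = pos.any() and (~pos).any()
        auc = float(roc_auc_score(pos, probs[:, k])) if present else None
        out[CLASS_NAMES[k]] = {
            "auc": auc,
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        }
    return out


def icc_agreement(ratings_a, ratings_b) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares over ``n`` paired
    continuous measurements (e.g. flattened keypoint coordinates from two
    annotators); symmetric in its arguments.
    """
    a = np.asarray(ratings_a, dtype=float).ravel()
    b = np.asarray(ratings_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise DomainError(f"rating vectors differ in length: {a.size} vs {b.size}")
    n = a.size
    if n < 2:
        raise DomainError("ICC needs at least 2 paired measurements")
    x = np.stack([a, b], axis=1)           # n subjects x k=2 raters
    k = 2
    grand = x.mean()
    subj_means = x.mean(axis=1)
    rater_means = x.mean(axis=0)
    ssr = k * np.sum((subj_means - grand) ** 2)
    ssc = n * np.sum((rater_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


@dataclass
class MetricsReport:
    """Bundle of the evaluation surface for one labeled set."""

    overall_accuracy: float
    confusion: ConfusionMatrix
    cell_pct: np.ndarray
    row_pct: np.ndarray
    per_class: dict
    icc: float | None = None
    icc_form: str = "ICC(2,1) two-way random, absolute agreement, single measure"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "confusion_counts": self.confusion.counts.tolist(),
            "cell_pct": self.cell_pct.tolist(),
            "row_pct": self.row_pct.tolist(),
            "per_class": self.per_class,
            "icc": self.icc,
            "icc_form": self.icc_form,
            **self.extra,
        }

    def to_text(self) -> str:
        lines = [f"overall accuracy: {self.overall_accuracy:.3f}",
                 "confusion (rows=true, cols=predicted):"]
        for i, name in enumerate(CLASS_NAMES):
            cells = "  ".join(f"{c:5d}" for c in self.confusion.counts[i])
            lines.append(f"  {name:>6}: {cells}   row-correct {self.row_pct[i, i]:.1f}%")
        for name, m in self.per_class.items():
            auc = "n/a" if m["auc"] is None else f"{m['auc']:.3f}"
            lines.append(f"  {name:>6}: AUC {auc}  precision {m['precision']:.3f}  "
                         f"specificity {m['specificity']:.3f}  sensitivity {m['sensitivity']:.3f}")
        if self.icc is not None:
            lines.append(f"ICC: {self.icc:.3f} [{self.icc_form}]")
        return "\n".join(lines)


def metrics_report(y_true, y_pred, class_probs=None, icc_pair=None) -> MetricsReport:
    """Assemble accuracy, confusion percentages, per-class metrics and ICC."""
    cm = confusion(y_true, y_pred)
    pct = percentages(cm)
    per_class = {}
    if class_probs is not None:
        per_class = one_vs_rest_metrics(y_true, class_probs)
    icc = icc_agreement(*icc_pair) if icc_pair is not None else None
    return MetricsReport(overall_accuracy=overall_accuracy(y_true, y_pred),
                         confusion=cm, cell_pct=pct["cell_pct"], row_pct=pct["row_pct"],
                         per_class=per_class, icc=icc)


def plot_confusion(cm: ConfusionMatrix, path, title: str = "") -> None:
    """Render the confusion matrix as a PNG.

    Ground-truth classes run along the x-axis and predictions along the
    y-axis; each cell is annotated with its count, its share of all
    samples, and — colored green on the diagonal, red off it — its share
    of the ground-truth column.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = cm.counts
    n = cm.n
    col = counts.T  # display: x = truth, y = prediction
    fig, ax = plt.subplots(figsize=(4.2, 4.0))
    ax.imshow(col, cmap="Blues", alpha=0.65)
    for i in range(N_CLASSES):        # i: predicted (y), j: true (x)
        for j in range(N_CLASSES):
            c = col[i, j]
            truth_total = counts[j].sum()
            share = 100.0 * c / n if n else 0.0
            rate = 100.0 * c / truth_total if truth_total else float("nan")
            color = "green" if i == j else "red"
            ax.text(j, i - 0.18, f"{c}", ha="center", fontsize=11, weight="bold")
            ax.text(j, i + 0.05, f"{share:.1f}%", ha="center", fontsize=8, color="black")
            ax.text(j, i + 0.26, f"{rate:.1f}%", ha="center", fontsize=8, color=color)
    ax.set_xticks(range(N_CLASSES), CLASS_NAMES)
    ax.set_yticks(range(N_CLASSES), CLASS_NAMES)
    ax.set_xlabel("ground truth")
    ax.set_ylabel("predicted")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
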