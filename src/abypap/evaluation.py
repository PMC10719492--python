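"""Regression and classification metrics for angle prediction, plus report
rendering.

The regression report carries six quantities: Pearson's R, mean absolute
error, RMSE, RELRMSE, and the slope and intercept of predicted regressed
on actual.  RELRMSE is RMSE divided by the root-mean-square of the actual
angles, making the error dimensionless; since packing angles sit near
-46 deg, RMSE/RELRMSE is always close to 45-46.  "Mean error" is the mean
absolute error (it is always below RMSE, by Jensen's inequality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix, matthews_corrcoef

CLASS_ORDER = ("min_outlier", "normal", "max_outlier")


@dataclass
class EvalReport:
    """The six regression metrics for one prediction set."""

    pearson_r: float
    mean_error: float
    rmse: float
    relrmse: float
    slope: float
    intercept: float
    n: int

    def to_row(self, method: str = "model") -> str:
        return "\t".join(
            [
                method,
                str(self.n),
                f"{self.pearson_r:.3f}",
                f"{self.mean_error:.3f}",
                f"{self.rmse:.3f}",
                f"{self.relrmse:.3f}",
                f"{self.slope:.3f}",
                f"{self.intercept:.3f}",
            ]
        )


@dataclass
class ClassReport:
    """Gatekeeper classification metrics."""

    mcc: float
    accuracy: float
    confusion: np.ndarray  # 3x3, rows=actual, cols=predicted, CLASS_ORDER


def regression_metrics(actual: Sequence[float], predicted: Sequence[float]) -> EvalReport:
    """Compute the six-metric regression report.

    ``slope``/``intercept`` are the ordinary-least-squares fit of
    predicted on actual, matching predicted-vs-actual scatter plots where
    a perfect model lies on the identity line.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError("actual and predicted must be equal-length 1-D arrays")
    if a.size < 2:
        raise ValueError("need at least two samples for correlation and slope")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(p))):
        raise ValueError("metrics require finite values")
    err = a - p
    rmse = float(np.sqrt(np.mean(err**2)))
    if np.std(a) == 0 or np.std(p) == 0:
        # degenerate: correlation undefined for a constant margin
        pearson = 0.0
        slope, intercept = (0.0, float(np.mean(p)))
        if np.std(a) > 0:
            res = stats.linregress(a, p)
            slope, intercept = float(res.slope), float(res.intercept)
    else:
        pearson = float(stats.pearsonr(a, p).statistic)
        res = stats.linregress(a, p)
        slope, intercept = float(res.slope), float(res.intercept)
    rms_actual = float(np.sqrt(np.mean(a**2)))
    return EvalReport(
        pearson_r=pearson,
        mean_error=float(np.mean(np.abs(err))),
        rmse=rmse,
        relrmse=rmse / rms_actual if rms_actual > 0 else float("nan"),
        slope=slope,
        intercept=intercept,
        n=int(a.size),
    )


def classification_metrics(
    actual: Sequence[str], predicted: Sequence[str]
) -> ClassReport:
    """Multiclass Matthews correlation, accuracy and the 3x3 confusion matrix.

    MCC uses the multiclass (Gorodkin) generalisation.  Degenerate inputs
    (any zero marginal, e.g. a single observed class) give MCC 0 with a
    warning, so tiny datasets keep pipelines running.
    """
    a = np.asarray(actual, dtype=object)
    p = np.asarray(predicted, dtype=object)
    if a.shape != p.shape or a.size == 0:
        raise ValueError("actual and predicted must be equal-length, non-empty")
    for label in np.unique(np.concatenate([a, p])):
        if label not in CLASS_ORDER:
            raise ValueError(f"unknown class label {label!r}")
    conf = confusion_matrix(a, p, labels=list(CLASS_ORDER))
    accuracy = float(np.trace(conf) / conf.sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on zero denominators
        mcc = float(matthews_corrcoef(a, p))
    if len(np.unique(a)) < 2 or len(np.unique(p)) < 2:
        warnings.warn("degenerate class marginals; MCC reported as 0")
        mcc = 0.0
    return ClassReport(mcc=mcc, accuracy=accuracy, confusion=conf)


METRICS_HEADER = "method\tn\tpearson_r\tmean_error\trmse\trelrmse\tslope\tintercept"


def render_report(
    actual: Sequence[float],
    predicted: Sequence[float],
    out_dir: str | Path,
    method: str = "model",
) -> list[Path]:
    """Write the metrics TSV row and the three standard evaluation panels.

    Panels: (a) predicted vs actual with the identity line, (b) histogram
    of prediction errors, (c) squared error against actual angle.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    report = regression_metrics(a, p)  # validates inputs
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    tsv = out_dir / f"{method}_metrics.tsv"
    tsv.write_text(METRICS_HEADER + "\n" + report.to_row(method) + "\n")
    written.append(tsv)

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(a, p, s=8, alpha=0.6)
    lims = [min(a.min(), p.min()) - 1, max(a.max(), p.max()) + 1]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("actual angle (deg)")
    ax.set_ylabel("predicted angle (deg)")
    ax.set_title(f"{method}: predicted vs actual")
    path = out_dir / f"{method}_scatter.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.hist(a - p, bins=30)
    ax.set_xlabel("actual - predicted (deg)")
    ax.set_ylabel("count")
    ax.set_title(f"{method}: error distribution")
    path = out_dir / f"{method}_errors.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(a, (a - p) ** 2, s=8, alpha=0.6)
    ax.set_xlabel("actual angle (deg)")
    ax.set_ylabel("squared error (deg$^2$)")
    ax.set_title(f"{method}: squared error by angle")
    path = out_dir / f"{method}_sqerror.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)
    return written
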