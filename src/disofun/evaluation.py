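"""Assessment protocol: per-residue metrics, ROC/AUC, fully-disordered-protein
calling, and the half-dataset resampling significance test.

Metrics are pooled over the concatenated residues of all evaluated proteins
(dataset-level, as in community disorder assessments); a per-protein-averaged
variant exists but is not the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

FULLY_DISORDERED_FRACTION = 0.95


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Binary + ranking metrics for one predictor on one dataset."""

    counts: ConfusionCounts
    mcc: float
    f1: float
    tpr: float
    fpr: float
    auc: float | None = None
    roc_points: list[tuple[float, float]] | None = None
    n_units: int = 0
    mcc_degenerate: bool = False

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1)


def _confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    y = np.asarray(labels).astype(int).ravel()
    p = np.asarray(predictions).astype(int).ravel()
    if y.shape != p.shape:
        raise ValueError(f"label/prediction length mismatch: {y.shape} vs {p.shape}")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _pool(tracks) -> np.ndarray:
    if isinstance(tracks, (list, tuple)):
        return np.concatenate([np.asarray(t).ravel() for t in tracks])
    return np.asarray(tracks).ravel()


def binary_metrics(labels, predictions) -> MetricsReport:
    """Confusion counts plus MCC, F1, TPR, FPR, pooled over proteins.

    ``labels`` and ``predictions`` may be single arrays or per-protein lists
    of 0/1 tracks (pooled by concatenation). A zero MCC denominator yields
    MCC = 0 with the ``mcc_degenerate`` flag set rather than NaN.
    """
    y = _pool(labels)
    p = _pool(predictions)
    c = _confusion(y, p)
    f1_denom = 2 * c.tp + c.fp + c.fn
    f1 = 2 * c.tp / f1_denom if f1_denom else 0.0
    mcc_denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    degenerate = mcc_denom == 0
    mcc = 0.0 if degenerate else (c.tp * c.tn - c.fp * c.fn) / np.sqrt(mcc_denom)
    tpr = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    fpr = c.fp / (c.fp + c.tn) if (c.fp + c.tn) else 0.0
    return MetricsReport(
        counts=c, mcc=float(mcc), f1=float(f1), tpr=float(tpr), fpr=float(fpr),
        n_units=c.n, mcc_degenerate=degenerate,
    )


def roc_auc(propensities, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC points and trapezoidal AUC, pooled over proteins.

    One point per unique propensity threshold plus the (0,0) and (1,1)
    endpoints; tied propensities receive half credit, equivalent to the
    probability that a random positive-negative pair is correctly ordered.
    """
    p = _pool(propensities)
    y = _pool(labels)
    if p.shape != y.shape:
        raise ValueError("propensity/label length mismatch")
    if np.unique(y).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, p, drop_intermediate=False)
    points = list(zip(fpr.tolist(), tpr.tolist()))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def per_protein_averaged_metrics(labels: list, predictions: list) -> dict[str, float]:
    """Non-default variant: average MCC/F1 over proteins instead of pooling."""
    reports = [binary_metrics(y, p) for y, p in zip(labels, predictions)]
    return {
        "mcc": float(np.mean([r.mcc for r in reports])),
        "f1": float(np.mean([r.f1 for r in reports])),
    }


def fully_disordered_truth(
    labels: np.ndarray, fraction: float = FULLY_DISORDERED_FRACTION
) -> bool:
    """True iff disordered residues cover at least ``fraction`` of the chain."""
    y = np.asarray(labels).ravel()
    if len(y) < 1:
        raise ValueError("empty label track")
    return bool(y.mean() >= fraction)


def fully_disordered_prediction(
    disorder_binary: np.ndarray, fraction: float = FULLY_DISORDERED_FRACTION
) -> bool:
    """True iff the predicted-disordered fraction reaches the cutoff."""
    return fully_disordered_truth(disorder_binary, fraction)


def evaluate_fully_disordered(truths, predictions) -> MetricsReport:
    """Protein-level confusion/MCC/F1 for fully-disordered-protein calling."""
    t = np.asarray(truths, dtype=int)
    p = np.asarray(predictions, dtype=int)
    return binary_metrics(t, p)


@dataclass
class ResamplingReport:
    """Outcome of the paired half-dataset resampling comparison."""

    metric: str
    values_a: list[float]
    values_b: list[float]
    differences: list[float]
    test: str  # "paired_t" | "wilcoxon" | "degenerate"
    normal: bool | None
    p_value: float
    seed: int
    n_replicates: int
    degenerate: bool = False
    resampled_replicates: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def _replicate_metric(metric, labels, outputs, idx) -> float:
    y = [labels[i] for i in idx]
    o = [outputs[i] for i in idx]
    if metric == "AUC":
        return roc_auc(o, y)[1]
    report = binary_metrics(y, o)
    return {"F1": report.f1, "MCC": report.mcc}[metric]


def resampling_significance(
    labels: list,
    outputs_a: list,
    outputs_b: list,
    metric: str = "AUC",
    n_replicates: int = 10,
    seed: int = 0,
    alpha_normality: float = 0.05,
) -> ResamplingReport:
    """Paired significance test by resampling half the test set.

    Each replicate draws floor(N/2) proteins without replacement (the same
    sample for both predictors), recomputes the metric, and the paired
    differences are tested: a two-sided paired t-test when an
    Anderson-Darling test does not reject normality of the differences at
    ``alpha_normality``, otherwise a two-sided Wilcoxon signed-rank test.

    For ``AUC`` the per-protein outputs are propensity tracks; for ``F1`` and
    ``MCC`` they are binary tracks. A replicate whose sample contains a single
    label class is redrawn with an advanced seed and recorded in the report.
    """
    if metric not in ("AUC", "F1", "MCC"):
        raise ValueError(f"unsupported metric {metric!r}")
    n = len(labels)
    if not (len(outputs_a) == len(outputs_b) == n):
        raise ValueError("predictors must be evaluated on identical proteins")
    if n < 4:
        raise ValueError("need at least 4 proteins to resample halves")
    rng = np.random.default_rng(seed)
    half = n // 2
    values_a, values_b, redrawn = [], [], []
    for rep in range(n_replicates):
        for attempt in range(100):
            idx = rng.choice(n, size=half, replace=False)
            pooled = np.concatenate([np.asarray(labels[i]).ravel() for i in idx])
            if np.unique(pooled).size >= 2:
                break
            redrawn.append(rep)
        else:
            raise ValueError("could not draw a two-class half-sample")
        values_a.append(_replicate_metric(metric, labels, outputs_a, idx))
        values_b.append(_replicate_metric(metric, labels, outputs_b, idx))

    d = np.array(values_a) - np.array(values_b)
    if np.allclose(d, 0.0):
        return ResamplingReport(
            metric=metric, values_a=values_a, values_b=values_b,
            differences=d.tolist(), test="degenerate", normal=None, p_value=1.0,
            seed=seed, n_replicates=n_replicates, degenerate=True,
            resampled_replicates=redrawn,
        )
    ad = stats.anderson(d, dist="norm", method="interpolate")
    normal = bool(ad.pvalue > alpha_normality)
    if normal:
        test = "paired_t"
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    else:
        test = "wilcoxon"
        p = float(stats.wilcoxon(d).pvalue)
    return ResamplingReport(
        metric=metric, values_a=values_a, values_b=values_b,
        differences=d.tolist(), test=test, normal=normal, p_value=p,
        seed=seed, n_replicates=n_replicates, resampled_replicates=redrawn,
    )
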