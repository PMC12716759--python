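"""Presence/absence model evaluation: AUC-ROC, threshold-dependent rates,
TSS, precision, the continuous Boyce index, and optimal-threshold selection
by maximising sensitivity + specificity."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .geodata import RasterGrid


@dataclass
class MetricsReport:
    """Per-evaluation metric bundle. ``boyce`` and ``precision`` may be None
    when undefined (single-window Boyce, no predicted positives)."""

    auc: float
    tss: float
    sensitivity: float
    specificity: float
    precision: float | None
    boyce: float | None
    threshold: float
    n_presence: int
    n_absence: int

    def __post_init__(self) -> None:
        assert abs(self.tss - (self.sensitivity + self.specificity - 1)) < 1e-12


def _check_two_classes(labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def confusion_rates(scores, labels, threshold: float):
    """(sensitivity, specificity, precision) with scores >= threshold
    predicted positive. Precision is None when nothing is predicted positive."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    _check_two_classes(labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    return sensitivity, specificity, precision


def roc_auc(scores, labels) -> float:
    """AUC-ROC; equals the Mann-Whitney U statistic / (n1*n0) with ties
    counted half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def optimal_threshold(scores, labels) -> float:
    """Observed score maximising sensitivity + specificity; ties broken
    toward the lower threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    _check_two_classes(labels)
    candidates = np.unique(scores)
    best_t, best_j = None, -np.inf
    for t in candidates:  # ascending, so strict > keeps the lowest optimum
        sens, spec, _ = confusion_rates(scores, labels, t)
        j = sens + spec
        if j > best_j + 1e-15:
            best_j, best_t = j, float(t)
    return best_t


def evaluate(scores, labels, *, boyce: float | None = None,
             threshold: float | None = None) -> MetricsReport:
    """Full metric bundle at the (given or optimised) threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if threshold is None:
        threshold = optimal_threshold(scores, labels)
    sens, spec, prec = confusion_rates(scores, labels, threshold)
    return MetricsReport(
        auc=roc_auc(scores, labels),
        tss=sens + spec - 1,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        boyce=boyce,
        threshold=threshold,
        n_presence=int((labels == 1).sum()),
        n_absence=int((labels == 0).sum()),
    )


def boyce_index(surface: RasterGrid, presence_hsi, n_bins: int = 10,
                window_width: float = 0.2) -> float | None:
    """Continuous Boyce index.

    Overlapping windows span the [0, 1] HSI range (``n_bins`` windows of
    ``window_width``, evenly stepped). Per window, P = fraction of presence
    HSI values inside, E = fraction of valid landscape cells inside; windows
    with E = 0 are dropped. The index is the Spearman rank correlation of
    P/E against the window midpoints; None when fewer than three windows
    remain informative or the ratios are constant.
    """
    presence_hsi = np.asarray(presence_hsi, float)
    if presence_hsi.size < 20:
        raise ValueError("boyce_index requires at least 20 presences")
    cells = surface.valid_values().astype(float)
    step = (1.0 - window_width) / (n_bins - 1)
    mids, ratios = [], []
    for i in range(n_bins):
        lo = i * step
        hi = lo + window_width
        e = np.mean((cells >= lo) & (cells <= hi))
        if e == 0:
            continue
        p = np.mean((presence_hsi >= lo) & (presence_hsi <= hi))
        mids.append(lo + window_width / 2)
        ratios.append(p / e)
    if len(mids) < 3 or np.allclose(ratios, ratios[0]):
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(mids, ratios).statistic
    return None if np.isnan(rho) else float(rho)
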