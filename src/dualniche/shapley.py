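"""Exact Shapley-value attribution by subset enumeration.

The Shapley value of feature i for a prediction f(x) is the weighted
average of its marginal contributions over all subsets S of the other
features:

    phi_i = sum_{S subseteq F\\{i}} |S|! (|F|-|S|-1)! / |F|!
            * [ v(S u {i}) - v(S) ]

with the interventional value function v(S) = E_b[ f(x_S, b_{F\\S}) ]:
features in S are taken from the explained sample x, the rest from rows
of a background sample, and the expectation is the mean over that
background. The attribution is exact (no sampling), satisfies
efficiency (base + sum phi = prediction), and is feasible for up to 15
features; explanations of the 4-member ensemble are averaged pointwise
into an ensemble Shapley matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

MAX_FEATURES = 15


@dataclass
class ShapMatrix:
    """Per-sample, per-feature attributions plus the background base value."""

    values: np.ndarray  # (n_samples, n_features)
    base_value: float
    feature_names: list[str]
    sample_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")

    def predictions(self) -> np.ndarray:
        """Model outputs implied by efficiency: base + row sums."""
        return self.base_value + self.values.sum(axis=1)


def _subset_values(predict, background: np.ndarray, x: np.ndarray) -> np.ndarray:
    """v(S) for every subset S of features, indexed by bitmask."""
    n_features = x.size
    n_subsets = 1 << n_features
    n_bg = background.shape[0]
    values = np.empty(n_subsets)
    # evaluate in chunks of subsets to bound memory
    chunk = max(1, 2**18 // max(n_bg, 1))
    for start in range(0, n_subsets, chunk):
        masks = np.arange(start, min(start + chunk, n_subsets))
        member = ((masks[:, None] >> np.arange(n_features)) & 1).astype(bool)
        hybrid = np.where(member[:, None, :], x[None, None, :],
                          background[None, :, :])
        flat = hybrid.reshape(-1, n_features)
        preds = np.asarray(predict(flat), float).reshape(len(masks), n_bg)
        values[masks] = preds.mean(axis=1)
    return values


def exact_shapley(predict, background: np.ndarray, x: np.ndarray
                  ) -> tuple[np.ndarray, float]:
    """Exact Shapley attribution of ``predict`` at sample ``x``.

    ``predict`` maps a (n, n_features) array to n outputs; ``background``
    supplies the reference distribution. Returns (phi, base_value).
    """
    x = np.asarray(x, float).ravel()
    background = np.atleast_2d(np.asarray(background, float))
    n_features = x.size
    if n_features > MAX_FEATURES:
        raise ValueError(
            f"{n_features} features exceeds the exact-enumeration bound "
            f"({MAX_FEATURES}); use a sampling approximation instead")
    if background.shape[1] != n_features:
        raise ValueError("background width must match feature count")
    v = _subset_values(predict, background, x)
    fact = [factorial(k) for k in range(n_features + 1)]
    denom = fact[n_features]
    phi = np.zeros(n_features)
    all_masks = np.arange(1 << n_features)
    sizes = np.array([bin(m).count("1") for m in all_masks])
    for i in range(n_features):
        bit = 1 << i
        without = all_masks[(all_masks & bit) == 0]
        s = sizes[without]
        w = np.array([fact[k] * fact[n_features - k - 1] for k in s]) / denom
        phi[i] = np.sum(w * (v[without | bit] - v[without]))
    return phi, float(v[0])


def shap_matrix(predict, samples: np.ndarray, background: np.ndarray,
                feature_names: list[str],
                sample_index: np.ndarray | None = None) -> ShapMatrix:
    """Exact Shapley values for every row of ``samples``."""
    samples = np.atleast_2d(np.asarray(samples, float))
    rows = []
    base = None
    for x in samples:
        phi, base = exact_shapley(predict, background, x)
        rows.append(phi)
    return ShapMatrix(np.vstack(rows), base, list(feature_names), sample_index)


def ensemble_shap(matrices: list[ShapMatrix]) -> ShapMatrix:
    """Pointwise mean of member Shapley matrices; the base value is the mean
    of member base values, so efficiency holds against the mean of member
    predictions."""
    if not matrices:
        raise ValueError("no matrices supplied")
    first = matrices[0]
    for m in matrices[1:]:
        if m.values.shape != first.values.shape:
            raise ValueError("matrix shapes differ")
        if m.feature_names != first.feature_names:
            raise ValueError("feature names differ")
    return ShapMatrix(
        values=np.mean([m.values for m in matrices], axis=0),
        base_value=float(np.mean([m.base_value for m in matrices])),
        feature_names=list(first.feature_names),
        sample_index=first.sample_index,
    )


def global_importance(matrix: ShapMatrix) -> list[tuple[str, float]]:
    """Mean |phi| per feature, descending; ties broken by name."""
    if matrix.values.shape[0] == 0:
        raise ValueError("empty matrix")
    scores = np.abs(matrix.values).mean(axis=0)
    pairs = list(zip(matrix.feature_names, scores.tolist()))
    return sorted(pairs, key=lambda p: (-p[1], p[0]))


def export_decision_and_dependence(matrix: ShapMatrix, samples: np.ndarray
                                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabular exports backing decision and dependence plots.

    Decision export: per-sample cumulative sums of phi starting from the
    base value, features ordered by ascending global importance so the last
    (most important) step lands on the prediction. Dependence export:
    (feature value, phi) pairs per feature.
    """
    samples = np.atleast_2d(np.asarray(samples, float))
    if samples.shape != matrix.values.shape:
        raise ValueError("samples not aligned with the Shapley matrix")
    order = [name for name, _ in reversed(global_importance(matrix))]
    idx = [matrix.feature_names.index(n) for n in order]
    decision_rows = []
    for s in range(matrix.values.shape[0]):
        cum = matrix.base_value
        for name, j in zip(order, idx):
            cum += matrix.values[s, j]
            decision_rows.append({"sample": s, "feature": name,
                                  "phi": matrix.values[s, j], "cumulative": cum})
    dependence_rows = []
    for j, name in enumerate(matrix.feature_names):
        for s in range(samples.shape[0]):
            dependence_rows.append({"feature": name, "value": samples[s, j],
                                    "phi": matrix.values[s, j], "sample": s})
    return pd.DataFrame(decision_rows), pd.DataFrame(dependence_rows)
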