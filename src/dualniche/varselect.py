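"""Collinearity screening of predictor tables before modelling.

Greedy Pearson filter: while any pair of surviving columns has |r| at or
above the threshold, remove the lower-importance member of the worst
(highest-|r|) pair. The surviving set therefore has all pairwise |r| below
the threshold. Importance defaults to equal, with ties broken by keeping
the lexicographically smaller name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SelectionReport:
    kept: list[str]
    dropped: list[tuple[str, str | None, float]]  # (name, partner, r)
    importance: dict[str, float] = field(default_factory=dict)

    @property
    def dropped_names(self) -> list[str]:
        return [d[0] for d in self.dropped]


def correlation_filter(samples: pd.DataFrame, threshold: float = 0.8,
                       importance: dict[str, float] | None = None) -> SelectionReport:
    """Greedy elimination of collinear columns (|Pearson r| >= threshold).

    Constant columns have undefined correlations and are dropped up front
    with a warning (partner None, r NaN).
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 rows to estimate correlations")
    names = list(samples.columns)
    importance = dict(importance or {})
    dropped: list[tuple[str, str | None, float]] = []

    alive = []
    for n in names:
        col = samples[n].to_numpy(float)
        if np.isclose(col.std(), 0):
            warnings.warn(f"column {n!r} is constant; dropped (undefined r)")
            dropped.append((n, None, float("nan")))
        else:
            alive.append(n)

    def score(n: str) -> float:
        return importance.get(n, 0.0)

    corr = samples[alive].corr(method="pearson").abs() if alive else pd.DataFrame()
    while len(alive) >= 2:
        sub = corr.loc[alive, alive].to_numpy().copy()
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        r = sub[i, j]
        if r < threshold:
            break
        a, b = alive[i], alive[j]
        # drop the lower-importance member; tie -> keep smaller name
        if (score(a), b) < (score(b), a):
            loser, partner = a, b
        else:
            loser, partner = b, a
        dropped.append((loser, partner, float(corr.loc[loser, partner])))
        alive.remove(loser)

    return SelectionReport(kept=alive, dropped=dropped, importance=importance)


def model_importance(ensemble, samples: pd.DataFrame | None = None) -> dict[str, float]:
    """Mean impurity-based feature importances across ensemble members,
    normalised to sum to 1."""
    members = getattr(ensemble, "members", None)
    if members is None:
        members = [ensemble]
    mats = []
    for m in members:
        if not hasattr(m, "feature_importances_"):
            raise ValueError("model is not fitted (no feature_importances_)")
        mats.append(np.asarray(m.feature_importances_, float))
    mean = np.mean(mats, axis=0)
    total = mean.sum()
    if total > 0:
        mean = mean / total
    names = getattr(ensemble, "feature_names", None)
    if names is None:
        names = list(samples.columns) if samples is not None else [
            f"f{i}" for i in range(len(mean))]
    return dict(zip(names, mean.tolist()))
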