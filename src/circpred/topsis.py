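"""TOPSIS multi-criteria ranking of alternatives (e.g. kernel functions).

TOPSIS (Technique for Order of Preference by Similarity to Ideal Solution)
scores each alternative by its relative closeness to a per-criterion ideal
point: vector-normalize each criterion column, apply criterion weights, form
the ideal (best per criterion) and anti-ideal (worst) points, and score
100 * d-/(d+ + d-) from the Euclidean distances to each.  Scores lie in
[0, 100]; a dominant alternative scores 100 and a dominated one 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class DecisionMatrix:
    """Alternatives x criteria values with weights and optimization senses."""

    values: pd.DataFrame
    weights: Sequence[float] | None = None  # default: equal
    directions: Sequence[str] | None = None  # 'benefit' (max) or 'cost' (min)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("decision matrix contains missing values")
        n_crit = self.values.shape[1]
        if self.weights is None:
            self.weights = np.full(n_crit, 1.0 / n_crit)
        else:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != n_crit or np.any(w <= 0):
                raise ValueError("weights must be positive, one per criterion")
            self.weights = w / w.sum()
        if self.directions is None:
            self.directions = ["benefit"] * n_crit
        elif len(self.directions) != n_crit or not set(self.directions) <= {
            "benefit",
            "cost",
        }:
            raise ValueError("directions must be 'benefit'/'cost', one per criterion")


def topsis_score(dm: DecisionMatrix) -> pd.Series:
    """Closeness scores in [0, 100], indexed by alternative, descending-rankable.

    Constant criterion columns carry no preference information and make the
    vector normalization degenerate; they are dropped with a warning.
    """
    if dm.values.shape[0] < 2:
        raise ValueError("TOPSIS needs at least 2 alternatives")
    V = dm.values.to_numpy(dtype=float)
    weights = np.asarray(dm.weights, dtype=float)
    directions = list(dm.directions)

    keep = V.std(axis=0) > 0
    if not keep.all():
        dropped = list(dm.values.columns[~keep])
        warnings.warn(f"dropping constant criterion column(s): {dropped}")
        V = V[:, keep]
        weights = weights[keep]
        directions = [d for d, k in zip(directions, keep) if k]
    if V.shape[1] == 0:
        raise ValueError("no informative criteria remain")
    weights = weights / weights.sum()

    norms = np.linalg.norm(V, axis=0)
    norms[norms == 0] = 1.0
    W = (V / norms) * weights

    benefit = np.array([d == "benefit" for d in directions])
    ideal = np.where(benefit, W.max(axis=0), W.min(axis=0))
    anti = np.where(benefit, W.min(axis=0), W.max(axis=0))
    d_plus = np.linalg.norm(W - ideal, axis=1)
    d_minus = np.linalg.norm(W - anti, axis=1)
    denom = d_plus + d_minus
    denom[denom == 0] = 1.0  # identical alternatives: define score 0
    return pd.Series(100.0 * d_minus / denom, index=dm.values.index, name="topsis")


def build_kernel_decision_matrix(
    metrics_by_kernel: Mapping[str, Mapping[str, Mapping[str, float]]],
    criteria: Sequence[str] = ("TPR", "TNR", "accuracy", "PPV", "auROC", "auPR"),
) -> DecisionMatrix:
    """Row-concatenate per-bin metric blocks into one benefit-only matrix.

    ``metrics_by_kernel[kernel][bin][metric]`` -> columns named "bin:metric"
    (e.g. 24 criteria for 4 bins x 6 metrics), suitable for an overall
    kernel ranking.
    """
    kernels = list(metrics_by_kernel)
    bins = list(next(iter(metrics_by_kernel.values())))
    data = {}
    for b in bins:
        for c in criteria:
            data[f"{b}:{c}"] = [metrics_by_kernel[k][b][c] for k in kernels]
    return DecisionMatrix(values=pd.DataFrame(data, index=kernels))
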