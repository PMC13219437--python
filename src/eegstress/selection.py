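"""Information-gain feature ranking against the binary stress label.

Each continuous feature column is discretized (equal-frequency by default,
equal-width or supervised entropy-minimization with an MDL stopping rule as
alternatives) and scored by the reduction in label entropy:
InG(A) = H(Y) - H(Y | A), in bits. Columns are ranked by gain, ties broken
lexicographically by name, and the top-k form the selected subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import LABEL_COLUMN


@dataclass(frozen=True)
class DiscretizationSpec:
    """How to bin a continuous feature before the gain computation."""

    method: str = "equal_frequency"
    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.method not in ("equal_width", "equal_frequency", "supervised_mdl"):
            raise ValueError(f"unknown discretization method {self.method!r}")
        if self.method != "supervised_mdl" and self.n_bins < 2:
            raise ValueError("n_bins must be >= 2 for unsupervised binning")


@dataclass(frozen=True)
class RankedFeatures:
    """Full non-increasing ranking plus the selected top-k subset."""

    ranking: tuple[tuple[str, float], ...]
    selected: tuple[str, ...]

    def gain(self, column: str) -> float:
        for name, g in self.ranking:
            if name == column:
                return g
        raise KeyError(column)

    def to_frame(self) -> pd.DataFrame:
        sel = set(self.selected)
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranking) + 1),
                "column": [c for c, _ in self.ranking],
                "gain_bits": [g for _, g in self.ranking],
                "selected": [c in sel for c, _ in self.ranking],
            }
        )


def entropy_of_labels(labels) -> float:
    """Empirical Shannon entropy of the class distribution in bits."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("need at least one label")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return -float(np.sum(p * np.log2(p)))


def conditional_entropy(feature_bins, labels) -> float:
    """Label entropy remaining after splitting on a discrete feature, in bits."""
    feature_bins = np.asarray(feature_bins)
    labels = np.asarray(labels)
    if feature_bins.size != labels.size:
        raise ValueError("feature and label vectors differ in length")
    n = labels.size
    total = 0.0
    for v in np.unique(feature_bins):
        mask = feature_bins == v
        total += (mask.sum() / n) * entropy_of_labels(labels[mask])
    return total


def discretize(values, labels, spec: DiscretizationSpec) -> np.ndarray:
    """Integer bin codes for a continuous column under ``spec``.

    equal_width spans [min, max]; equal_frequency cuts at empirical
    quantiles (duplicate edges merged, so heavily tied columns may produce
    fewer bins); supervised_mdl recursively splits at entropy-minimizing
    cut points, accepting a split only if it passes the minimum description
    length criterion, and ignores ``n_bins``.
    """
    x = np.asarray(values, dtype=float)
    if spec.method == "supervised_mdl":
        cuts = _mdl_cut_points(x, np.asarray(labels))
        return np.searchsorted(cuts, x, side="right")
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        return np.zeros(x.size, dtype=int)
    if spec.method == "equal_width":
        edges = np.linspace(lo, hi, spec.n_bins + 1)
    else:  # equal_frequency
        qs = np.linspace(0, 1, spec.n_bins + 1)
        edges = np.unique(np.quantile(x, qs))
        if edges.size < 2:
            return np.zeros(x.size, dtype=int)
    codes = np.searchsorted(edges[1:-1], x, side="right")
    return codes.astype(int)


def information_gain(
    feature_values, labels, disc: DiscretizationSpec | None = None
) -> float:
    """InG(A) = H(Y) - H(Y|A) in bits after discretizing the feature.

    Clipped at 0 to absorb negative floating-point residue; bounded above
    by H(Y).
    """
    disc = disc or DiscretizationSpec()
    labels = np.asarray(labels)
    bins = discretize(feature_values, labels, disc)
    gain = entropy_of_labels(labels) - conditional_entropy(bins, labels)
    return max(gain, 0.0)


def rank_and_select(
    table: pd.DataFrame, k: int = 10, disc: DiscretizationSpec | None = None
) -> RankedFeatures:
    """Gain for every feature column, sorted non-increasing; top-k selected.

    ``table`` must carry the binary label column. Ties are broken by column
    name so the ranking is deterministic.
    """
    if LABEL_COLUMN not in table.columns:
        raise ValueError("feature table carries no label column")
    if k <= 0:
        raise ValueError("k must be positive")
    disc = disc or DiscretizationSpec()
    labels = table[LABEL_COLUMN].to_numpy()
    columns = [c for c in table.columns if c != LABEL_COLUMN]
    if k > len(columns):
        raise ValueError(f"k={k} exceeds the {len(columns)} feature columns")
    gains = {
        c: information_gain(table[c].to_numpy(), labels, disc) for c in columns
    }
    ordered = sorted(gains.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankedFeatures(
        ranking=tuple(ordered), selected=tuple(c for c, _ in ordered[:k])
    )


def _mdl_cut_points(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Entropy-minimization cut points with the MDL acceptance criterion.

    Recursively evaluates boundary cut points of the sorted column; a split
    is kept only when the information gain exceeds
    (log2(n-1) + log2(3^c - 2) - c0*H0 + c1*H1 + c2*H2 terms) / n,
    the standard minimum-description-length stopping rule.
    """
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    cuts: list[float] = []
    _mdl_split(xs, ys, cuts)
    return np.asarray(sorted(cuts))


def _class_entropy_counts(y: np.ndarray) -> tuple[float, int]:
    _, counts = np.unique(y, return_counts=True)
    p = counts / y.size
    return -float(np.sum(p * np.log2(p))), counts.size


def _mdl_split(xs: np.ndarray, ys: np.ndarray, cuts: list[float]) -> None:
    n = xs.size
    if n < 4:
        return
    h_parent, k_parent = _class_entropy_counts(ys)
    if k_parent < 2:
        return
    # candidate cut indices: boundaries between distinct adjacent values
    change = np.nonzero(np.diff(xs) > 0)[0]
    if change.size == 0:
        return
    best = None
    for i in change:
        left, right = ys[: i + 1], ys[i + 1 :]
        h_l, _ = _class_entropy_counts(left)
        h_r, _ = _class_entropy_counts(right)
        h_split = (left.size * h_l + right.size * h_r) / n
        if best is None or h_split < best[0]:
            best = (h_split, i, h_l, h_r)
    assert best is not None
    h_split, i, h_l, h_r = best
    gain = h_parent - h_split
    _, k_l = _class_entropy_counts(ys[: i + 1])
    _, k_r = _class_entropy_counts(ys[i + 1 :])
    delta = (
        math.log2(3**k_parent - 2)
        - (k_parent * h_parent - k_l * h_l - k_r * h_r)
    )
    threshold = (math.log2(n - 1) + delta) / n
    if gain <= threshold:
        return
    cuts.append(float((xs[i] + xs[i + 1]) / 2.0))
    _mdl_split(xs[: i + 1], ys[: i + 1], cuts)
    _mdl_split(xs[i + 1 :], ys[i + 1 :], cuts)
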