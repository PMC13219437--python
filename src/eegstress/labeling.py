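"""PSQ-score thresholding into stressed / non-stressed / excluded.

The cohort's Perceived Stress Questionnaire scores define two symmetric
thresholds mu -/+ sigma/2. Scores strictly below the lower threshold are
non-stressed, strictly above the upper are stressed, and the intermediate
band (boundary equality included) is excluded from the binary problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import LABEL_COLUMN

STRESSED = "stressed"
NON_STRESSED = "non_stressed"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class LabelingRule:
    """Cohort PSQ moments and the derived symmetric thresholds."""

    mu: float
    sigma: float
    t_low: float = field(init=False)
    t_high: float = field(init=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu) or not np.isfinite(self.sigma):
            raise ValueError("mu and sigma must be finite")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        object.__setattr__(self, "t_low", self.mu - self.sigma / 2.0)
        object.__setattr__(self, "t_high", self.mu + self.sigma / 2.0)


def compute_thresholds(psq_scores) -> LabelingRule:
    """Fit the labeling rule to a cohort's scores.

    Uses the arithmetic mean and the sample (n-1) standard deviation, the
    same divisor convention as the feature kernel's std.
    """
    scores = np.asarray(psq_scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 PSQ scores")
    if not np.isfinite(scores).all():
        raise ValueError("PSQ scores must be finite")
    return LabelingRule(mu=float(scores.mean()), sigma=float(scores.std(ddof=1)))


def assign_labels(scores: pd.DataFrame, rule: LabelingRule) -> pd.DataFrame:
    """Three-way label for every subject.

    ``scores`` must hold columns ``subject_id`` and ``psq_score``; the result
    holds ``subject_id`` and ``label``. Non-finite scores are reported
    per-subject in one error.
    """
    required = {"subject_id", "psq_score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores table needs columns {sorted(required)}")
    psq = scores["psq_score"].to_numpy(dtype=float)
    bad = scores.loc[~np.isfinite(psq), "subject_id"].tolist()
    if bad:
        raise ValueError(f"non-finite PSQ score for subject(s): {bad}")
    label = np.where(
        psq < rule.t_low, NON_STRESSED,
        np.where(psq > rule.t_high, STRESSED, EXCLUDED),
    )
    return pd.DataFrame(
        {"subject_id": scores["subject_id"].to_numpy(), LABEL_COLUMN: label}
    )


def _instance_subject(instance_id: str) -> str:
    """Subject behind an instance id ("subj" or "subj@offset")."""
    return str(instance_id).split("@", 1)[0]


def attach_labels(table: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Join binary labels onto a feature table and drop excluded subjects.

    Works for both per-subject and per-segment tables (segment instance ids
    carry their subject as the "subject@offset" prefix). Raises if any
    instance's subject is unlabeled or if every subject is excluded.
    """
    lab = labels.set_index(labels["subject_id"].astype(str))[LABEL_COLUMN]
    subjects = [_instance_subject(i) for i in table.index]
    unlabeled = sorted({s for s in subjects if s not in lab.index})
    if unlabeled:
        raise ValueError(f"no PSQ label for subject(s): {unlabeled}")
    assigned = lab.loc[subjects].to_numpy()
    keep = assigned != EXCLUDED
    if not keep.any():
        raise ValueError(
            "all subjects fall in the excluded PSQ band; nothing to classify"
        )
    out = table.loc[keep].copy()
    out[LABEL_COLUMN] = assigned[keep]
    return out
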