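"""The 20 time-domain EEG descriptors and the instance feature table.

Per window and electrode the package computes: four moment statistics
(mean, std, skew, kurt), extremum amplitudes and latencies with their derived
ratios (pp, ppt, pps, lmin, lmax, amp_max, amp_min, alar, lar), first/second
absolute-difference means in raw and normalized form (mdif1, mdif2,
mdif1norm, mdif2norm), signal energy raw and per-sample (energy,
energy_norm), and an amplitude-histogram Shannon entropy in bits.

Conventions (all deliberate, see docs/methods.md):

* std uses the n-1 divisor; skew and kurt are 1/n sums of the standardized
  third/fourth powers, so a Gaussian gives kurt ~ 3 (not excess).
* Latencies are 1-based first-occurrence sample indices divided by fs, hence
  strictly positive, which keeps alar's denominator safe.
* mdif1/mdif2 divide the valid-index difference sums by N (total samples);
  the "norm" variants divide the same sums by N-1 and N-2.
* Zero-variance windows set skew/kurt (and ratio guards pps, lar) to 0 and
  raise the ``degenerate`` flag instead of dropping the instance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .segmentation import Segment

logger = logging.getLogger(__name__)

#: canonical feature order; the column contract is "<electrode>_<feature>"
FEATURE_NAMES = (
    "mean", "std", "kurt", "skew", "pp", "ppt", "pps", "lmin",
    "amp_max", "amp_min", "alar", "mdif1", "mdif2", "lmax",
    "mdif1norm", "mdif2norm", "energy", "energy_norm", "lar", "entropy",
)

LABEL_COLUMN = "label"

_degenerate_logged = False


@dataclass(frozen=True)
class FeatureOptions:
    """Tunables of the feature kernel.

    entropy_bins
        number of equal-width amplitude histogram bins (default 64).
    entropy_signed
        True gives the Shannon form -sum c log2 c (non-negative); False gives
        the raw signed sum (an "as-printed" toggle, always <= 0).
    """

    entropy_bins: int = 64
    entropy_signed: bool = True

    def __post_init__(self) -> None:
        if self.entropy_bins < 2:
            raise ValueError("entropy_bins must be >= 2")


@dataclass(frozen=True)
class FeatureVector:
    """The 20 named values for one window plus a degenerate-window flag."""

    values: Mapping[str, float]
    degenerate: bool

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[f] for f in FEATURE_NAMES])


def compute_moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, sample std (n-1), and Pearson-standardized skew and kurtosis.

    Constant input is degenerate: std is 0 and skew/kurt are reported as 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples for moments")
    mean = float(np.mean(x))
    std = float(np.std(x, ddof=1))
    if std == 0.0:
        _log_degenerate_once()
        return mean, 0.0, 0.0, 0.0
    z = (x - mean) / std
    skew = float(np.mean(z**3))
    kurt = float(np.mean(z**4))
    return mean, std, skew, kurt


def compute_extrema_features(
    x: np.ndarray, fs: float
) -> tuple[float, float, float, float, float, float, float, float, float]:
    """Extremum amplitudes, 1-based first-occurrence latencies, and ratios.

    Returns (amp_max, amp_min, lmax, lmin, pp, ppt, pps, alar, lar).
    pps is 0 when the two extrema coincide in time; lar is 0 when the
    maximum amplitude is 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample vector")
    if fs <= 0:
        raise ValueError("fs must be positive")
    amp_max = float(np.max(x))
    amp_min = float(np.min(x))
    lmax = (int(np.argmax(x)) + 1) / fs
    lmin = (int(np.argmin(x)) + 1) / fs
    pp = amp_max - amp_min
    ppt = abs(lmax - lmin)
    pps = pp / ppt if ppt > 0 else 0.0
    alar = abs(amp_max) / lmax
    lar = lmax / amp_max if amp_max != 0 else 0.0
    return amp_max, amp_min, lmax, lmin, pp, ppt, pps, alar, lar


def compute_difference_features(
    x: np.ndarray,
) -> tuple[float, float, float, float]:
    """First/second absolute-difference sums under the four printed divisors.

    With S1 = sum |x[n] - x[n-1]| over the N-1 adjacent pairs and
    S2 = sum |x[n+1] - 2 x[n] + x[n-1]| over the N-2 interior points:
    mdif1 = S1/N, mdif1norm = S1/(N-1), mdif2 = S2/N, mdif2norm = S2/(N-2).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples for difference features")
    d1 = np.abs(np.diff(x))
    d2 = np.abs(np.diff(x, n=2))
    s1 = float(d1.sum())
    s2 = float(d2.sum())
    return s1 / n, s2 / n, s1 / (n - 1), s2 / (n - 2)


def compute_energy(x: np.ndarray) -> tuple[float, float]:
    """Signal energy sum(x^2) and its per-sample normalization."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample vector")
    energy = float(np.sum(x * x))
    return energy, energy / x.size


def compute_entropy(
    x: np.ndarray, n_bins: int = 64, signed: bool = True
) -> float:
    """Amplitude-histogram Shannon entropy in bits.

    Equal-width bins span [min(x), max(x)]; a constant vector occupies a
    single bin and has zero entropy. ``signed=False`` drops the leading
    minus (the raw sum of c*log2(c), which is <= 0).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample vector")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    ent = -float(np.sum(p * np.log2(p)))
    return ent if signed else -ent


def extract_features(
    seg: Segment, options: FeatureOptions | None = None
) -> FeatureVector:
    """All 20 descriptors for one segment, composed from the kernels above."""
    options = options or FeatureOptions()
    x = np.asarray(seg.samples, dtype=float)
    if x.size < 3:
        raise ValueError("segment must hold at least 3 samples")
    mean, std, skew, kurt = compute_moments(x)
    amp_max, amp_min, lmax, lmin, pp, ppt, pps, alar, lar = (
        compute_extrema_features(x, seg.fs)
    )
    mdif1, mdif2, mdif1norm, mdif2norm = compute_difference_features(x)
    energy, energy_norm = compute_energy(x)
    entropy = compute_entropy(x, options.entropy_bins, options.entropy_signed)
    values = {
        "mean": mean, "std": std, "kurt": kurt, "skew": skew,
        "pp": pp, "ppt": ppt, "pps": pps, "lmin": lmin,
        "amp_max": amp_max, "amp_min": amp_min, "alar": alar,
        "mdif1": mdif1, "mdif2": mdif2, "lmax": lmax,
        "mdif1norm": mdif1norm, "mdif2norm": mdif2norm,
        "energy": energy, "energy_norm": energy_norm,
        "lar": lar, "entropy": entropy,
    }
    return FeatureVector(values=values, degenerate=(std == 0.0))


def _feature_matrix(
    X: np.ndarray, fs: float, options: FeatureOptions
) -> np.ndarray:
    """Vectorized kernel: rows of ``X`` are windows, output is rows x 20.

    Kept numerically identical to the per-segment path (which the oracle
    tests exercise); only the entropy histogram needs a Python loop.
    """
    X = np.asarray(X, dtype=float)
    n_rows, n = X.shape
    if n < 3:
        raise ValueError("windows must hold at least 3 samples")
    mean = X.mean(axis=1)
    std = X.std(axis=1, ddof=1)
    ok = std > 0
    z = np.zeros_like(X)
    np.divide(X - mean[:, None], std[:, None], out=z, where=ok[:, None])
    skew = np.where(ok, (z**3).mean(axis=1), 0.0)
    kurt = np.where(ok, (z**4).mean(axis=1), 0.0)
    if not ok.all():
        _log_degenerate_once()

    amp_max = X.max(axis=1)
    amp_min = X.min(axis=1)
    lmax = (X.argmax(axis=1) + 1) / fs
    lmin = (X.argmin(axis=1) + 1) / fs
    pp = amp_max - amp_min
    ppt = np.abs(lmax - lmin)
    pps = np.divide(pp, ppt, out=np.zeros(n_rows), where=ppt > 0)
    alar = np.abs(amp_max) / lmax
    lar = np.divide(lmax, amp_max, out=np.zeros(n_rows), where=amp_max != 0)

    s1 = np.abs(np.diff(X, axis=1)).sum(axis=1)
    s2 = np.abs(np.diff(X, n=2, axis=1)).sum(axis=1)
    energy = (X * X).sum(axis=1)

    entropy = np.empty(n_rows)
    for i in range(n_rows):
        entropy[i] = compute_entropy(
            X[i], options.entropy_bins, options.entropy_signed
        )

    cols = {
        "mean": mean, "std": std, "kurt": kurt, "skew": skew,
        "pp": pp, "ppt": ppt, "pps": pps, "lmin": lmin,
        "amp_max": amp_max, "amp_min": amp_min, "alar": alar,
        "mdif1": s1 / n, "mdif2": s2 / n, "lmax": lmax,
        "mdif1norm": s1 / (n - 1), "mdif2norm": s2 / (n - 2),
        "energy": energy, "energy_norm": energy / n,
        "lar": lar, "entropy": entropy,
    }
    return np.column_stack([cols[f] for f in FEATURE_NAMES])


def feature_columns(electrodes: Iterable[str]) -> list[str]:
    """Column names under the "<electrode>_<feature>" contract."""
    return [f"{e}_{f}" for e in electrodes for f in FEATURE_NAMES]


def build_feature_table(
    segments: Iterable[Segment],
    aggregation: str = "per_subject_mean",
    options: FeatureOptions | None = None,
) -> pd.DataFrame:
    """Assemble the instances x (electrode, feature) table.

    ``per_subject_mean`` averages each (electrode, feature) over a subject's
    windows, giving one row per subject indexed by subject id.
    ``per_segment`` gives one row per (subject, window offset) with the
    electrodes side by side, indexed by "<subject>@<start_s>".

    Every subject must supply the same electrode set with equal window
    counts per electrode; a subject missing a channel is a hard error.
    """
    if aggregation not in ("per_subject_mean", "per_segment"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    options = options or FeatureOptions()

    segs = list(segments)
    if not segs:
        raise ValueError("no segments supplied")
    electrodes: list[str] = []
    for s in segs:
        if s.channel not in electrodes:
            electrodes.append(s.channel)

    # subject -> channel -> list of (start_s, samples)
    by_subject: dict[str, dict[str, list[tuple[float, np.ndarray]]]] = {}
    for s in segs:
        by_subject.setdefault(s.subject_id, {}).setdefault(s.channel, []).append(
            (s.start_s, s.samples)
        )
    fs = segs[0].fs

    rows: list[np.ndarray] = []
    index: list[str] = []
    for subject, by_ch in by_subject.items():
        missing = [e for e in electrodes if e not in by_ch]
        if missing:
            raise ValueError(
                f"subject {subject!r} is missing channel(s) {missing}"
            )
        per_channel: list[np.ndarray] = []
        starts_ref: list[float] | None = None
        for e in electrodes:
            chunk = sorted(by_ch[e], key=lambda t: t[0])
            starts = [c[0] for c in chunk]
            if starts_ref is None:
                starts_ref = starts
            elif starts != starts_ref:
                raise ValueError(
                    f"subject {subject!r}: window offsets differ across channels"
                )
            M = _feature_matrix(
                np.vstack([c[1] for c in chunk]), fs, options
            )
            per_channel.append(M)
        assert starts_ref is not None
        stacked = np.hstack(per_channel)  # windows x (electrodes*20)
        if aggregation == "per_subject_mean":
            rows.append(stacked.mean(axis=0))
            index.append(subject)
        else:
            for i, start in enumerate(starts_ref):
                rows.append(stacked[i])
                index.append(f"{subject}@{start:g}")

    table = pd.DataFrame(
        np.vstack(rows), index=pd.Index(index, name="instance"),
        columns=feature_columns(electrodes),
    )
    if table.index.has_duplicates:
        raise ValueError("duplicate instance identifiers in feature table")
    return table


def _log_degenerate_once() -> None:
    global _degenerate_logged
    if not _degenerate_logged:
        logger.warning(
            "zero-variance window encountered; skew/kurt set to 0 "
            "(reported once per process)"
        )
        _degenerate_logged = True
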