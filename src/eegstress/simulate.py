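"""Synthetic EEG + PSQ cohorts with known class structure.

The generator stands in for a resting-state cohort: each subject gets a
multichannel signal built from a 1/f background, alpha- (8-12 Hz) and
beta-band (13-30 Hz) oscillations with slowly drifting phase, a weak
high-band (40-70 Hz) noise component, occasional impulses, and a mild
amplitude quantization — plus a PSQ score drawn from a class-conditional
normal.

Class structure is planted through per-subject "knobs" (overall amplitude,
DC offset, high-band share, impulse magnitude, quantization step, ...).
Every knob varies between subjects; planting a feature shifts the mean of
its knob for the stressed class by ``effect_size`` times that knob's
between-subject spread, so the standardized between-class difference of the
planted feature is approximately ``effect_size``. Which knob drives which
of the 20 features is fixed in ``KNOB_BY_FEATURE``; the three latency
features (lmin, lmax, ppt) have no controllable knob because window-level
extremum timing is uniform by construction, and requesting them raises a
parameterization error.

Everything is a pure function of ``SimParams`` (including its seed):
per-subject random streams are derived from the cohort seed with the
spawn-key counter scheme ``SeedSequence(seed, spawn_key=(1, subject_index))``,
so subject k is reproducible independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .labeling import NON_STRESSED, STRESSED
from .segmentation import DEFAULT_MONTAGE, EEGRecording

#: knob driving each plantable feature; latency features are absent
KNOB_BY_FEATURE: dict[str, str] = {
    "mean": "dc",
    "std": "amplitude", "pp": "amplitude", "energy": "amplitude",
    "energy_norm": "amplitude", "amp_max": "amplitude",
    "amp_min": "amplitude", "pps": "amplitude", "alar": "amplitude",
    "lar": "amplitude",
    "mdif1": "highband", "mdif2": "highband",
    "mdif1norm": "highband", "mdif2norm": "highband",
    "entropy": "quantization",
    "kurt": "impulse",
    "skew": "impulse_asymmetry",
}

#: between-subject spread of each knob (the unit in which effects are planted)
_KNOB_SD = {
    "dc": 0.05,               # DC offset, units of base signal std
    "amplitude": 0.08,        # log overall amplitude
    "highband": 0.35,         # log high-band variance share
    "quantization": 0.35,     # log quantization step
    "impulse": 0.25,          # log impulse magnitude
    "impulse_asymmetry": 0.08,  # probability an impulse is positive
}


@dataclass(frozen=True)
class SimParams:
    """Cohort-level simulation parameters.

    Defaults are the package's study conditions: 4 electrodes, 250 Hz
    (2500 Hz supported), 480 s per subject, stress prevalence 0.45, and
    class-conditional PSQ normals whose mixture reproduces a cohort mean
    of ~30.2 and SD of ~15.5 on the 0-100 scale.
    """

    n_subjects: int = 120
    channels: tuple[str, ...] = DEFAULT_MONTAGE
    fs: float = 250.0
    duration_s: float = 480.0
    stress_prevalence: float = 0.45
    psq_mean_by_class: tuple[float, float] = (45.6, 17.6)  # (stressed, non)
    psq_sd: float = 6.85
    psq_range: tuple[float, float] = (0.0, 100.0)
    effect_size: float = 1.5
    planted_features: tuple[str, ...] = ("mean", "kurt", "entropy")
    noise_spectrum: Mapping[str, float] = field(
        default_factory=lambda: {
            "alpha_exponent": 1.0,   # 1/f^alpha background slope
            "tonal_fraction": 0.45,  # variance share of the oscillations
            "beta_share": 0.35,      # beta share within the oscillations
            "highband_share": 0.25,  # baseline 40-70 Hz variance share
            "base_amplitude": 10.0,  # overall scale, arbitrary microvolt-ish
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not (0.0 < self.stress_prevalence < 1.0):
            raise ValueError("stress_prevalence must lie strictly in (0, 1)")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if self.psq_sd <= 0:
            raise ValueError("psq_sd must be positive")
        unknown = set(self.planted_features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature name(s): {sorted(unknown)}")
        unplantable = set(self.planted_features) - set(KNOB_BY_FEATURE)
        if unplantable:
            raise ValueError(
                f"feature(s) {sorted(unplantable)} have no generator knob "
                "(window-level extremum timing is uniform by construction)"
            )
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "planted_features", tuple(self.planted_features))

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    def knob_shifts(self) -> dict[str, float]:
        """Class shift per knob: effect_size x that knob's subject spread."""
        shifts: dict[str, float] = {}
        for f in self.planted_features:
            knob = KNOB_BY_FEATURE[f]
            shifts[knob] = self.effect_size * _KNOB_SD[knob]
        return shifts


@dataclass(frozen=True)
class SyntheticCohort:
    recordings: tuple[EEGRecording, ...]
    participants: pd.DataFrame  # subject_id, psq_score, true_class
    params: SimParams


def _subject_rng(params: SimParams, subject_seed: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(1, subject_seed))
    )


def _pink_noise(rng: np.random.Generator, n: int, fs: float, alpha: float) -> np.ndarray:
    """Unit-variance 1/f^alpha noise via spectral shaping."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    shape = np.zeros(freqs.size)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    return x / x.std()


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-variance band-limited white noise (flat passband lo..hi Hz)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        mask = freqs >= freqs.max() / 2  # degenerate very-low fs fallback
    x = np.fft.irfft(spec * mask, n=n)
    return x / x.std()


def _oscillation(
    rng: np.random.Generator, n: int, fs: float, f_lo: float, f_hi: float
) -> np.ndarray:
    """Unit-variance sinusoid with a random carrier and drifting phase."""
    f0 = rng.uniform(f_lo, f_hi)
    phase0 = rng.uniform(0, 2 * np.pi)
    drift = np.cumsum(rng.normal(0.0, 0.05 / np.sqrt(fs), size=n))
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * f0 * t + phase0 + drift)
    return x / x.std()


def simulate_subject(
    true_class: str, params: SimParams, subject_seed: int
) -> tuple[EEGRecording, float]:
    """One subject's recording and PSQ score.

    ``true_class`` is ``"stressed"`` or ``"non_stressed"``; the stressed
    class receives the knob shifts of ``params.knob_shifts()``. The PSQ
    score comes from the class-conditional normal, clipped to
    ``params.psq_range``.
    """
    if true_class not in (STRESSED, NON_STRESSED):
        raise ValueError(f"true_class must be stressed/non_stressed, got {true_class!r}")
    rng = _subject_rng(params, subject_seed)
    spec = dict(params.noise_spectrum)
    shifts = params.knob_shifts() if true_class == STRESSED else {}
    n = params.n_samples
    base_amp = spec["base_amplitude"]

    # subject-level knobs (shared across channels)
    log_amp = rng.normal(shifts.get("amplitude", 0.0), _KNOB_SD["amplitude"])
    dc = base_amp * rng.normal(shifts.get("dc", 0.0), _KNOB_SD["dc"])
    tonal = np.clip(rng.normal(spec["tonal_fraction"], 0.03), 0.05, 0.9)
    beta_share = np.clip(rng.normal(spec["beta_share"], 0.05), 0.05, 0.95)
    log_h = rng.normal(
        np.log(spec["highband_share"]) + shifts.get("highband", 0.0),
        _KNOB_SD["highband"],
    )
    h_share = float(np.clip(np.exp(log_h), 0.0, 0.8))
    quant_step = float(
        np.exp(rng.normal(np.log(0.15) + shifts.get("quantization", 0.0),
                          _KNOB_SD["quantization"]))
    )
    impulse_scale = float(
        np.exp(rng.normal(np.log(1.0) + shifts.get("impulse", 0.0),
                          _KNOB_SD["impulse"]))
    )
    p_positive = float(
        np.clip(rng.normal(0.5 + shifts.get("impulse_asymmetry", 0.0),
                           _KNOB_SD["impulse_asymmetry"]), 0.0, 1.0)
    )

    amp = base_amp * np.exp(log_amp)
    rows = np.empty((len(params.channels), n))
    for c in range(len(params.channels)):
        bg = _pink_noise(rng, n, params.fs, spec["alpha_exponent"])
        osc_a = _oscillation(rng, n, params.fs, 8.0, min(12.0, params.fs / 2 * 0.9))
        osc_b = _oscillation(rng, n, params.fs, 13.0, min(30.0, params.fs / 2 * 0.9))
        high = _band_noise(
            rng, n, params.fs, 40.0, min(70.0, params.fs / 2 * 0.95)
        )
        core = (
            np.sqrt(1.0 - tonal) * bg
            + np.sqrt(tonal * (1.0 - beta_share)) * osc_a
            + np.sqrt(tonal * beta_share) * osc_b
        )
        x = np.sqrt(1.0 - h_share) * core + np.sqrt(h_share) * high
        # sparse impulses (~0.2% of samples) at a few signal SDs
        n_imp = max(1, int(round(0.002 * n)))
        pos = rng.choice(n, size=n_imp, replace=False)
        signs = np.where(rng.random(n_imp) < p_positive, 1.0, -1.0)
        mags = 3.0 * impulse_scale * (1.0 + rng.exponential(0.5, size=n_imp))
        x[pos] += signs * mags
        x = amp * x
        if quant_step > 0:
            q = quant_step * amp
            x = q * np.round(x / q)
        rows[c] = x + dc

    rec = EEGRecording(
        subject_id=f"S{subject_seed:04d}",
        channel_names=params.channels,
        fs=params.fs,
        samples=rows,
    )
    mu_s, mu_n = params.psq_mean_by_class
    mu = mu_s if true_class == STRESSED else mu_n
    psq = float(np.clip(rng.normal(mu, params.psq_sd), *params.psq_range))
    return rec, psq


def simulate_cohort(params: SimParams) -> SyntheticCohort:
    """A full cohort: Bernoulli(prevalence) class flags, one recording and
    PSQ score per subject, all derived from ``params.seed``."""
    assign_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(0,))
    )
    classes = np.where(
        assign_rng.random(params.n_subjects) < params.stress_prevalence,
        STRESSED, NON_STRESSED,
    )
    recordings: list[EEGRecording] = []
    rows = []
    for i, cls in enumerate(classes):
        rec, psq = simulate_subject(str(cls), params, subject_seed=i)
        recordings.append(rec)
        rows.append({"subject_id": rec.subject_id, "psq_score": psq,
                     "true_class": cls})
    return SyntheticCohort(
        recordings=tuple(recordings),
        participants=pd.DataFrame(rows),
        params=params,
    )


def with_params(params: SimParams, **updates) -> SimParams:
    """Convenience: a validated copy of ``params`` with fields replaced."""
    return replace(params, **updates)
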