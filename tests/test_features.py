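"""Feature kernel: hand-worked examples, oracle equivalence, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eegstress import FEATURE_NAMES, FeatureOptions, build_feature_table, extract_features
from eegstress.features import (
    compute_difference_features,
    compute_energy,
    compute_entropy,
    compute_extrema_features,
    compute_moments,
    feature_columns,
)
from eegstress.segmentation import Segment

from _reference import ref_features

ATOL = 1e-9


def seg(x, fs=1.0, subject="S0", channel="AF7", start=0.0):
    return Segment(
        subject_id=subject, channel=channel, start_s=start, fs=fs,
        samples=np.asarray(x, dtype=float),
    )


class TestMoments:
    def test_hand_example(self):
        mean, std, skew, kurt = compute_moments(np.array([1, 2, 3, 4, 5.0]))
        assert mean == 3.0
        assert std == pytest.approx(math.sqrt(2.5))
        assert skew == pytest.approx(0.0, abs=ATOL)

    def test_constant_vector_is_degenerate(self):
        mean, std, skew, kurt = compute_moments(np.full(10, 7.0))
        assert (mean, std, skew, kurt) == (7.0, 0.0, 0.0, 0.0)

    def test_gaussian_limits(self, rng):
        x = rng.standard_normal(100_000)
        _, _, skew, kurt = compute_moments(x)
        assert abs(skew) < 0.05
        assert abs(kurt - 3.0) < 0.1


class TestExtrema:
    def test_hand_example_one_based_latency(self):
        amp_max, amp_min, lmax, lmin, pp, ppt, pps, alar, lar = (
            compute_extrema_features(np.array([0.0, 3.0, -1.0, 2.0]), fs=1.0)
        )
        assert (amp_max, amp_min) == (3.0, -1.0)
        assert (lmax, lmin) == (2.0, 3.0)
        assert (pp, ppt, pps) == (4.0, 1.0, 4.0)
        assert alar == pytest.approx(1.5)
        assert lar == pytest.approx(2.0 / 3.0)

    def test_constant_vector_guards(self):
        amp_max, amp_min, lmax, lmin, pp, ppt, pps, alar, lar = (
            compute_extrema_features(np.full(5, 2.0), fs=10.0)
        )
        assert pp == 0.0 and ppt == 0.0 and pps == 0.0
        assert lmax == lmin == 0.1  # first occurrence, 1-based

    def test_maximum_at_first_sample_has_positive_latency(self):
        out = compute_extrema_features(np.array([5.0, 1.0, 2.0]), fs=2.0)
        amp_max, _, lmax = out[0], out[1], out[2]
        assert lmax == 0.5
        assert out[7] == pytest.approx(amp_max / lmax)  # alar finite


class TestDifferences:
    def test_first_difference_divisors(self):
        mdif1, _, mdif1norm, _ = compute_difference_features(np.array([0.0, 1.0, 3.0]))
        assert mdif1 == pytest.approx(1.0)
        assert mdif1norm == pytest.approx(1.5)

    def test_second_difference_divisors(self):
        _, mdif2, _, mdif2norm = compute_difference_features(
            np.array([0.0, 1.0, 3.0, 4.0])
        )
        assert mdif2 == pytest.approx(0.5)
        assert mdif2norm == pytest.approx(1.0)

    def test_dc_offset_cancels(self, rng):
        x = rng.standard_normal(50)
        a = compute_difference_features(x)
        b = compute_difference_features(x + 17.3)
        assert a == pytest.approx(b, abs=1e-10)

    def test_short_vector_rejected(self):
        with pytest.raises(ValueError):
            compute_difference_features(np.array([1.0, 2.0]))


class TestEnergy:
    def test_hand_example(self):
        assert compute_energy(np.array([1.0, 2.0, 2.0])) == (9.0, 3.0)

    def test_zeros(self):
        assert compute_energy(np.zeros(4)) == (0.0, 0.0)

    def test_quadratic_scaling(self, rng):
        x = rng.standard_normal(30)
        e1, n1 = compute_energy(x)
        e2, n2 = compute_energy(3.0 * x)
        assert e2 == pytest.approx(9.0 * e1)
        assert n2 == pytest.approx(9.0 * n1)


class TestEntropy:
    def test_constant_vector_zero(self):
        assert compute_entropy(np.full(100, 1.0)) == 0.0

    def test_two_equal_bins_one_bit(self):
        x = np.array([0.0] * 50 + [1.0] * 50)
        assert compute_entropy(x, n_bins=2) == pytest.approx(1.0)

    def test_uniform_limit_log2_bins(self, rng):
        x = rng.random(1_000_000)
        assert compute_entropy(x, n_bins=64) == pytest.approx(6.0, abs=0.01)

    def test_as_printed_toggle_negates(self, rng):
        x = rng.standard_normal(500)
        assert compute_entropy(x, signed=False) == -compute_entropy(x, signed=True)


class TestExtractFeatures:
    def test_toy_segment_matches_loop_oracle(self):
        s = seg([0.0, 1.0, 3.0, 4.0, 1.0], fs=1.0)
        fv = extract_features(s, FeatureOptions(entropy_bins=2))
        ref = ref_features(s.samples, fs=1.0, n_bins=2)
        for name in FEATURE_NAMES:
            assert fv[name] == pytest.approx(ref[name], abs=ATOL), name

    def test_composition_matches_suboperations(self, rng):
        x = rng.standard_normal(64)
        fv = extract_features(seg(x, fs=8.0))
        mean, std, skew, kurt = compute_moments(x)
        assert fv["mean"] == mean and fv["std"] == std
        assert fv["skew"] == skew and fv["kurt"] == kurt
        e, en = compute_energy(x)
        assert fv["energy"] == e and fv["energy_norm"] == en

    def test_constant_segment_sets_degenerate_flag(self):
        fv = extract_features(seg(np.full(10, 3.0)))
        assert fv.degenerate
        for name in ("pp", "ppt", "pps", "mdif1", "mdif2", "skew", "kurt"):
            assert fv[name] == 0.0

    def test_oracle_equivalence_random_vectors(self, rng):
        """1000 random windows: vectorized kernel == straight-loop oracle."""
        for _ in range(1000):
            n = rng.integers(8, 96)
            kind = rng.integers(3)
            if kind == 0:
                x = rng.standard_normal(n)
            elif kind == 1:
                x = rng.integers(-5, 6, size=n).astype(float)
            else:
                x = np.cumsum(rng.standard_normal(n))
            fs = float(rng.choice([1.0, 100.0, 250.0]))
            fv = extract_features(seg(x, fs=fs), FeatureOptions(entropy_bins=16))
            ref = ref_features(x, fs=fs, n_bins=16)
            for name in FEATURE_NAMES:
                assert fv[name] == pytest.approx(
                    ref[name], rel=1e-9, abs=1e-9
                ), f"{name} on n={n}"


@st.composite
def windows(draw):
    n = draw(st.integers(min_value=8, max_value=64))
    vals = draw(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=n, max_size=n,
        )
    )
    return np.asarray(vals)


class TestInvariances:
    @given(x=windows(), c=st.floats(min_value=-20, max_value=20, allow_nan=False))
    def test_dc_shift(self, x, c):
        a = extract_features(seg(x))
        b = extract_features(seg(x + c))
        for name in ("std", "skew", "kurt", "pp", "ppt", "pps",
                     "mdif1", "mdif2", "mdif1norm", "mdif2norm"):
            assert b[name] == pytest.approx(a[name], rel=1e-7, abs=1e-7), name
        assert b["mean"] == pytest.approx(a["mean"] + c, rel=1e-9, abs=1e-7)

    @given(
        x=st.lists(st.integers(min_value=-100, max_value=100),
                   min_size=8, max_size=64),
        a=st.floats(min_value=0.1, max_value=10, allow_nan=False),
    )
    def test_amplitude_scaling(self, x, a):
        # grid-valued windows: scaling by a cannot collapse distinct values
        # into float ties, which would move first-occurrence latencies
        x = np.asarray(x, dtype=float) / 2.0
        f0 = extract_features(seg(x))
        f1 = extract_features(seg(a * x))
        for name in ("std", "pp", "pps", "mdif1", "mdif2",
                     "mdif1norm", "mdif2norm"):
            assert f1[name] == pytest.approx(a * f0[name], rel=1e-7, abs=1e-7), name
        assert f1["energy"] == pytest.approx(a * a * f0["energy"], rel=1e-7, abs=1e-9)
        for name in ("skew", "kurt", "entropy"):
            assert f1[name] == pytest.approx(f0[name], rel=1e-7, abs=1e-7), name

    @given(x=windows())
    def test_time_reversal(self, x):
        f0 = extract_features(seg(x))
        f1 = extract_features(seg(x[::-1].copy()))
        for name in ("mean", "std", "skew", "kurt", "pp", "energy", "entropy"):
            assert f1[name] == pytest.approx(f0[name], rel=1e-9, abs=1e-9), name

    @given(x=windows())
    def test_structural_invariants(self, x):
        fv = extract_features(seg(x, fs=4.0))
        n = len(x)
        assert fv["pp"] >= 0
        assert fv["amp_max"] >= fv["amp_min"]
        assert fv["energy"] >= 0
        assert fv["energy"] == pytest.approx(n * fv["energy_norm"], rel=1e-12)
        assert 0 < fv["lmin"] <= n / 4.0
        assert 0 < fv["lmax"] <= n / 4.0
        assert fv["entropy"] >= 0


class TestFeatureTable:
    def _segments(self, n_subjects=2, n_windows=2, channels=("AF7", "AF8"),
                  seed=0, identical=False):
        rng = np.random.default_rng(seed)
        out = []
        for s in range(n_subjects):
            base = rng.standard_normal(20)
            for ch in channels:
                x_ch = rng.standard_normal(20)
                for w in range(n_windows):
                    x = x_ch if identical else rng.standard_normal(20)
                    out.append(seg(x, fs=2.0, subject=f"S{s}", channel=ch,
                                   start=w * 10.0))
        return out

    def test_default_montage_gives_80_named_columns(self):
        segs = self._segments(channels=("AF7", "AF8", "TP7", "TP8"))
        table = build_feature_table(segs)
        assert table.shape[1] == 80
        assert list(table.columns) == feature_columns(("AF7", "AF8", "TP7", "TP8"))

    def test_single_window_mean_equals_per_segment(self):
        segs = self._segments(n_subjects=1, n_windows=1)
        mean_tbl = build_feature_table(segs, "per_subject_mean")
        seg_tbl = build_feature_table(segs, "per_segment")
        np.testing.assert_allclose(mean_tbl.to_numpy(), seg_tbl.to_numpy())

    def test_identical_windows_mean_is_idempotent(self):
        segs = self._segments(n_subjects=1, n_windows=2, identical=True)
        mean_tbl = build_feature_table(segs, "per_subject_mean")
        seg_tbl = build_feature_table(segs, "per_segment")
        np.testing.assert_allclose(
            mean_tbl.to_numpy()[0], seg_tbl.to_numpy()[0], rtol=1e-12
        )

    def test_missing_channel_names_subject(self):
        segs = self._segments(n_subjects=2)
        segs = [s for s in segs if not (s.subject_id == "S1" and s.channel == "AF8")]
        with pytest.raises(ValueError, match="S1"):
            build_feature_table(segs)
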