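"""Straight-loop reference implementations used as independent oracles.

Deliberately naive: plain Python loops and math, no numpy vectorization, so
they share no code path with the package's kernels.
"""

import math


def ref_features(x, fs, n_bins=64, signed_entropy=True):
    """All 20 descriptors for one window, computed with explicit loops."""
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / (n - 1)
    std = math.sqrt(var)
    if std > 0:
        skew = sum(((v - mean) / std) ** 3 for v in x) / n
        kurt = sum(((v - mean) / std) ** 4 for v in x) / n
    else:
        skew = kurt = 0.0

    amp_max = max(x)
    amp_min = min(x)
    i_max = next(i for i, v in enumerate(x) if v == amp_max)
    i_min = next(i for i, v in enumerate(x) if v == amp_min)
    lmax = (i_max + 1) / fs
    lmin = (i_min + 1) / fs
    pp = amp_max - amp_min
    ppt = abs(lmax - lmin)
    pps = pp / ppt if ppt > 0 else 0.0
    alar = abs(amp_max) / lmax
    lar = lmax / amp_max if amp_max != 0 else 0.0

    s1 = sum(abs(x[i] - x[i - 1]) for i in range(1, n))
    s2 = sum(abs(x[i + 1] - 2 * x[i] + x[i - 1]) for i in range(1, n - 1))
    mdif1 = s1 / n
    mdif2 = s2 / n
    mdif1norm = s1 / (n - 1)
    mdif2norm = s2 / (n - 2)

    energy = sum(v * v for v in x)
    energy_norm = energy / n

    entropy = ref_entropy(x, n_bins, signed_entropy)

    return {
        "mean": mean, "std": std, "kurt": kurt, "skew": skew,
        "pp": pp, "ppt": ppt, "pps": pps, "lmin": lmin,
        "amp_max": amp_max, "amp_min": amp_min, "alar": alar,
        "mdif1": mdif1, "mdif2": mdif2, "lmax": lmax,
        "mdif1norm": mdif1norm, "mdif2norm": mdif2norm,
        "energy": energy, "energy_norm": energy_norm,
        "lar": lar, "entropy": entropy,
    }


def ref_entropy(x, n_bins, signed=True):
    lo, hi = min(x), max(x)
    if lo == hi:
        return 0.0
    width = (hi - lo) / n_bins
    counts = [0] * n_bins
    for v in x:
        idx = int((v - lo) / width)
        if idx == n_bins:  # right edge belongs to the last bin
            idx -= 1
        counts[idx] += 1
    n = len(x)
    ent = -sum(
        (c / n) * math.log2(c / n) for c in counts if c > 0
    )
    return ent if signed else -ent


def ref_label_entropy(labels):
    n = len(labels)
    out = 0.0
    for cls in set(labels):
        p = sum(1 for l in labels if l == cls) / n
        out -= p * math.log2(p)
    return out


def ref_information_gain(feature_bins, labels):
    """InG over already-discrete feature values by direct enumeration."""
    n = len(labels)
    h = ref_label_entropy(labels)
    cond = 0.0
    for v in set(feature_bins):
        sub = [l for b, l in zip(feature_bins, labels) if b == v]
        cond += (len(sub) / n) * ref_label_entropy(sub)
    return h - cond
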